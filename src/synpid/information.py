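"""Pairwise information measures on binary activity rasters.

For a pair of binary neurons (X, Y) observed over time, the total
information their present state carries about their joint future state at
lag ``tau`` is the time-delayed mutual information (TDMI),

    TDMI = I(X_t, Y_t ; X_{t+tau}, Y_{t+tau}),

estimated here by the plug-in method on the empirical distribution over the
16 joint outcomes.  The TDMI is decomposed into redundant, unique and
synergistic components with the minimum-mutual-information (MMI)
redundancy:

    RI = min( I(X_t ; future), I(Y_t ; future) )
    UI(X) = I(X_t ; future) - RI
    UI(Y) = I(Y_t ; future) - RI
    SI = TDMI - max( I(X_t ; future), I(Y_t ; future) )

where ``future = (X_{t+tau}, Y_{t+tau})``.  All quantities are in bits.
MMI guarantees non-negativity of all four components and forces at least
one unique component to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairJointDistribution",
    "PIDComponents",
    "estimate_pair_joint",
    "mutual_information",
    "tdmi",
    "pid_mmi",
    "pid_from_joint_table",
    "pairwise_pid_table",
]

_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class PairJointDistribution:
    """Empirical distribution over (X_t, Y_t, X_{t+tau}, Y_{t+tau}).

    ``probs`` has shape (2, 2, 2, 2) indexed [x_t, y_t, x_fut, y_fut];
    entries are non-negative and sum to one.
    """

    probs: np.ndarray
    sample_count: int
    tau: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2, 2, 2, 2):
            raise ValueError(f"probs must have shape (2,2,2,2), got {p.shape}")
        if np.any(p < -_CLIP_TOL):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {p.sum():.9f}, not 1")
        object.__setattr__(self, "probs", p)

    def as_uv_table(self) -> np.ndarray:
        """Return the 4x4 table over U=(X_t,Y_t) rows and V=(future) columns."""
        return self.probs.reshape(4, 4)


@dataclass(frozen=True)
class PIDComponents:
    """MMI partial information decomposition of a pair's TDMI, in bits."""

    tdmi: float
    ui_x: float
    ui_y: float
    ri: float
    si: float

    @property
    def constant_pair(self) -> bool:
        """True when the pair carried no time-delayed information at all."""
        return self.tdmi <= _CLIP_TOL


def _validate_binary_series(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(x, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return x.astype(np.int64)


def estimate_pair_joint(x, y, tau: int = 1) -> PairJointDistribution:
    """Plug-in joint distribution of a neuron pair's present and lagged state.

    Counts the ``T - tau`` aligned 4-tuples ``(x_t, y_t, x_{t+tau},
    y_{t+tau})`` and normalises to relative frequencies.
    """
    x = _validate_binary_series(x, "x")
    y = _validate_binary_series(y, "y")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = x.size - tau
    if n < 1:
        raise ValueError(f"need T - tau >= 1, got T={x.size}, tau={tau}")
    code = (x[:-tau] * 8 + y[:-tau] * 4 + x[tau:] * 2 + y[tau:]).astype(np.int64)
    counts = np.bincount(code, minlength=16).astype(float)
    return PairJointDistribution(
        probs=(counts / n).reshape(2, 2, 2, 2), sample_count=n, tau=tau
    )


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information I(U;V) in bits from a joint probability table.

    ``joint[u, v]`` is p(u, v); marginals are computed from the table.
    Terms with p(u, v) = 0 contribute zero (the 0 log 0 convention).
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim != 2:
        raise ValueError("joint table must be two-dimensional")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"joint table sums to {total:.9f}, not 1")
    if np.any(p < -_CLIP_TOL):
        raise ValueError("joint table has negative entries")
    pu = p.sum(axis=1, keepdims=True)
    pv = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.ones_like(p)
    np.divide(p, pu * pv, out=ratio, where=mask)
    return float(np.sum(p[mask] * np.log2(ratio[mask])))


def tdmi(joint: PairJointDistribution) -> float:
    """TDMI in bits: MI between (X_t, Y_t) and (X_{t+tau}, Y_{t+tau})."""
    return mutual_information(joint.as_uv_table())


def pid_from_joint_table(probs: np.ndarray) -> PIDComponents:
    """MMI-PID from a (2,2,2,2) probability table [x_t, y_t, x_fut, y_fut]."""
    p = np.asarray(probs, dtype=float)
    total = mutual_information(p.reshape(4, 4))
    # single-source MIs with the joint future state
    mi_x = mutual_information(p.sum(axis=1).reshape(2, 4))
    mi_y = mutual_information(p.sum(axis=0).reshape(2, 4))
    ri = min(mi_x, mi_y)
    ui_x = mi_x - ri
    ui_y = mi_y - ri
    si = total - max(mi_x, mi_y)
    comps = np.array([total, ui_x, ui_y, ri, si])
    if np.any(comps < -1e-9):
        raise ValueError(f"PID component below tolerance: {comps}")
    comps = np.clip(comps, 0.0, None)
    return PIDComponents(*comps)


def pid_mmi(joint: PairJointDistribution) -> PIDComponents:
    """MMI partial information decomposition of a pair's TDMI."""
    return pid_from_joint_table(joint.probs)


def pairwise_pid_table(
    raster,
    positions=None,
    tau: int = 1,
    max_pairs: int = 500_000,
    min_pair_distance_um: float = 0.0,
    seed: int = 0,
):
    """PID of every neuron pair of a binary raster, as a DataFrame.

    Parameters
    ----------
    raster : (T, N) binary array
    positions : optional DataFrame with columns neuron_id, x_um, y_um;
        when given, a distance_um column is added and pairs closer than
        ``min_pair_distance_um`` are dropped.
    max_pairs : cap on the number of pairs; above it a uniform random
        subsample (seeded) is analysed.

    Constant neurons yield zero TDMI and all-zero components; they are kept
    and flagged in the ``constant_pair`` column so downstream normalisation
    can exclude them.
    """
    import pandas as pd

    raster = np.asarray(raster)
    n = raster.shape[1]
    ii, jj = np.triu_indices(n, k=1)
    dist = None
    if positions is not None:
        xy = positions.sort_values("neuron_id")[["x_um", "y_um"]].to_numpy(float)
        if xy.shape[0] != n:
            raise ValueError(
                f"positions cover {xy.shape[0]} neurons, raster has {n}"
            )
        dist = np.hypot(xy[ii, 0] - xy[jj, 0], xy[ii, 1] - xy[jj, 1])
        keep = dist >= min_pair_distance_um
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
    if ii.size > max_pairs:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(ii.size, size=max_pairs, replace=False))
        ii, jj = ii[sel], jj[sel]
        if dist is not None:
            dist = dist[sel]
    rows = []
    for k in range(ii.size):
        joint = estimate_pair_joint(raster[:, ii[k]], raster[:, jj[k]], tau=tau)
        c = pid_mmi(joint)
        rows.append((ii[k], jj[k], c.tdmi, c.ui_x, c.ui_y, c.ri, c.si,
                     c.constant_pair))
    df = pd.DataFrame(
        rows, columns=["i", "j", "tdmi", "ui_x", "ui_y", "ri", "si",
                       "constant_pair"]
    )
    if dist is not None:
        df.insert(2, "distance_um", dist)
    return df
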