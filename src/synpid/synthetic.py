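"""Spatially embedded binary raster generator with known ground truth.

Emulates mesoscale recordings of binarised neural activity: N neurons
scattered uniformly in a square field of view (default 3 mm a side,
nominal 7.5 Hz frame rate), binary activity with temporal persistence, and
pairwise Pearson correlations decaying with inter-neuron distance as

    c(d) = c_inf + (c0 - c_inf) * exp(-d / lambda),

i.e. an exponential decay toward a non-zero asymptote, the structure a
correlation-length analysis is designed to recover.  Optional XOR-coupled
triplets plant purely synergistic time-delayed interactions.

Mechanism: a dichotomized Gaussian.  A latent stationary AR(1) Gaussian
process with unit marginal variance and spatial cross-correlation is
thresholded at the quantile giving the requested per-frame activation
probability.  The latent pairwise correlations are obtained by numerically
inverting the binary-correlation map of the thresholded bivariate normal
(a tetrachoric-style inversion on a monotone grid), so the *binary*
correlations — not merely the latent ones — land on the planted kernel.
The resulting latent correlation matrix need not be positive
semidefinite; it is projected to the nearest PSD matrix by eigenvalue
clipping before sampling, which perturbs the planted kernel slightly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "GeneratorParams",
    "generate_positions",
    "simulate_raster",
    "simulate_dataset",
    "traces_from_raster",
    "planted_motif_params",
]


@dataclass
class GeneratorParams:
    """Ground-truth parameters of one synthetic recording.

    Distances and the field side are in micrometres; ``persistence`` is the
    lag-1 autocorrelation of the latent dynamics; ``firing_prob`` the
    per-frame activation probability; ``xor_triplets`` lists (source_a,
    source_b, target) neuron ids whose target copies the XOR of the two
    sources from the previous frame, corrupted at ``xor_flip_prob``.
    """

    n_neurons: int = 200
    n_timepoints: int = 20_000
    field_size: float = 3000.0
    lambda_true: float = 500.0
    c0_true: float = 0.1
    c_inf_true: float = 0.01
    persistence: float = 0.3
    firing_prob: float = 0.05
    xor_triplets: list = field(default_factory=list)
    xor_flip_prob: float = 0.05
    seed: int = 0
    frame_rate_hz: float = 7.5  # metadata only

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be non-negative")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not 0 <= self.c_inf_true <= self.c0_true < 1:
            raise ValueError(
                "correlation targets must satisfy 0 <= c_inf_true <= "
                f"c0_true < 1, got c0={self.c0_true}, c_inf={self.c_inf_true}"
            )
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be positive")
        if not 0 < self.firing_prob < 1:
            raise ValueError("firing_prob must lie in (0, 1)")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must lie in [0, 1)")
        if not 0 <= self.xor_flip_prob < 0.5:
            raise ValueError("xor_flip_prob must lie in [0, 0.5)")
        ids = set()
        for trip in self.xor_triplets:
            if len(trip) != 3:
                raise ValueError("xor_triplets entries must be (a, b, target)")
            a, b, t = trip
            # the target may coincide with source b: then the pair (a, t)
            # is the canonical purely synergistic XOR pair (t's future is
            # the XOR of the pair's own joint past)
            if a == b or not all(0 <= v < self.n_neurons for v in (a, b, t)):
                raise ValueError(f"invalid xor triplet {trip}")
            if t in ids:
                raise ValueError(f"neuron {t} is target of two xor triplets")
            ids.add(t)


def generate_positions(
    n_neurons: int, field_size: float = 3000.0, seed: int = 0
) -> pd.DataFrame:
    """Place neurons uniformly at random in the square [0, field_size]^2."""
    if n_neurons < 0:
        raise ValueError("n_neurons must be non-negative")
    if field_size <= 0:
        raise ValueError("field_size must be positive")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, field_size, size=(n_neurons, 2))
    return pd.DataFrame(
        {"neuron_id": np.arange(n_neurons), "x_um": xy[:, 0], "y_um": xy[:, 1]}
    )


def _binary_corr_inverse_grid(firing_prob: float, n_grid: int = 64):
    """Tabulate binary correlation vs latent correlation for inversion.

    For standard bivariate normal latents thresholded at t (active when
    z > t with P = firing_prob), the binary correlation is
    (P11(rho) - p^2) / (p (1 - p)), strictly increasing in rho.
    """
    t = stats.norm.isf(firing_prob)
    rho = np.concatenate([np.linspace(0.0, 0.99, n_grid), [0.999]])
    p11 = np.array(
        [
            stats.multivariate_normal.cdf(
                [-t, -t], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]
            )
            for r in rho
        ]
    )
    r_bin = (p11 - firing_prob**2) / (firing_prob * (1 - firing_prob))
    r_bin[0] = 0.0
    return r_bin, rho


def _latent_correlation_matrix(dist: np.ndarray, params: GeneratorParams):
    target = params.c_inf_true + (
        params.c0_true - params.c_inf_true
    ) * np.exp(-dist / params.lambda_true)
    np.fill_diagonal(target, 1.0)
    r_grid, rho_grid = _binary_corr_inverse_grid(params.firing_prob)
    if target.max(initial=0.0, where=~np.eye(len(target), dtype=bool)) > r_grid[-1]:
        raise ValueError(
            "requested binary correlation exceeds what the dichotomized "
            f"Gaussian can attain at firing_prob={params.firing_prob} "
            f"(c0_true={params.c0_true})"
        )
    latent = np.interp(target, r_grid, rho_grid)
    np.fill_diagonal(latent, 1.0)
    # PSD projection: clip negative eigenvalues, restore unit variances
    w, v = np.linalg.eigh(latent)
    w = np.clip(w, 0.0, None)
    latent = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(latent), 1e-12, None))
    latent = latent / np.outer(d, d)
    return latent


def simulate_raster(positions: pd.DataFrame, params: GeneratorParams) -> np.ndarray:
    """Sample a (n_timepoints, n_neurons) binary raster from the generator.

    Deterministic under a fixed ``params.seed``; XOR triplet targets are
    overwritten after thresholding.
    """
    n = params.n_neurons
    if len(positions) != n:
        raise ValueError(
            f"positions cover {len(positions)} neurons, params expect {n}"
        )
    rng = np.random.default_rng(params.seed)
    t_len = params.n_timepoints
    if n == 0:
        return np.zeros((t_len, 0), dtype=np.int8)
    xy = positions.sort_values("neuron_id")[["x_um", "y_um"]].to_numpy(float)
    dist = np.hypot(
        xy[:, 0:1] - xy[:, 0:1].T, xy[:, 1:2] - xy[:, 1:2].T
    )
    latent_corr = _latent_correlation_matrix(dist, params)
    w, v = np.linalg.eigh(latent_corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))

    a = params.persistence
    burn = 0 if a == 0 else min(2000, max(100, int(np.ceil(-14 / np.log(a)))))
    innov = rng.standard_normal((t_len + burn, n)) @ factor.T
    if a > 0:
        z = signal.lfilter([np.sqrt(1 - a**2)], [1.0, -a], innov, axis=0)
        z = z[burn:]
    else:
        z = innov
    threshold = stats.norm.isf(params.firing_prob)
    raster = (z > threshold).astype(np.int8)

    for src_a, src_b, tgt in params.xor_triplets:
        flips = (rng.random(t_len - 1) < params.xor_flip_prob).astype(np.int8)
        if tgt in (src_a, src_b):
            # recursive dynamics: the target feeds back into its own update
            for s in range(t_len - 1):
                raster[s + 1, tgt] = (
                    raster[s, src_a] ^ raster[s, src_b] ^ flips[s]
                )
        else:
            xor = raster[:-1, src_a] ^ raster[:-1, src_b]
            raster[1:, tgt] = xor ^ flips
    return raster


def simulate_dataset(params: GeneratorParams):
    """Positions plus raster from one parameter set (shared seed)."""
    positions = generate_positions(params.n_neurons, params.field_size, params.seed)
    return positions, simulate_raster(positions, params)


def planted_motif_params(
    seed: int,
    n_neurons: int = 100,
    n_timepoints: int = 3000,
    n_motifs: int = 15,
    lambda_true: float = 300.0,
    c0_true: float = 0.3,
) -> tuple[pd.DataFrame, GeneratorParams]:
    """Study conditions for the two-layer path-decomposition demonstration.

    A spatially redundant background (short correlation length, zero
    asymptote) plus ``n_motifs`` planted XOR pairs spanning the longest
    available inter-neuron distances: each motif is a triplet (a, t, t),
    so the pair (a, t) is purely synergistic.  Fair per-frame activation
    keeps the XOR relation maximally synergistic.  Motif pairs are
    disjoint and chosen greedily by decreasing distance.

    Returns the positions table and the generator parameters.
    """
    positions = generate_positions(n_neurons, 3000.0, seed)
    xy = positions[["x_um", "y_um"]].to_numpy(float)
    dist = np.hypot(xy[:, 0:1] - xy[:, 0:1].T, xy[:, 1:2] - xy[:, 1:2].T)
    order = np.dstack(np.unravel_index(np.argsort(-dist, axis=None), dist.shape))[0]
    used: set[int] = set()
    triplets = []
    for i, j in order:
        if i == j or i in used or j in used:
            continue
        triplets.append((int(i), int(j), int(j)))
        used |= {int(i), int(j)}
        if len(triplets) == n_motifs:
            break
    params = GeneratorParams(
        n_neurons=n_neurons, n_timepoints=n_timepoints,
        lambda_true=lambda_true, c0_true=c0_true, c_inf_true=0.0,
        persistence=0.3, firing_prob=0.5, xor_triplets=triplets, seed=seed,
    )
    return positions, params


def traces_from_raster(
    raster: np.ndarray, amplitude: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Continuous nonnegative traces from a binary raster.

    Active frames take ``amplitude`` plus Gaussian noise, quiet frames noise
    only, clipped at zero — a deliberately minimal stand-in for deconvolved
    activity, used to exercise the HMM binarizer against known states.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    raster = np.asarray(raster, dtype=float)
    if noise_sd == 0:
        return amplitude * raster
    rng = np.random.default_rng(seed)
    noisy = amplitude * raster + rng.normal(0.0, noise_sd, size=raster.shape)
    return np.clip(noisy, 0.0, None)
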