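"""Two-state HMM binarization of continuous deconvolved activity traces.

Each neuron's nonnegative trace is modelled as a 2-state hidden Markov
chain with Gaussian emissions, fitted by EM.  The per-timepoint binary
state is the argmax of the forward-backward posterior marginal — the most
probable state at each time point, not the single most probable path —
with the higher-emission-mean state labelled Active (1).  This avoids a
hand-set threshold per neuron.

The EM fit is initialised deterministically from the trace itself (state
means at the 20th and 95th percentiles, 0.95 self-transition), so repeated
fits of the same trace give identical models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)
# hmmlearn logs a non-convergence line per EM run at WARNING; per-neuron
# fits make that pure noise, and the converged flag already carries it
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = ["HmmModel", "fit_hmm", "decode_states", "posterior_marginals",
           "binarize_dataset", "HmmBinarizer"]


@dataclass(frozen=True)
class HmmModel:
    """Fitted 2-state Gaussian HMM; state 1 is the higher-mean (Active) state."""

    means: np.ndarray          # (2,) emission means, trace units
    sds: np.ndarray            # (2,) emission standard deviations
    transmat: np.ndarray       # (2, 2) row-stochastic
    startprob: np.ndarray      # (2,)
    converged: bool
    log_likelihood: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if np.abs(self.transmat.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("transition rows must sum to 1")
            if np.any(self.sds <= 0):
                raise ValueError("emission sds must be positive")
            if self.means[1] < self.means[0]:
                raise ValueError("state 1 must have the larger emission mean")

    def _as_hmmlearn(self) -> GaussianHMM:
        hmm = GaussianHMM(n_components=2, covariance_type="diag",
                          init_params="", params="")
        hmm.startprob_ = self.startprob.copy()
        hmm.transmat_ = self.transmat.copy()
        hmm.means_ = self.means.reshape(2, 1).copy()
        hmm.covars_ = (self.sds.reshape(2, 1) ** 2).copy()
        return hmm


def _validate_trace(trace) -> np.ndarray:
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 10:
        raise ValueError(f"trace length {trace.size} < 10")
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite values")
    return trace


def fit_hmm(trace, max_iter: int = 200, tol: float = 1e-4,
            seed: int = 0) -> HmmModel:
    """EM fit of a 2-state Gaussian HMM to one trace.

    A zero-variance trace cannot identify two states; it returns a flagged
    degenerate model whose decoding is all-quiet, rather than raising.
    """
    trace = _validate_trace(trace)
    if trace.std() < 1e-12:
        return HmmModel(
            means=np.array([trace[0], trace[0]]),
            sds=np.array([1.0, 1.0]),
            transmat=np.eye(2),
            startprob=np.array([1.0, 0.0]),
            converged=True, log_likelihood=float("nan"), degenerate=True,
        )
    lo, hi = np.percentile(trace, [20, 95])
    if hi - lo < 1e-9:
        hi = lo + max(1e-3, 0.1 * abs(lo) + 1e-3)
    init_sd = max(trace.std() / 4, 1e-3)
    hmm = GaussianHMM(
        n_components=2, covariance_type="diag", n_iter=max_iter, tol=tol,
        init_params="", params="stmc", random_state=seed,
        min_covar=1e-6,
    )
    hmm.startprob_ = np.array([0.5, 0.5])
    hmm.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    hmm.means_ = np.array([[lo], [hi]])
    hmm.covars_ = np.full((2, 1), init_sd**2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(trace.reshape(-1, 1))
    order = np.argsort(hmm.means_.ravel())  # relabel: Active = higher mean
    return HmmModel(
        means=hmm.means_.ravel()[order],
        sds=np.sqrt(hmm.covars_.ravel()[order]),
        transmat=hmm.transmat_[np.ix_(order, order)],
        startprob=hmm.startprob_[order],
        converged=bool(hmm.monitor_.converged),
        log_likelihood=float(hmm.monitor_.history[-1]),
    )


def posterior_marginals(trace, model: HmmModel) -> np.ndarray:
    """(T, 2) forward-backward posterior state probabilities."""
    trace = _validate_trace(trace)
    if model.degenerate:
        out = np.zeros((trace.size, 2))
        out[:, 0] = 1.0
        return out
    return model._as_hmmlearn().predict_proba(trace.reshape(-1, 1))


def decode_states(trace, model: HmmModel) -> np.ndarray:
    """Per-timepoint most probable state (posterior-marginal argmax), in {0,1}."""
    if model.degenerate:
        return np.zeros(np.asarray(trace).size, dtype=np.int8)
    return posterior_marginals(trace, model).argmax(axis=1).astype(np.int8)


class HmmBinarizer(TransformerMixin, BaseEstimator):
    """Column-wise HMM binarizer for a (T, N) trace matrix.

    sklearn-style transformer: ``fit`` learns one 2-state Gaussian HMM per
    neuron, ``transform`` emits the posterior-argmax binary raster.  Input
    that is already binary is passed through unchanged by
    :func:`binarize_dataset`.

    Attributes
    ----------
    models_ : list[HmmModel]
        Per-neuron fitted models.
    n_degenerate_ : int
        Number of zero-variance neurons decoded as all-quiet.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-4, seed: int = 0):
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None):
        X = self._check_input(X)
        self.models_ = [
            fit_hmm(X[:, j], max_iter=self.max_iter, tol=self.tol,
                    seed=self.seed)
            for j in range(X.shape[1])
        ]
        self.n_degenerate_ = sum(m.degenerate for m in self.models_)
        if self.n_degenerate_:
            logger.warning(
                "%d of %d neurons had zero-variance traces; decoded all-quiet",
                self.n_degenerate_, X.shape[1],
            )
        return self

    def transform(self, X) -> np.ndarray:
        X = self._check_input(X)
        if len(self.models_) != X.shape[1]:
            raise ValueError(
                f"fitted on {len(self.models_)} neurons, got {X.shape[1]}"
            )
        return np.column_stack(
            [decode_states(X[:, j], m) for j, m in enumerate(self.models_)]
        ).astype(np.int8)

    @staticmethod
    def _check_input(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("expected a (T, N) matrix with N >= 1")
        if not np.isfinite(X).all():
            raise ValueError("traces contain non-finite values")
        return X


def binarize_dataset(traces, max_iter: int = 200, tol: float = 1e-4,
                     seed: int = 0) -> np.ndarray:
    """Binarize a (T, N) trace matrix; already-binary input passes through."""
    traces = HmmBinarizer._check_input(traces)
    if np.isin(traces, (0.0, 1.0)).all():
        return traces.astype(np.int8)
    return HmmBinarizer(max_iter=max_iter, tol=tol, seed=seed).fit_transform(traces)
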