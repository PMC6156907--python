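"""Composite-likelihood magnitude adjustment.

The composite likelihood multiplies case-control and trio components as
if the units were independent; with individuals extracted from shared
pedigrees they are not, so posterior spread computed from the raw
composite likelihood is too small.  The magnitude adjustment rescales
the log composite likelihood by

    k = p / sum_i lambda_i,

where lambda_1..lambda_p are the eigenvalues of H^{-1} J with
H = -E[Hessian of l_cf] (sensitivity) and J = Var[score of l_cf]
(variability).  Under a correctly specified model with independent
units H = J and k = 1; positive within-cluster dependence inflates J
relative to H and drives k below 1, shrinking the effective sample
size.  Since sum_i lambda_i = trace(H^{-1} J), k = p / trace(H^{-1} J).

The adjusted block is (alpha, beta) — p = K + 1 — with the haplotype
frequencies held fixed at their current values while differentiating:
the inferential targets are the regression effects, and numerical
Hessians across the frequency simplex are unstable.  Derivatives are
central finite differences of the observed-data (phase-marginalised)
composite log-likelihood.  J is estimated empirically by summing score
contributions within pedigree clusters:  J = sum_c s_c s_c^T, which is
exactly where the familial dependence enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .core import FrequencyVector, HaplotypeList
from .errors import AdjustmentError
from .likelihoods import LikelihoodEngine, ParameterVector

__all__ = [
    "AdjustmentState",
    "score_vector",
    "estimate_H",
    "estimate_J",
    "adjustment_factor",
    "adjusted_loglik",
    "compute_adjustment",
    "fit_regression_mle",
]

_REL_STEP = 1e-5        # gradient step: 1e-5 * max(1, |param|)
_HESS_REL_STEP = 1e-4   # second differences amplify roundoff by 1/h^2
_H_EIG_FLOOR = 1e-8


@dataclass
class AdjustmentState:
    """H, J, the eigenvalues of H^{-1}J, and the resulting scalar k."""

    H: np.ndarray
    J: np.ndarray
    eigvals: np.ndarray
    k: float
    p: int

    def __post_init__(self):
        if self.k <= 0:
            raise AdjustmentError(f"adjustment factor must be positive, got {self.k}")


def _steps(x: np.ndarray) -> np.ndarray:
    return _REL_STEP * np.maximum(1.0, np.abs(x))


def _check_finite(value, where: str):
    if not np.all(np.isfinite(value)):
        raise AdjustmentError(f"non-finite log-likelihood at {where}; adjustment aborted")


def _total_fn(engine: LikelihoodEngine, freqs: FrequencyVector):
    def fn(x):
        return engine.total_loglik(x[0], x[1:], freqs)
    return fn


def _unit_fn(engine: LikelihoodEngine, freqs: FrequencyVector):
    def fn(x):
        return engine.unit_logliks(x[0], x[1:], freqs)
    return fn


def _pack(params: ParameterVector) -> np.ndarray:
    return np.concatenate([[params.regression.alpha], params.regression.beta])


def _engine(params, cc_subjects, trios, haplotypes, max_missing=2) -> LikelihoodEngine:
    return LikelihoodEngine(cc_subjects, trios, haplotypes,
                            mode=params.regression.mode, max_missing=max_missing)


# ---------------------------------------------------------------------------
# finite-difference machinery (engine-level, reused by the sampler)
# ---------------------------------------------------------------------------

def _fd_gradient(fn, x: np.ndarray) -> np.ndarray:
    h = _steps(x)
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp, fm = fn(xp), fn(xm)
        _check_finite([fp, fm], f"gradient stencil, parameter {i}")
        g[i] = (fp - fm) / (2.0 * h[i])
    return g


def _fd_unit_scores(unit_fn, x: np.ndarray) -> np.ndarray:
    """(n_units, p) matrix of per-unit score contributions."""
    h = _steps(x)
    cols = []
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        up, um = unit_fn(xp), unit_fn(xm)
        _check_finite(up, f"unit scores +h, parameter {i}")
        _check_finite(um, f"unit scores -h, parameter {i}")
        cols.append((up - um) / (2.0 * h[i]))
    return np.column_stack(cols) if cols else np.empty((0, 0))


def _fd_hessian(fn, x: np.ndarray) -> np.ndarray:
    p = x.size
    h = _HESS_REL_STEP * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = fn(x)
    _check_finite(f0, "Hessian centre")
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp, fm = fn(xp), fn(xm)
        _check_finite([fp, fm], f"Hessian diagonal, parameter {i}")
        H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xpm[i] += h[i]; xpm[j] -= h[j]
            xmp[i] -= h[i]; xmp[j] += h[j]
            xmm[[i, j]] -= [h[i], h[j]]
            vals = [fn(xpp), fn(xpm), fn(xmp), fn(xmm)]
            _check_finite(vals, f"Hessian off-diagonal ({i},{j})")
            H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def score_vector(params: ParameterVector, cc_subjects, trios,
                 haplotypes: HaplotypeList, max_missing: int = 2) -> np.ndarray:
    """Finite-difference score of the observed composite log-likelihood.

    Gradient with respect to (alpha, beta), frequencies fixed; central
    differences with step ``1e-5 * max(1, |param|)``.
    """
    engine = _engine(params, cc_subjects, trios, haplotypes, max_missing)
    return _fd_gradient(_total_fn(engine, params.freqs), _pack(params))


def estimate_H(params: ParameterVector, cc_subjects, trios,
               haplotypes: HaplotypeList, max_missing: int = 2) -> np.ndarray:
    """Sensitivity matrix: minus the observed-information Hessian, symmetrised."""
    engine = _engine(params, cc_subjects, trios, haplotypes, max_missing)
    return engine_H(engine, _pack(params), params.freqs)


def estimate_J(params: ParameterVector, cc_subjects, trios,
               haplotypes: HaplotypeList, max_missing: int = 2) -> np.ndarray:
    """Variability matrix: sum over pedigree clusters of s_c s_c^T.

    Per-unit score contributions (each case-control subject, each trio)
    are summed within their pedigree cluster before the outer product,
    so within-pedigree dependence inflates J — this is the quantity the
    adjustment exists to capture.
    """
    engine = _engine(params, cc_subjects, trios, haplotypes, max_missing)
    return engine_J(engine, _pack(params), params.freqs)


def engine_H(engine: LikelihoodEngine, x: np.ndarray, freqs: FrequencyVector) -> np.ndarray:
    return -_fd_hessian(_total_fn(engine, freqs), x)


def engine_J(engine: LikelihoodEngine, x: np.ndarray, freqs: FrequencyVector) -> np.ndarray:
    if engine.n_clusters < 2:
        raise AdjustmentError("J needs at least two pedigree clusters")
    scores = _fd_unit_scores(_unit_fn(engine, freqs), x)   # (n_units, p)
    S = np.zeros((engine.n_clusters, x.size))
    np.add.at(S, engine.cluster_ids, scores)
    return S.T @ S


def adjustment_factor(H: np.ndarray, J: np.ndarray,
                      eig_floor: float = _H_EIG_FLOOR) -> AdjustmentState:
    """Eigenvalues of H^{-1} J and k = p / sum(lambda).

    Solved as the generalized symmetric eigenproblem J v = lambda H v
    after flooring H's eigenvalues at ``eig_floor * max_eig`` so H is
    positive definite; note sum(lambda) = trace(H^{-1} J).
    """
    H = np.asarray(H, dtype=float)
    J = np.asarray(J, dtype=float)
    p = H.shape[0]
    if H.shape != (p, p) or J.shape != (p, p):
        raise AdjustmentError("H and J must be square matrices of the same size")
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    if w.max() <= 0:
        raise AdjustmentError("H has no positive eigenvalue; adjustment impossible")
    w = np.maximum(w, eig_floor * w.max())
    Hf = (V * w) @ V.T
    eigvals = scipy.linalg.eigh(0.5 * (J + J.T), Hf, eigvals_only=True)
    total = float(eigvals.sum())
    if total <= 0:
        raise AdjustmentError(f"sum of eigenvalues of H^-1 J is {total} <= 0")
    k = p / total
    return AdjustmentState(H=Hf, J=J, eigvals=np.asarray(eigvals), k=k, p=p)


def adjusted_loglik(k: float, loglik_value: float) -> float:
    """The magnitude-adjusted log-likelihood l* = k * l_cf."""
    if k <= 0:
        raise AdjustmentError("k must be positive")
    return k * loglik_value


def compute_adjustment(engine: LikelihoodEngine, alpha: float, beta,
                       freqs: FrequencyVector) -> AdjustmentState:
    """H, J and k at the current parameter state (engine-level hot path)."""
    x = np.concatenate([[alpha], np.atleast_1d(np.asarray(beta, dtype=float))])
    H = engine_H(engine, x, freqs)
    J = engine_J(engine, x, freqs)
    return adjustment_factor(H, J)


def fit_regression_mle(engine: LikelihoodEngine, freqs: FrequencyVector,
                       x0: np.ndarray | None = None) -> np.ndarray:
    """Maximise the observed composite log-likelihood over (alpha, beta).

    Frequencies fixed; used to evaluate H and J at the composite MLE.
    The retrospective likelihood flattens as alpha -> -inf (alpha cancels
    from the limiting model), a plateau that can strand a single
    quasi-Newton run, so the solver is started both from ``x0`` and from
    the origin and the better optimum is kept.
    """
    p = engine.n_haplotypes  # 1 + K
    starts = [np.zeros(p)]
    if x0 is not None and np.any(x0 != 0.0):
        starts.append(np.asarray(x0, dtype=float))

    def nll(x):
        return -engine.total_loglik(x[0], x[1:], freqs)

    best = None
    for s in starts:
        res = scipy.optimize.minimize(nll, s, method="L-BFGS-B",
                                      options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    return best.x
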