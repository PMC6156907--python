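"""MCMC for the adjusted-posterior haplotype association model.

The target is the k-adjusted posterior over (latent diplotypes Z,
alpha, beta, Laplace shrinkage rate, haplotype frequencies): every
conditional raises its composite-likelihood factor to the power k, so a
single well-defined tempered target is sampled.  k itself comes from H
and J evaluated at the composite MLE of (alpha, beta) with the
chain-initial EM frequencies plugged in (see ChainState.update_k), on a
configurable schedule.

Priors follow the logistic Bayesian LASSO lineage: beta_j ~
Laplace(0, rate lambda_s) with lambda_s ~ Gamma(a, b) (conjugate Gibbs
update), alpha ~ Normal(0, sigma_alpha^2), frequencies ~ flat Dirichlet
updated by a Metropolis-Hastings step with a Dirichlet proposal centred
at the current value.  Phases are Gibbs-sampled from their compatible
sets.

Significance per haplotype combines a Bayes factor for {|beta_j| >
epsilon} against its prior odds with the 95% equal-tailed credible
interval of the odds ratio exp(beta_j): a haplotype is flagged when
BF > 2 and the interval excludes 1.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from .adjustment import (
    AdjustmentState,
    adjustment_factor,
    engine_H,
    engine_J,
    fit_regression_mle,
)
from .core import FrequencyVector, HaplotypeList, build_haplotype_list
from .errors import AdjustmentError, ConfigError, DataError
from .likelihoods import LikelihoodEngine

__all__ = [
    "MCMCConfig",
    "HaplotypeSummary",
    "PosteriorSummary",
    "MCMCResult",
    "ChainState",
    "run_mcmc",
    "bayes_factor",
    "prior_exceedance",
    "classify_significant",
]


@dataclass
class MCMCConfig:
    """Sampler configuration.

    ``a``, ``b`` parameterise the Gamma hyperprior on the Laplace
    shrinkage rate (defaults 20, 20: prior mean rate 1, tightly
    informative as is conventional for this model family);
    ``epsilon_null`` defines the BF null {|beta| <= epsilon}, default
    log(1.1) i.e. an OR within 10% of 1.  ``k_update_every`` controls
    how often the magnitude adjustment is recomputed (1 = every
    iteration).  ``fix_*`` freeze a component at a given value — used
    to reduce the model for oracle comparisons and for sensitivity
    checks; ``fix_k=1`` with no trios reduces the sampler to plain
    case-control LBL.
    """

    n_iter: int = 2000
    n_burn: int = 500
    thin: int = 1
    n_chains: int = 2
    seed: int = 0
    mode: str = "additive"
    adapt_proposals: bool = True
    a: float = 20.0
    b: float = 20.0
    sigma_alpha: float = 10.0
    epsilon_null: float = math.log(1.1)
    bf_threshold: float = 2.0
    ci_level: float = 0.95
    k_update_every: int = 1
    k_at_current_freqs: bool = False
    n_joint_steps: int = 3
    prop_sd_alpha: float = 0.35
    prop_sd_beta: float = 0.45
    freq_concentration: float = 200.0
    max_missing: int = 2
    pool_threshold: float = 0.0
    inbreeding: float = 0.0
    rhat_threshold: float = 1.1
    fix_alpha: float | None = None
    fix_freqs: np.ndarray | None = None
    fix_shrink: float | None = None
    fix_k: float | None = None

    def __post_init__(self):
        if self.n_burn >= self.n_iter:
            raise ConfigError("n_burn must be smaller than n_iter")
        if self.epsilon_null <= 0:
            raise ConfigError("epsilon_null must be positive")
        if self.thin < 1 or self.n_chains < 1:
            raise ConfigError("thin and n_chains must be >= 1")
        if self.k_update_every < 1:
            raise ConfigError("k_update_every must be >= 1")
        if self.fix_freqs is not None:
            self.fix_freqs = np.asarray(self.fix_freqs, dtype=float)


@dataclass
class HaplotypeSummary:
    """One results row: a non-baseline haplotype's posterior summaries."""

    haplotype: str
    freq: float
    or_mean: float
    ci_lower: float
    ci_upper: float
    bf: float
    significant: bool


@dataclass
class PosteriorSummary:
    """Per-haplotype posterior table plus the baseline label."""

    rows: list
    baseline: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "haplotype": r.haplotype,
                    "freq": r.freq,
                    "OR": r.or_mean,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "BF": r.bf,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )

    def row(self, haplotype: str) -> HaplotypeSummary:
        for r in self.rows:
            if r.haplotype == haplotype:
                return r
        raise KeyError(haplotype)


@dataclass
class MCMCResult:
    summary: PosteriorSummary
    haplotypes: HaplotypeList
    chains: dict
    rhat: np.ndarray | None
    ess: np.ndarray | None
    k_trajectory: np.ndarray
    warnings: list
    config: MCMCConfig

    def beta_draws(self, j: int | None = None) -> np.ndarray:
        """Pooled post-burn-in beta draws (all chains), optionally one column."""
        b = self.chains["beta"].reshape(-1, self.chains["beta"].shape[-1])
        return b if j is None else b[:, j]


# ---------------------------------------------------------------------------
# prior mass and Bayes factor
# ---------------------------------------------------------------------------

def prior_exceedance(config: MCMCConfig) -> float:
    """Prior P(|beta_j| > epsilon) under the marginal shrinkage prior.

    With rate lambda fixed the Laplace tail gives exp(-lambda*epsilon);
    otherwise the Gamma(a, b) hyperprior is integrated out by 1-D
    quadrature.
    """
    eps = config.epsilon_null
    if config.fix_shrink is not None:
        return float(math.exp(-config.fix_shrink * eps))
    val, _ = quad(
        lambda lam: math.exp(-lam * eps) * gamma_dist.pdf(lam, config.a, scale=1.0 / config.b),
        0.0, np.inf,
    )
    return float(val)


def bayes_factor(beta_chain, config: MCMCConfig) -> float:
    """Posterior odds over prior odds for the non-null event {|beta| > epsilon}.

    The posterior mass is the chain fraction exceeding epsilon, clipped
    to [1/(M+1), M/(M+1)] to keep the odds finite.
    """
    chain = np.asarray(beta_chain, dtype=float).ravel()
    M = chain.size
    if M < 100:
        raise DataError(f"Bayes factor needs a chain of length >= 100, got {M}")
    r = np.mean(np.abs(chain) > config.epsilon_null)
    r = float(np.clip(r, 1.0 / (M + 1), M / (M + 1.0)))
    q = prior_exceedance(config)
    return (r / (1.0 - r)) / (q / (1.0 - q))


def classify_significant(row: HaplotypeSummary, bf_threshold: float = 2.0) -> bool:
    """Flag a haplotype: BF above threshold AND the OR interval excludes 1."""
    excludes_one = not (row.ci_lower <= 1.0 <= row.ci_upper)
    return bool(row.bf > bf_threshold and excludes_one)


# ---------------------------------------------------------------------------
# chain state
# ---------------------------------------------------------------------------

def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    return float((conc - 1.0) @ np.log(x) + gammaln(conc.sum()) - gammaln(conc).sum())


class ChainState:
    """One MCMC chain: latent phases, parameters, and the current adjustment.

    Exposes the individual update steps (``sample_phases``,
    ``update_alpha``, ``update_beta``, ``update_shrink``,
    ``update_freqs``, ``update_k``) so each conditional can be audited
    in isolation; :func:`run_mcmc` drives the full sweep.
    """

    def __init__(self, engine: LikelihoodEngine, config: MCMCConfig,
                 rng: np.random.Generator, f_init: np.ndarray,
                 overdisperse: bool = True):
        self.engine = engine
        self.space = engine.space
        self.config = config
        self.rng = rng
        self.K = engine.n_haplotypes - 1
        self.d = config.inbreeding

        if config.fix_alpha is not None:
            self.alpha = float(config.fix_alpha)
        else:
            self.alpha = float(rng.normal(0.0, 0.5)) if overdisperse else 0.0
        self.beta = (rng.normal(0.0, 0.25, self.K) if overdisperse
                     else np.zeros(self.K))
        self.lam = float(config.fix_shrink if config.fix_shrink is not None
                         else config.a / config.b)
        if config.fix_freqs is not None:
            f0 = np.asarray(config.fix_freqs, dtype=float)
        else:
            f0 = np.maximum(np.asarray(f_init, dtype=float), 1e-6)
        self.f = f0 / f0.sum()
        self._f_plugin = self.f.copy()  # plug-in point for the k computation
        self.k = float(config.fix_k) if config.fix_k is not None else 1.0
        self.adjustment: AdjustmentState | None = None
        self._mle_warm: np.ndarray | None = None
        self.iteration = 0

        # per-block proposal scales, adapted during burn-in (sweep() only)
        self.sd_alpha = config.prop_sd_alpha
        self.sd_beta = np.full(self.K, config.prop_sd_beta)
        self.freq_conc = config.freq_concentration
        self._acc_alpha = 0
        self._acc_beta = np.zeros(self.K, dtype=int)
        self._acc_freq = 0
        self._adapt_batch = 50
        # joint adaptive-Metropolis move on the (alpha, beta) block: the
        # retrospective likelihood identifies alpha only weakly and the
        # (alpha, beta) posterior is strongly ridged, so component-wise
        # walks alone mix slowly; the proposal covariance is estimated
        # from burn-in draws (Haario-style, frozen after burn-in)
        self._joint_scale = 1.0
        self._acc_joint = 0
        self._joint_chol: np.ndarray | None = None
        self._hist = []

        self._build_groups()
        self.z_cc = np.zeros(len(engine.cc_subjects), dtype=np.int64)
        self.zc_assign = np.zeros(len(engine.trios), dtype=np.int64)
        self.zu_assign = np.zeros(len(engine.trios), dtype=np.int64)
        self.sample_phases()

    # -- setup --------------------------------------------------------------

    def _build_groups(self):
        """Compile static index structures for vectorised phase sampling.

        Units sharing (compatible set, phenotype) form one group; all
        groups' candidate lists are concatenated once so each iteration
        draws every unit's phase with a single cumulative-sum /
        searchsorted pass instead of a per-group Python loop.
        """
        eng = self.engine
        cc_groups = {}
        for i in range(eng.cc_y.size):
            seg = eng.cc_idx[eng.cc_offsets[i]:eng.cc_offsets[i + 1]]
            key = (int(eng.cc_y[i]), seg.tobytes())
            cc_groups.setdefault(key, (seg, []))[1].append(i)
        segs, starts, ys = [], [0], []
        m_start = np.zeros(eng.cc_y.size, dtype=np.int64)
        m_end = np.zeros(eng.cc_y.size, dtype=np.int64)
        for (y, _), (seg, members) in cc_groups.items():
            segs.append(seg)
            ys.append(np.full(seg.size, y, dtype=np.int8))
            m_start[members] = starts[-1]
            m_end[members] = starts[-1] + seg.size
            starts.append(starts[-1] + seg.size)
        self._cc_seg = np.concatenate(segs) if segs else np.empty(0, dtype=np.int64)
        self._cc_seg_y = np.concatenate(ys) if ys else np.empty(0, dtype=np.int8)
        self._cc_m_start = m_start
        self._cc_m_end = m_end
        self._cc_g_starts = np.array(starts[:-1], dtype=np.int64)
        self._cc_g_len = np.diff(np.array(starts, dtype=np.int64))

        trio_groups = {}
        for i in range(len(eng.trios)):
            zc = eng.trio_zc[eng.trio_offsets[i]:eng.trio_offsets[i + 1]]
            zu = eng.trio_zu[eng.trio_offsets[i]:eng.trio_offsets[i + 1]]
            key = (zc.tobytes(), zu.tobytes())
            trio_groups.setdefault(key, (zc, zu, []))[2].append(i)
        zcs, zus, starts = [], [], [0]
        n_tr = len(eng.trios)
        t_start = np.zeros(n_tr, dtype=np.int64)
        t_end = np.zeros(n_tr, dtype=np.int64)
        for zc, zu, members in trio_groups.values():
            zcs.append(zc)
            zus.append(zu)
            t_start[members] = starts[-1]
            t_end[members] = starts[-1] + zc.size
            starts.append(starts[-1] + zc.size)
        self._tr_zc = np.concatenate(zcs) if zcs else np.empty(0, dtype=np.int64)
        self._tr_zu = np.concatenate(zus) if zus else np.empty(0, dtype=np.int64)
        self._tr_m_start = t_start
        self._tr_m_end = t_end
        self._tr_g_starts = np.array(starts[:-1], dtype=np.int64)
        self._tr_g_len = np.diff(np.array(starts, dtype=np.int64))

    def freqs(self, f: np.ndarray | None = None) -> FrequencyVector:
        return FrequencyVector((self.f if f is None else f).copy(), self.d)

    # -- likelihood bookkeeping ---------------------------------------------

    def _refresh_counts(self):
        P = self.space.n_pairs
        y = self.engine.cc_y
        self._n1 = np.bincount(self.z_cc[y == 1], minlength=P).astype(float)
        self._n0 = np.bincount(self.z_cc[y == 0], minlength=P).astype(float)
        self._tc = np.bincount(self.zc_assign, minlength=P).astype(float) \
            if self.zc_assign.size else np.zeros(P)
        self._tu = np.bincount(self.zu_assign, minlength=P).astype(float) \
            if self.zu_assign.size else np.zeros(P)
        self._cur_ll = self.complete_loglik()

    def complete_loglik(self, alpha=None, beta=None, f=None) -> float:
        """Complete-data composite log-likelihood at the stored phases."""
        return self.engine.complete_loglik_from_counts(
            self._n1, self._n0, self._tc, self._tu,
            self.alpha if alpha is None else alpha,
            self.beta if beta is None else beta,
            self.f if f is None else f,
            d=self.d,
        )

    # -- update steps --------------------------------------------------------

    def sample_phases(self):
        """Gibbs-draw every unit's phase from its compatible set.

        Each candidate's weight is its own composite-likelihood factor
        raised to the power k; as k -> 0 the draw tends to uniform over
        the compatible set.
        """
        logpen1, logpen0, logpp, _, _ = self.engine._factors(
            self.alpha, self.beta, self.f, self.d)
        rng = self.rng
        k = self.k
        if self._cc_seg.size:
            logw = k * (np.where(self._cc_seg_y == 1,
                                 logpen1[self._cc_seg], logpen0[self._cc_seg])
                        + logpp[self._cc_seg])
            pos = self._segment_draws(logw, self._cc_g_starts, self._cc_g_len,
                                      self._cc_m_start, self._cc_m_end,
                                      rng.random(self.z_cc.size))
            self.z_cc = self._cc_seg[pos]
        if self._tr_zc.size:
            logw = k * (logpen1[self._tr_zc] + logpp[self._tr_zc]
                        + logpp[self._tr_zu])
            pos = self._segment_draws(logw, self._tr_g_starts, self._tr_g_len,
                                      self._tr_m_start, self._tr_m_end,
                                      rng.random(self.zc_assign.size))
            self.zc_assign = self._tr_zc[pos]
            self.zu_assign = self._tr_zu[pos]
        self._refresh_counts()

    @staticmethod
    def _segment_draws(logw, g_starts, g_len, m_start, m_end, u):
        """Categorical draw per unit from its group's slice of ``logw``.

        Weights are exponentiated after a per-segment max shift (the
        normalisation cancels within each categorical draw but keeps
        every segment's weights representable), cumulated once, and
        each unit's uniform is mapped into its slice by a single
        searchsorted call.
        """
        seg_max = np.maximum.reduceat(logw, g_starts)
        w = np.exp(logw - np.repeat(seg_max, g_len))
        C = np.concatenate([[0.0], np.cumsum(w)])
        base = C[m_start]
        t = base + u * (C[m_end] - base)
        return np.searchsorted(C, t, side="right") - 1

    def _mh_accept(self, log_ratio: float) -> bool:
        return math.log(self.rng.uniform()) < log_ratio

    def update_alpha(self, proposal: float | None = None) -> bool:
        if self.config.fix_alpha is not None:
            return False
        prop = self.alpha + self.rng.normal(0.0, self.sd_alpha) \
            if proposal is None else proposal
        ll_p = self.complete_loglik(alpha=prop)
        sa2 = self.config.sigma_alpha ** 2
        logr = self.k * (ll_p - self._cur_ll) - (prop ** 2 - self.alpha ** 2) / (2.0 * sa2)
        if self._mh_accept(logr):
            self.alpha = float(prop)
            self._cur_ll = ll_p
            self._acc_alpha += 1
            return True
        return False

    def update_beta(self, j: int, proposal: float | None = None) -> bool:
        prop_beta = self.beta.copy()
        prop_beta[j] = self.beta[j] + self.rng.normal(0.0, self.sd_beta[j]) \
            if proposal is None else proposal
        ll_p = self.complete_loglik(beta=prop_beta)
        logr = (self.k * (ll_p - self._cur_ll)
                - self.lam * (abs(prop_beta[j]) - abs(self.beta[j])))
        if self._mh_accept(logr):
            self.beta = prop_beta
            self._cur_ll = ll_p
            self._acc_beta[j] += 1
            return True
        return False

    def update_shrink(self) -> float:
        """Gibbs draw of the Laplace rate from its Gamma full conditional."""
        if self.config.fix_shrink is None:
            shape = self.config.a + self.K
            rate = self.config.b + float(np.sum(np.abs(self.beta)))
            self.lam = float(self.rng.gamma(shape, 1.0 / rate))
        return self.lam

    def update_freqs(self) -> bool:
        if self.config.fix_freqs is not None:
            return False
        conc = self.freq_conc * self.f + 0.5
        prop = self.rng.dirichlet(conc)
        if prop.min() < 1e-10:
            return False  # auto-reject: would zero out a haplotype
        conc_back = self.freq_conc * prop + 0.5
        ll_p = self.complete_loglik(f=prop)
        if not np.isfinite(ll_p):
            return False  # an assigned haplotype lost its support
        logr = (self.k * (ll_p - self._cur_ll)
                + _dirichlet_logpdf(self.f, conc_back)
                - _dirichlet_logpdf(prop, conc))
        if self._mh_accept(logr):
            self.f = np.asarray(prop, dtype=float)
            self._cur_ll = ll_p
            self._acc_freq += 1
            return True
        return False

    def _log_prior_ab(self, alpha: float, beta: np.ndarray) -> float:
        sa2 = self.config.sigma_alpha ** 2
        return -alpha ** 2 / (2.0 * sa2) - self.lam * float(np.sum(np.abs(beta)))

    def update_joint(self) -> bool:
        """Adaptive-Metropolis step on the whole (alpha, beta) block."""
        if self._joint_chol is None or self.config.fix_alpha is not None:
            return False
        p = 1 + self.K
        step = (self._joint_scale * 2.38 / np.sqrt(p)) * (
            self._joint_chol @ self.rng.normal(size=p))
        prop_a = self.alpha + step[0]
        prop_b = self.beta + step[1:]
        ll_p = self.complete_loglik(alpha=prop_a, beta=prop_b)
        logr = (self.k * (ll_p - self._cur_ll)
                + self._log_prior_ab(prop_a, prop_b)
                - self._log_prior_ab(self.alpha, self.beta))
        if self._mh_accept(logr):
            self.alpha = float(prop_a)
            self.beta = prop_b
            self._cur_ll = ll_p
            self._acc_joint += 1
            return True
        return False

    def _update_joint_proposal(self):
        if len(self._hist) < 200:
            return
        X = np.asarray(self._hist[-2000:])
        cov = np.cov(X.T) + 1e-8 * np.eye(1 + self.K)
        try:
            self._joint_chol = np.linalg.cholesky(np.atleast_2d(cov))
        except np.linalg.LinAlgError:
            pass

    def update_k(self) -> AdjustmentState | None:
        """Recompute H, J and k at a consistent plug-in parameter point.

        H and J are evaluated at the composite MLE of (alpha, beta) with
        the frequencies plugged in at their chain-initial (EM) estimate:
        the empirical variability matrix sum_c s_c s_c^T estimates
        Var[score] only where the total score vanishes, so evaluating at
        an arbitrary chain state would conflate dependence with distance
        from the optimum and drive k to zero, and evaluating at the
        chain's current frequency draw was observed to turn k into a
        noisy random multiplier of the tempered target.  With
        ``k_at_current_freqs`` the frequencies follow the chain state
        instead (then k genuinely changes between updates).  On numerical
        failure the previous k is retained (the adjustment is a
        rescaling, not a likelihood component, so a stale value only
        delays the correction).
        """
        if self.config.fix_k is not None:
            return None
        if self.config.k_at_current_freqs:
            freqs = self.freqs()
        else:
            if self.adjustment is not None:
                return self.adjustment  # plug-in point is fixed: k is a constant
            freqs = FrequencyVector(self._f_plugin.copy(), self.d)
        try:
            x = fit_regression_mle(self.engine, freqs, x0=self._mle_warm)
            self._mle_warm = x
            H = engine_H(self.engine, x, freqs)
            J = engine_J(self.engine, x, freqs)
            st = adjustment_factor(H, J)
        except AdjustmentError:
            return None
        self.adjustment = st
        self.k = st.k
        return st

    def _adapt(self):
        """Robbins-Monro scale adaptation toward standard acceptance targets.

        Runs in batches during burn-in only, so the post-burn-in kernel
        is a fixed (valid) Metropolis-Hastings transition.
        """
        b = self._adapt_batch
        step = min(0.5, 2.0 / np.sqrt(1.0 + self.iteration / b))
        self.sd_alpha *= math.exp(step * (self._acc_alpha / b - 0.44))
        for j in range(self.K):
            self.sd_beta[j] *= math.exp(step * (self._acc_beta[j] / b - 0.44))
        # higher concentration = smaller simplex moves = higher acceptance
        self.freq_conc *= math.exp(-step * (self._acc_freq / b - 0.30))
        self.freq_conc = float(np.clip(self.freq_conc, 10.0, 1e6))
        if self._joint_chol is not None:
            self._joint_scale *= math.exp(step * (self._acc_joint / b - 0.25))
        self._update_joint_proposal()
        self._acc_alpha = 0
        self._acc_beta[:] = 0
        self._acc_freq = 0
        self._acc_joint = 0

    def sweep(self):
        """One full MCMC iteration."""
        self.sample_phases()
        self.update_alpha()
        for j in range(self.K):
            self.update_beta(j)
        for _ in range(self.config.n_joint_steps):
            self.update_joint()
        self.update_shrink()
        self.update_freqs()
        if self.config.fix_k is None and self.iteration % self.config.k_update_every == 0:
            self.update_k()
        self.iteration += 1
        if self.config.adapt_proposals and self.iteration <= self.config.n_burn:
            if self.config.fix_alpha is None:
                self._hist.append(np.concatenate([[self.alpha], self.beta]))
            if self.iteration % self._adapt_batch == 0:
                self._adapt()


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _pool_haplotypes(hl: HaplotypeList, f: np.ndarray, threshold: float):
    """Fold haplotypes with EM frequency below threshold into the baseline."""
    if threshold <= 0:
        return hl, f, None
    keep = [0] + [i for i in range(1, len(hl)) if f[i] >= threshold]
    if len(keep) == len(hl):
        return hl, f, None
    index_map = np.zeros(len(hl), dtype=np.int64)
    for new, old in enumerate(keep):
        index_map[old] = new
    retained = HaplotypeList(hl.matrix[keep])
    f_ret = f[keep].copy()
    f_ret[0] += f.sum() - f[keep].sum()
    return retained, f_ret, (hl, index_map)


def run_mcmc(cc_subjects, trios=(), config: MCMCConfig | None = None,
             haplotypes: HaplotypeList | None = None,
             freqs_init: np.ndarray | None = None) -> MCMCResult:
    """Run the full sampler and summarise the posterior.

    If no haplotype list is supplied it is built from the data (EM
    frequencies, descending order, most-frequent baseline) and
    optionally pooled at ``config.pool_threshold``.  Chains are seeded
    from deterministic substreams of ``config.seed``; identical inputs
    give bitwise-identical results.
    """
    config = config or MCMCConfig()
    warnings_list: list = []
    pool_info = None
    if haplotypes is None:
        hl_full, f_full = build_haplotype_list(cc_subjects, trios,
                                               max_missing=config.max_missing)
        haplotypes, f_em, pool_info = _pool_haplotypes(hl_full, f_full,
                                                       config.pool_threshold)
        if pool_info is not None:
            warnings_list.append(
                f"pooled {len(pool_info[0]) - len(haplotypes)} haplotypes below "
                f"frequency {config.pool_threshold} into the baseline"
            )
        if freqs_init is None:
            freqs_init = f_em
    if freqs_init is None:
        from .core import estimate_frequencies_em
        genos = [s.genotype for s in cc_subjects]
        for t in trios:
            genos.extend([t.g_father, t.g_mother, t.g_child])
        freqs_init = estimate_frequencies_em(genos, haplotypes,
                                             max_missing=config.max_missing)

    full_hl, index_map = pool_info if pool_info is not None else (None, None)
    engine = LikelihoodEngine(cc_subjects, trios, haplotypes, mode=config.mode,
                              max_missing=config.max_missing,
                              full_haplotypes=full_hl, index_map=index_map,
                              warn=warnings_list.append)

    K = engine.n_haplotypes - 1
    n_keep = (config.n_iter - config.n_burn + config.thin - 1) // config.thin
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    alpha_ch = np.empty((config.n_chains, n_keep))
    beta_ch = np.empty((config.n_chains, n_keep, K))
    lam_ch = np.empty((config.n_chains, n_keep))
    f_ch = np.empty((config.n_chains, n_keep, K + 1))
    k_ch = np.empty((config.n_chains, n_keep))
    k_traj = np.empty((config.n_chains, config.n_iter))

    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        state = ChainState(engine, config, rng, freqs_init,
                           overdisperse=config.n_chains > 1)
        kept = 0
        for it in range(config.n_iter):
            state.sweep()
            k_traj[c, it] = state.k
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                alpha_ch[c, kept] = state.alpha
                beta_ch[c, kept] = state.beta
                lam_ch[c, kept] = state.lam
                f_ch[c, kept] = state.f
                k_ch[c, kept] = state.k
                kept += 1

    chains = {"alpha": alpha_ch, "beta": beta_ch, "lam": lam_ch,
              "freqs": f_ch, "k": k_ch}

    rhat = ess = None
    if config.n_chains >= 2 and K > 0:
        import arviz as az

        rhat = np.empty(K)
        ess = np.empty(K)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for j in range(K):
                rhat[j] = float(np.asarray(az.rhat(beta_ch[:, :, j])))
                ess[j] = float(np.asarray(az.ess(beta_ch[:, :, j])))
        bad = np.nonzero(rhat > config.rhat_threshold)[0]
        for j in bad:
            warnings_list.append(
                f"R-hat {rhat[j]:.3f} > {config.rhat_threshold} for beta of "
                f"haplotype {engine.haplotypes.label(j + 1)}"
            )

    lo_q = 100.0 * (1.0 - config.ci_level) / 2.0
    hi_q = 100.0 - lo_q
    rows = []
    beta_flat = beta_ch.reshape(-1, K)
    f_flat = f_ch.reshape(-1, K + 1)
    for j in range(K):
        draws_or = np.exp(beta_flat[:, j])
        lo, hi = np.percentile(draws_or, [lo_q, hi_q])
        row = HaplotypeSummary(
            haplotype=engine.haplotypes.label(j + 1),
            freq=float(f_flat[:, j + 1].mean()),
            or_mean=float(draws_or.mean()),
            ci_lower=float(lo),
            ci_upper=float(hi),
            bf=bayes_factor(beta_flat[:, j], config),
            significant=False,
        )
        row.significant = classify_significant(row, config.bf_threshold)
        if not (lo <= row.or_mean <= hi):
            warnings_list.append(
                f"posterior mean OR outside its equal-tailed CI for haplotype "
                f"{row.haplotype} (skewed posterior)"
            )
        rows.append(row)

    summary = PosteriorSummary(rows=rows, baseline=engine.haplotypes.label(0))
    return MCMCResult(summary=summary, haplotypes=engine.haplotypes, chains=chains,
                      rhat=rhat, ess=ess, k_trajectory=k_traj,
                      warnings=warnings_list, config=config)
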