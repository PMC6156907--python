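"""Composite likelihood for joint case-control + case-parent-trio data.

Three components, all retrospective (appropriate for sampling ascertained
on phenotype):

* case-control: ``L_c = prod_i P(Z_i | Y_i, params)`` where
  ``P(z|Y=1) ∝ [theta_z/(1+theta_z)] P(z)`` and
  ``P(z|Y=0) ∝ [1/(1+theta_z)] P(z)``, normalised over the full
  diplotype set (the conventional retrospective normalisation of the
  logistic Bayesian LASSO lineage, isolated in :func:`retro_prob` so an
  alternative can be swapped in);
* trio: ``L_f = prod_i P(Z_ic | Y_ic=1, params) P(Z_iu | params)`` —
  the affected child's diplotype retrospectively, the untransmitted
  parental pair at its plain population probability (allelic
  exchangeability lets the trio factor this way);
* composite: ``L_cf = L_c * L_f``, a product of valid likelihoods that
  deliberately ignores between-unit dependence (corrected downstream by
  the magnitude adjustment).

Complete-data forms take explicit diplotype assignments; observed-data
forms marginalise over all genotype-compatible assignments and are what
the adjustment module differentiates.  All arithmetic is on the log
scale with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import (
    MISSING,
    FrequencyVector,
    HaplotypeList,
    HaplotypePair,
    PairSpace,
    RegressionParams,
    TrioRecord,
)
from .errors import DataError, ImpossibleStateError, MendelianInconsistencyError

__all__ = [
    "RegressionParams",
    "ParameterVector",
    "retro_prob",
    "cc_loglik",
    "trio_loglik",
    "composite_loglik",
    "observed_cc_loglik",
    "observed_trio_loglik",
    "trio_configurations",
    "LikelihoodEngine",
]


@dataclass
class ParameterVector:
    """The full parameter vector: logistic regression, frequencies, shrinkage.

    ``shrink_scale`` is the rate of the Laplace (double-exponential)
    shrinkage prior on the beta coefficients — a prior hyperparameter,
    not one of the eigenvalues of the adjustment.
    """

    regression: RegressionParams
    freqs: FrequencyVector
    shrink_scale: float = 1.0

    def __post_init__(self):
        if self.freqs.n_haplotypes != self.regression.n_effects + 1:
            raise DataError(
                "frequency vector length must be K+1 for K regression effects"
            )
        if self.shrink_scale <= 0:
            raise DataError("shrink_scale must be positive")

    @property
    def n_haplotypes(self) -> int:
        return self.freqs.n_haplotypes

    @property
    def p_adjust(self) -> int:
        """Dimension of the (alpha, beta) block entering H and J."""
        return 1 + self.regression.n_effects


# ---------------------------------------------------------------------------
# per-pair log factors
# ---------------------------------------------------------------------------

def _log_factors(space: PairSpace, params: ParameterVector):
    """log penetrance factors and log pair probabilities for every pair.

    Returns (logpen1, logpen0, logpp, logden1, logden0) where
    logpen1 = log[theta/(1+theta)], logpen0 = log[1/(1+theta)] and
    logden_y is the retrospective normaliser for phenotype y.
    """
    lt = space.log_theta(params.regression.alpha, params.regression.beta,
                         params.regression.mode)
    logpen1 = -np.logaddexp(0.0, -lt)
    logpen0 = -np.logaddexp(0.0, lt)
    logpp = space.log_pair_probs(params.freqs)
    logden1 = logsumexp(logpen1 + logpp)
    logden0 = logsumexp(logpen0 + logpp)
    return logpen1, logpen0, logpp, logden1, logden0


def retro_prob(pair: HaplotypePair, y: int, params: ParameterVector) -> float:
    """Retrospective diplotype probability P(Z = pair | Y = y, params).

    Penetrance-weighted HWE prior, normalised over the complete pair set,
    so ``sum_z retro_prob(z, y) = 1`` for each phenotype.
    """
    if y not in (0, 1):
        raise DataError("phenotype must be 0 or 1")
    space = PairSpace(n_haplotypes=params.n_haplotypes, mode=params.regression.mode)
    logpen1, logpen0, logpp, logden1, logden0 = _log_factors(space, params)
    i = space.pair_index(pair.first, pair.second)
    if y == 1:
        return float(np.exp(logpen1[i] + logpp[i] - logden1))
    return float(np.exp(logpen0[i] + logpp[i] - logden0))


def cc_loglik(assignments, params: ParameterVector) -> float:
    """Complete-data case-control log-likelihood for (pair, phenotype) pairs."""
    if not assignments:
        return 0.0
    space = PairSpace(n_haplotypes=params.n_haplotypes, mode=params.regression.mode)
    logpen1, logpen0, logpp, logden1, logden0 = _log_factors(space, params)
    total = 0.0
    for pair, y in assignments:
        i = space.pair_index(pair.first, pair.second)
        term = (logpen1[i] + logpp[i] - logden1) if y == 1 else (logpen0[i] + logpp[i] - logden0)
        if not np.isfinite(term):
            raise ImpossibleStateError(
                f"zero-probability assignment: pair ({pair.first},{pair.second}), y={y}"
            )
        total += term
    return float(total)


def trio_loglik(assignments, params: ParameterVector) -> float:
    """Complete-data trio log-likelihood for (child pair, untransmitted pair) tuples."""
    if not assignments:
        return 0.0
    space = PairSpace(n_haplotypes=params.n_haplotypes, mode=params.regression.mode)
    logpen1, _, logpp, logden1, _ = _log_factors(space, params)
    total = 0.0
    for zc, zu in assignments:
        ic = space.pair_index(zc.first, zc.second)
        iu = space.pair_index(zu.first, zu.second)
        term = (logpen1[ic] + logpp[ic] - logden1) + logpp[iu]
        if not np.isfinite(term):
            raise ImpossibleStateError(
                f"zero-probability trio assignment: Zc=({zc.first},{zc.second}), "
                f"Zu=({zu.first},{zu.second})"
            )
        total += term
    return float(total)


def composite_loglik(cc_assignments, trio_assignments, params: ParameterVector) -> float:
    """log L_cf = log L_c + log L_f (the composite factorisation)."""
    return cc_loglik(cc_assignments, params) + trio_loglik(trio_assignments, params)


# ---------------------------------------------------------------------------
# trio phase configurations
# ---------------------------------------------------------------------------

def trio_configurations(trio: TrioRecord, space: PairSpace, max_missing: int = 2):
    """All (child pair, untransmitted pair) configurations consistent with a trio.

    A configuration is consistent when some assignment of parental
    diplotypes compatible with G_f and G_m transmits a pair compatible
    with G_c; the untransmitted pair collects the two remaining parental
    haplotypes.  Returns deduplicated ``(zc_indices, zu_indices)`` arrays
    in deterministic order; raises on Mendelian impossibility.
    """
    cf = space.compatible(trio.g_father, max_missing=max_missing)
    cm = space.compatible(trio.g_mother, max_missing=max_missing)
    gc = trio.g_child
    obs = gc != MISSING
    hm = space.haplotypes.matrix
    configs = set()
    for pf in cf:
        f1, f2 = space.pairs[pf]
        for pm in cm:
            m1, m2 = space.pairs[pm]
            for tf, uf in ((f1, f2), (f2, f1)):
                for tm, um in ((m1, m2), (m2, m1)):
                    if np.any(hm[tf, obs] + hm[tm, obs] != gc[obs]):
                        continue
                    zc = space.pair_index(int(tf), int(tm))
                    zu = space.pair_index(int(uf), int(um))
                    configs.add((zc, zu))
    if not configs:
        raise MendelianInconsistencyError(
            f"trio {trio.trio_id or trio.pedigree_id}: no consistent phase configuration"
        )
    ordered = sorted(configs)
    zc_idx = np.array([c[0] for c in ordered], dtype=np.int64)
    zu_idx = np.array([c[1] for c in ordered], dtype=np.int64)
    return zc_idx, zu_idx


# ---------------------------------------------------------------------------
# observed-data (phase-marginalised) log-likelihoods
# ---------------------------------------------------------------------------

def observed_cc_loglik(subjects, params: ParameterVector,
                       haplotypes: HaplotypeList, max_missing: int = 2) -> float:
    """Case-control log-likelihood marginalised over compatible diplotypes."""
    engine = LikelihoodEngine(subjects, (), haplotypes,
                              mode=params.regression.mode, max_missing=max_missing)
    return engine.total_loglik(params.regression.alpha, params.regression.beta,
                               params.freqs)


def observed_trio_loglik(trios, params: ParameterVector,
                         haplotypes: HaplotypeList, max_missing: int = 2) -> float:
    """Trio log-likelihood marginalised over consistent phase configurations."""
    engine = LikelihoodEngine((), trios, haplotypes,
                              mode=params.regression.mode, max_missing=max_missing)
    return engine.total_loglik(params.regression.alpha, params.regression.beta,
                               params.freqs)


# ---------------------------------------------------------------------------
# vectorised engine
# ---------------------------------------------------------------------------

def _segment_logsumexp(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """log-sum-exp over contiguous segments defined by offsets (len n+1).

    Segments must be non-empty; -inf entries are handled.
    """
    if offsets.size <= 1:
        return np.empty(0)
    starts = offsets[:-1]
    mx = np.maximum.reduceat(values, starts)
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    rep = np.repeat(safe_mx, np.diff(offsets))
    sums = np.add.reduceat(np.exp(values - rep), starts)
    with np.errstate(divide="ignore"):
        out = safe_mx + np.log(sums)
    return np.where(np.isfinite(mx), out, -np.inf)


class LikelihoodEngine:
    """Precompiled observed-data composite likelihood over one block.

    Compiles each case-control subject to its compatible pair-index set
    and each trio to its consistent (Z_c, Z_u) configuration set, all as
    flat ragged arrays, so a likelihood evaluation is a handful of
    vectorised gathers — the adjustment module calls this hundreds of
    times per k update.

    ``pool_map``, when given, maps raw haplotype indices to retained
    ones (low-frequency haplotypes folded into the baseline) before
    sets are compiled.
    """

    def __init__(self, cc_subjects, trios, haplotypes: HaplotypeList,
                 mode: str = "additive", max_missing: int = 2,
                 full_haplotypes: HaplotypeList | None = None,
                 index_map=None, warn=None):
        self.haplotypes = haplotypes
        self.mode = mode
        self.space = PairSpace(haplotypes, mode=mode)
        self.cc_subjects = list(cc_subjects)
        self.trios = list(trios)

        # Pooling fallback: genotypes are first enumerated against the
        # retained list; only a genotype with no retained-list diplotype has
        # its full-list completions folded onto the baseline category, so no
        # unit is dropped and typical units keep their clean compatible sets.
        if index_map is not None:
            if full_haplotypes is None:
                raise DataError("index_map requires the full haplotype list")
            enum_space = PairSpace(full_haplotypes)
            imap = np.asarray(index_map, dtype=np.int64)
            mapped = np.sort(imap[enum_space.pairs], axis=1)
            pair_map = np.array(
                [self.space.pair_index(int(a), int(b)) for a, b in mapped],
                dtype=np.int64,
            )
        else:
            enum_space = self.space
            pair_map = None

        def fold(idx: np.ndarray) -> np.ndarray:
            return idx if pair_map is None else np.unique(pair_map[idx])

        cc_concat, cc_off, ys = [], [0], []
        for s in self.cc_subjects:
            idx = self.space.compatible(s.genotype, max_missing=max_missing)
            if idx.size == 0 and pair_map is not None:
                idx = fold(enum_space.compatible(s.genotype, max_missing=max_missing))
            if idx.size == 0:
                raise DataError(
                    f"subject {s.subject_id or s.pedigree_id}: genotype incompatible "
                    "with the haplotype list"
                )
            cc_concat.append(idx)
            cc_off.append(cc_off[-1] + idx.size)
            ys.append(s.phenotype)
        self.cc_idx = np.concatenate(cc_concat) if cc_concat else np.empty(0, dtype=np.int64)
        self.cc_offsets = np.array(cc_off, dtype=np.int64)
        self.cc_y = np.array(ys, dtype=np.int8)

        tc_concat, tu_concat, t_off = [], [], [0]
        for t in self.trios:
            try:
                zc, zu = trio_configurations(t, self.space, max_missing=max_missing)
            except MendelianInconsistencyError:
                if pair_map is None:
                    raise
                zc, zu = trio_configurations(t, enum_space, max_missing=max_missing)
                cfg = np.unique(np.column_stack([pair_map[zc], pair_map[zu]]), axis=0)
                zc, zu = cfg[:, 0], cfg[:, 1]
            tc_concat.append(zc)
            tu_concat.append(zu)
            t_off.append(t_off[-1] + zc.size)
        self.trio_zc = np.concatenate(tc_concat) if tc_concat else np.empty(0, dtype=np.int64)
        self.trio_zu = np.concatenate(tu_concat) if tu_concat else np.empty(0, dtype=np.int64)
        self.trio_offsets = np.array(t_off, dtype=np.int64)

        # units = cc subjects then trios; cluster index per unit for J
        ped_ids = [s.pedigree_id for s in self.cc_subjects] + [t.pedigree_id for t in self.trios]
        uniq = sorted(set(ped_ids))
        lookup = {p: i for i, p in enumerate(uniq)}
        self.cluster_ids = np.array([lookup[p] for p in ped_ids], dtype=np.int64)
        self.n_clusters = len(uniq)
        self.cluster_labels = uniq

        overlap = {s.subject_id for s in self.cc_subjects if s.subject_id} & {
            m for t in self.trios for m in (t.trio_id,) if m
        }
        if overlap and warn is not None:
            warn(f"ids appear in both the case-control and trio streams: {sorted(overlap)}")

    @property
    def n_units(self) -> int:
        return len(self.cc_subjects) + len(self.trios)

    @property
    def n_haplotypes(self) -> int:
        return self.space.n_haplotypes

    @staticmethod
    def _split_freqs(freqs):
        if isinstance(freqs, FrequencyVector):
            return freqs.f, freqs.d
        return np.asarray(freqs, dtype=float), 0.0

    def _factors(self, alpha: float, beta: np.ndarray, f: np.ndarray, d: float):
        # hand-rolled 1-D logsumexp: this runs in the sampler/adjustment hot
        # loop where scipy's generic implementation dominates the profile
        lt = alpha + self.space.design(self.mode) @ beta
        logpen1 = -np.logaddexp(0.0, -lt)
        logpen0 = -np.logaddexp(0.0, lt)
        fa = f[self.space.pairs[:, 0]]
        fb = f[self.space.pairs[:, 1]]
        pp = np.where(self.space.is_hom, d * fa + (1.0 - d) * fa * fb,
                      2.0 * (1.0 - d) * fa * fb)
        with np.errstate(divide="ignore"):
            logpp = np.log(pp)
        v1 = logpen1 + logpp
        v0 = logpen0 + logpp
        m1 = v1.max()
        m0 = v0.max()
        logden1 = m1 + np.log(np.exp(v1 - m1).sum())
        logden0 = m0 + np.log(np.exp(v0 - m0).sum())
        return logpen1, logpen0, logpp, logden1, logden0

    def unit_logliks(self, alpha: float, beta, freqs, d: float | None = None) -> np.ndarray:
        """Per-unit observed-data log-likelihood (cc subjects then trios).

        ``freqs`` may be a :class:`FrequencyVector` or a bare frequency
        array (then ``d`` applies, default 0).
        """
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        f, d0 = self._split_freqs(freqs)
        logpen1, logpen0, logpp, logden1, logden0 = self._factors(
            alpha, beta, f, d0 if d is None else d)
        parts = []
        if self.cc_y.size:
            num = np.where(self.cc_y[self._cc_unit_of()] == 1,
                           logpen1[self.cc_idx], logpen0[self.cc_idx]) + logpp[self.cc_idx]
            ll = _segment_logsumexp(num, self.cc_offsets)
            ll -= np.where(self.cc_y == 1, logden1, logden0)
            parts.append(ll)
        if self.trio_offsets.size > 1:
            num = logpen1[self.trio_zc] + logpp[self.trio_zc] + logpp[self.trio_zu]
            ll = _segment_logsumexp(num, self.trio_offsets) - logden1
            parts.append(ll)
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def _cc_unit_of(self) -> np.ndarray:
        # element -> owning subject index, cached
        cached = getattr(self, "_cc_unit_cache", None)
        if cached is None or cached.size != self.cc_idx.size:
            cached = np.repeat(np.arange(self.cc_y.size), np.diff(self.cc_offsets))
            self._cc_unit_cache = cached
        return cached

    def total_loglik(self, alpha: float, beta, freqs, d: float | None = None) -> float:
        u = self.unit_logliks(alpha, beta, freqs, d)
        return float(u.sum()) if u.size else 0.0

    # -- complete-data likelihood from sufficient counts (sampler hot path) --

    def complete_loglik_from_counts(self, n1_counts, n0_counts, tc_counts, tu_counts,
                                    alpha: float, beta, freqs,
                                    d: float | None = None) -> float:
        """Complete-data composite log-likelihood given per-pair assignment counts."""
        f, d0 = self._split_freqs(freqs)
        logpen1, logpen0, logpp, logden1, logden0 = self._factors(
            alpha, np.atleast_1d(np.asarray(beta, dtype=float)), f,
            d0 if d is None else d)
        n1 = float(n1_counts.sum())
        n0 = float(n0_counts.sum())
        m = float(tc_counts.sum())

        def dot(counts, vals):
            # avoid 0 * -inf = nan at zero-probability pairs nobody occupies
            nz = counts != 0
            return float(counts[nz] @ vals[nz]) if np.any(nz) else 0.0

        ll = (dot(n1_counts, logpen1 + logpp) - n1 * logden1
              + dot(n0_counts, logpen0 + logpp) - n0 * logden0
              + dot(tc_counts, logpen1 + logpp) - m * logden1
              + dot(tu_counts, logpp))
        return float(ll)
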