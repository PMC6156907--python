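"""Haplotype blocks, diplotypes and regression coding.

A haplotype block is an ordered set of L biallelic SNPs.  Alleles are
coded 0 (major) / 1 (minor), so a haplotype is a binary vector of length
L and an individual's unphased genotype is the minor-allele dosage
vector (entries 0/1/2, or -1 for missing).  The latent quantity the
whole package revolves around is the *diplotype*: the unordered pair of
haplotypes an individual carries, which maps many-to-one onto the
observed genotype.

This module provides:

* the domain types (:class:`Haplotype`, :class:`HaplotypePair`,
  :class:`FrequencyVector`, :class:`SubjectRecord`, :class:`TrioRecord`,
  :class:`RegressionParams`);
* :class:`PairSpace`, the vectorised workhorse that enumerates all
  (K+1)(K+2)/2 unordered pairs over a K+1 haplotype list, their
  population probabilities, design codings and genotype compatibility;
* genotype-compatible pair enumeration, Hardy-Weinberg diplotype
  probabilities with an optional inbreeding coefficient, mode-of-
  inheritance design vectors and the logistic odds;
* an EM estimator for haplotype frequencies, used to build an ordered
  haplotype list (descending frequency, baseline = most frequent) from
  unphased data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, MissingnessError

MISSING = -1

MODES = ("additive", "dominant", "recessive")

__all__ = [
    "MISSING",
    "MODES",
    "Haplotype",
    "HaplotypePair",
    "FrequencyVector",
    "RegressionParams",
    "SubjectRecord",
    "TrioRecord",
    "HaplotypeList",
    "PairSpace",
    "enumerate_pairs",
    "pair_probability",
    "design_vector",
    "odds",
    "estimate_frequencies_em",
    "build_haplotype_list",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    """One haplotype: ordered minor-allele indicators plus its list index.

    Index 0 is the baseline (most frequent) haplotype of its block.
    """

    alleles: tuple
    index: int

    def __post_init__(self):
        if not all(a in (0, 1) for a in self.alleles):
            raise DataError(f"haplotype alleles must be 0/1, got {self.alleles}")
        if self.index < 0:
            raise DataError("haplotype index must be non-negative")

    @property
    def label(self) -> str:
        """Allele string, e.g. ``'01101'``."""
        return "".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class HaplotypePair:
    """Unordered diplotype: two haplotype indices, stored with first <= second."""

    first: int
    second: int

    def __post_init__(self):
        if self.first < 0 or self.second < 0:
            raise DataError("haplotype indices must be non-negative")
        if self.first > self.second:  # normalise to the canonical order
            a, b = self.second, self.first
            object.__setattr__(self, "first", a)
            object.__setattr__(self, "second", b)

    @property
    def is_homozygous(self) -> bool:
        return self.first == self.second


@dataclass
class FrequencyVector:
    """Haplotype population frequencies plus an inbreeding coefficient.

    ``f`` holds K+1 probabilities in haplotype-list order.  ``d`` is the
    within-individual allelic correlation (0 = Hardy-Weinberg, the
    default); negative values down-weight homozygotes and are bounded
    below by ``-min_j f_j/(1-f_j)`` so all pair probabilities stay
    non-negative.
    """

    f: np.ndarray
    d: float = 0.0

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size < 1:
            raise DataError("frequency vector must be a non-empty 1-D array")
        if np.any(self.f < 0):
            raise DataError("haplotype frequencies must be non-negative")
        total = float(self.f.sum())
        if abs(total - 1.0) > 1e-8:
            raise DataError(f"haplotype frequencies must sum to 1, got {total}")
        self.f = self.f / total  # exact renormalisation
        if not self.d < 1.0:
            raise DataError(f"inbreeding coefficient d={self.d} must be < 1")
        if self.d < 0:
            # homozygote probability d f + (1-d) f^2 >= 0 constrains d from
            # below; only interior frequencies 0 < f < 1 bind
            interior = self.f[(self.f > 0) & (self.f < 1.0)]
            lo = -float(np.min(interior / (1.0 - interior))) if interior.size else -np.inf
            if not (lo < self.d):
                raise DataError(f"inbreeding coefficient d={self.d} must exceed {lo}")

    @property
    def n_haplotypes(self) -> int:
        return self.f.size


@dataclass
class RegressionParams:
    """Logistic model for the disease odds given a diplotype Z.

    log theta_Z = alpha + X_Z . beta, where theta_Z = P(Y=1|Z)/P(Y=0|Z),
    alpha is the baseline log-odds (phenocopy level) and beta_j the
    log-odds-ratio of haplotype j under the chosen mode of inheritance.
    """

    alpha: float
    beta: np.ndarray
    mode: str = "additive"

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.mode not in MODES:
            raise ConfigError(f"unknown inheritance mode {self.mode!r}; choose from {MODES}")
        if not np.isfinite(self.alpha) or not np.all(np.isfinite(self.beta)):
            raise DataError("regression parameters must be finite")

    @property
    def n_effects(self) -> int:
        return self.beta.size


def _as_genotype(g) -> np.ndarray:
    g = np.asarray(g, dtype=np.int8)
    if g.ndim != 1:
        raise DataError("genotype must be a 1-D dosage vector")
    ok = (g == MISSING) | ((g >= 0) & (g <= 2))
    if not np.all(ok):
        raise DataError(f"genotype entries must be 0/1/2 or {MISSING} (missing)")
    return g


@dataclass
class SubjectRecord:
    """One case-control individual: dosage genotype, phenotype, pedigree label."""

    genotype: np.ndarray
    phenotype: int
    pedigree_id: str
    subject_id: str = ""
    true_pair: HaplotypePair | None = None  # kept by the simulator for recovery tests

    def __post_init__(self):
        self.genotype = _as_genotype(self.genotype)
        if self.phenotype not in (0, 1):
            raise DataError(f"phenotype must be 0/1, got {self.phenotype}")
        if not np.any(self.genotype != MISSING):
            raise DataError("subject genotype is entirely missing")
        if not self.pedigree_id:
            raise DataError("pedigree_id must be non-empty")


@dataclass
class TrioRecord:
    """A case-parent trio (affected child plus both parents), unphased.

    The child phenotype is 1 by ascertainment.  Mendelian consistency at
    fully typed SNPs is validated on construction.
    """

    g_father: np.ndarray
    g_mother: np.ndarray
    g_child: np.ndarray
    pedigree_id: str
    trio_id: str = ""
    true_child_pair: HaplotypePair | None = None
    true_untransmitted_pair: HaplotypePair | None = None

    phenotype_child: int = field(default=1, init=False)

    def __post_init__(self):
        self.g_father = _as_genotype(self.g_father)
        self.g_mother = _as_genotype(self.g_mother)
        self.g_child = _as_genotype(self.g_child)
        if not (len(self.g_father) == len(self.g_mother) == len(self.g_child)):
            raise DataError("trio genotype vectors must share a length")
        if not self.pedigree_id:
            raise DataError("pedigree_id must be non-empty")
        from .errors import MendelianInconsistencyError

        bad = self.mendelian_violations()
        if bad.size:
            raise MendelianInconsistencyError(
                f"trio {self.trio_id or self.pedigree_id}: Mendelian inconsistency at "
                f"SNP position(s) {bad.tolist()}"
            )

    def mendelian_violations(self) -> np.ndarray:
        """Indices of fully typed SNPs where the child dosage is impossible."""
        return mendelian_violations(self.g_father, self.g_mother, self.g_child)


def mendelian_violations(g_father, g_mother, g_child) -> np.ndarray:
    """SNP indices where a child dosage cannot arise from the parents.

    Only fully typed SNPs are checked.  Transmissible allele counts from
    a parent dosage: 0 -> {0}, 1 -> {0, 1}, 2 -> {1}.
    """
    gf, gm, gc = (np.asarray(g, dtype=np.int8) for g in (g_father, g_mother, g_child))
    typed = (gf != MISSING) & (gm != MISSING) & (gc != MISSING)
    lo = (gf == 2).astype(int) + (gm == 2).astype(int)
    hi = (gf > 0).astype(int) + (gm > 0).astype(int)
    bad = typed & ((gc < lo) | (gc > hi))
    return np.nonzero(bad)[0]


# ---------------------------------------------------------------------------
# haplotype list
# ---------------------------------------------------------------------------

class HaplotypeList:
    """An ordered, duplicate-free list of haplotypes over one block.

    Order is fixed at construction (descending estimated frequency, ties
    broken lexicographically by allele string); index 0 is the baseline.
    """

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=np.int8)
        if m.ndim != 2:
            raise DataError("haplotype matrix must be 2-D (n_haplotypes x L)")
        if not np.all((m == 0) | (m == 1)):
            raise DataError("haplotype alleles must be 0/1")
        labels = ["".join(map(str, row)) for row in m]
        if len(set(labels)) != len(labels):
            raise DataError("haplotype list contains duplicates")
        self.matrix = m
        self._labels = labels

    @classmethod
    def from_strings(cls, strings) -> "HaplotypeList":
        return cls([[int(c) for c in s] for s in strings])

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    @property
    def labels(self) -> list:
        return list(self._labels)

    def label(self, i: int) -> str:
        return self._labels[i]

    def haplotype(self, i: int) -> Haplotype:
        return Haplotype(tuple(int(a) for a in self.matrix[i]), i)

    def index_of(self, label: str) -> int:
        try:
            return self._labels.index(label)
        except ValueError:
            raise KeyError(f"haplotype {label!r} not in list") from None

    def __repr__(self):
        return f"HaplotypeList({self._labels})"


# ---------------------------------------------------------------------------
# pair space
# ---------------------------------------------------------------------------

class PairSpace:
    """All unordered haplotype pairs over a K+1 haplotype list.

    Pairs are enumerated in row-major order ``(0,0),(0,1),...,(K,K)``
    with first <= second, so pair order is deterministic given the list.
    Precomputes the design matrix for each inheritance mode on demand,
    homozygosity flags, and (when built from a :class:`HaplotypeList`)
    the per-pair summed allele vectors used for genotype compatibility.
    """

    def __init__(self, haplotypes: HaplotypeList | None = None, n_haplotypes: int | None = None,
                 mode: str = "additive"):
        if haplotypes is None and n_haplotypes is None:
            raise ConfigError("PairSpace needs a HaplotypeList or n_haplotypes")
        if mode not in MODES:
            raise ConfigError(f"unknown inheritance mode {mode!r}; choose from {MODES}")
        self.haplotypes = haplotypes
        n = len(haplotypes) if haplotypes is not None else int(n_haplotypes)
        if n < 1:
            raise DataError("need at least one haplotype")
        self.n_haplotypes = n
        self.mode = mode
        pairs = [(a, b) for a in range(n) for b in range(a, n)]
        self.pairs = np.array(pairs, dtype=np.int64)          # (P, 2)
        self.n_pairs = len(pairs)
        self.is_hom = self.pairs[:, 0] == self.pairs[:, 1]
        self._index = {tuple(p): i for i, p in enumerate(pairs)}
        # copies[p, j] = number of copies of haplotype j in pair p
        copies = np.zeros((self.n_pairs, n), dtype=np.int8)
        np.add.at(copies, (np.arange(self.n_pairs), self.pairs[:, 0]), 1)
        np.add.at(copies, (np.arange(self.n_pairs), self.pairs[:, 1]), 1)
        self.copies = copies
        self._design = {}
        if haplotypes is not None:
            hm = haplotypes.matrix.astype(np.int8)
            self.pair_sums = hm[self.pairs[:, 0]] + hm[self.pairs[:, 1]]  # (P, L)
        else:
            self.pair_sums = None

    def pair_index(self, first: int, second: int) -> int:
        a, b = (first, second) if first <= second else (second, first)
        return self._index[(a, b)]

    def pair_index_array(self, first, second) -> np.ndarray:
        """Vectorised pair index lookup (row-major closed form)."""
        first = np.asarray(first, dtype=np.int64)
        second = np.asarray(second, dtype=np.int64)
        a = np.minimum(first, second)
        b = np.maximum(first, second)
        n = self.n_haplotypes
        return a * n - (a * (a - 1)) // 2 + (b - a)

    def design(self, mode: str | None = None) -> np.ndarray:
        """(P, K) design matrix; column j codes non-baseline haplotype j+1."""
        mode = mode or self.mode
        if mode not in MODES:
            raise ConfigError(f"unknown inheritance mode {mode!r}; choose from {MODES}")
        if mode not in self._design:
            c = self.copies[:, 1:]  # baseline column excluded
            if mode == "additive":
                X = c.astype(float)
            elif mode == "dominant":
                X = (c >= 1).astype(float)
            else:  # recessive
                X = (c == 2).astype(float)
            self._design[mode] = X
        return self._design[mode]

    # -- probabilities ------------------------------------------------------

    def pair_probs(self, freqs: FrequencyVector) -> np.ndarray:
        """Population probability of every pair under HWE with inbreeding d."""
        f = freqs.f
        if f.size != self.n_haplotypes:
            raise DataError("frequency vector length mismatch with haplotype list")
        fa = f[self.pairs[:, 0]]
        fb = f[self.pairs[:, 1]]
        d = freqs.d
        p = np.where(self.is_hom, d * fa + (1.0 - d) * fa * fb, 2.0 * (1.0 - d) * fa * fb)
        return p

    def log_pair_probs(self, freqs: FrequencyVector) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pair_probs(freqs))

    def log_theta(self, alpha: float, beta: np.ndarray, mode: str | None = None) -> np.ndarray:
        """Per-pair log disease odds alpha + X_Z . beta."""
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        if beta.size != self.n_haplotypes - 1:
            raise DataError(f"beta must have length {self.n_haplotypes - 1}")
        return alpha + self.design(mode) @ beta

    # -- genotype compatibility --------------------------------------------

    def compatible(self, genotype, max_missing: int = 2) -> np.ndarray:
        """Indices of pairs whose allele sums match the genotype where typed.

        An empty result is valid: it signals a genotype incompatible with
        the retained haplotype list.  More than ``max_missing`` missing
        SNPs raises :class:`MissingnessError` (completion enumeration is
        combinatorial in missingness).
        """
        if self.pair_sums is None:
            raise ConfigError("this PairSpace has no allele matrix; build from a HaplotypeList")
        g = _as_genotype(genotype)
        if g.size != self.haplotypes.n_snps:
            raise DataError("genotype length does not match the block's SNP count")
        n_miss = int(np.sum(g == MISSING))
        if n_miss > max_missing:
            raise MissingnessError(
                f"genotype has {n_miss} missing SNPs, exceeding the cap of {max_missing}"
            )
        obs = g != MISSING
        ok = np.all(self.pair_sums[:, obs] == g[obs], axis=1)
        return np.nonzero(ok)[0]


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def enumerate_pairs(genotype, haplotypes: HaplotypeList, max_missing: int = 2) -> list:
    """Genotype-compatible diplotypes, in deterministic pair order.

    Returns the (possibly empty) list of :class:`HaplotypePair` whose
    summed allele vectors reproduce the genotype at every typed SNP.
    """
    space = PairSpace(haplotypes)
    idx = space.compatible(genotype, max_missing=max_missing)
    return [HaplotypePair(int(space.pairs[i, 0]), int(space.pairs[i, 1])) for i in idx]


def pair_probability(pair: HaplotypePair, freqs: FrequencyVector) -> float:
    """Population probability of an unordered diplotype.

    Under HWE (d=0): f_j^2 for homozygotes, 2 f_j f_k for heterozygotes;
    with inbreeding d the homozygote becomes d f_j + (1-d) f_j^2 and the
    heterozygote 2 (1-d) f_j f_k.
    """
    j, k = pair.first, pair.second
    if k >= freqs.n_haplotypes:
        raise DataError("pair index exceeds frequency vector length")
    f = freqs.f
    d = freqs.d
    if j == k:
        return float(d * f[j] + (1.0 - d) * f[j] ** 2)
    return float(2.0 * (1.0 - d) * f[j] * f[k])


def design_vector(pair: HaplotypePair, mode: str, n_haplotypes: int) -> np.ndarray:
    """Length-K regression coding of a diplotype (baseline haplotype 0 excluded)."""
    if mode not in MODES:
        raise ConfigError(f"unknown inheritance mode {mode!r}; choose from {MODES}")
    if pair.second >= n_haplotypes:
        raise DataError("pair index exceeds haplotype count")
    counts = np.zeros(n_haplotypes, dtype=int)
    counts[pair.first] += 1
    counts[pair.second] += 1
    c = counts[1:]
    if mode == "additive":
        return c.astype(float)
    if mode == "dominant":
        return (c >= 1).astype(float)
    return (c == 2).astype(float)


def odds(pair: HaplotypePair, params: RegressionParams) -> float:
    """Disease odds theta_Z = exp(alpha + X_Z . beta); computed on the log scale."""
    x = design_vector(pair, params.mode, params.n_effects + 1)
    return math.exp(params.alpha + float(x @ params.beta))


# ---------------------------------------------------------------------------
# frequency EM and list construction
# ---------------------------------------------------------------------------

def estimate_frequencies_em(genotypes, haplotypes: HaplotypeList, max_missing: int = 2,
                            max_iter: int = 500, tol: float = 1e-9) -> np.ndarray:
    """EM estimate of haplotype frequencies from unphased genotypes.

    Standard gene-counting EM: E-step weights each compatible diplotype
    by its HWE probability under the current frequencies, M-step counts
    expected haplotype copies.  Genotypes with no compatible pair are
    ignored (the caller decides how to pool them).
    """
    space = PairSpace(haplotypes)
    sets = []
    for g in genotypes:
        idx = space.compatible(g, max_missing=max_missing)
        if idx.size:
            sets.append(idx)
    n_hap = len(haplotypes)
    if not sets:
        return np.full(n_hap, 1.0 / n_hap)
    f = np.full(n_hap, 1.0 / n_hap)
    a_idx = space.pairs[:, 0]
    b_idx = space.pairs[:, 1]
    for _ in range(max_iter):
        p = np.where(space.is_hom, f[a_idx] * f[b_idx], 2.0 * f[a_idx] * f[b_idx])
        counts = np.zeros(n_hap)
        for idx in sets:
            w = p[idx]
            tot = w.sum()
            if tot <= 0:
                continue
            w = w / tot
            np.add.at(counts, a_idx[idx], w)
            np.add.at(counts, b_idx[idx], w)
        new_f = counts / counts.sum()
        delta = float(np.max(np.abs(new_f - f)))
        f = new_f
        if delta < tol:
            break
    return f


def _candidate_haplotypes(genotypes, n_snps: int, max_missing: int = 2) -> np.ndarray:
    """Union of haplotypes appearing in some diplotype completion of the data.

    For a dosage vector the compatible haplotypes form a sub-hypercube:
    allele fixed to 0 where dosage 0, fixed to 1 where dosage 2, free at
    heterozygous or missing SNPs — and every such haplotype has a valid
    partner, so the union over subjects is exactly the candidate set.
    """
    seen = set()
    for g in genotypes:
        g = _as_genotype(g)
        if g.size != n_snps:
            raise DataError("genotype length mismatch")
        if int(np.sum(g == MISSING)) > max_missing:
            continue
        free = np.nonzero((g == 1) | (g == MISSING))[0]
        base = np.where(g == 2, 1, 0).astype(np.int8)
        for bits in itertools.product((0, 1), repeat=free.size):
            h = base.copy()
            h[free] = bits
            seen.add(tuple(int(x) for x in h))
    if not seen:
        raise DataError("no usable genotypes to build a haplotype list from")
    return np.array(sorted(seen), dtype=np.int8)


def build_haplotype_list(cc_subjects, trios=(), max_missing: int = 2):
    """Build the block's ordered haplotype list and EM frequencies from data.

    Candidate haplotypes are collected from all diplotype completions of
    the case-control and trio-member genotypes, frequencies estimated by
    EM treating members as unrelated (initialisation only — the sampler
    updates frequencies), and the list ordered by descending frequency
    with lexicographic tie-break.  Index 0 (most frequent) is the
    baseline category.

    Returns ``(HaplotypeList, freq_array)`` aligned with each other.
    """
    genotypes = [s.genotype for s in cc_subjects]
    for t in trios:
        genotypes.extend([t.g_father, t.g_mother, t.g_child])
    if not genotypes:
        raise DataError("no data supplied")
    n_snps = len(genotypes[0])
    cand = _candidate_haplotypes(genotypes, n_snps, max_missing=max_missing)
    hl = HaplotypeList(cand)
    f = estimate_frequencies_em(genotypes, hl, max_missing=max_missing)
    labels = hl.labels
    order = sorted(range(len(hl)), key=lambda i: (-f[i], labels[i]))
    return HaplotypeList(cand[order]), f[order]
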