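"""Simulators for case-control, trio and pedigree-structured haplotype data.

Data are generated under exactly the model the inference assumes: a
Hardy-Weinberg pool of block haplotypes (linkage disequilibrium is
carried implicitly by drawing whole haplotypes), a logistic penetrance
log theta_Z = alpha + X_Z beta, Mendelian transmission within families,
and ascertainment by rejection (case/control quotas; trios kept only
when the child is affected).  Pedigree mode gene-drops a user-supplied
family template and extracts both case-control subjects and complete
affected-child trios from every family under a shared pedigree id —
the overlapping-extraction dependence the magnitude adjustment is built
to correct.

The generators emit unphased dosage genotypes; the true diplotypes are
retained on each record for recovery tests.  Fixed seeds give bitwise-
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    FrequencyVector,
    HaplotypeList,
    HaplotypePair,
    PairSpace,
    RegressionParams,
    SubjectRecord,
    TrioRecord,
)
from .errors import DataError, SimulationError

__all__ = [
    "PedigreeTemplate",
    "SimulationSpec",
    "default_template",
    "singleton_template",
    "block_pool",
    "simulate_case_control",
    "simulate_trios",
    "simulate_pedigrees",
    "type_I_error_study",
    "StudyResult",
]

_BATCH = 4096


@dataclass(frozen=True)
class PedigreeTemplate:
    """Family structure replicated per simulated pedigree.

    ``members`` is an ordered list of ``(id, father_id, mother_id)``
    with ``None`` parents marking founders.  Parents must precede their
    children, so the structure is acyclic by construction.
    """

    members: tuple

    def __post_init__(self):
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate member ids in pedigree template")
        seen = set()
        n_founders = 0
        for mid, fa, mo in self.members:
            if (fa is None) != (mo is None):
                raise DataError(f"member {mid}: either both or neither parent")
            if fa is None:
                n_founders += 1
            else:
                if fa not in seen or mo not in seen:
                    raise DataError(f"member {mid}: parents must precede children")
            seen.add(mid)
        if n_founders < 2:
            raise DataError("template needs at least 2 founders")


def default_template() -> PedigreeTemplate:
    """Three-generation template: 2 founders, 2 offspring, a married-in
    founder and one grandchild — small, but one family can yield cases,
    controls and an affected-child trio simultaneously."""
    return PedigreeTemplate((
        ("gf", None, None),
        ("gm", None, None),
        ("o1", "gf", "gm"),
        ("o2", "gf", "gm"),
        ("sp", None, None),
        ("gc", "o1", "sp"),
    ))


def singleton_template() -> PedigreeTemplate:
    """Two unrelated founders per 'family' (no within-family dependence)."""
    return PedigreeTemplate((("a", None, None), ("b", None, None)))


def block_pool():
    """A 7-SNP haplotype pool with four common and two rare haplotypes.

    Patterned after an ABCC1-like block: one haplotype fixed at
    frequency 0.1663, the rest chosen to give a realistic spread with
    two rare (< 0.05) members; frequencies sum to one exactly.
    """
    labels = ["0000000", "0010001", "0101010", "1100000", "1111111", "1011010"]
    freqs = np.array([0.40, 0.20, 0.1663, 0.15, 0.0437, 0.04])
    return HaplotypeList.from_strings(labels), FrequencyVector(freqs)


@dataclass
class SimulationSpec:
    """Generating model and sample-size quotas for one simulated dataset."""

    haplotypes: HaplotypeList
    freqs: FrequencyVector
    regression: RegressionParams
    n_cases: int = 0
    n_controls: int = 0
    n_trios: int = 0
    pedigree_template: PedigreeTemplate | None = None
    seed: int = 0
    max_rejection_draws: int = 5_000_000

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_trios) < 0:
            raise DataError("sample-size quotas must be non-negative")
        if self.freqs.n_haplotypes != len(self.haplotypes):
            raise DataError("frequency vector length must match the haplotype pool")
        if self.regression.n_effects != len(self.haplotypes) - 1:
            raise DataError("beta length must be K for a K+1 haplotype pool")


def _machinery(spec: SimulationSpec):
    space = PairSpace(spec.haplotypes, mode=spec.regression.mode)
    pp = space.pair_probs(spec.freqs)
    lt = space.log_theta(spec.regression.alpha, spec.regression.beta,
                         spec.regression.mode)
    p_aff = 1.0 / (1.0 + np.exp(-lt))
    return space, pp, p_aff


def _rng(spec: SimulationSpec, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.seed)


# ---------------------------------------------------------------------------
# independent units
# ---------------------------------------------------------------------------

def simulate_case_control(spec: SimulationSpec,
                          rng: np.random.Generator | None = None) -> list:
    """Rejection-sample independent subjects to the case/control quotas."""
    rng = _rng(spec, rng)
    space, pp, p_aff = _machinery(spec)
    hm = spec.haplotypes.matrix
    need_case, need_ctrl = spec.n_cases, spec.n_controls
    out: list = []
    draws = 0
    idx = 0
    while need_case > 0 or need_ctrl > 0:
        if draws >= spec.max_rejection_draws:
            raise SimulationError(
                f"case-control rejection sampling exhausted {draws} draws "
                f"(still need {need_case} cases, {need_ctrl} controls)"
            )
        n = min(_BATCH, spec.max_rejection_draws - draws)
        draws += n
        pairs = rng.choice(space.n_pairs, size=n, p=pp)
        ys = (rng.uniform(size=n) < p_aff[pairs]).astype(int)
        for p, y in zip(pairs, ys):
            if y == 1 and need_case > 0:
                need_case -= 1
            elif y == 0 and need_ctrl > 0:
                need_ctrl -= 1
            else:
                continue
            a, b = space.pairs[p]
            out.append(SubjectRecord(
                genotype=hm[a] + hm[b],
                phenotype=int(y),
                pedigree_id=f"cc{idx}",
                subject_id=f"cc{idx}",
                true_pair=HaplotypePair(int(a), int(b)),
            ))
            idx += 1
            if need_case == 0 and need_ctrl == 0:
                break
    return out


def simulate_trios(spec: SimulationSpec,
                   rng: np.random.Generator | None = None) -> list:
    """Independent case-parent trios ascertained through an affected child."""
    rng = _rng(spec, rng)
    space, pp, p_aff = _machinery(spec)
    hm = spec.haplotypes.matrix
    out: list = []
    draws = 0
    while len(out) < spec.n_trios:
        if draws >= spec.max_rejection_draws:
            raise SimulationError(
                f"trio rejection sampling exhausted {draws} draws "
                f"(have {len(out)}/{spec.n_trios} trios)"
            )
        n = min(_BATCH, spec.max_rejection_draws - draws)
        draws += n
        pf = rng.choice(space.n_pairs, size=n, p=pp)
        pm = rng.choice(space.n_pairs, size=n, p=pp)
        pick_f = rng.integers(0, 2, size=n)
        pick_m = rng.integers(0, 2, size=n)
        tf = space.pairs[pf, pick_f]
        uf = space.pairs[pf, 1 - pick_f]
        tm = space.pairs[pm, pick_m]
        um = space.pairs[pm, 1 - pick_m]
        child_pair = space.pair_index_array(tf, tm)
        keep = rng.uniform(size=n) < p_aff[child_pair]
        for i in np.nonzero(keep)[0]:
            if len(out) >= spec.n_trios:
                break
            j = len(out)
            out.append(TrioRecord(
                g_father=hm[space.pairs[pf[i], 0]] + hm[space.pairs[pf[i], 1]],
                g_mother=hm[space.pairs[pm[i], 0]] + hm[space.pairs[pm[i], 1]],
                g_child=hm[tf[i]] + hm[tm[i]],
                pedigree_id=f"trio{j}",
                trio_id=f"trio{j}",
                true_child_pair=HaplotypePair(int(tf[i]), int(tm[i])),
                true_untransmitted_pair=HaplotypePair(int(uf[i]), int(um[i])),
            ))
    return out


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def _gene_drop(template: PedigreeTemplate, space: PairSpace, pp: np.ndarray,
               p_aff: np.ndarray, rng: np.random.Generator):
    """One family: diplotype (as ordered hap indices) and phenotype per member."""
    haps: dict = {}
    pheno: dict = {}
    for mid, fa, mo in template.members:
        if fa is None:
            p = rng.choice(space.n_pairs, p=pp)
            h = (int(space.pairs[p, 0]), int(space.pairs[p, 1]))
            if rng.integers(0, 2):  # randomise order so transmission is symmetric
                h = (h[1], h[0])
        else:
            h = (haps[fa][rng.integers(0, 2)], haps[mo][rng.integers(0, 2)])
        haps[mid] = h
        pair = space.pair_index(h[0], h[1])
        pheno[mid] = int(rng.uniform() < p_aff[pair])
    return haps, pheno


def simulate_pedigrees(spec: SimulationSpec,
                       rng: np.random.Generator | None = None):
    """Gene-drop replicated family templates until all quotas are met.

    Returns ``(cc_subjects, trios)``.  Every phenotyped member enters
    the case-control stream (subject to quota) and every affected child
    with both parents in the template yields a trio, so individuals can
    appear in both streams — all units of one family share its
    pedigree id.
    """
    if spec.pedigree_template is None:
        raise DataError("simulate_pedigrees needs a pedigree_template")
    rng = _rng(spec, rng)
    template = spec.pedigree_template
    space, pp, p_aff = _machinery(spec)
    hm = spec.haplotypes.matrix
    parents_of = {m[0]: (m[1], m[2]) for m in template.members}

    cc: list = []
    trios: list = []
    need_case, need_ctrl, need_trio = spec.n_cases, spec.n_controls, spec.n_trios
    fam = 0
    max_fams = max(1, spec.max_rejection_draws // max(1, len(template.members)))
    while need_case > 0 or need_ctrl > 0 or need_trio > 0:
        if fam >= max_fams:
            raise SimulationError(
                f"pedigree simulation exhausted {fam} families (still need "
                f"{need_case} cases, {need_ctrl} controls, {need_trio} trios)"
            )
        fam_id = f"fam{fam}"
        fam += 1
        haps, pheno = _gene_drop(template, space, pp, p_aff, rng)
        geno = {m: hm[h[0]] + hm[h[1]] for m, h in haps.items()}
        for mid, fa, mo in template.members:
            if fa is not None and pheno[mid] == 1 and need_trio > 0:
                need_trio -= 1
                # untransmitted haplotype of each parent; the child's stored
                # order is (paternal, maternal) by construction
                tf, tm = haps[mid]
                uf = haps[fa][1] if haps[fa][0] == tf else haps[fa][0]
                um = haps[mo][1] if haps[mo][0] == tm else haps[mo][0]
                trios.append(TrioRecord(
                    g_father=geno[fa], g_mother=geno[mo], g_child=geno[mid],
                    pedigree_id=fam_id, trio_id=f"{fam_id}:{mid}",
                    true_child_pair=HaplotypePair(tf, tm),
                    true_untransmitted_pair=HaplotypePair(uf, um),
                ))
            y = pheno[mid]
            if y == 1 and need_case > 0:
                need_case -= 1
            elif y == 0 and need_ctrl > 0:
                need_ctrl -= 1
            else:
                continue
            h = haps[mid]
            cc.append(SubjectRecord(
                genotype=geno[mid], phenotype=y, pedigree_id=fam_id,
                subject_id=f"{fam_id}:{mid}",
                true_pair=HaplotypePair(h[0], h[1]),
            ))
    return cc, trios


# ---------------------------------------------------------------------------
# type-I error harness
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Stratified null rejection rates with binomial standard errors."""

    table: pd.DataFrame
    n_replicates: int
    n_failed: int
    failures: list = field(default_factory=list)

    def rate(self, stratum: str) -> float:
        sel = self.table[self.table["stratum"] == stratum]
        return float(sel["rate"].iloc[0]) if len(sel) else float("nan")


def type_I_error_study(spec: SimulationSpec, n_reps: int, mcmc_config,
                       seed: int | None = None,
                       rare_threshold: float = 0.05) -> StudyResult:
    """Null-model rejection rates of the BF & CI rule, by haplotype frequency.

    ``spec`` must encode the null (beta = 0).  Each replicate simulates
    a fresh dataset (pedigree-structured if the spec has a template,
    independent otherwise), runs the full sampler, and counts each
    non-baseline haplotype's significance call as one Bernoulli trial.
    Trials are stratified by the *generating-pool* frequency of the
    haplotype (haplotypes not in the pool — phase artifacts — count as
    rare).  Failed replicates are excluded and reported.
    """
    from .sampler import run_mcmc

    if np.any(spec.regression.beta != 0.0):
        raise DataError("type-I error study requires a null spec (beta = 0)")
    pool = {spec.haplotypes.label(i): float(spec.freqs.f[i])
            for i in range(len(spec.haplotypes))}
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = ss.spawn(n_reps)
    counts = {"common": [0, 0], "rare": [0, 0]}  # stratum -> [tests, rejects]
    failures: list = []
    for r in range(n_reps):
        rng = np.random.Generator(np.random.PCG64(children[r]))
        rep_seed = int(children[r].generate_state(1, np.uint32)[0] % (2**31))
        try:
            if spec.pedigree_template is not None:
                cc, trios = simulate_pedigrees(spec, rng)
            else:
                cc = simulate_case_control(spec, rng)
                trios = simulate_trios(spec, rng)
            cfg = replace(mcmc_config, seed=rep_seed)
            res = run_mcmc(cc, trios, cfg)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failures.append(f"replicate {r}: {type(exc).__name__}: {exc}")
            continue
        for row in res.summary.rows:
            freq_true = pool.get(row.haplotype, 0.0)
            stratum = "common" if freq_true >= rare_threshold else "rare"
            counts[stratum][0] += 1
            counts[stratum][1] += int(row.significant)
    records = []
    for stratum, (n_tests, n_rej) in counts.items():
        rate = n_rej / n_tests if n_tests else float("nan")
        se = float(np.sqrt(rate * (1 - rate) / n_tests)) if n_tests else float("nan")
        records.append({"stratum": stratum, "n_tests": n_tests,
                        "n_reject": n_rej, "rate": rate, "se": se})
    table = pd.DataFrame(records)
    return StudyResult(table=table, n_replicates=n_reps,
                       n_failed=len(failures), failures=failures)
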