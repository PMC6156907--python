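"""Linkage PED/MAP input and output, the MAF screen, and results tables.

The on-disk dialect is classic linkage format: MAP rows ``chrom id cM
bp``; PED rows with six leading columns (family, individual, father,
mother, sex, phenotype) followed by two allele columns per SNP, allele
``0`` meaning missing.  Phenotype coding defaults to 2=case /
1=control / 0 or -9=missing, with an optional 1/0 dialect.

At load time alleles are oriented so that 1 codes the *minor* allele,
determined from sample allele frequencies (ties broken by allele name:
the lexicographically larger name is called minor).  Complete
affected-child trios — both parents present and genotyped, child
genotyped and affected — are extracted automatically; their members do
not re-enter the case-control stream.  Every excluded individual or
SNP is recorded in the dataset's provenance log with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, SubjectRecord, TrioRecord, mendelian_violations
from .errors import ConfigError, DataError, MendelianInconsistencyError

__all__ = [
    "Dataset",
    "read_block_spec",
    "read_ped",
    "write_ped",
    "maf_filter",
    "write_results",
    "read_results",
]

_PHENO_DIALECTS = {
    "12": {"2": 1, "1": 0, "0": None, "-9": None},
    "01": {"1": 1, "0": 0, "-9": None},
}


@dataclass
class Dataset:
    """Loaded study data: record streams plus map metadata and provenance."""

    subjects: list
    trios: list
    snp_ids: list
    positions: list
    chromosomes: list
    provenance: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def dosage_matrix(self) -> np.ndarray:
        """All genotypes (subjects then trio members) as one dosage matrix."""
        rows = [s.genotype for s in self.subjects]
        for t in self.trios:
            rows.extend([t.g_father, t.g_mother, t.g_child])
        return np.array(rows, dtype=np.int8) if rows else np.empty((0, self.n_snps), np.int8)


def read_block_spec(path) -> list:
    """Block definition file: one SNP id per line, comments with '#'."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    if not ids:
        raise DataError(f"block spec {path} contains no SNP ids")
    if len(set(ids)) != len(ids):
        raise DataError(f"block spec {path} lists duplicate SNP ids")
    return ids


def _read_map(map_path):
    snp_ids, positions, chroms = [], [], []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise DataError(f"{map_path}:{ln}: MAP line needs 4 columns, got {len(parts)}")
        chroms.append(parts[0])
        snp_ids.append(parts[1])
        positions.append(int(parts[3]))
    if len(set(snp_ids)) != len(snp_ids):
        raise DataError(f"{map_path}: duplicate SNP ids")
    return snp_ids, positions, chroms


def read_ped(ped_path, map_path, block=None, phenotype_coding: str = "12",
             max_missing: int = 2) -> Dataset:
    """Load a PED/MAP pair, orient alleles, and split into subject streams.

    ``block`` may be a path to a block-spec file or a list of SNP ids;
    when given, genotypes are restricted to those SNPs in map order.
    """
    if phenotype_coding not in _PHENO_DIALECTS:
        raise ConfigError(
            f"unknown phenotype coding {phenotype_coding!r}; valid: "
            f"{sorted(_PHENO_DIALECTS)}"
        )
    pheno_map = _PHENO_DIALECTS[phenotype_coding]
    snp_ids, positions, chroms = _read_map(map_path)
    n_all = len(snp_ids)

    if block is not None:
        block_ids = read_block_spec(block) if isinstance(block, (str, Path)) else list(block)
        unknown = set(block_ids) - set(snp_ids)
        if unknown:
            raise DataError(f"block SNPs not in map: {sorted(unknown)}")
        keep = [i for i, s in enumerate(snp_ids) if s in set(block_ids)]
    else:
        keep = list(range(n_all))
    snp_ids = [snp_ids[i] for i in keep]
    positions = [positions[i] for i in keep]
    chroms = [chroms[i] for i in keep]
    L = len(keep)

    individuals = []  # (fam, iid, fid, mid, pheno, alleles (L,2) of str)
    provenance = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_all:
            raise DataError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_all} columns "
                f"(6 + 2x{n_all} SNPs), got {len(parts)}"
            )
        fam, iid, fid, mid, _sex, pheno_code = parts[:6]
        if not fam:
            raise DataError(f"{ped_path}:{ln}: empty family id")
        if pheno_code not in pheno_map:
            raise DataError(
                f"{ped_path}:{ln}: phenotype code {pheno_code!r} outside the "
                f"{phenotype_coding!r} dialect"
            )
        geno = np.array(parts[6:], dtype=object).reshape(n_all, 2)[keep]
        individuals.append((fam, iid, fid, mid, pheno_map[pheno_code], geno))

    # minor-allele orientation per SNP from pooled sample frequencies
    minor = []
    for j in range(L):
        counts: dict = {}
        for rec in individuals:
            for a in rec[5][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise DataError(f"SNP {snp_ids[j]}: more than two alleles {alleles}")
        if not alleles:
            minor.append(None)
            provenance.append(f"SNP {snp_ids[j]}: all genotypes missing")
        elif len(alleles) == 1:
            minor.append(None)  # monomorphic: dosage 0 everywhere
        else:
            a, b = alleles  # a < b lexicographically
            if counts[a] < counts[b]:
                minor.append(a)
            elif counts[b] < counts[a]:
                minor.append(b)
            else:
                minor.append(b)  # tie: larger allele name is called minor
    def dosage(geno) -> np.ndarray:
        g = np.full(L, MISSING, dtype=np.int8)
        for j in range(L):
            a1, a2 = geno[j]
            if a1 == "0" or a2 == "0":
                continue
            if minor[j] is None:
                g[j] = 0
            else:
                g[j] = int(a1 == minor[j]) + int(a2 == minor[j])
        return g

    by_family: dict = {}
    for rec in individuals:
        by_family.setdefault(rec[0], []).append(rec)

    subjects, trios = [], []
    for fam, members in by_family.items():
        lookup = {iid: (fid, mid, ph, geno) for _, iid, fid, mid, ph, geno in members}
        dosages = {iid: dosage(v[3]) for iid, v in lookup.items()}
        usable = {}
        for iid, g in dosages.items():
            n_miss = int(np.sum(g == MISSING))
            if not np.any(g != MISSING):
                provenance.append(f"{fam}:{iid}: excluded (all genotypes missing)")
            elif n_miss > max_missing:
                provenance.append(
                    f"{fam}:{iid}: excluded ({n_miss} missing SNPs exceeds cap {max_missing})"
                )
            else:
                usable[iid] = g
        in_trio = set()
        for iid, (fid, mid, ph, _g) in lookup.items():
            if ph != 1 or fid == "0" or mid == "0":
                continue
            if fid not in usable or mid not in usable or iid not in usable:
                continue
            bad = mendelian_violations(usable[fid], usable[mid], usable[iid])
            if bad.size:
                raise MendelianInconsistencyError(
                    f"family {fam}, child {iid}: Mendelian inconsistency at "
                    f"SNP(s) {[snp_ids[i] for i in bad]}"
                )
            trios.append(TrioRecord(
                g_father=usable[fid], g_mother=usable[mid], g_child=usable[iid],
                pedigree_id=fam, trio_id=f"{fam}:{iid}",
            ))
            in_trio.update({iid, fid, mid})
        for iid, (fid, mid, ph, _g) in lookup.items():
            if iid in in_trio:
                if iid in usable and ph is not None:
                    provenance.append(f"{fam}:{iid}: member of a trio, not re-used as subject")
                continue
            if ph is None:
                provenance.append(f"{fam}:{iid}: excluded (missing phenotype)")
                continue
            if iid not in usable:
                continue
            subjects.append(SubjectRecord(
                genotype=usable[iid], phenotype=ph, pedigree_id=fam,
                subject_id=f"{fam}:{iid}",
            ))
    return Dataset(subjects=subjects, trios=trios, snp_ids=snp_ids,
                   positions=positions, chromosomes=chroms, provenance=provenance)


def write_ped(subjects, trios, snp_ids, ped_path, map_path,
              positions=None, chromosome: str = "1") -> None:
    """Write records as linkage PED/MAP (major allele '1', minor '2').

    Case-control subjects become singleton rows in their pedigree's
    family; trios become father/mother/child rows with parent phenotype
    missing and the child affected.
    """
    L = len(snp_ids)
    positions = positions if positions is not None else [(i + 1) * 1000 for i in range(L)]
    with open(map_path, "w") as fh:
        for s, p in zip(snp_ids, positions):
            fh.write(f"{chromosome}\t{s}\t0\t{p}\n")

    def allele_cols(g):
        out = []
        for v in g:
            out.extend({0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2")}.get(int(v), ("0", "0")))
        return out

    with open(ped_path, "w") as fh:
        for i, s in enumerate(subjects):
            iid = s.subject_id or f"s{i}"
            row = [s.pedigree_id, iid, "0", "0", "0", "2" if s.phenotype == 1 else "1"]
            fh.write(" ".join(row + allele_cols(s.genotype)) + "\n")
        for i, t in enumerate(trios):
            base = t.trio_id or f"t{i}"
            fa, mo, ch = f"{base}_f", f"{base}_m", f"{base}_c"
            fh.write(" ".join([t.pedigree_id, fa, "0", "0", "1", "0"]
                              + allele_cols(t.g_father)) + "\n")
            fh.write(" ".join([t.pedigree_id, mo, "0", "0", "2", "0"]
                              + allele_cols(t.g_mother)) + "\n")
            fh.write(" ".join([t.pedigree_id, ch, fa, mo, "0", "2"]
                              + allele_cols(t.g_child)) + "\n")


def maf_filter(dosages, snp_ids=None, threshold: float = 0.01):
    """Retain SNPs with sample MAF >= threshold (default the 1% screen).

    MAF is computed over non-missing alleles and folded at 0.5; the
    boundary is inclusive (MAF exactly at the threshold is retained).
    Returns ``(retained_ids, report)`` where the report lists each
    SNP's MAF and decision; all-missing SNPs are excluded with a
    warning row.
    """
    dosages = np.asarray(dosages)
    n_snps = dosages.shape[1]
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(n_snps)]
    records, retained = [], []
    for j in range(n_snps):
        col = dosages[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            records.append({"snp": snp_ids[j], "maf": np.nan, "retained": False,
                            "reason": "all genotypes missing"})
            continue
        af = float(obs.sum()) / (2.0 * obs.size)
        maf = min(af, 1.0 - af)
        keep = maf >= threshold
        if keep:
            retained.append(snp_ids[j])
        records.append({"snp": snp_ids[j], "maf": maf, "retained": keep,
                        "reason": "" if keep else f"MAF {maf:.4g} < {threshold}"})
    return retained, pd.DataFrame(records)


_RESULT_COLUMNS = ["block", "haplotype", "freq", "OR", "ci_lower", "ci_upper",
                   "BF", "significant"]


def write_results(summary, path, block: str = "B1") -> None:
    """Write a posterior summary as a results TSV (haplotypes prefixed 'h')."""
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in summary.rows:
            fh.write("\t".join([
                block, f"h{r.haplotype}",
                f"{r.freq:.10g}", f"{r.or_mean:.10g}",
                f"{r.ci_lower:.10g}", f"{r.ci_upper:.10g}",
                f"{r.bf:.10g}", str(bool(r.significant)),
            ]) + "\n")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _RESULT_COLUMNS:
        raise DataError(f"unexpected results columns in {path}: {list(df.columns)}")
    return df
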