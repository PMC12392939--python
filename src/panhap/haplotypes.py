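"""Gene-haplotype enumeration and haplotype-phenotype association.

A haplotype is the ordered allele string an accession carries over the SNP
sites of a gene region. Accessions with any heterozygous call in the region
are excluded (reason ``het``), as are those with missing calls (``missing``);
the remaining homozygous allele strings are grouped and labelled H1, H2, ...
in order of descending carrier frequency.

Significance among haplotype trait-value groups uses Duncan's multiple range
test: a stepwise studentized-range procedure whose critical value for a span
of p ordered means is q(1 - alpha_p, p, df) * sqrt(MSE / n_h), with
protection level alpha_p = 1 - (1 - alpha)^(p - 1) and n_h the harmonic mean
group size. A span declared homogeneous protects all of its sub-spans. The
superior haplotype is the qualifying group with the highest mean whose Duncan
letter set is disjoint from that of the lowest-mean qualifying group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

# call codes in a SnpGenotypeMatrix
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class SnpGenotypeMatrix:
    """Accessions x biallelic SNP sites with calls in {hom-ref, het, hom-alt, missing}."""

    accessions: list[str]
    #: site metadata: columns chrom, pos, ref, alt; sorted by (chrom, pos)
    sites: pd.DataFrame
    #: int8 codes, shape (n_accessions, n_sites): 0/1/2/-1
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accessions), len(self.sites)):
            raise ValueError("calls shape does not match accessions x sites")
        self.sites = self.sites.reset_index(drop=True)
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index
        if not (order.values == np.arange(len(self.sites))).all():
            self.sites = self.sites.loc[order].reset_index(drop=True)
            self.calls = self.calls[:, order.values]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        m = ((self.sites["chrom"] == chrom)
             & (self.sites["pos"] >= start) & (self.sites["pos"] <= end))
        return np.flatnonzero(m.values)

    @classmethod
    def from_variant_records(cls, records, samples: Sequence[str] | None = None
                             ) -> "SnpGenotypeMatrix":
        from .io_formats import Genotype

        snps = [r for r in records if r.is_snp]
        if samples is None:
            samples = list(snps[0].samples) if snps else []
        code = {Genotype.HOM_REF: HOM_REF, Genotype.HET: HET,
                Genotype.HOM_ALT: HOM_ALT, Genotype.MISSING: MISSING}
        calls = np.full((len(samples), len(snps)), MISSING, dtype=np.int8)
        for j, r in enumerate(snps):
            for i, s in enumerate(samples):
                call = r.samples.get(s)
                if call is not None:
                    calls[i, j] = code[call.genotype]
        sites = pd.DataFrame({
            "chrom": [r.chrom for r in snps],
            "pos": [r.pos for r in snps],
            "ref": [r.ref for r in snps],
            "alt": [r.alt for r in snps],
        })
        return cls(list(samples), sites, calls)


@dataclass
class HaplotypeTable:
    """Per-accession haplotype labels for one gene region."""

    gene_id: str
    site_index: np.ndarray            # indices into the source matrix sites
    sites: pd.DataFrame
    assignments: dict[str, str]       # accession -> label
    excluded: dict[str, str]          # accession -> "het" | "missing"
    haplotype_strings: dict[str, str]  # label -> allele string
    frequencies: dict[str, int]       # label -> carrier count

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_strings)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, lab, self.haplotype_strings[lab])
                for a, lab in self.assignments.items()]
        rows += [(a, f"excluded:{r}", "") for a, r in self.excluded.items()]
        return pd.DataFrame(rows, columns=["accession", "haplotype", "alleles"])


def enumerate_haplotypes(
    matrix: SnpGenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    gene_id: str = "region",
) -> HaplotypeTable:
    """Group accessions by their homozygous allele string over a region.

    Heterozygous carriers are excluded first, then accessions with missing
    calls; labels H1, H2, ... follow descending frequency with ties broken by
    first occurrence.
    """
    if region is None:
        idx = np.arange(matrix.n_sites)
    else:
        idx = matrix.site_indices(*region)
    if len(idx) == 0:
        raise ValueError(f"{gene_id}: no SNPs in region {region}")
    sites = matrix.sites.iloc[idx]
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    strings: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for i, acc in enumerate(matrix.accessions):
        row = matrix.calls[i, idx]
        if (row == HET).any():
            excluded[acc] = "het"
        elif (row == MISSING).any():
            excluded[acc] = "missing"
        else:
            alleles = np.where(row == HOM_ALT, alts, refs)
            strings[acc] = "".join(alleles)
    # descending frequency, ties by first occurrence among accessions
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for i, (acc, s) in enumerate(strings.items()):
        counts[s] = counts.get(s, 0) + 1
        first.setdefault(s, i)
    ordered = sorted(counts, key=lambda s: (-counts[s], first[s]))
    label_of = {s: f"H{i + 1}" for i, s in enumerate(ordered)}
    assignments = {acc: label_of[s] for acc, s in strings.items()}
    return HaplotypeTable(
        gene_id=gene_id,
        site_index=idx,
        sites=sites.reset_index(drop=True),
        assignments=assignments,
        excluded=excluded,
        haplotype_strings={label_of[s]: s for s in ordered},
        frequencies={label_of[s]: counts[s] for s in ordered},
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def duncan_critical_q(p: int, df: float, alpha: float) -> float:
    """Duncan critical studentized-range value for a span of p means.

    Uses the protection level alpha_p = 1 - (1 - alpha)^(p - 1).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(studentized_range.ppf(1.0 - alpha_p, p, df))


@dataclass
class DuncanGrouping:
    """Haplotype group means with Duncan significance letters."""

    table: pd.DataFrame     # index: group label (descending mean); n, mean, letters
    alpha: float
    df_error: int
    mse: float

    def letters(self, group: str) -> set[str]:
        return set(self.table.loc[group, "letters"])

    def different(self, a: str, b: str) -> bool:
        """True when the two groups share no significance letter."""
        return not (self.letters(a) & self.letters(b))


def duncan_mrt(groups: Mapping[str, Sequence[float]],
               alpha: float = 0.05) -> DuncanGrouping:
    """Duncan's multiple range test over trait values grouped by haplotype.

    Requires >= 2 groups with n >= 2 each. Raises on zero within-group
    variance everywhere (the test statistic is undefined).
    """
    names = list(groups)
    data = {k: np.asarray(list(groups[k]), dtype=float) for k in names}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
        if not np.isfinite(v).all():
            raise ValueError(f"group {k!r} has non-finite values")
    ns = np.array([len(data[k]) for k in names])
    means = np.array([data[k].mean() for k in names])
    n_tot = int(ns.sum())
    df_error = n_tot - len(names)
    if df_error < 1:
        raise ValueError("residual degrees of freedom < 1")
    sse = float(sum(((data[k] - data[k].mean()) ** 2).sum() for k in names))
    if sse == 0.0:
        raise ValueError("zero within-group variance everywhere; "
                         "Duncan's test is undefined")
    mse = sse / df_error
    n_h = len(names) / float((1.0 / ns).sum())
    se = np.sqrt(mse / n_h)

    order = np.argsort(-means, kind="stable")
    sorted_names = [names[i] for i in order]
    sorted_means = means[order]
    g = len(sorted_names)

    # stepwise multiple range procedure: test the widest span first; a span
    # found homogeneous protects all its sub-spans
    homogeneous: list[tuple[int, int]] = []
    visited: set[tuple[int, int]] = set()

    def scan(i: int, j: int) -> None:
        if i >= j or (i, j) in visited:
            return
        visited.add((i, j))
        p = j - i + 1
        lsr = duncan_critical_q(p, df_error, alpha) * se
        if sorted_means[i] - sorted_means[j] <= lsr:
            homogeneous.append((i, j))
            return
        scan(i, j - 1)
        scan(i + 1, j)

    scan(0, g - 1)
    # keep maximal homogeneous spans only
    spans = [s for s in homogeneous
             if not any(o != s and o[0] <= s[0] and s[1] <= o[1]
                        for o in homogeneous)]
    spans = sorted(set(spans))
    # every group not inside any span stands alone
    covered = set()
    for a, b in spans:
        covered.update(range(a, b + 1))
    for i in range(g):
        if i not in covered:
            spans.append((i, i))
    spans = sorted(set(spans))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(g)]
    for li, (a, b) in enumerate(spans):
        ch = alphabet[li] if li < len(alphabet) else f"<{li}>"
        for i in range(a, b + 1):
            letters[i] += ch
    table = pd.DataFrame(
        {"n": ns[order], "mean": sorted_means, "letters": letters},
        index=pd.Index(sorted_names, name="group"))
    return DuncanGrouping(table=table, alpha=alpha, df_error=df_error, mse=mse)


# ---------------------------------------------------------------------------
# Superior-haplotype calling
# ---------------------------------------------------------------------------

@dataclass
class SuperiorCall:
    gene_id: str
    superior: str | None
    inferior: str | None
    min_n: int
    reason: str | None = None
    grouping: DuncanGrouping | None = None


def call_superior_haplotype(
    table: HaplotypeTable,
    phenotypes: pd.Series,
    min_n: int = 5,
    alpha: float = 0.05,
) -> SuperiorCall:
    """Call the superior haplotype for a gene from phenotype group means.

    Only haplotypes with at least ``min_n`` phenotyped carriers qualify. The
    superior call requires the top-mean group's Duncan letters to be disjoint
    from the bottom-mean group's; otherwise no superior haplotype is declared.
    """
    groups: dict[str, list[float]] = {}
    for acc, lab in table.assignments.items():
        if acc in phenotypes.index:
            v = float(phenotypes[acc])
            groups.setdefault(lab, []).append(v)
    qualifying = {k: v for k, v in groups.items() if len(v) >= min_n}
    if len(qualifying) < 2:
        return SuperiorCall(table.gene_id, None, None, min_n,
                            reason="fewer than 2 qualifying haplotypes")
    try:
        grouping = duncan_mrt(qualifying, alpha=alpha)
    except ValueError as e:
        return SuperiorCall(table.gene_id, None, None, min_n, reason=str(e))
    top = grouping.table.index[0]
    bottom = grouping.table.index[-1]
    if grouping.different(top, bottom):
        return SuperiorCall(table.gene_id, top, bottom, min_n,
                            grouping=grouping)
    return SuperiorCall(table.gene_id, None, bottom, min_n,
                        reason="top and bottom groups not separated",
                        grouping=grouping)


# ---------------------------------------------------------------------------
# Haplotype assignment for new accessions
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssignment:
    accession: str
    label: str | None            # catalogue label, "novel", or None if excluded
    reason: str | None = None    # "het" | "missing" for exclusions
    alleles: str | None = None   # the novel allele string when label == "novel"


def assign_haplotypes(
    matrix: SnpGenotypeMatrix, catalogue: HaplotypeTable
) -> list[HaplotypeAssignment]:
    """Assign catalogue haplotype labels to new accessions.

    The new matrix must cover the catalogue's SNP sites exactly (chrom, pos,
    ref, alt); an exact allele-string match receives the catalogue label,
    het/missing carriers are excluded, and unseen strings are "novel".
    """
    want = catalogue.sites[["chrom", "pos", "ref", "alt"]]
    key_cols = ["chrom", "pos", "ref", "alt"]
    have = matrix.sites[key_cols].reset_index()
    merged = want.merge(have, on=key_cols, how="left")
    if merged["index"].isna().any():
        row = merged[merged["index"].isna()].iloc[0]
        raise ValueError(
            f"catalogue site {row['chrom']}:{row['pos']} missing from matrix")
    idx = merged["index"].to_numpy(dtype=int)
    refs = want["ref"].to_numpy()
    alts = want["alt"].to_numpy()
    by_string = {s: lab for lab, s in catalogue.haplotype_strings.items()}
    out: list[HaplotypeAssignment] = []
    for i, acc in enumerate(matrix.accessions):
        row = matrix.calls[i, idx]
        if (row == HET).any():
            out.append(HaplotypeAssignment(acc, None, reason="het"))
        elif (row == MISSING).any():
            out.append(HaplotypeAssignment(acc, None, reason="missing"))
        else:
            s = "".join(np.where(row == HOM_ALT, alts, refs))
            lab = by_string.get(s)
            if lab is None:
                out.append(HaplotypeAssignment(acc, "novel", alleles=s))
            else:
                out.append(HaplotypeAssignment(acc, lab))
    return out
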