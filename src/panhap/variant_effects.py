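"""Variant filtering, functional-effect classification, and summary tables.

Region assignment tests exon membership first (so "exonic" includes UTR
positions), then introns; everything outside a gene span is intergenic.
Coding SNPs are classified by strand-aware codon translation under the
standard nuclear code: same amino acid -> synonymous, stop gained ->
nonsense, otherwise missense. CDS InDels are frameshift when their size is
not a multiple of three, inframe otherwise. Splice annotation follows the
common convention: donor/acceptor = first/last two intronic bases of an
intron (in transcription order), splice_region = within 8 intronic or 3
exonic bases of an exon-intron junction.

A variant overlapping several genes takes the most severe consequence
(nonsense > frameshift > missense > inframe > splice donor/acceptor >
synonymous > UTR > splice_region > intronic), ties broken by the smaller
gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .io_formats import GeneModel, VariantRecord

REGIONS = ("intergenic", "intronic", "exonic")
EXONIC_SUBCLASSES = ("missense", "nonsense", "synonymous", "utr",
                     "frameshift", "inframe", "none")
SPLICE_CLASSES = ("donor", "acceptor", "splice_region", "none")

# splice windows (bases from the exon-intron junction)
SPLICE_SITE_INTRON_BASES = 2
SPLICE_REGION_INTRON_BASES = 8
SPLICE_REGION_EXON_BASES = 3


@dataclass
class VariantEffect:
    region: str                      # intergenic | intronic | exonic
    subclass: str = "none"           # exonic subclass
    splice: str = "none"             # donor | acceptor | splice_region | none
    gene_id: str | None = None
    aa_change: str | None = None     # e.g. Leu90Trp, when coding SNP
    boundary_spanning: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"bad region {self.region!r}")
        if self.subclass not in EXONIC_SUBCLASSES:
            raise ValueError(f"bad subclass {self.subclass!r}")
        if self.region != "exonic" and self.subclass != "none":
            raise ValueError("subclass requires region == exonic")


_SEVERITY = {
    "nonsense": 0, "frameshift": 1, "missense": 2, "inframe": 3,
    "donor": 4, "acceptor": 4, "synonymous": 5, "utr": 6,
    "splice_region": 7, "intronic": 8, "exonic_none": 9, "intergenic": 10,
}


def _severity(effect: VariantEffect) -> int:
    if effect.subclass in ("nonsense", "frameshift", "missense", "inframe",
                           "synonymous"):
        base = _SEVERITY[effect.subclass]
    elif effect.splice in ("donor", "acceptor"):
        base = _SEVERITY["donor"]
    elif effect.subclass == "utr":
        base = _SEVERITY["utr"]
    elif effect.splice == "splice_region":
        base = _SEVERITY["splice_region"]
    elif effect.region == "intronic":
        base = _SEVERITY["intronic"]
    elif effect.region == "exonic":
        base = _SEVERITY["exonic_none"]
    else:
        base = _SEVERITY["intergenic"]
    # splice-site annotation upgrades intronic/synonymous severity
    if effect.splice in ("donor", "acceptor"):
        base = min(base, _SEVERITY["donor"])
    return base


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    removed_qual: int = 0
    removed_depth: int = 0


def filter_variants(
    records: Sequence[VariantRecord],
    min_qual: float = 20.0,
    min_depth: int = 50,
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep records with qual >= min_qual and depth >= min_depth (inclusive).

    Record depth is the sum of available per-sample depths; a record with no
    depth anywhere fails the depth rule. A record failing both rules is
    counted under both in the report.
    """
    report = FilterReport(n_input=len(records))
    kept: list[VariantRecord] = []
    for r in records:
        ok_qual = r.qual is not None and r.qual >= min_qual
        depth = r.total_depth
        ok_depth = depth is not None and depth >= min_depth
        if not ok_qual:
            report.removed_qual += 1
        if not ok_depth:
            report.removed_depth += 1
        if ok_qual and ok_depth:
            kept.append(r)
    report.n_retained = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in translation order (1-based)."""
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def _affected_pos(v: VariantRecord) -> int:
    """Leftmost affected genomic base of a variant (1-based).

    SNPs/MNPs affect their own position; anchored InDels affect the base
    after the shared anchor.
    """
    if v.svtype is not None:
        return v.pos
    if len(v.ref) == len(v.alt):
        return v.pos
    return v.pos + 1


def _affected_span(v: VariantRecord) -> tuple[int, int]:
    if v.svtype is not None:
        return v.pos, v.end if v.end is not None else v.pos
    return v.pos, v.pos + max(len(v.ref) - 1, 0)


def _indel_size(v: VariantRecord) -> int:
    return v.sv_length if v.svtype is not None else abs(len(v.ref) - len(v.alt))


def _splice_annotation(gene: GeneModel, pos: int, in_exon: bool) -> str:
    """Splice annotation of a position relative to the gene's introns."""
    for intron_i, (s, e) in enumerate(gene.introns):
        if s <= pos <= e:
            d_left = pos - s       # bases from the intron's left junction
            d_right = e - pos
            # transcription order: on + the left junction is the donor side
            left_is_donor = gene.strand == "+"
            if d_left < SPLICE_SITE_INTRON_BASES:
                return "donor" if left_is_donor else "acceptor"
            if d_right < SPLICE_SITE_INTRON_BASES:
                return "acceptor" if left_is_donor else "donor"
            if min(d_left, d_right) < SPLICE_REGION_INTRON_BASES:
                return "splice_region"
            return "none"
    if in_exon:
        introns = gene.introns
        for s, e in gene.exons:
            if s <= pos <= e:
                has_left_intron = any(ie == s - 1 for _, ie in introns)
                has_right_intron = any(js == e + 1 for js, _ in introns)
                if has_left_intron and pos - s < SPLICE_REGION_EXON_BASES:
                    return "splice_region"
                if has_right_intron and e - pos < SPLICE_REGION_EXON_BASES:
                    return "splice_region"
    return "none"


def _classify_in_gene(
    v: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> VariantEffect:
    pos = _affected_pos(v)
    span = _affected_span(v)
    in_exon = any(s <= pos <= e for s, e in gene.exons)
    boundary = False
    if span[1] > span[0]:
        # does the affected span cross an exon-intron junction?
        for s, e in gene.exons:
            if span[0] < s <= span[1] or span[0] <= e < span[1]:
                boundary = True
                break
    splice = _splice_annotation(gene, pos, in_exon)
    if not in_exon:
        return VariantEffect("intronic", "none", splice, gene.gene_id,
                             boundary_spanning=boundary)
    in_cds = any(s <= pos <= e for s, e in gene.cds)
    if not in_cds:
        return VariantEffect("exonic", "utr", splice, gene.gene_id,
                             boundary_spanning=boundary)
    if not gene.coding_valid:
        # gene flagged at load time; no coding-effect call is made
        return VariantEffect("exonic", "none", splice, gene.gene_id,
                             boundary_spanning=boundary)
    # coding position
    if v.svtype is not None or len(v.ref) != len(v.alt):
        sub = "frameshift" if _indel_size(v) % 3 != 0 else "inframe"
        return VariantEffect("exonic", sub, splice, gene.gene_id,
                             boundary_spanning=boundary)
    # SNP (or MNP classified base-by-base at its leftmost base)
    cds_pos = _cds_positions(gene)
    i = cds_pos.index(pos)
    codon_i, offset = divmod(i, 3)
    codon_positions = cds_pos[3 * codon_i:3 * codon_i + 3]
    seq = genome[gene.chrom]
    bases = [seq[p - 1] for p in codon_positions]
    alt_base = v.alt[0] if len(v.alt) == 1 else v.alt[pos - v.pos]
    ref_base = v.ref[0] if len(v.ref) == 1 else v.ref[pos - v.pos]
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = alt_base.translate(_COMPLEMENT)
    ref_codon = "".join(bases)
    alt_codon_l = list(bases)
    alt_codon_l[offset] = alt_base
    alt_codon = "".join(alt_codon_l)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        sub = "synonymous"
    elif alt_aa == "*":
        sub = "nonsense"
    else:
        sub = "missense"
    aa_change = f"{_aa3(ref_aa)}{codon_i + 1}{_aa3(alt_aa)}"
    return VariantEffect("exonic", sub, splice, gene.gene_id,
                         aa_change=aa_change, boundary_spanning=boundary)


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def classify_effect(
    v: VariantRecord,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> VariantEffect:
    """Classify one variant's functional effect against gene models.

    The variant's REF allele must agree with the genome sequence; a mismatch
    raises naming the position. With several overlapping genes the most
    severe consequence wins, ties broken by the smaller gene id.
    """
    if v.chrom not in genome:
        raise ValueError(f"unknown chromosome {v.chrom!r}")
    seq = genome[v.chrom]
    if v.svtype is None:
        observed = seq[v.pos - 1:v.pos - 1 + len(v.ref)]
        if observed.upper() != v.ref.upper():
            raise ValueError(
                f"REF mismatch at {v.chrom}:{v.pos}: VCF {v.ref!r} vs "
                f"genome {observed!r}")
    else:
        if seq[v.pos - 1].upper() != v.ref[:1].upper():
            raise ValueError(
                f"REF mismatch at {v.chrom}:{v.pos}: VCF {v.ref[:1]!r} vs "
                f"genome {seq[v.pos - 1]!r}")
    pos = _affected_pos(v)
    hits = [g for g in genes if g.chrom == v.chrom and g.spans(pos)]
    if not hits:
        return VariantEffect("intergenic")
    effects = [_classify_in_gene(v, g, genome) for g in hits]
    effects.sort(key=lambda e: (_severity(e), e.gene_id))
    return effects[0]


def classify_effects(
    records: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[VariantEffect]:
    return [classify_effect(v, genes, genome) for v in records]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeSummary:
    """Per-chromosome variant counts, densities per Mb, and shares of total."""

    table: pd.DataFrame  # index chrom; columns count, density_per_mb, share_pct

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())


def chromosome_summary_from_counts(
    counts: Mapping[str, int], chrom_lengths: Mapping[str, int]
) -> ChromosomeSummary:
    """Build the per-chromosome summary from precomputed counts."""
    for chrom in counts:
        if chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {chrom!r}")
        if chrom_lengths[chrom] <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
    total = sum(counts.values())
    rows = {}
    for chrom in counts:
        n = int(counts[chrom])
        mb = chrom_lengths[chrom] / 1e6
        rows[chrom] = {
            "count": n,
            "density_per_mb": round(n / mb, 2),
            "share_pct": round(100.0 * n / total, 2) if total else 0.0,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["count"] = table["count"].astype(int)
    return ChromosomeSummary(table.sort_index())


def summarize_by_chromosome(
    records: Sequence[VariantRecord],
    chrom_lengths: Mapping[str, int],
) -> ChromosomeSummary:
    counts: dict[str, int] = {}
    for r in records:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {r.chrom!r}")
        counts[r.chrom] = counts.get(r.chrom, 0) + 1
    return chromosome_summary_from_counts(counts, chrom_lengths)


@dataclass
class GeneSetSummary:
    name: str
    n_variants: int
    n_genes: int              # unique genes in the set hit by >= 1 variant
    mean_per_gene: float      # n_variants / n_genes, 2 decimals; 0 if empty
    empty: bool = False


def summarize_gene_set(
    records: Sequence[VariantRecord],
    effects: Sequence[VariantEffect],
    gene_set: Iterable[str],
    name: str = "gene_set",
) -> GeneSetSummary:
    """Count variants whose affected gene is in the set.

    Genes without any variant do not enter the per-gene mean denominator.
    """
    wanted = set(gene_set)
    hit_genes: set[str] = set()
    n = 0
    for eff in effects:
        if eff.gene_id is not None and eff.gene_id in wanted:
            n += 1
            hit_genes.add(eff.gene_id)
    if not hit_genes:
        return GeneSetSummary(name, 0, 0, 0.0, empty=True)
    return GeneSetSummary(name, n, len(hit_genes),
                          round(n / len(hit_genes), 2))


@dataclass
class RegionReport:
    chrom: str
    start: int
    end: int
    total: int
    by_size_class: dict[str, int]        # snp / indel / sv
    genic: int
    intergenic: int
    intronic: int
    exonic: int
    exonic_subclasses: dict[str, int]

    def __post_init__(self) -> None:
        assert self.genic + self.intergenic == self.total
        assert self.intronic + self.exonic == self.genic
        assert sum(self.exonic_subclasses.values()) == self.exonic
        assert sum(self.by_size_class.values()) == self.total


def region_report(
    records: Sequence[VariantRecord],
    effects: Sequence[VariantEffect],
    chrom: str,
    start: int,
    end: int,
) -> RegionReport:
    """Variant breakdown inside a 1-based closed genomic interval."""
    if end < start:
        raise ValueError(f"empty interval {chrom}:{start}-{end}")
    by_size = {"snp": 0, "indel": 0, "sv": 0}
    genic = intergenic = intronic = exonic = 0
    subclasses: dict[str, int] = {}
    total = 0
    for r, eff in zip(records, effects):
        if r.chrom != chrom or not (start <= r.pos <= end):
            continue
        total += 1
        by_size[r.size_class] += 1
        if eff.region == "intergenic":
            intergenic += 1
        else:
            genic += 1
            if eff.region == "intronic":
                intronic += 1
            else:
                exonic += 1
                subclasses[eff.subclass] = subclasses.get(eff.subclass, 0) + 1
    return RegionReport(chrom, start, end, total, by_size, genic, intergenic,
                        intronic, exonic, subclasses)


def effects_to_frame(
    records: Sequence[VariantRecord], effects: Sequence[VariantEffect]
) -> pd.DataFrame:
    rows = []
    for r, e in zip(records, effects):
        rows.append({
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "size_class": r.size_class, "region": e.region,
            "subclass": e.subclass, "splice": e.splice,
            "gene_id": e.gene_id or "", "aa_change": e.aa_change or "",
        })
    return pd.DataFrame(rows)
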