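"""Readers and writers for the external formats the pipeline consumes.

Dialects handled here:

* OrthoFinder ``Orthogroups.tsv``: tab-separated, first column ``Orthogroup``,
  remaining columns one per genome holding comma-space-separated gene lists
  (possibly empty).
* VCF 4.2 (via cyvcf2): QUAL and per-sample GT/DP are honoured; the INFO keys
  ``SVTYPE``/``END``/``STRANDS`` are parsed for structural-variant records.
  Multi-allelic sites are split into biallelic records.
* GFF3 with a gene -> mRNA -> exon/CDS hierarchy (via gffutils); FASTA via
  Biopython.

Coordinate convention: external formats keep their native 1-based closed
coordinates; all internal arithmetic is 0-based half-open, converted only at
this boundary.
"""

from __future__ import annotations

import os
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import cyvcf2
import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupTable:
    """Gene-family membership: family id -> per-genome gene-id lists."""

    family_ids: list[str]
    genome_ids: list[str]
    #: members[i][j] = list of gene ids of genome j in family i (may be empty)
    members: list[list[list[str]]]

    def __post_init__(self) -> None:
        if len(set(self.family_ids)) != len(self.family_ids):
            dup = _first_duplicate(self.family_ids)
            raise FormatError(f"duplicate family id: {dup!r}")
        seen: set[str] = set()
        for fam, row in zip(self.family_ids, self.members):
            if len(row) != len(self.genome_ids):
                raise FormatError(f"family {fam!r}: ragged member row")
            for genes in row:
                for g in genes:
                    if g in seen:
                        raise FormatError(
                            f"gene {g!r} appears in more than one family")
                    seen.add(g)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def to_presence_absence(self) -> "PresenceAbsenceMatrix":
        from .pangenome import PresenceAbsenceMatrix

        counts = np.array(
            [[len(genes) for genes in row] for row in self.members],
            dtype=np.int64,
        ).reshape(self.n_families, len(self.genome_ids))
        return PresenceAbsenceMatrix(
            family_ids=list(self.family_ids),
            genome_ids=list(self.genome_ids),
            gene_counts=counts,
        )


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


def read_orthogroups(path: str | os.PathLike) -> OrthogroupTable:
    """Read an OrthoFinder ``Orthogroups.tsv`` file.

    Raises :class:`FormatError` on duplicate family ids or ragged rows (the
    error names the offending id / line number).
    """
    family_ids: list[str] = []
    members: list[list[list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        genome_ids = cols[1:]
        if not genome_ids:
            raise FormatError(f"{path}: no genome columns in header")
        ncol = len(cols)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: ragged row "
                    f"({len(fields)} fields, expected {ncol})")
            family_ids.append(fields[0])
            members.append(
                [[g for g in cell.split(", ") if g] for cell in fields[1:]])
    return OrthogroupTable(family_ids, genome_ids, members)


def write_orthogroups(table: OrthogroupTable, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.genome_ids) + "\n")
        for fam, row in zip(table.family_ids, table.members):
            fh.write(fam + "\t" + "\t".join(", ".join(c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass
class SampleCall:
    genotype: Genotype
    depth: int | None = None


@dataclass
class VariantRecord:
    """One biallelic SNP / InDel / SV with per-sample calls.

    ``pos`` is 1-based as in VCF. SVs carry ``svtype``, ``end`` (1-based
    closed) and ``strands``; their length follows the closed-interval
    convention ``end - pos + 1`` unless an insertion length is given.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    id: str | None = None
    samples: dict[str, SampleCall] = field(default_factory=dict)
    svtype: str | None = None
    end: int | None = None
    strands: str | None = None
    ins_len: int | None = None
    from_multiallelic: bool = False

    @property
    def is_sv(self) -> bool:
        return self.svtype is not None or self.indel_size >= 50

    @property
    def is_snp(self) -> bool:
        return (self.svtype is None and len(self.ref) == 1
                and len(self.alt) == 1 and not self.alt.startswith("<"))

    @property
    def indel_size(self) -> int:
        if self.svtype is not None:
            return self.sv_length
        return abs(len(self.ref) - len(self.alt))

    @property
    def sv_length(self) -> int:
        if self.ins_len is not None:
            return self.ins_len
        if self.end is not None:
            return self.end - self.pos + 1
        return abs(len(self.ref) - len(self.alt))

    @property
    def size_class(self) -> str:
        """``snp`` | ``indel`` (<50 bp) | ``sv`` (>=50 bp)."""
        if self.is_snp:
            return "snp"
        return "sv" if self.indel_size >= 50 else "indel"

    @property
    def total_depth(self) -> int | None:
        depths = [c.depth for c in self.samples.values() if c.depth is not None]
        return sum(depths) if depths else None


@dataclass
class VcfLoadReport:
    n_records: int = 0
    n_skipped_malformed: int = 0
    n_split_multiallelic: int = 0
    skipped_lines: list[int] = field(default_factory=list)


_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))*$")


def _prescreen_vcf(path: str | os.PathLike) -> tuple[str, VcfLoadReport]:
    """Drop data lines whose GT fields violate the VCF genotype grammar.

    htslib aborts the whole stream on such lines, so the record-level
    skip-and-report contract is enforced before cyvcf2 sees the text.
    Returns a path to the screened file (a tempfile if anything was dropped).
    """
    report = VcfLoadReport()
    kept: list[str] = []
    dropped = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                kept.append(line)
                continue
            fields = line.rstrip("\n").split("\t")
            ok = True
            if len(fields) > 9:
                fmt = fields[8].split(":")
                try:
                    gt_i = fmt.index("GT")
                except ValueError:
                    gt_i = None
                if gt_i is not None:
                    for cell in fields[9:]:
                        parts = cell.split(":")
                        if gt_i >= len(parts) or not _GT_RE.match(parts[gt_i]):
                            ok = False
                            break
            if ok:
                kept.append(line)
            else:
                dropped = True
                report.n_skipped_malformed += 1
                report.skipped_lines.append(lineno)
                warnings.warn(
                    f"{path}:{lineno}: malformed genotype, record skipped")
    if not dropped:
        return str(path), report
    tmp = tempfile.NamedTemporaryFile(
        "wt", suffix=".vcf", delete=False, encoding="utf-8")
    tmp.writelines(kept)
    tmp.close()
    return tmp.name, report


def _decode_gt(alleles: Sequence[int], alt_index: int) -> Genotype:
    """Map a genotype over a multi-allelic site onto one split alt allele.

    Alleles other than REF (0) and the chosen ALT become missing.
    """
    calls = []
    for a in alleles:
        if a < 0:
            return Genotype.MISSING
        if a == 0:
            calls.append(0)
        elif a == alt_index:
            calls.append(1)
        else:
            return Genotype.MISSING
    if all(c == 0 for c in calls):
        return Genotype.HOM_REF
    if all(c == 1 for c in calls):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(
    path: str | os.PathLike, with_report: bool = False
) -> list[VariantRecord] | tuple[list[VariantRecord], VcfLoadReport]:
    """Read a VCF 4.2 file into :class:`VariantRecord` objects.

    Multi-allelic sites are split into biallelic records (flagged
    ``from_multiallelic``); malformed genotypes cause a record-level warning
    and skip, counted in the load report.
    """
    screened, report = _prescreen_vcf(path)
    records: list[VariantRecord] = []
    vcf = cyvcf2.VCF(screened)
    sample_names = list(vcf.samples)
    try:
        for v in vcf:
            alts = list(v.ALT)
            if len(alts) > 1:
                report.n_split_multiallelic += 1
            depths = None
            if sample_names:
                try:
                    dp = v.format("DP")
                    if dp is not None:
                        depths = [
                            int(d[0]) if d[0] >= 0 else None for d in dp]
                except KeyError:
                    depths = None
            info = dict(v.INFO)
            for ai, alt in enumerate(alts, start=1):
                samples: dict[str, SampleCall] = {}
                for si, name in enumerate(sample_names):
                    gt = _decode_gt(v.genotypes[si][:-1], ai)
                    d = depths[si] if depths is not None else None
                    samples[name] = SampleCall(gt, d)
                records.append(VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    # htslib stores QUAL as float32; recover printed precision
                    qual=round(v.QUAL, 4) if v.QUAL is not None else None,
                    id=v.ID,
                    samples=samples,
                    svtype=info.get("SVTYPE"),
                    end=int(info["END"]) if "END" in info else None,
                    strands=info.get("STRANDS"),
                    ins_len=(int(info["SVLEN"])
                             if "SVLEN" in info
                             and info.get("SVTYPE") == "INS" else None),
                    from_multiallelic=len(alts) > 1,
                ))
    finally:
        vcf.close()
        if screened != str(path):
            os.unlink(screened)
    report.n_records = len(records)
    if with_report:
        return records, report
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as VCF 4.2, emitting every field :func:`read_vcf` consumes."""
    sample_names: list[str] = []
    for r in records:
        for s in r.samples:
            if s not in sample_names:
                sample_names.append(s)
    gt_code = {
        Genotype.HOM_REF: "0/0", Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./.",
    }
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=STRANDS,Number=1,Type=String,Description="SV strands">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(r.chrom for r in records):
                fh.write(f"##contig=<ID={name}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_names:
            header += ["FORMAT"] + sample_names
        fh.write("\t".join(header) + "\n")
        for r in records:
            info_parts = []
            if r.svtype is not None:
                info_parts.append(f"SVTYPE={r.svtype}")
            if r.end is not None:
                info_parts.append(f"END={r.end}")
            if r.strands is not None:
                info_parts.append(f"STRANDS={r.strands}")
            if r.ins_len is not None:
                info_parts.append(f"SVLEN={r.ins_len}")
            row = [
                r.chrom, str(r.pos), r.id or ".", r.ref, r.alt,
                f"{r.qual:g}" if r.qual is not None else ".",
                "PASS", ";".join(info_parts) or ".",
            ]
            if sample_names:
                row.append("GT:DP")
                for s in sample_names:
                    call = r.samples.get(s, SampleCall(Genotype.MISSING))
                    d = "." if call.depth is None else str(call.depth)
                    row.append(f"{gt_code[call.genotype]}:{d}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GFF3 / FASTA gene models
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 1-based closed


@dataclass
class GeneModel:
    """A protein-coding gene model on one chromosome.

    All intervals are 1-based closed, stored in ascending genomic order
    regardless of strand; on the minus strand the translation order is the
    reverse of the stored order. UTRs are derived as exon minus CDS.
    ``coding_valid`` is False when the CDS length is not a multiple of three;
    such genes are excluded from coding-effect calls.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    coding_valid: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = -1
        for s, e in self.exons:
            if s <= prev_end:
                raise FormatError(f"{self.gene_id}: overlapping exons")
            if e < s:
                raise FormatError(f"{self.gene_id}: inverted exon interval")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise FormatError(
                    f"{self.gene_id}: CDS [{cs},{ce}] not contained in an exon")
        if self.cds_length % 3 != 0:
            self.coding_valid = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def utrs(self) -> tuple[list[Interval], list[Interval]]:
        """(5' UTR, 3' UTR) intervals, strand-aware."""
        if not self.cds:
            return (list(self.exons), [])
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        left: list[Interval] = []
        right: list[Interval] = []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo - 1)))
            if e > cds_hi:
                right.append((max(s, cds_hi + 1), e))
        if self.strand == "+":
            return (left, right)
        return (right, left)

    @property
    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def spans(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in translation order (reverse-complemented on minus)."""
        seq = genome[self.chrom]
        parts = [seq[s - 1:e] for s, e in self.cds]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_gff3(
    path: str | os.PathLike, with_warnings: bool = False
) -> list[GeneModel] | tuple[list[GeneModel], list[str]]:
    """Parse a GFF3 with gene -> mRNA -> exon/CDS hierarchy into gene models.

    Uses the primary (first) mRNA of each gene. A CDS outside every exon is a
    hard error; a CDS length not divisible by three flags the gene
    non-coding-valid with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True)
    genes: list[GeneModel] = []
    warns: list[str] = []
    for g in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        exons = [(f.start, f.end)
                 for f in db.children(mrna, featuretype="exon",
                                      order_by="start")]
        cds = [(f.start, f.end)
               for f in db.children(mrna, featuretype="CDS",
                                    order_by="start")]
        model = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            exons=exons, cds=cds)
        if not model.coding_valid:
            msg = (f"{g.id}: CDS length {model.cds_length} not divisible by 3;"
                   " excluded from coding-effect calls")
            warns.append(msg)
            warnings.warn(msg)
        genes.append(model)
    if with_warnings:
        return genes, warns
    return genes


def write_gff3(
    genes: Sequence[GeneModel], path: str | os.PathLike
) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start)):
            cols = [g.chrom, "panhap", "gene", str(g.start), str(g.end), ".",
                    g.strand, ".", f"ID={g.gene_id}"]
            fh.write("\t".join(cols) + "\n")
            mid = f"{g.gene_id}.t1"
            fh.write("\t".join([
                g.chrom, "panhap", "mRNA", str(g.start), str(g.end), ".",
                g.strand, ".", f"ID={mid};Parent={g.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.chrom, "panhap", "exon", str(s), str(e), ".",
                    g.strand, ".", f"ID={mid}.exon{i};Parent={mid}"]) + "\n")
            # phase runs in translation order
            cds_t = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phased = []
            for (s, e) in cds_t:
                phase = (3 - consumed % 3) % 3
                phased.append((s, e, phase))
                consumed += e - s + 1
            for i, (s, e, ph) in enumerate(sorted(phased), 1):
                fh.write("\t".join([
                    g.chrom, "panhap", "CDS", str(s), str(e), ".",
                    g.strand, str(ph), f"ID={mid}.cds{i};Parent={mid}"]) + "\n")


# ---------------------------------------------------------------------------
# Plain tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | os.PathLike, trait: str | None = None
                    ) -> pd.Series:
    """Read a phenotype CSV (accession, trait value) into a Series.

    Values must be finite; one value per accession.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need accession + trait columns")
    acc_col = df.columns[0]
    trait_col = trait if trait is not None else df.columns[1]
    if df[acc_col].duplicated().any():
        dup = df[acc_col][df[acc_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate accession {dup!r}")
    values = pd.to_numeric(df[trait_col], errors="coerce")
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite trait values")
    return pd.Series(values.values, index=df[acc_col].values, name=trait_col)


def read_table(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    """Read a generic CSV/TSV table (UTF-8, header row)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=kwargs.pop("sep", sep), **kwargs)
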