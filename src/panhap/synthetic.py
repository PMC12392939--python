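"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is testable without external data:
the generators emit presence/absence matrices with exact per-class counts,
toy annotated genomes whose variants have known effect classes, SV call sets
with planted cluster structure, and SNP-haplotype + phenotype datasets with
planted additive haplotype effects under homoscedastic Gaussian noise.

All generators are pure functions of (spec, seed): identical inputs give
byte-identical outputs. A single global seed is combined with a per-stream
id (CRC32 of the stream name) so stages can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .haplotypes import HOM_ALT, HOM_REF, HET, MISSING, SnpGenotypeMatrix
from .io_formats import (GeneModel, Genotype, SampleCall, VariantRecord)
from .pangenome import PresenceAbsenceMatrix
from .sv_merge import SVRecord


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent RNG for a named generator stream."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# Pan-genome presence/absence matrices
# ---------------------------------------------------------------------------

@dataclass
class PangenomeSimSpec:
    """Class structure of a simulated pan-genome.

    Defaults mirror the published chickpea pan-genome: 17 genomes with
    17,483 core, 2,656 softcore, 13,986 dispensable and 220 private gene
    families (34,345 in total). The dispensable occupancy distribution is a
    probability vector over occupancies 2..n_genomes-2 (uniform when None).
    """

    n_genomes: int = 17
    n_core: int = 17483
    n_softcore: int = 2656
    n_dispensable: int = 13986
    n_private: int = 220
    dispensable_occupancy: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ValueError("need at least 3 genomes")
        for name in ("n_core", "n_softcore", "n_dispensable", "n_private"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = 2, self.n_genomes - 2
        width = max(hi - lo + 1, 0)
        if self.dispensable_occupancy is None:
            if width > 0:
                self.dispensable_occupancy = [1.0 / width] * width
            else:
                self.dispensable_occupancy = []
        occ = np.asarray(self.dispensable_occupancy, dtype=float)
        if self.n_dispensable > 0:
            if len(occ) != width:
                raise ValueError(
                    f"occupancy vector must cover occupancies {lo}..{hi} "
                    f"({width} entries, got {len(occ)})")
            if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
                raise ValueError("occupancy vector must be a probability "
                                 "vector over occupancy 2..n_genomes-2")

    @property
    def n_families(self) -> int:
        return self.n_core + self.n_softcore + self.n_dispensable + self.n_private


def _exact_partition(total: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``probs``."""
    raw = probs * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_pangenome_matrix(
    spec: PangenomeSimSpec,
) -> tuple[PresenceAbsenceMatrix, pd.Series]:
    """Generate a presence/absence matrix with exact per-class counts.

    Returns the matrix and the true class label per family. Dispensable
    occupancy counts are drawn by exact largest-remainder partition of the
    spec distribution, never by sampling; private families are assigned to
    genomes round-robin.
    """
    rng = stream_rng(spec.seed, "pangenome")
    n = spec.n_genomes
    genome_ids = [f"G{i + 1:02d}" for i in range(n)]
    rows: list[np.ndarray] = []
    labels: list[str] = []
    fam_ids: list[str] = []

    def add(label: str, occ_row: np.ndarray) -> None:
        fam_ids.append(f"OG{len(fam_ids):07d}")
        labels.append(label)
        rows.append(occ_row)

    for _ in range(spec.n_core):
        add("core", np.ones(n, dtype=bool))
    for _ in range(spec.n_softcore):
        row = np.ones(n, dtype=bool)
        row[rng.integers(n)] = False
        add("softcore", row)
    if spec.n_dispensable > 0:
        occ_probs = np.asarray(spec.dispensable_occupancy, dtype=float)
        per_occ = _exact_partition(spec.n_dispensable, occ_probs)
        for occ_i, count in enumerate(per_occ):
            occupancy = occ_i + 2
            for _ in range(count):
                row = np.zeros(n, dtype=bool)
                row[rng.choice(n, size=occupancy, replace=False)] = True
                add("dispensable", row)
    for i in range(spec.n_private):
        row = np.zeros(n, dtype=bool)
        row[i % n] = True       # round-robin
        add("private", row)

    counts = np.stack(rows).astype(np.int64)
    matrix = PresenceAbsenceMatrix(fam_ids, genome_ids, counts)
    truth = pd.Series(labels, index=fam_ids, name="class")
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotated toy genomes
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n non-stop codons."""
    out = []
    while len(out) < n:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                offset: int) -> tuple[str, GeneModel]:
    """Build one gene region starting at 1-based genomic ``offset``.

    Returns the genomic-forward region sequence and the gene model.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    n_codons = int(rng.integers(30, 81))          # incl. start, excl. stop
    utr5 = int(rng.integers(0, 31))
    utr3 = int(rng.integers(0, 31))
    cds_seq = "ATG" + _random_codons(rng, n_codons - 1) + \
        ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    transcript = _random_seq(rng, utr5) + cds_seq + _random_seq(rng, utr3)
    t_len = len(transcript)
    cds_t = (utr5 + 1, utr5 + len(cds_seq))        # 1-based transcript coords
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, t_len), size=n_exons - 1,
                                 replace=False))
    else:
        cuts = []
    bounds = [0] + list(cuts) + [t_len]
    exon_t = [(bounds[i] + 1, bounds[i + 1]) for i in range(n_exons)]
    introns = [_random_seq(rng, int(rng.integers(36, 117))) for _ in cuts]
    introns = ["GT" + s + "AG" for s in introns]

    # lay out region in transcript orientation
    region_parts: list[str] = []
    exon_r: list[tuple[int, int]] = []
    cursor = 0
    for i, (ts, te) in enumerate(exon_t):
        seq = transcript[ts - 1:te]
        exon_r.append((cursor + 1, cursor + len(seq)))
        region_parts.append(seq)
        cursor += len(seq)
        if i < len(introns):
            region_parts.append(introns[i])
            cursor += len(introns[i])
    region = "".join(region_parts)

    def t2r(tpos: int) -> int:
        """transcript position -> region position (both 1-based)."""
        for (ts, te), (rs, _re) in zip(exon_t, exon_r):
            if ts <= tpos <= te:
                return rs + (tpos - ts)
        raise ValueError("position not exonic")

    cds_r: list[tuple[int, int]] = []
    for (ts, te) in exon_t:
        s = max(ts, cds_t[0])
        e = min(te, cds_t[1])
        if s <= e:
            cds_r.append((t2r(s), t2r(e)))

    if strand == "-":
        region = str(Seq(region).reverse_complement())
        L = len(region)
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        exon_r = sorted(flip(iv) for iv in exon_r)
        cds_r = sorted(flip(iv) for iv in cds_r)

    shift = offset - 1
    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=[(s + shift, e + shift) for s, e in exon_r],
        cds=[(s + shift, e + shift) for s, e in cds_r])
    return region, model


def generate_annotated_genome(
    n_chroms: int = 2,
    n_genes: int = 20,
    seed: int = 0,
    margin: int = 80,
    chrom_length: int | None = None,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a toy genome (FASTA-ready dict) with annotated gene models.

    Genes sit on both strands with 1-4 exons, a mod-3 CDS with no internal
    stop codon, and intergenic gaps of at least ``margin`` bp. When
    ``chrom_length`` is given, packing that does not fit raises.
    """
    rng = stream_rng(seed, "genome")
    chroms = {f"Ca{i + 1}": [] for i in range(n_chroms)}
    cursors = {c: 0 for c in chroms}
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        chrom = f"Ca{(gi % n_chroms) + 1}"
        gap = margin + int(rng.integers(0, margin + 1))
        chroms[chrom].append(_random_seq(rng, gap))
        cursors[chrom] += gap
        region, model = _build_gene(
            rng, f"gene{gi + 1:04d}", chrom, cursors[chrom] + 1)
        chroms[chrom].append(region)
        cursors[chrom] += len(region)
        genes.append(model)
    genome: dict[str, str] = {}
    for chrom in chroms:
        tail = margin + int(rng.integers(0, margin + 1))
        chroms[chrom].append(_random_seq(rng, tail))
        cursors[chrom] += tail
        seq = "".join(chroms[chrom])
        if chrom_length is not None:
            if len(seq) > chrom_length:
                raise ValueError(
                    f"{chrom}: gene packing needs {len(seq)} bp, only "
                    f"{chrom_length} available")
            seq = seq + _random_seq(rng, chrom_length - len(seq))
        genome[chrom] = seq
    return genome, genes


# ---------------------------------------------------------------------------
# Variants with known effect class
# ---------------------------------------------------------------------------

EFFECT_CLASSES = ("intergenic", "intronic", "utr", "synonymous", "missense",
                  "nonsense", "frameshift", "splice")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate_gene(gene: GeneModel, genome: Mapping[str, str]) -> str:
    return str(Seq(gene.coding_sequence(genome)).translate())


def _snp_truth_class(gene: GeneModel, genome: Mapping[str, str],
                     pos: int, alt: str) -> str | None:
    """True coding class of a SNP by full-CDS mutation and re-translation."""
    seq = genome[gene.chrom]
    mutated = dict(genome)
    mutated[gene.chrom] = seq[:pos - 1] + alt + seq[pos:]
    ref_prot = _translate_gene(gene, genome)
    alt_prot = _translate_gene(gene, mutated)
    if alt_prot == ref_prot:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if any(alt_prot[i] == "*" for i in diffs):
        return "nonsense"
    return "missense"


def _intron_interior(gene: GeneModel, pad: int = 8) -> list[int]:
    out = []
    for s, e in gene.introns:
        out.extend(range(s + pad, e - pad + 1))
    return out


def _splice_site_positions(gene: GeneModel) -> list[int]:
    out = []
    for s, e in gene.introns:
        out.extend([s, s + 1, e - 1, e])
    return out


def _utr_positions(gene: GeneModel, pad: int = 3) -> list[int]:
    """Exonic non-CDS positions away from exon-intron junctions."""
    introns = gene.introns
    out = []
    utr5, utr3 = gene.utrs
    for s, e in utr5 + utr3:
        for p in range(s, e + 1):
            near = False
            for es, ee in gene.exons:
                if es <= p <= ee:
                    if (any(ie == es - 1 for _, ie in introns)
                            and p - es < pad):
                        near = True
                    if (any(js == ee + 1 for js, _ in introns)
                            and ee - p < pad):
                        near = True
            if not near:
                out.append(p)
    return out


def _cds_interior_positions(gene: GeneModel, pad: int = 3) -> list[int]:
    introns = gene.introns
    out = []
    for s, e in gene.cds:
        for p in range(s, e + 1):
            if (any(ie == s - 1 for _, ie in introns) and p - s < pad):
                continue
            if (any(js == e + 1 for js, _ in introns) and e - p < pad):
                continue
            out.append(p)
    return out


def generate_variants(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    class_counts: Mapping[str, int],
    seed: int = 0,
    sample: str = "s1",
) -> tuple[list[VariantRecord], list[str]]:
    """Generate variants of requested effect classes with truth labels.

    Coding-class truth is established by full-CDS mutation and
    re-translation, independent of the effect classifier. InDels are kept
    below 50 bp. Raises when a requested class is unreachable on the given
    genome (e.g. coding classes without any CDS).
    """
    for cls in class_counts:
        if cls not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {cls!r}")
    rng = stream_rng(seed, "variants")
    coding_genes = [g for g in genes if g.cds and g.coding_valid]
    records: list[VariantRecord] = []
    labels: list[str] = []
    used: set[tuple[str, int]] = set()

    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append((g.start, g.end))

    def claim(chrom: str, pos: int, span: int = 1) -> bool:
        keys = [(chrom, pos + i) for i in range(span)]
        if any(k in used for k in keys):
            return False
        used.update(keys)
        return True

    def emit(chrom: str, pos: int, ref: str, alt: str, label: str) -> None:
        qual = float(np.round(rng.uniform(30, 60), 1))
        depth = int(rng.integers(55, 120))
        records.append(VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
            samples={sample: SampleCall(Genotype.HOM_ALT, depth)}))
        labels.append(label)

    def alt_base(ref: str) -> str:
        choices = [b for b in "ACGT" if b != ref]
        return choices[int(rng.integers(3))]

    def pick_intergenic() -> tuple[str, int]:
        chroms = list(genome)
        for _ in range(10000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
            if any(s <= pos <= e for s, e in gene_spans.get(chrom, ())):
                continue
            return chrom, pos
        raise ValueError("no intergenic position available")

    for cls, want in class_counts.items():
        made = 0
        attempts = 0
        max_attempts = 200 * max(want, 1) + 1000
        if cls in ("intronic", "utr", "synonymous", "missense", "nonsense",
                   "frameshift", "splice") and not coding_genes:
            if want > 0:
                raise ValueError(
                    f"cannot place {cls!r} variants: no valid coding gene")
        while made < want:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {want} {cls!r} variants "
                    f"(placed {made}) on this genome")
            if cls == "intergenic":
                chrom, pos = pick_intergenic()
                if not claim(chrom, pos):
                    continue
                ref = genome[chrom][pos - 1]
                emit(chrom, pos, ref, alt_base(ref), cls)
                made += 1
                continue
            g = coding_genes[int(rng.integers(len(coding_genes)))]
            seq = genome[g.chrom]
            if cls == "intronic":
                pool = _intron_interior(g)
            elif cls == "utr":
                pool = _utr_positions(g)
            elif cls == "splice":
                pool = _splice_site_positions(g)
            else:
                pool = _cds_interior_positions(g)
            if not pool:
                continue
            pos = pool[int(rng.integers(len(pool)))]
            ref = seq[pos - 1]
            if cls == "frameshift":
                size = int(rng.integers(1, 3))      # 1-2 bp, never mod 3
                anchor = pos - 1
                if anchor < g.cds[0][0]:
                    continue
                in_same = any(s <= anchor and pos + size - 1 <= e
                              for s, e in g.cds)
                if not in_same:
                    continue
                ref_del = seq[anchor - 1:anchor + size]
                if not claim(g.chrom, anchor, size + 1):
                    continue
                emit(g.chrom, anchor, ref_del, ref_del[0], cls)
                made += 1
                continue
            alt = alt_base(ref)
            if cls in ("synonymous", "missense", "nonsense"):
                found = None
                for cand in [b for b in "ACGT" if b != ref]:
                    if _snp_truth_class(g, genome, pos, cand) == cls:
                        found = cand
                        break
                if found is None:
                    continue
                alt = found
            if not claim(g.chrom, pos):
                continue
            emit(g.chrom, pos, ref, alt, cls)
            made += 1
    order = np.argsort([(r.chrom, r.pos) for r in records], axis=0)
    idx = sorted(range(len(records)),
                 key=lambda i: (records[i].chrom, records[i].pos))
    return [records[i] for i in idx], [labels[i] for i in idx]


# ---------------------------------------------------------------------------
# SV call sets with planted clusters
# ---------------------------------------------------------------------------

def generate_sv_callsets(
    n_samples: int = 5,
    n_clusters: int = 10,
    jitter_sd: float = 50.0,
    seed: int = 0,
    cluster_gap: int = 10000,
    chrom: str = "Ca1",
) -> tuple[dict[str, list[SVRecord]], dict[tuple[str, int], int]]:
    """Per-sample SV call tables with known cluster structure.

    Cluster centroids are spaced ``cluster_gap`` bp apart; members share type
    and strands and have breakpoints jittered by a truncated
    Normal(0, jitter_sd). Jitter beyond half the inter-cluster gap is
    rejected (clusters must stay separable). Truth maps (sample, index in
    that sample's list) -> cluster id.
    """
    if jitter_sd > cluster_gap / 2:
        raise ValueError("jitter sd exceeds half the inter-cluster gap; "
                         "clusters would not be separable")
    rng = stream_rng(seed, "sv")
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    callsets: dict[str, list[SVRecord]] = {s: [] for s in samples}
    truth: dict[tuple[str, int], int] = {}
    types = ["DEL", "INS", "INV", "DUP"]
    cap = max(min(3 * jitter_sd, cluster_gap / 2 - 1), 0)
    for ci in range(n_clusters):
        centroid = 50000 + ci * cluster_gap
        svtype = types[int(rng.integers(len(types)))]
        strands = ["+-", "-+", "++", "--"][int(rng.integers(4))]
        length = int(rng.integers(60, 2000))
        support = int(rng.integers(1, n_samples + 1))
        members = rng.choice(n_samples, size=support, replace=False)
        for si in sorted(members):
            def jit() -> int:
                while True:
                    j = rng.normal(0, jitter_sd) if jitter_sd > 0 else 0.0
                    if abs(j) <= cap or jitter_sd == 0:
                        return int(round(j))
            start = centroid + jit()
            if svtype == "INS":
                end = start
                rec = SVRecord(samples[si], chrom, start, end, svtype,
                               strands, length=length + jit() // 10)
            else:
                end = start + length - 1 + jit()
                end = max(end, start + 50)
                rec = SVRecord(samples[si], chrom, start, end, svtype,
                               strands)
            if rec.span_length < 50:
                rec = SVRecord(samples[si], chrom, start, start + 59,
                               svtype, strands,
                               length=60 if svtype == "INS" else None)
            truth[(samples[si], len(callsets[samples[si]]))] = ci
            callsets[samples[si]].append(rec)
    return callsets, truth


# ---------------------------------------------------------------------------
# Haplotype + phenotype datasets
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSimSpec:
    """Planted-haplotype dataset layout.

    Trait values are haplotype mean + Normal(0, noise_sd) noise, in grams of
    100-seed weight; defaults plant the published extreme group means
    (29.84 g superior vs 14.66 g inferior).
    """

    n_accessions: int = 100
    n_snps: int = 6
    n_haplotypes: int = 2
    means: Sequence[float] = (29.84, 14.66)
    noise_sd: float = 1.0
    het_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "Ca4"
    region_start: int = 13239546

    def __post_init__(self) -> None:
        if self.n_haplotypes > 2 ** self.n_snps:
            raise ValueError("more haplotypes than 2^n_snps allows")
        if len(self.means) != self.n_haplotypes:
            raise ValueError("one mean per haplotype required")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class HaplotypeTruth:
    haplotype_of: dict[str, int]        # accession -> haplotype index
    allele_matrix: np.ndarray           # haplotype x snp, 0=ref 1=alt
    means: np.ndarray
    superior: int                       # index of largest planted mean


def generate_haplotype_dataset(
    spec: HaplotypeSimSpec,
) -> tuple[SnpGenotypeMatrix, pd.Series, HaplotypeTruth]:
    """SNP genotype matrix + phenotype table with planted haplotype effects."""
    rng = stream_rng(spec.seed, "haplotype")
    # distinct haplotype allele vectors: enumerate low integers as bit rows
    alleles = np.zeros((spec.n_haplotypes, spec.n_snps), dtype=np.int8)
    codes = rng.choice(2 ** spec.n_snps, size=spec.n_haplotypes,
                       replace=False)
    for h, code in enumerate(codes):
        alleles[h] = [(int(code) >> b) & 1 for b in range(spec.n_snps)]
    accessions = [f"acc{i + 1:04d}" for i in range(spec.n_accessions)]
    hap_of = np.tile(np.arange(spec.n_haplotypes),
                     spec.n_accessions // spec.n_haplotypes + 1)
    hap_of = hap_of[:spec.n_accessions]
    rng.shuffle(hap_of)
    calls = np.where(alleles[hap_of] == 1, HOM_ALT, HOM_REF).astype(np.int8)
    if spec.het_rate > 0:
        mask = rng.random(calls.shape) < spec.het_rate
        calls[mask] = HET
    if spec.missing_rate > 0:
        mask = (rng.random(calls.shape) < spec.missing_rate) & (calls != HET)
        calls[mask] = MISSING
    means = np.asarray(spec.means, dtype=float)
    noise = (rng.normal(0.0, spec.noise_sd, size=spec.n_accessions)
             if spec.noise_sd > 0 else np.zeros(spec.n_accessions))
    trait = means[hap_of] + noise
    sites = pd.DataFrame({
        "chrom": spec.chrom,
        "pos": spec.region_start + 100 * np.arange(spec.n_snps),
        "ref": "A",
        "alt": "G",
    })
    matrix = SnpGenotypeMatrix(accessions, sites, calls)
    phenotypes = pd.Series(trait, index=accessions, name="seed_weight_100_g")
    truth = HaplotypeTruth(
        haplotype_of=dict(zip(accessions, map(int, hap_of))),
        allele_matrix=alleles,
        means=means,
        superior=int(np.argmax(means)),
    )
    return matrix, phenotypes, truth


# ---------------------------------------------------------------------------
# KASP matrices
# ---------------------------------------------------------------------------

def generate_kasp_matrix(
    n_markers: int = 23,
    n_polymorphic: int = 20,
    cultivars: Sequence[str] | None = None,
    donor: str = "ICC4958",
    seed: int = 0,
) -> "pd.DataFrame":
    """KASP call matrix where exactly ``n_polymorphic`` markers differ from
    the donor in at least one cultivar. Columns: marker, superior_allele,
    donor column, then cultivar calls in {A, B, H, NA}.
    """
    if n_polymorphic > n_markers:
        raise ValueError("n_polymorphic cannot exceed n_markers")
    rng = stream_rng(seed, "kasp")
    if cultivars is None:
        cultivars = [f"CV{i + 1:02d}" for i in range(15)]
    markers = [f"CKAM{2100 + i}" for i in range(n_markers)]
    poly = set(rng.choice(n_markers, size=n_polymorphic, replace=False))
    rows = []
    for mi, m in enumerate(markers):
        donor_call = "A" if rng.random() < 0.5 else "B"
        other = "B" if donor_call == "A" else "A"
        calls = {}
        if mi in poly:
            n_diff = int(rng.integers(1, len(cultivars) + 1))
            diff = set(rng.choice(len(cultivars), size=n_diff, replace=False))
            for ci, cv in enumerate(cultivars):
                calls[cv] = other if ci in diff else donor_call
        else:
            for cv in cultivars:
                calls[cv] = donor_call if rng.random() < 0.9 else (
                    "H" if rng.random() < 0.5 else "NA")
        rows.append({"marker": m, "superior_allele": donor_call,
                     donor: donor_call, **calls})
    return pd.DataFrame(rows).set_index("marker")
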