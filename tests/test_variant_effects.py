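import numpy as np
import pytest
from Bio.Seq import Seq

from panhap import synthetic, variant_effects as ve
from panhap.io_formats import (GeneModel, Genotype, SampleCall, VariantRecord)

from helpers import translate_with_snp


def _label_of(effect: ve.VariantEffect) -> str:
    """Map a VariantEffect onto the generator's truth vocabulary."""
    if effect.region == "intergenic":
        return "intergenic"
    if effect.splice in ("donor", "acceptor"):
        return "splice"
    if effect.region == "intronic":
        return "intronic"
    return effect.subclass


class TestFilter:
    @staticmethod
    def _rec(qual, depth):
        samples = {}
        if depth is not None:
            samples["s1"] = SampleCall(Genotype.HOM_ALT, depth)
        return VariantRecord("Ca1", 10, "A", "G", qual=qual, samples=samples)

    def test_quality_rule_boundary(self):
        kept, report = ve.filter_variants(
            [self._rec(19.9, 60), self._rec(20.0, 50)])
        assert len(kept) == 1 and kept[0].qual == 20.0
        assert report.removed_qual == 1

    def test_missing_depth_fails(self):
        kept, report = ve.filter_variants([self._rec(30, None)])
        assert kept == [] and report.removed_depth == 1

    def test_against_predicate_oracle(self, rng):
        records = [self._rec(float(q), int(d) if d > 0 else None)
                   for q, d in zip(rng.uniform(0, 40, 300),
                                   rng.integers(-10, 120, 300))]
        kept, _ = ve.filter_variants(records)
        expect = [r for r in records
                  if r.qual >= 20 and r.total_depth is not None
                  and r.total_depth >= 50]
        assert kept == expect


class TestClassify:
    def test_intergenic_between_genes(self, toy_genome):
        genome, genes = toy_genome
        gene = genes[0]
        pos = gene.end + 5  # inside the intergenic margin
        ref = genome[gene.chrom][pos - 1]
        alt = "A" if ref != "A" else "G"
        v = VariantRecord(gene.chrom, pos, ref, alt)
        assert ve.classify_effect(v, genes, genome).region == "intergenic"

    def test_known_synonymous_codon_change(self):
        # single-exon plus-strand gene: ATG AAA TAA; AAA->AAG is silent (Lys)
        genome = {"c": "TT" + "ATGAAATAA" + "TT"}
        gene = GeneModel("g1", "c", "+", exons=[(3, 11)], cds=[(3, 11)])
        v = VariantRecord("c", 8, "A", "G")
        eff = ve.classify_effect(v, [gene], genome)
        assert eff.subclass == "synonymous"
        assert eff.aa_change == "Lys2Lys"

    def test_known_nonsense_on_minus_strand(self):
        # minus-strand gene: transcript ATG TGG TAA <=> genomic revcomp
        transcript = "ATGTGGTAA"
        genomic = str(Seq(transcript).reverse_complement())
        genome = {"c": "GG" + genomic + "GG"}
        gene = GeneModel("g1", "c", "-", exons=[(3, 11)], cds=[(3, 11)])
        # codon 2 TGG(Trp) -> TGA(stop): transcript base 6 G->A,
        # genomic position = 3 + (9 - 6) = 6, base C -> T
        v = VariantRecord("c", 6, "C", "T")
        eff = ve.classify_effect(v, [gene], genome)
        assert eff.subclass == "nonsense"
        assert eff.aa_change == "Trp2Ter"

    def test_ref_mismatch_error_names_position(self, toy_genome):
        genome, genes = toy_genome
        chrom = genes[0].chrom
        ref = genome[chrom][99]
        wrong = "A" if ref != "A" else "C"
        v = VariantRecord(chrom, 100, wrong, "T" if wrong != "T" else "G")
        with pytest.raises(ValueError, match=f"{chrom}:100"):
            ve.classify_effect(v, genes, genome)

    def test_full_agreement_with_translation_oracle(self, toy_genome,
                                                    labelled_variants):
        """500 generated variants: classifier vs full-CDS re-translation."""
        genome, genes = toy_genome
        records, labels = labelled_variants
        assert len(records) == 500
        effects = ve.classify_effects(records, genes, genome)
        agree = [_label_of(e) == t for e, t in zip(effects, labels)]
        assert all(agree)
        # coding SNP calls re-checked against the independent oracle
        by_id = {g.gene_id: g for g in genes}
        for r, e in zip(records, effects):
            if e.subclass in ("synonymous", "missense", "nonsense") \
                    and r.is_snp:
                g = by_id[e.gene_id]
                ref_prot = str(Seq(g.coding_sequence(genome)).translate())
                alt_prot = translate_with_snp(g, genome, r.pos, r.alt)
                if e.subclass == "synonymous":
                    assert alt_prot == ref_prot
                elif e.subclass == "nonsense":
                    diffs = [i for i, (a, b)
                             in enumerate(zip(ref_prot, alt_prot)) if a != b]
                    assert any(alt_prot[i] == "*" for i in diffs)
                else:
                    assert alt_prot != ref_prot
                    assert "*" not in alt_prot[:-1]

    def test_strand_symmetry(self, toy_genome, labelled_variants):
        """Reverse-complementing genome, models and alleles changes nothing."""
        genome, genes = toy_genome
        records, _ = labelled_variants
        snps = [r for r in records if r.is_snp][:150]
        effects = ve.classify_effects(snps, genes, genome)
        comp = str.maketrans("ACGT", "TGCA")
        rc_genome = {c: str(Seq(s).reverse_complement())
                     for c, s in genome.items()}
        lengths = {c: len(s) for c, s in genome.items()}

        def flip_iv(chrom, iv):
            L = lengths[chrom]
            return (L - iv[1] + 1, L - iv[0] + 1)

        rc_genes = [GeneModel(
            g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
            exons=sorted(flip_iv(g.chrom, iv) for iv in g.exons),
            cds=sorted(flip_iv(g.chrom, iv) for iv in g.cds))
            for g in genes]
        for r, eff in zip(snps, effects):
            L = lengths[r.chrom]
            rv = VariantRecord(r.chrom, L - r.pos + 1,
                               r.ref.translate(comp), r.alt.translate(comp))
            rc_eff = ve.classify_effect(rv, rc_genes, rc_genome)
            assert (rc_eff.region, rc_eff.subclass, rc_eff.splice,
                    rc_eff.gene_id, rc_eff.aa_change) == \
                (eff.region, eff.subclass, eff.splice, eff.gene_id,
                 eff.aa_change)


class TestChromosomeSummary:
    def test_published_ca6_share(self):
        # published per-chromosome SNP structure: Ca6 and Ca8 counts fixed,
        # the remainder spread over the other six chromosomes
        counts = {"Ca6": 590013, "Ca4": 393226, "Ca8": 75911}
        rest = 2473162 - sum(counts.values())
        for i, c in enumerate(["Ca1", "Ca2", "Ca3", "Ca5", "Ca7"]):
            counts[c] = rest // 5 + (1 if i < rest % 5 else 0)
        lengths = {c: 70_000_000 for c in counts}
        summary = ve.chromosome_summary_from_counts(counts, lengths)
        assert summary.total == 2473162
        assert summary.table.loc["Ca6", "share_pct"] == 23.86
        assert summary.table.loc["Ca8", "share_pct"] == 3.07

    def test_single_chromosome_share_100(self):
        s = ve.chromosome_summary_from_counts({"Ca1": 7}, {"Ca1": 10 ** 6})
        assert s.table.loc["Ca1", "share_pct"] == 100.0
        assert s.table.loc["Ca1", "density_per_mb"] == 7.0

    def test_against_counting_oracle(self, rng):
        chroms = [f"Ca{i}" for i in range(1, 5)]
        records = [VariantRecord(str(rng.choice(chroms)),
                                 int(rng.integers(1, 1000)), "A", "G")
                   for _ in range(500)]
        lengths = {c: 10 ** 6 for c in chroms}
        summary = ve.summarize_by_chromosome(records, lengths)
        for c in chroms:
            expect = sum(r.chrom == c for r in records)
            if expect:
                assert summary.table.loc[c, "count"] == expect
        assert summary.total == 500

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            ve.chromosome_summary_from_counts({"Ca1": 5}, {"Ca1": 0})


class TestGeneSetSummary:
    @staticmethod
    def _fake(n_variants, genes_cycle):
        records, effects = [], []
        for i in range(n_variants):
            records.append(VariantRecord("Ca1", i + 1, "A", "G"))
            effects.append(ve.VariantEffect(
                "exonic", "missense", gene_id=genes_cycle[i % len(genes_cycle)]))
        return records, effects

    def test_published_flowering_time_mean(self):
        genes = [f"fl{i:03d}" for i in range(181)]
        records, effects = self._fake(2598, genes)
        s = ve.summarize_gene_set(records, effects, genes)
        assert (s.n_variants, s.n_genes, s.mean_per_gene) == (2598, 181, 14.35)

    def test_empty_set_flagged(self):
        records, effects = self._fake(5, ["g1"])
        s = ve.summarize_gene_set(records, effects, ["other"])
        assert (s.n_variants, s.n_genes, s.mean_per_gene, s.empty) == \
            (0, 0, 0.0, True)

    def test_against_group_by_oracle(self, rng):
        gene_ids = [f"g{i}" for i in range(30)]
        records, effects = [], []
        for i in range(400):
            g = str(rng.choice(gene_ids + [None]))
            records.append(VariantRecord("Ca1", i + 1, "A", "G"))
            effects.append(ve.VariantEffect(
                "exonic" if g != "None" else "intergenic",
                "missense" if g != "None" else "none",
                gene_id=None if g == "None" else g))
        wanted = set(gene_ids[:15])
        s = ve.summarize_gene_set(records, effects, wanted)
        hits = [e.gene_id for e in effects if e.gene_id in wanted]
        assert s.n_variants == len(hits)
        assert s.n_genes == len(set(hits))


class TestRegionReport:
    def test_published_hotspot_breakdown(self, rng):
        """700 variants (534 SNP + 166 InDel), 42 genic = 17 intronic + 25 exonic."""
        records, effects = [], []
        start, end = 13239546, 13547009
        positions = rng.choice(np.arange(start, end), size=700, replace=False)
        kinds = (["snp"] * 534) + (["indel"] * 166)
        regions = (["intronic"] * 17 + ["exonic"] * 25
                   + ["intergenic"] * 658)
        for pos, kind, region in zip(positions, kinds, regions):
            ref, alt = ("A", "G") if kind == "snp" else ("AT", "A")
            records.append(VariantRecord("Ca4", int(pos), ref, alt))
            effects.append(ve.VariantEffect(
                region,
                "missense" if region == "exonic" else "none",
                gene_id="g1" if region != "intergenic" else None))
        report = ve.region_report(records, effects, "Ca4", start, end)
        assert report.total == 700
        assert report.by_size_class == {"snp": 534, "indel": 166, "sv": 0}
        assert report.genic == 42
        assert (report.intronic, report.exonic) == (17, 25)
        assert report.intergenic == 658

    def test_region_without_variants_is_all_zero(self):
        report = ve.region_report([], [], "Ca1", 1, 100)
        assert report.total == 0 and report.genic == 0

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty interval"):
            ve.region_report([], [], "Ca1", 100, 50)

    def test_against_interval_filter_oracle(self, toy_genome,
                                            labelled_variants, rng):
        genome, genes = toy_genome
        records, _ = labelled_variants
        effects = ve.classify_effects(records, genes, genome)
        for _ in range(20):
            chrom = str(rng.choice(list(genome)))
            a, b = sorted(rng.integers(1, len(genome[chrom]), size=2))
            report = ve.region_report(records, effects, chrom, int(a), int(b))
            inside = [i for i, r in enumerate(records)
                      if r.chrom == chrom and a <= r.pos <= b]
            assert report.total == len(inside)
            assert report.genic == sum(
                effects[i].region != "intergenic" for i in inside)
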