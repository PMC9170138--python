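"""Consequence prediction against manual translations and an independent
hand-coded codon-table oracle."""

import numpy as np
import pytest

from fhmap.annotation import (
    Category,
    GeneModel,
    Impact,
    ReferenceMismatchError,
    annotate_variant,
    cds_is_complete,
    impact_of,
    load_gene_models,
    load_genome,
    most_severe,
    mutated_cds,
    predict_truncation,
    stops_in_frame,
    translate,
)
from fhmap.model import VariantSite

# fully independent oracle codon table (hand-written, not Biopython)
_ORACLE_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMP = str.maketrans("ACGT", "TGCA")


def _oracle_translate(seq):
    return "".join(_ORACLE_TABLE[seq[i:i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def _plus_model(cds, offset=100, contig="chr", strand="+"):
    """Single-exon model with CDS at [offset+1 .. offset+len(cds)]."""
    start, end = offset + 1, offset + len(cds)
    return GeneModel("g", "t", contig, strand, ((start, end),), ((start, end),))


def _genome_for(cds, offset=100, strand="+", pad=2000):
    plus = cds if strand == "+" else cds.translate(_COMP)[::-1]
    return {"chr": "A" * offset + plus + "G" * pad}


def _site(pos, ref, alt):
    return VariantSite("chr", pos, ref, (alt,), {})


TOY = "ATGCTGACCGGGTAA"  # M L T G *


class TestToyExamples:
    def test_frameshift_deletion_with_early_stop(self):
        genome = _genome_for(TOY)
        model = _plus_model(TOY)
        # delete the C at CDS position 4 (anchored at CDS 3)
        site = _site(103, "GC", "G")
        cons = annotate_variant(site, [model], genome)[0]
        assert cons.category is Category.FRAMESHIFT
        assert cons.impact is Impact.HIGH
        assert cons.truncated_length == 1  # mutated CDS reads ATG TGA ...
        trunc = predict_truncation(model, site, genome)
        assert (trunc.truncated_length, trunc.stop_codon, trunc.stop_lost) == (1, 2, False)

    def test_synonymous_substitution(self):
        genome = _genome_for(TOY)
        site = _site(112, "G", "A")  # GGG -> GGA, both Gly
        cons = annotate_variant(site, [_plus_model(TOY)], genome)[0]
        assert cons.category is Category.SYNONYMOUS
        assert cons.impact is Impact.LOW

    def test_intergenic_far_from_any_gene(self):
        genome = _genome_for(TOY, pad=20_000)
        site = _site(12_000, "G", "T")
        cons = annotate_variant(site, [_plus_model(TOY)], genome)
        assert len(cons) == 1
        assert cons[0].category is Category.INTERGENIC
        assert cons[0].impact is Impact.MODIFIER

    def test_p193fs_notation_on_long_cds(self):
        # 1,788-nt CDS whose codon 193 is CCA (Pro); delete CDS base 578
        cds = "ATG" + "GCT" * 594 + "TAA"
        cds = cds[: 576] + "CCA" + cds[579:]
        assert len(cds) == 1788
        genome = _genome_for(cds)
        # anchor at CDS 577 (genomic 677), deleting CDS 578
        site = _site(677, "CC", "C")
        cons = annotate_variant(site, [_plus_model(cds)], genome)[0]
        assert cons.category is Category.FRAMESHIFT
        assert cons.hgvs_p == "p.P193fs"

    def test_nonsense_substitution_truncation_and_start_loss(self):
        cds = "ATGTGGACCGGGTAA"  # M W T G *
        genome = _genome_for(cds)
        model = _plus_model(cds)
        nonsense = _site(106, "G", "A")  # codon 2 TGG -> TGA
        cons = annotate_variant(nonsense, [model], genome)[0]
        assert cons.category is Category.STOP_GAINED
        assert cons.truncated_length == 1
        trunc = predict_truncation(model, nonsense, genome)
        assert (trunc.truncated_length, trunc.stop_codon) == (1, 2)
        start = _site(101, "A", "T")  # codon 1 ATG -> TTG
        start_cons = annotate_variant(start, [model], genome)[0]
        assert start_cons.category is Category.START_LOST
        assert start_cons.impact is Impact.HIGH

    def test_nonsense_at_first_codon_truncates_to_zero(self):
        # codon 1 already mutated to a stop leaves a zero-length peptide
        cds = "TACGCTGCTTAA"
        genome = _genome_for(cds)
        model = _plus_model(cds)
        site = _site(103, "C", "A")  # codon 1 TAC -> TAA
        trunc = predict_truncation(model, site, genome)
        assert (trunc.truncated_length, trunc.stop_codon) == (0, 1)

    def test_frameshift_with_no_downstream_stop_flags_stop_lost(self):
        cds = "ATGAAACCCTTTTAA"
        genome = _genome_for(cds)
        model = _plus_model(cds)
        site = _site(106, "AC", "A")  # delete CDS position 7
        trunc = predict_truncation(model, site, genome)
        assert trunc.stop_lost is True
        assert trunc.truncated_length is None

    def test_reference_mismatch_raises(self):
        genome = _genome_for(TOY)
        with pytest.raises(ReferenceMismatchError):
            annotate_variant(_site(101, "C", "T"), [_plus_model(TOY)], genome)


class TestNonCodingRegions:
    def _two_exon_model(self):
        # exons [101..130] and [201..230]; CDS [111..130]+[201..220]
        return GeneModel(
            "g", "t", "chr", "+",
            exons=((101, 130), (201, 230)),
            cds=((111, 130), (201, 220)),
        )

    def test_intron_utr_and_splice_region(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        seq = seq[:110] + "ATG" + seq[113:]
        genome = {"chr": seq}
        model = self._two_exon_model()

        def cat(pos):
            site = VariantSite("chr", pos, genome["chr"][pos - 1],
                               ("A" if genome["chr"][pos - 1] != "A" else "C",), {})
            return annotate_variant(site, [model], genome)[0].category

        assert cat(105) is Category.UTR          # exon 1, before CDS
        assert cat(131) is Category.SPLICE_REGION  # first intronic base
        assert cat(132) is Category.SPLICE_REGION
        assert cat(150) is Category.INTRONIC
        assert cat(200) is Category.SPLICE_REGION  # 1 bp before exon 2
        assert cat(225) is Category.UTR          # exon 2 after CDS end


class TestImpactTable:
    @pytest.mark.parametrize("category,impact", [
        (Category.FRAMESHIFT, Impact.HIGH),
        (Category.STOP_GAINED, Impact.HIGH),
        (Category.STOP_LOST, Impact.HIGH),
        (Category.SPLICE_REGION, Impact.HIGH),
        (Category.MISSENSE, Impact.MODERATE),
        (Category.INFRAME_INDEL, Impact.MODERATE),
        (Category.SYNONYMOUS, Impact.LOW),
        (Category.INTRONIC, Impact.MODIFIER),
        (Category.UTR, Impact.MODIFIER),
        (Category.INTERGENIC, Impact.MODIFIER),
    ])
    def test_impact_assignment(self, category, impact):
        assert impact_of(category) is impact


def _random_cds(rng, n_codons):
    codons = [c for c in _ORACLE_TABLE if _ORACLE_TABLE[c] != "*"]
    body = rng.choice(codons, size=n_codons - 2)
    return "ATG" + "".join(body) + rng.choice(["TAA", "TAG", "TGA"])


def _oracle_category(cds, kind, cpos, alt_base=None, edit_len=None):
    """Direct coding-level surgery + translation, no genomic mapping."""
    if kind == "snv":
        mutated = cds[: cpos - 1] + alt_base + cds[cpos:]
        if mutated == cds:
            return None
        ref_p, mut_p = _oracle_translate(cds), _oracle_translate(mutated)
        if mut_p == ref_p:
            return Category.SYNONYMOUS
        codon = (cpos - 1) // 3
        if codon == 0 and mutated[:3] != "ATG":
            return Category.START_LOST
        if mut_p[codon] == "*" and ref_p[codon] != "*":
            return Category.STOP_GAINED
        if ref_p[codon] == "*" and mut_p[codon] != "*":
            return Category.STOP_LOST
        return Category.MISSENSE
    if kind == "del":
        return Category.FRAMESHIFT if edit_len % 3 else Category.INFRAME_INDEL
    if kind == "ins":
        return Category.FRAMESHIFT if edit_len % 3 else Category.INFRAME_INDEL
    raise AssertionError(kind)


def random_coding_pair(rng, offset=50):
    """(site, model, genome, expected_category) with a random strand."""
    n_codons = int(rng.integers(10, 60))
    cds = _random_cds(rng, n_codons)
    L = len(cds)
    strand = "+" if rng.random() < 0.5 else "-"
    genome = _genome_for(cds, offset=offset, strand=strand, pad=200)
    model = _plus_model(cds, offset=offset, strand=strand)
    plus = genome["chr"]

    def g(c):  # genomic position of coding base c
        return offset + c if strand == "+" else offset + (L - c + 1)

    kind = rng.choice(["snv", "del", "ins"], p=[0.5, 0.3, 0.2])
    if kind == "snv":
        cpos = int(rng.integers(1, L + 1))
        alt_c = rng.choice([b for b in "ACGT" if b != cds[cpos - 1]])
        gp = g(cpos)
        alt_g = alt_c if strand == "+" else alt_c.translate(_COMP)
        site = _site(gp, plus[gp - 1], alt_g)
        expected = _oracle_category(cds, "snv", cpos, alt_base=alt_c)
    elif kind == "del":
        length = int(rng.integers(1, 5))
        c1 = int(rng.integers(2, L - length))  # keep the anchor inside the contig
        g1 = min(g(c1), g(c1 + length - 1))
        g2 = max(g(c1), g(c1 + length - 1))
        site = _site(g1 - 1, plus[g1 - 2 : g2], plus[g1 - 2])
        expected = _oracle_category(cds, "del", c1, edit_len=length)
    else:
        length = int(rng.integers(1, 5))
        ins = "".join(rng.choice(list("ACGT"), size=length))
        c = int(rng.integers(1, L))  # insert between coding c and c+1
        anchor = g(c) if strand == "+" else g(c + 1)
        ins_plus = ins if strand == "+" else ins.translate(_COMP)[::-1]
        site = _site(anchor, plus[anchor - 1], plus[anchor - 1] + ins_plus)
        expected = _oracle_category(cds, "ins", c, edit_len=length)
    return site, model, genome, expected


class TestRandomisedOracle:
    def test_category_agreement_on_random_cds_variant_pairs(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(300):
            site, model, genome, expected = random_coding_pair(rng)
            if expected is None:
                continue
            got = annotate_variant(site, [model], genome)[0].category
            assert got is expected, (site, model.strand, expected, got)
            n_checked += 1
        assert n_checked > 250

    def test_translation_agrees_with_oracle_table(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            cds = _random_cds(rng, int(rng.integers(5, 40)))
            assert translate(cds) == _oracle_translate(cds)

    def test_inframe_deletions_never_frameshift(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            cds = _random_cds(rng, 30)
            genome = _genome_for(cds)
            model = _plus_model(cds)
            c1 = int(rng.integers(2, len(cds) - 7))
            plus = genome["chr"]
            g1 = 100 + c1
            site = _site(g1 - 1, plus[g1 - 2 : g1 + 2], plus[g1 - 2])  # 3-bp deletion
            cons = annotate_variant(site, [model], genome)[0]
            assert cons.category is not Category.FRAMESHIFT

    def test_strand_symmetry_of_cds_reconstruction(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            cds = _random_cds(rng, 20)
            for strand in "+-":
                genome = _genome_for(cds, strand=strand)
                model = _plus_model(cds, strand=strand)
                assert model.cds_sequence(genome) == cds


class TestOrfHelpers:
    def test_clean_cds_is_complete(self):
        assert cds_is_complete("ATG" + "GCT" * 10 + "TAA")

    def test_internal_stop_or_bad_ends_incomplete(self):
        assert not cds_is_complete("ATG" + "TAA" + "GCT" * 10 + "TAA")
        assert not cds_is_complete("CTG" + "GCT" * 10 + "TAA")
        assert not cds_is_complete("ATG" + "GCT" * 10 + "GCA")

    def test_stop_counting_per_frame(self):
        seq = ("TTAA" * 30)
        assert all(stops_in_frame(seq, f) >= 2 for f in range(3))


class TestGff3AndFasta(object):
    def test_round_trip_through_files(self, tmp_path):
        from fhmap.simulate import CrossConfig, simulate_parents, emit_gene_models, emit_reference

        cfg = CrossConfig(seed=13, n_contigs=1, contig_length=20_000, causal_position=10_000)
        parents = simulate_parents(cfg)
        fasta, gff3 = str(tmp_path / "g.fasta"), str(tmp_path / "g.gff3")
        emit_reference(parents, fasta)
        emit_gene_models(parents, gff3)
        genome = load_genome(fasta)
        models = load_gene_models(gff3)
        assert genome["contig_1"] == parents.sequences["contig_1"]
        assert len(models) == 1
        assert models[0].cds == parents.gene.cds
        assert models[0].strand == parents.gene.strand
        assert cds_is_complete(models[0].cds_sequence(genome))
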