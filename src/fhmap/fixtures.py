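"""Synthetic demonstration dataset for the candidate-filtration funnel.

Builds a 9-kb toy contig carrying a clean coding gene and a spurious "gene"
with stop codons in every reading frame, plus 20 planted variants whose
funnel fate is known by construction: 15 pass the impact filter and 11 of
those are removed by the 50-bp cluster screen (8) or the reading-frame
confidence screen (3), leaving 4 survivors. This mirrors the shape of a
real mapping funnel while staying fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from .annotation import GeneModel, Impact, annotate_variant, most_severe
from .mapping import LinkedRegion, ParentLabel
from .model import GenotypeCall, Role, VariantSite

_GENE_A_START = 1001
_GENE_A_CODONS = 400  # CDS 1200 nt at [1001..2200]
_JUNK_START = 5001
_JUNK_LEN = 600


@dataclass
class FunnelDemo:
    genome: Dict[str, str]
    models: List[GeneModel]
    regions: List[LinkedRegion]
    sites: List[VariantSite]
    expected_survivor_positions: List[int]
    n_high_moderate: int


def _site(genome: Dict[str, str], pos: int, alt: str, bio: str = "0/0") -> VariantSite:
    ref = genome["chrT"][pos - 1]
    assert ref != alt
    calls = {}
    for role, spec in ((Role.PARENT_LVG, "1/1"), (Role.PARENT_BIO, bio), (Role.F2_POOL, "1/1")):
        a, b = (int(x) for x in spec.split("/"))
        ad = tuple(15 if i in (a, b) else 0 for i in range(2))
        calls[role] = GenotypeCall((a, b), ad, sum(ad))
    return VariantSite("chrT", pos, ref, (alt,), calls)


def _damaging_alt(genome, models, pos) -> str:
    """First substitution at ``pos`` with HIGH or MODERATE impact."""
    ref = genome["chrT"][pos - 1]
    for alt in "ACGT":
        if alt == ref:
            continue
        cons = most_severe(annotate_variant(_site(genome, pos, alt), models, genome))
        if cons.impact in (Impact.HIGH, Impact.MODERATE):
            return alt
    raise AssertionError(f"no damaging substitution found at {pos}")


def build_funnel_demo() -> FunnelDemo:
    # clean gene A: ATG + 398x GCT(Ala) + TAA
    gene_a_cds = "ATG" + "GCT" * (_GENE_A_CODONS - 2) + "TAA"
    # junk gene: TTAA repeats put stop codons in all three frames
    junk_cds = ("TTAA" * 200)[:_JUNK_LEN]
    chrom = ["A"] * 9000
    chrom[_GENE_A_START - 1 : _GENE_A_START - 1 + len(gene_a_cds)] = gene_a_cds
    chrom[_JUNK_START - 1 : _JUNK_START - 1 + len(junk_cds)] = junk_cds
    genome = {"chrT": "".join(chrom)}
    gene_a = GeneModel(
        gene_id="geneA", transcript_id="txA", contig="chrT", strand="+",
        exons=((_GENE_A_START, _GENE_A_START + len(gene_a_cds) - 1),),
        cds=((_GENE_A_START, _GENE_A_START + len(gene_a_cds) - 1),),
    )
    gene_junk = GeneModel(
        gene_id="geneJunk", transcript_id="txJunk", contig="chrT", strand="+",
        exons=((_JUNK_START, _JUNK_START + _JUNK_LEN - 1),),
        cds=((_JUNK_START, _JUNK_START + _JUNK_LEN - 1),),
    )
    models = [gene_a, gene_junk]
    regions = [
        LinkedRegion(contig="chrT", start=1, end=6000, parent_label=ParentLabel.LVG,
                     n_windows=10, mean_score=0.97)
    ]

    def cds_a(cds_pos: int) -> int:
        return _GENE_A_START + cds_pos - 1

    sites: List[VariantSite] = []
    # 4 isolated damaging variants in gene A (the true survivors):
    # second base of codons 10/60/110/160 -> GCT(Ala) -> GAT(Asp), missense
    survivors = [cds_a(3 * k - 1) for k in (10, 60, 110, 160)]
    for pos in survivors:
        sites.append(_site(genome, pos, "A"))
    # 8 damaging variants in a dense cluster (step 12 bp): all fail the
    # 50-bp neighbour screen
    for i in range(8):
        sites.append(_site(genome, cds_a(749 + 12 * i), "A"))
    # 3 isolated damaging variants in the junk gene: fail ORF confidence
    for offset in (100, 220, 340):
        pos = _JUNK_START + offset
        sites.append(_site(genome, pos, _damaging_alt(genome, models, pos)))
    # 2 variants outside the linked region
    for pos in (8000, 8200):
        sites.append(_site(genome, pos, "G"))
    # 2 variants also carried by the mapping parent (not unique)
    for k in (320, 360):
        sites.append(_site(genome, cds_a(3 * k - 1), "A", bio="0/1"))
    # 1 synonymous variant (third base of codon 380: GCT -> GCC)
    sites.append(_site(genome, cds_a(3 * 380), "C"))
    sites.sort(key=lambda s: s.position)
    return FunnelDemo(
        genome=genome,
        models=models,
        regions=regions,
        sites=sites,
        expected_survivor_positions=sorted(survivors),
        n_high_moderate=15,
    )
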