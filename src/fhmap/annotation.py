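"""Miniature variant-effect predictor over GFF3 gene models and a FASTA genome.

Consequences are determined by re-translating the mutated coding sequence:
single-base substitutions become synonymous / missense / stop_gained /
stop_lost / start_lost; coding indels become frameshift (net length not a
multiple of 3, with downstream premature-stop prediction) or inframe_indel;
everything else falls into splice_region / utr / intronic / intergenic.
Putative impact follows the familiar four-tier HIGH / MODERATE / LOW /
MODIFIER convention of SnpEff-style annotators.

Protein notation is deliberately simplified: ``p.<RefAA><codon>fs`` for
frameshifts and ``p.<RefAA><codon><AltAA>`` for substitutions, with no
3'-rule repositioning of indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils
from Bio.Data import CodonTable
from Bio.Seq import Seq
from pyfaidx import Fasta

from .model import FhmapError, ValidationError, VariantSite

_STD = CodonTable.unambiguous_dna_by_id[1]
_CODON: Dict[str, str] = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    _CODON[_stop] = "*"

#: intronic bases on each side of an exon that count as splice region
SPLICE_REGION_BP = 2


class ReferenceMismatchError(FhmapError):
    pass


class Category(str, Enum):
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


_IMPACT_OF: Dict[Category, Impact] = {
    Category.FRAMESHIFT: Impact.HIGH,
    Category.STOP_GAINED: Impact.HIGH,
    Category.STOP_LOST: Impact.HIGH,
    Category.START_LOST: Impact.HIGH,
    Category.SPLICE_REGION: Impact.HIGH,
    Category.MISSENSE: Impact.MODERATE,
    Category.INFRAME_INDEL: Impact.MODERATE,
    Category.SYNONYMOUS: Impact.LOW,
    Category.INTRONIC: Impact.MODIFIER,
    Category.UTR: Impact.MODIFIER,
    Category.INTERGENIC: Impact.MODIFIER,
}

_SEVERITY = {imp: i for i, imp in enumerate([Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER])}


def impact_of(category: Category) -> Impact:
    """Putative impact tier of a consequence category (pure lookup)."""
    return _IMPACT_OF[category]


def translate(seq: str) -> str:
    """Translate complete codons of ``seq`` (standard nuclear table);
    trailing partial codons are ignored, unknown codons become 'X'."""
    seq = seq.upper()
    return "".join(_CODON.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """One transcript's exon/CDS structure on the genome.

    Intervals are 1-based closed, sorted and non-overlapping in genomic
    order. A transcript with no CDS intervals is non-coding.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")
        for ivals in (self.exons, self.cds):
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValidationError("intervals must be sorted and non-overlapping")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValidationError("CDS intervals must lie within exons")
        if self.cds and self.cds_length < 3:
            raise ValidationError("coding transcripts need CDS length >= 3")

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def overlaps(self, pos: int) -> bool:
        s, e = self.span
        return s - SPLICE_REGION_BP <= pos <= e + SPLICE_REGION_BP

    # -- sequence access -------------------------------------------------
    def cds_sequence_plus(self, genome: Mapping[str, str]) -> str:
        """Concatenated CDS in genomic (plus-strand) orientation."""
        chrom = genome[self.contig]
        return "".join(chrom[s - 1 : e] for s, e in self.cds).upper()

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Coding sequence in translation orientation."""
        plus = self.cds_sequence_plus(genome)
        return revcomp(plus) if self.strand == "-" else plus

    def genomic_to_cds_plus(self, pos: int) -> Optional[int]:
        """1-based offset of a genomic position within the plus-orientation
        CDS concatenation, or None if the position is not coding."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                return offset + pos - s + 1
            offset += e - s + 1
        return None

    def to_coding_coord(self, cds_plus: int) -> int:
        return cds_plus if self.strand == "+" else self.cds_length - cds_plus + 1

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return self.genomic_to_cds_plus(pos) is not None

    def in_splice_region(self, pos: int) -> bool:
        if self.in_exon(pos):
            return False
        for s, e in self.exons:
            if 0 < s - pos <= SPLICE_REGION_BP and s != self.span[0]:
                return True
            if 0 < pos - e <= SPLICE_REGION_BP and e != self.span[1]:
                return True
        return False


@dataclass(frozen=True)
class Consequence:
    category: Category
    impact: Impact
    gene_id: str = ""
    transcript_id: str = ""
    hgvs_p: str = ""
    truncated_length: Optional[int] = None


@dataclass(frozen=True)
class TruncationResult:
    truncated_length: Optional[int]  # amino acids before the novel stop
    stop_codon: Optional[int]  # 1-based codon index of the novel stop
    stop_lost: bool  # no stop before the end of the mutated CDS


def _check_reference(site: VariantSite, genome: Mapping[str, str]) -> None:
    chrom = genome.get(site.contig)
    if chrom is None:
        raise ReferenceMismatchError(f"contig {site.contig!r} not in genome")
    ref = chrom[site.position - 1 : site.position - 1 + len(site.ref_allele)].upper()
    if ref != site.ref_allele.upper():
        raise ReferenceMismatchError(
            f"{site.contig}:{site.position} ref {site.ref_allele!r} != genome {ref!r}"
        )


def _trim_common_prefix(ref: str, alt: str) -> Tuple[int, str, str]:
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    return k, ref[k:], alt[k:]


def mutated_cds(
    model: GeneModel, site: VariantSite, genome: Mapping[str, str], alt_index: int = 0
) -> Tuple[str, str, int]:
    """Reference CDS, mutated CDS (both in coding orientation) and the
    1-based coding coordinate of the first changed base.

    Indels must fall within a single CDS interval (toy-model scope);
    coordinate surgery is done in plus orientation, with reverse
    complementation applied last for minus-strand transcripts.
    """
    _check_reference(site, genome)
    ref = site.ref_allele.upper()
    alt = site.alt_alleles[alt_index].upper()
    k, del_seq, ins_seq = _trim_common_prefix(ref, alt)
    plus = model.cds_sequence_plus(genome)
    length = model.cds_length
    if del_seq:
        first = site.position + k
        last = first + len(del_seq) - 1
        c1 = model.genomic_to_cds_plus(first)
        c2 = model.genomic_to_cds_plus(last)
        if c1 is None or c2 is None or c2 - c1 != last - first:
            raise ValidationError(
                f"indel at {site.contig}:{site.position} is not contained in one CDS interval"
            )
        mutated_plus = plus[: c1 - 1] + ins_seq + plus[c1 - 1 + len(del_seq) :]
        if model.strand == "+":
            first_changed = c1
        else:
            first_changed = length - c2 + 1
    else:  # pure insertion anchored after position site.position + k - 1
        anchor = site.position + k - 1
        cpoint = model.genomic_to_cds_plus(anchor)
        if cpoint is None:
            raise ValidationError(
                f"insertion anchor at {site.contig}:{anchor} is not coding"
            )
        mutated_plus = plus[:cpoint] + ins_seq + plus[cpoint:]
        first_changed = cpoint + 1 if model.strand == "+" else length - cpoint + 1
    ref_cds = revcomp(plus) if model.strand == "-" else plus
    mut_cds = revcomp(mutated_plus) if model.strand == "-" else mutated_plus
    return ref_cds, mut_cds, first_changed


def predict_truncation(
    model: GeneModel, site: VariantSite, genome: Mapping[str, str], alt_index: int = 0
) -> TruncationResult:
    """Translate the mutated CDS to the first stop codon.

    Reports the amino-acid count before that stop when it is premature
    (earlier than the reference stop); flags ``stop_lost`` when no stop
    occurs before the end of the mutated sequence.
    """
    ref_cds, mut_cds, _ = mutated_cds(model, site, genome, alt_index)
    ref_protein = translate(ref_cds)
    mut_protein = translate(mut_cds)
    stop_at = mut_protein.find("*")
    if stop_at < 0:
        return TruncationResult(None, None, stop_lost=True)
    ref_stop = ref_protein.find("*")
    ref_stop_codon = ref_stop + 1 if ref_stop >= 0 else len(ref_protein) + 1
    if stop_at + 1 < ref_stop_codon:
        return TruncationResult(stop_at, stop_at + 1, stop_lost=False)
    return TruncationResult(None, stop_at + 1, stop_lost=False)


def _aa1(aa: str) -> str:
    return aa if aa else "?"


def _coding_consequence(
    model: GeneModel, site: VariantSite, genome: Mapping[str, str], alt_index: int
) -> Consequence:
    ref_cds, mut_cds, first_changed = mutated_cds(model, site, genome, alt_index)
    codon_no = (first_changed - 1) // 3 + 1
    ref_protein = translate(ref_cds)
    ref_aa = ref_protein[codon_no - 1] if codon_no <= len(ref_protein) else "?"
    net = len(mut_cds) - len(ref_cds)
    common = dict(gene_id=model.gene_id, transcript_id=model.transcript_id)
    if net != 0:
        if net % 3 != 0:
            trunc = predict_truncation(model, site, genome, alt_index)
            return Consequence(
                Category.FRAMESHIFT,
                impact_of(Category.FRAMESHIFT),
                hgvs_p=f"p.{_aa1(ref_aa)}{codon_no}fs",
                truncated_length=trunc.truncated_length,
                **common,
            )
        return Consequence(
            Category.INFRAME_INDEL,
            impact_of(Category.INFRAME_INDEL),
            hgvs_p=f"p.{_aa1(ref_aa)}{codon_no}del" if len(mut_cds) < len(ref_cds) else f"p.{_aa1(ref_aa)}{codon_no}ins",
            **common,
        )
    # length-preserving substitution: compare translations codon-wise
    mut_protein = translate(mut_cds)
    mut_aa = mut_protein[codon_no - 1] if codon_no <= len(mut_protein) else "?"
    hgvs = f"p.{_aa1(ref_aa)}{codon_no}{_aa1(mut_aa)}"
    if mut_protein == ref_protein:
        return Consequence(Category.SYNONYMOUS, impact_of(Category.SYNONYMOUS), hgvs_p=hgvs, **common)
    if codon_no == 1 and ref_cds[:3] == "ATG" and mut_cds[:3] != "ATG":
        return Consequence(Category.START_LOST, impact_of(Category.START_LOST), hgvs_p=hgvs, **common)
    if mut_aa == "*" and ref_aa != "*":
        return Consequence(
            Category.STOP_GAINED,
            impact_of(Category.STOP_GAINED),
            hgvs_p=hgvs,
            truncated_length=codon_no - 1,
            **common,
        )
    if ref_aa == "*" and mut_aa != "*":
        return Consequence(Category.STOP_LOST, impact_of(Category.STOP_LOST), hgvs_p=hgvs, **common)
    return Consequence(Category.MISSENSE, impact_of(Category.MISSENSE), hgvs_p=hgvs, **common)


def annotate_variant(
    site: VariantSite,
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    alt_index: int = 0,
) -> List[Consequence]:
    """One consequence per overlapping transcript; intergenic if none."""
    _check_reference(site, genome)
    out: List[Consequence] = []
    pos = site.position
    for model in models:
        if model.contig != site.contig or not model.overlaps(pos):
            continue
        common = dict(gene_id=model.gene_id, transcript_id=model.transcript_id)
        if model.is_coding and model.in_cds(pos):
            out.append(_coding_consequence(model, site, genome, alt_index))
        elif model.in_exon(pos):
            out.append(Consequence(Category.UTR, impact_of(Category.UTR), **common))
        elif model.in_splice_region(pos):
            out.append(
                Consequence(Category.SPLICE_REGION, impact_of(Category.SPLICE_REGION), **common)
            )
        else:
            s, e = model.span
            if s <= pos <= e:
                out.append(Consequence(Category.INTRONIC, impact_of(Category.INTRONIC), **common))
    if not out:
        out.append(Consequence(Category.INTERGENIC, Impact.MODIFIER))
    return out


def most_severe(consequences: Sequence[Consequence]) -> Consequence:
    """Pick the most severe consequence (SnpEff-style canonical report)."""
    return min(consequences, key=lambda c: (_SEVERITY[c.impact], list(Category).index(c.category)))


# -- reading-frame confidence helpers -----------------------------------

def cds_is_complete(seq: str) -> bool:
    """A complete reading frame: length % 3 == 0, starts ATG, ends with a
    stop, and no internal stop in the annotated frame."""
    seq = seq.upper()
    if len(seq) % 3 != 0 or len(seq) < 6:
        return False
    if not seq.startswith("ATG"):
        return False
    protein = translate(seq)
    return protein.endswith("*") and "*" not in protein[:-1]


def stops_in_frame(seq: str, frame: int) -> int:
    """Number of stop codons when translating ``seq`` in forward ``frame``."""
    return translate(seq[frame:]).count("*")


# -- external formats -----------------------------------------------------

def load_genome(path: str) -> Dict[str, str]:
    """Load a FASTA genome fully into memory as {contig: sequence}."""
    fasta = Fasta(path, rebuild=False)
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def load_gene_models(path: str) -> List[GeneModel]:
    """Read transcripts (mRNA features with exon/CDS children) from GFF3."""
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: List[GeneModel] = []
    for t in db.features_of_type(("mRNA", "transcript")):
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(t, featuretype="exon"))
        )
        cds = tuple(sorted((f.start, f.end) for f in db.children(t, featuretype="CDS")))
        if not exons:
            exons = cds
        gene_id = t.attributes.get("Parent", [t.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=t.id,
                contig=t.seqid,
                strand=t.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models
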