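"""Candidate-variant filtration funnel.

Five filters, applied in order, narrow the variant list to candidate causal
mutations: (1) containment in a mutant-parent-linked region, (2) presence in
mutant parent and pool but not the mapping parent, (3) HIGH/MODERATE
putative impact, (4) a 50-bp variant-cluster screen against alignment-noise
pileups, and (5) a reading-frame confidence screen against spuriously
annotated transcripts in low-quality assembly regions. Each candidate keeps
a per-filter audit trail.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .annotation import (
    Consequence,
    GeneModel,
    Impact,
    annotate_variant,
    cds_is_complete,
    most_severe,
    stops_in_frame,
)
from .mapping import LinkedRegion, ParentLabel
from .model import Role, VariantSite


@dataclass(frozen=True)
class FunnelParams:
    cluster_radius: int = 50
    max_neighbors: int = 1
    #: neighbors counted against the full pre-filter variant list ("all")
    #: or only the surviving candidate list ("candidates")
    neighbor_background: str = "all"
    #: a transcript fails ORF confidence only if every forward frame holds
    #: at least this many stop codons
    min_stops_all_frames: int = 2


@dataclass
class CandidateVariant:
    site: VariantSite
    consequence: Optional[Consequence] = None
    flags: Dict[str, Optional[bool]] = field(
        default_factory=lambda: {
            "in_region": None,
            "unique_to_mutant": None,
            "impact_ok": None,
            "cluster_ok": None,
            "orf_ok": None,
        }
    )
    warnings: List[str] = field(default_factory=list)

    @property
    def survives(self) -> bool:
        return all(v is True for v in self.flags.values())


def restrict_to_regions(
    sites: Sequence[VariantSite], regions: Sequence[LinkedRegion]
) -> List[VariantSite]:
    """Keep sites positioned inside any of ``regions`` (1-based closed)."""
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append((r.start, r.end))
    out = []
    for s in sites:
        for start, end in by_contig.get(s.contig, ()):
            if start <= s.position <= end:
                out.append(s)
                break
    return out


def carries_any_alt(site: VariantSite, role: Role) -> Optional[int]:
    """Index of the first alt allele the sample carries, else None."""
    call = site.call(role)
    if call.is_missing:
        return None
    for i in range(1, site.n_alleles):
        if call.carries(i):
            return i
    return None


def is_unique_to_mutant(site: VariantSite) -> bool:
    """True when the mutant parent AND the pool carry an alt allele (any
    zygosity) that the mapping parent does not carry at all."""
    pool = site.call(Role.F2_POOL)
    lvg = site.call(Role.PARENT_LVG)
    bio = site.call(Role.PARENT_BIO)
    for i in range(1, site.n_alleles):
        if lvg.carries(i) and pool.carries(i) and not bio.carries(i):
            return True
    return False


def unique_to_mutant(sites: Sequence[VariantSite]) -> List[VariantSite]:
    return [s for s in sites if is_unique_to_mutant(s)]


def filter_by_impact(candidates: Sequence[CandidateVariant]) -> List[CandidateVariant]:
    return [
        c
        for c in candidates
        if c.consequence is not None
        and c.consequence.impact in (Impact.HIGH, Impact.MODERATE)
    ]


def count_neighbors(
    site: VariantSite,
    background: Sequence[VariantSite],
    radius: int = 50,
) -> int:
    """Other variants on the same contig within +-radius bp (the site itself,
    identified by contig and position, is not its own neighbor)."""
    n = 0
    for other in background:
        if other.contig != site.contig:
            continue
        if other.position == site.position:
            continue
        if abs(other.position - site.position) <= radius:
            n += 1
    return n


def cluster_filter(
    sites: Sequence[VariantSite],
    background: Optional[Sequence[VariantSite]] = None,
    radius: int = 50,
    max_neighbors: int = 1,
) -> List[VariantSite]:
    """Drop sites with more than ``max_neighbors`` other variants within
    +-``radius`` bp (combined up- and downstream count)."""
    if background is None:
        background = sites
    pos_by_contig: Dict[str, List[int]] = {}
    for s in background:
        pos_by_contig.setdefault(s.contig, []).append(s.position)
    for positions in pos_by_contig.values():
        positions.sort()
    kept = []
    for s in sites:
        positions = pos_by_contig.get(s.contig, [])
        lo = bisect_left(positions, s.position - radius)
        hi = bisect_right(positions, s.position + radius)
        n = hi - lo
        # discount background entries at the site's own position
        n -= bisect_right(positions, s.position) - bisect_left(positions, s.position)
        if n <= max_neighbors:
            kept.append(s)
    return kept


def orf_confidence(
    model: Optional[GeneModel],
    genome: Mapping[str, str],
    min_stops_all_frames: int = 2,
) -> Tuple[bool, Optional[str]]:
    """(passes, warning) for the reading-frame confidence rule.

    A transcript with a complete reference reading frame passes cleanly.
    An incomplete one is rescanned in all three forward frames and fails
    only when every frame contains >= ``min_stops_all_frames`` stop codons
    (the hallmark of a spurious gene model in a noisy assembly region);
    otherwise it passes with a low-confidence warning. Non-coding or
    unannotated transcripts pass unchanged.
    """
    if model is None or not model.is_coding:
        return True, None
    seq = model.cds_sequence(genome)
    if cds_is_complete(seq):
        return True, None
    if all(stops_in_frame(seq, f) >= min_stops_all_frames for f in range(3)):
        return False, None
    return True, f"low-confidence reading frame in {model.transcript_id}"


def orf_confidence_filter(
    candidates: Sequence[CandidateVariant],
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    min_stops_all_frames: int = 2,
) -> List[CandidateVariant]:
    by_tid = {m.transcript_id: m for m in models}
    kept = []
    for c in candidates:
        model = by_tid.get(c.consequence.transcript_id) if c.consequence else None
        ok, warning = orf_confidence(model, genome, min_stops_all_frames)
        if warning:
            c.warnings.append(warning)
        if ok:
            kept.append(c)
    return kept


@dataclass
class FunnelReport:
    stages: List[Tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count"])


def run_funnel(
    sites: Sequence[VariantSite],
    regions: Sequence[LinkedRegion],
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    params: FunnelParams = FunnelParams(),
) -> Tuple[FunnelReport, List[CandidateVariant], List[CandidateVariant]]:
    """Apply the five filters in order.

    Returns the stage-count report, the audit list (every input site with
    its per-filter flags evaluated up to its first failure) and the
    survivors. Candidates are annotated with their most severe consequence
    across overlapping transcripts.
    """
    lvg_regions = [r for r in regions if r.parent_label is ParentLabel.LVG]
    candidates = [CandidateVariant(site=s) for s in sites]
    stages: List[Tuple[str, int]] = [("input", len(candidates))]

    in_region = set(id(s) for s in restrict_to_regions(sites, lvg_regions))
    live = []
    for c in candidates:
        c.flags["in_region"] = id(c.site) in in_region
        if c.flags["in_region"]:
            live.append(c)
    stages.append(("in_lvg_region", len(live)))

    nxt = []
    for c in live:
        c.flags["unique_to_mutant"] = is_unique_to_mutant(c.site)
        if c.flags["unique_to_mutant"]:
            nxt.append(c)
    live = nxt
    stages.append(("unique_to_mutant", len(live)))

    nxt = []
    for c in live:
        c.consequence = most_severe(annotate_variant(c.site, models, genome))
        c.flags["impact_ok"] = c.consequence.impact in (Impact.HIGH, Impact.MODERATE)
        if c.flags["impact_ok"]:
            nxt.append(c)
    live = nxt
    stages.append(("high_moderate_impact", len(live)))

    background = sites if params.neighbor_background == "all" else [c.site for c in live]
    clustered_ok = set(
        id(s)
        for s in cluster_filter(
            [c.site for c in live],
            background=background,
            radius=params.cluster_radius,
            max_neighbors=params.max_neighbors,
        )
    )
    nxt = []
    for c in live:
        c.flags["cluster_ok"] = id(c.site) in clustered_ok
        if c.flags["cluster_ok"]:
            nxt.append(c)
    live = nxt
    stages.append(("cluster_screen", len(live)))

    by_tid = {m.transcript_id: m for m in models}
    nxt = []
    for c in live:
        model = by_tid.get(c.consequence.transcript_id) if c.consequence else None
        ok, warning = orf_confidence(model, genome, params.min_stops_all_frames)
        if warning:
            c.warnings.append(warning)
        c.flags["orf_ok"] = ok
        if ok:
            nxt.append(c)
    live = nxt
    stages.append(("orf_confidence", len(live)))

    return FunnelReport(stages), candidates, live


def candidates_table(candidates: Sequence[CandidateVariant]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        cons = c.consequence
        rows.append(
            {
                "contig": c.site.contig,
                "position": c.site.position,
                "ref": c.site.ref_allele,
                "alt": ",".join(c.site.alt_alleles),
                "gene": cons.gene_id if cons else "",
                "category": cons.category.value if cons else "",
                "impact": cons.impact.value if cons else "",
                "hgvs_p": cons.hgvs_p if cons else "",
                **{f"flag_{k}": v for k, v in c.flags.items()},
                "survives": c.survives,
            }
        )
    return pd.DataFrame(rows)
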