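"""Parental marker classification.

A *unique homozygous SNP* is a site where exactly one inbred parent is
homozygous for a non-reference allele; these act as ancestry markers for the
pooled offspring. Classification is allele-aware: a parent pair homozygous
for two *different* alternate alleles is informative but ambiguous and falls
into OTHER (scored 0.5 downstream), and a site where both parents share the
same homozygous alternate allele is uninformative (SHARED_HOM, skipped when
the pool is also homozygous).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .model import GenotypeCall, Role, VariantSite

#: Parental read depth below which a call is demoted to missing before
#: classification (symmetric with the pool coverage rule).
DEFAULT_MIN_PARENT_DEPTH = 5


class MarkerClass(str, Enum):
    UNIQUE_HOM_LVG = "UNIQUE_HOM_LVG"
    UNIQUE_HOM_BIO = "UNIQUE_HOM_BIO"
    SHARED_HOM = "SHARED_HOM"
    OTHER = "OTHER"


@dataclass(frozen=True)
class MarkerCensus:
    n_unique_hom_lvg: int
    n_unique_hom_bio: int


def _effective(call: GenotypeCall, min_depth: int) -> GenotypeCall:
    if not call.is_missing and call.total_depth < min_depth:
        return GenotypeCall.missing(len(call.allele_depths) or 2, call.total_depth)
    return call


def classify_site(
    site: VariantSite, min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH
) -> MarkerClass:
    """Classify a site by parental informativeness.

    UNIQUE_HOM_LVG: the Lakeview parent is homozygous for a non-reference
    allele and the Bio14.6 parent is not homozygous for that same allele
    (symmetrically for UNIQUE_HOM_BIO); SHARED_HOM: both parents homozygous
    for the same non-reference allele; OTHER: everything else (het parents,
    both hom-ref, missing or low-depth parental calls, conflicting hom-alt).
    """
    lvg = _effective(site.call(Role.PARENT_LVG), min_parent_depth)
    bio = _effective(site.call(Role.PARENT_BIO), min_parent_depth)
    lvg_hom = lvg.hom_allele
    bio_hom = bio.hom_allele
    lvg_hom_alt = lvg_hom is not None and lvg_hom != 0
    bio_hom_alt = bio_hom is not None and bio_hom != 0
    if lvg_hom_alt and bio_hom_alt:
        if lvg_hom == bio_hom:
            return MarkerClass.SHARED_HOM
        return MarkerClass.OTHER  # conflicting hom-alt alleles: ambiguous
    if lvg_hom_alt:
        return MarkerClass.UNIQUE_HOM_LVG
    if bio_hom_alt:
        return MarkerClass.UNIQUE_HOM_BIO
    return MarkerClass.OTHER


def census_markers(
    sites: Iterable[VariantSite], min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH
) -> MarkerCensus:
    """Count unique homozygous markers per parent (marker-density imbalance)."""
    n_lvg = 0
    n_bio = 0
    for site in sites:
        cls = classify_site(site, min_parent_depth)
        if cls is MarkerClass.UNIQUE_HOM_LVG:
            n_lvg += 1
        elif cls is MarkerClass.UNIQUE_HOM_BIO:
            n_bio += 1
    return MarkerCensus(n_lvg, n_bio)


def swap_parent_roles(site: VariantSite) -> VariantSite:
    """Return the site with the two parental calls exchanged (pool untouched)."""
    calls: Dict[Role, GenotypeCall] = dict(site.calls)
    lvg = calls.get(Role.PARENT_LVG)
    bio = calls.get(Role.PARENT_BIO)
    if lvg is not None:
        calls[Role.PARENT_BIO] = lvg
    else:
        calls.pop(Role.PARENT_BIO, None)
    if bio is not None:
        calls[Role.PARENT_LVG] = bio
    else:
        calls.pop(Role.PARENT_LVG, None)
    return replace(site, calls=calls)


def _gt_str(call: GenotypeCall) -> str:
    if call.is_missing:
        return "./."
    a, b = call.allele_indices  # type: ignore[misc]
    return f"{a}/{b}"


def marker_report(
    sites: Sequence[VariantSite], min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH
) -> pd.DataFrame:
    """Tabular marker report: contig, position, class, parental genotypes."""
    rows = []
    for site in sites:
        rows.append(
            {
                "contig": site.contig,
                "position": site.position,
                "marker_class": classify_site(site, min_parent_depth).value,
                "gt_parent_lvg": _gt_str(site.call(Role.PARENT_LVG)),
                "gt_parent_bio": _gt_str(site.call(Role.PARENT_BIO)),
            }
        )
    return pd.DataFrame(
        rows, columns=["contig", "position", "marker_class", "gt_parent_lvg", "gt_parent_bio"]
    )
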