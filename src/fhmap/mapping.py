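"""Weighted homozygosity scoring, rolling windows and region calling.

This is the core of the mapping-by-sequencing scan. Every SNP the F2 pool
carries is weighted by the pool's zygosity and the parental marker class:

===========  ===============  =====
pool call    marker class     score
===========  ===============  =====
homozygous   UNIQUE_HOM_LVG    1.0
homozygous   UNIQUE_HOM_BIO    0.0
homozygous   SHARED_HOM        (skipped)
homozygous   OTHER             0.5
heterozygous UNIQUE_HOM_LVG    0.8
heterozygous UNIQUE_HOM_BIO    0.2
heterozygous SHARED_HOM        0.5
heterozygous OTHER             0.5
===========  ===============  =====

The intermediate 0.8/0.2 weights damp the influence of the ~3:1 parental
marker-density imbalance. Scores are averaged in a rolling window of 100
scored SNPs; windows with mean >= 0.9 (<= 0.1) are merged into regions
linked to the mutant (mapping) parental background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .markers import (
    DEFAULT_MIN_PARENT_DEPTH,
    MarkerCensus,
    MarkerClass,
    census_markers,
    classify_site,
)
from .model import ConfigurationError, Role, VariantClass, VariantSite
from .variant_io import filter_by_pool_coverage


class PoolZygosity(str, Enum):
    HOM = "HOM"
    HET = "HET"


class ParentLabel(str, Enum):
    LVG = "LVG"
    BIO = "BIO"


@dataclass(frozen=True)
class ScanParameters:
    """Tunable scan parameters (defaults are the study's settings)."""

    window_size: int = 100
    hi: float = 0.9
    lo: float = 0.1
    min_pool_depth: int = 5
    min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH
    min_windows: int = 1

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ConfigurationError("window_size must be >= 1")
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ConfigurationError("need 0 <= lo < hi <= 1")
        if self.min_pool_depth < 0:
            raise ConfigurationError("min_pool_depth must be >= 0")


@dataclass(frozen=True)
class ScoredSnp:
    site: VariantSite
    marker_class: MarkerClass
    pool_zygosity: PoolZygosity
    score: Optional[float]
    skipped: bool


@dataclass(frozen=True)
class WindowScore:
    contig: str
    first_ordinal: int  # index into the per-contig non-skipped scored sequence
    last_ordinal: int
    start: int  # genomic position of the first contributing SNP
    end: int  # genomic position of the last contributing SNP
    mean_score: float


@dataclass(frozen=True)
class LinkedRegion:
    contig: str
    start: int
    end: int
    parent_label: ParentLabel
    n_windows: int
    mean_score: float


_SCORE_TABLE: Dict[Tuple[PoolZygosity, MarkerClass], Optional[float]] = {
    (PoolZygosity.HOM, MarkerClass.UNIQUE_HOM_LVG): 1.0,
    (PoolZygosity.HOM, MarkerClass.UNIQUE_HOM_BIO): 0.0,
    (PoolZygosity.HOM, MarkerClass.SHARED_HOM): None,  # skipped
    (PoolZygosity.HOM, MarkerClass.OTHER): 0.5,
    (PoolZygosity.HET, MarkerClass.UNIQUE_HOM_LVG): 0.8,
    (PoolZygosity.HET, MarkerClass.UNIQUE_HOM_BIO): 0.2,
    (PoolZygosity.HET, MarkerClass.SHARED_HOM): 0.5,
    (PoolZygosity.HET, MarkerClass.OTHER): 0.5,
}


def score_snp(
    pool_zygosity: PoolZygosity, marker_class: MarkerClass
) -> Optional[float]:
    """Weight for one pool SNP; ``None`` means the SNP is skipped."""
    return _SCORE_TABLE[(pool_zygosity, marker_class)]


def pool_zygosity_of(site: VariantSite) -> Optional[PoolZygosity]:
    """HOM for a homozygous non-reference pool call, HET for a heterozygous
    one, ``None`` for anything that is not a pool SNP genotype (missing or
    homozygous-reference: the pool carries no variant there)."""
    call = site.call(Role.F2_POOL)
    if call.is_missing:
        return None
    if call.is_het:
        return PoolZygosity.HET
    if call.hom_allele not in (None, 0):
        return PoolZygosity.HOM
    return None


def score_sites(
    sites: Sequence[VariantSite], params: ScanParameters = ScanParameters()
) -> List[ScoredSnp]:
    """Classify and weight every scannable pool SNP.

    Only SNPs (not INDELs) that the pool itself carries enter the scan;
    the pool-coverage filter is assumed to have been applied upstream.
    """
    scored: List[ScoredSnp] = []
    for site in sites:
        if site.variant_class is not VariantClass.SNP:
            continue
        zyg = pool_zygosity_of(site)
        if zyg is None:
            continue
        cls = classify_site(site, params.min_parent_depth)
        s = score_snp(zyg, cls)
        scored.append(
            ScoredSnp(
                site=site,
                marker_class=cls,
                pool_zygosity=zyg,
                score=s,
                skipped=s is None,
            )
        )
    return scored


def rolling_windows(
    scored: Sequence[ScoredSnp], params: ScanParameters = ScanParameters()
) -> List[WindowScore]:
    """Rolling mean over every run of ``window_size`` consecutive non-skipped
    SNPs on one contig, advancing one SNP per step.

    Skipped SNPs do not occupy window slots; contigs with fewer scored SNPs
    than the window size yield no windows. Scores are multiples of 0.1, so
    window sums are accumulated as exact integers (score x 10) and the mean
    is a single float division — bit-reproducible and free of cumulative
    rounding drift.
    """
    w = params.window_size
    windows: List[WindowScore] = []
    # group by contig, preserving input order
    by_contig: Dict[str, List[ScoredSnp]] = {}
    order: List[str] = []
    for snp in scored:
        c = snp.site.contig
        if c not in by_contig:
            by_contig[c] = []
            order.append(c)
        by_contig[c].append(snp)
    for contig in order:
        snps = [s for s in by_contig[contig] if not s.skipped]
        n = len(snps)
        if n < w:
            continue
        tens = np.rint(np.array([s.score for s in snps]) * 10.0).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(tens)])
        pos = np.array([s.site.position for s in snps])
        for i in range(n - w + 1):
            mean = (csum[i + w] - csum[i]) / (10.0 * w)
            windows.append(
                WindowScore(
                    contig=contig,
                    first_ordinal=i,
                    last_ordinal=i + w - 1,
                    start=int(pos[i]),
                    end=int(pos[i + w - 1]),
                    mean_score=float(mean),
                )
            )
    return windows


def call_linked_regions(
    windows: Sequence[WindowScore], params: ScanParameters = ScanParameters()
) -> List[LinkedRegion]:
    """Merge threshold-passing windows into parent-linked regions.

    Windows with mean >= ``hi`` are LVG-linked, <= ``lo`` BIO-linked
    (thresholds inclusive, as stated). Same-label qualifying windows whose
    SNP-ordinal spans overlap or abut (i.e. share a contributing SNP or are
    adjacent in window order) are merged — non-qualifying windows in
    between do not break a region, so same-label regions on a contig are
    genomically disjoint (positions are monotone in ordinal). Region bounds
    are the min/max genomic positions of contributing windows.
    ``min_windows`` (default 1) discards regions supported by fewer windows.
    """
    regions: List[LinkedRegion] = []
    open_regions: Dict[Tuple[str, ParentLabel], dict] = {}

    def flush(key: Tuple[str, ParentLabel]) -> None:
        cur = open_regions.pop(key, None)
        if cur is not None and cur["n"] >= params.min_windows:
            regions.append(
                LinkedRegion(
                    contig=key[0],
                    start=cur["start"],
                    end=cur["end"],
                    parent_label=key[1],
                    n_windows=cur["n"],
                    mean_score=cur["sum"] / cur["n"],
                )
            )

    for win in windows:
        if win.mean_score >= params.hi:
            label = ParentLabel.LVG
        elif win.mean_score <= params.lo:
            label = ParentLabel.BIO
        else:
            continue
        key = (win.contig, label)
        cur = open_regions.get(key)
        if cur is not None and win.first_ordinal <= cur["last_ordinal"] + 1:
            cur["end"] = max(cur["end"], win.end)
            cur["last_ordinal"] = max(cur["last_ordinal"], win.last_ordinal)
            cur["n"] += 1
            cur["sum"] += win.mean_score
        else:
            flush(key)
            open_regions[key] = {
                "start": win.start,
                "end": win.end,
                "last_ordinal": win.last_ordinal,
                "n": 1,
                "sum": win.mean_score,
            }
    for key in list(open_regions):
        flush(key)
    regions.sort(key=lambda r: (r.contig, r.start))
    return regions


@dataclass
class ScanResult:
    census: MarkerCensus
    scored: List[ScoredSnp]
    windows: List[WindowScore]
    regions: List[LinkedRegion]
    log: Dict[str, int] = field(default_factory=dict)


def run_scan(
    sites: Sequence[VariantSite], params: ScanParameters = ScanParameters()
) -> ScanResult:
    """Full scan: coverage filter -> classify -> score -> window -> merge."""
    covered = filter_by_pool_coverage(sites, params.min_pool_depth)
    census = census_markers(covered, params.min_parent_depth)
    scored = score_sites(covered, params)
    windows = rolling_windows(scored, params)
    regions = call_linked_regions(windows, params)
    log = {
        "n_input_sites": len(sites),
        "n_pool_covered": len(covered),
        "n_scanned_snps": len(scored),
        "n_skipped_snps": sum(1 for s in scored if s.skipped),
        "n_windows": len(windows),
        "n_regions": len(regions),
    }
    return ScanResult(census=census, scored=scored, windows=windows, regions=regions, log=log)


def scores_table(scored: Sequence[ScoredSnp]) -> pd.DataFrame:
    rows = [
        {
            "contig": s.site.contig,
            "position": s.site.position,
            "marker_class": s.marker_class.value,
            "pool_zygosity": s.pool_zygosity.value,
            "score": s.score if s.score is not None else float("nan"),
            "skipped": s.skipped,
        }
        for s in scored
    ]
    return pd.DataFrame(
        rows, columns=["contig", "position", "marker_class", "pool_zygosity", "score", "skipped"]
    )


def windows_table(windows: Sequence[WindowScore]) -> pd.DataFrame:
    rows = [
        {
            "contig": w.contig,
            "start": w.start,
            "end": w.end,
            "first_ordinal": w.first_ordinal,
            "last_ordinal": w.last_ordinal,
            "mean_score": w.mean_score,
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "first_ordinal", "last_ordinal", "mean_score"]
    )
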