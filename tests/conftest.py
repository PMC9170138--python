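"""Shared fixtures: hand-built variant sites and the constructed
filtration demonstration (15 damaging variants, 4 true survivors)."""

from __future__ import annotations

from typing import Optional, Tuple

import pytest

from fhmap.fixtures import FunnelDemo, build_funnel_demo
from fhmap.model import GenotypeCall, Role, VariantSite


def gt(spec: Optional[str], ad: Optional[Tuple[int, ...]] = None, dp: Optional[int] = None
       ) -> GenotypeCall:
    """Build a call from a '0/1'-style string (None or './.' = missing)."""
    if spec is None or spec == "./.":
        n = len(ad) if ad else 2
        return GenotypeCall.missing(n, dp or 0)
    a, b = (int(x) for x in spec.replace("|", "/").split("/"))
    if ad is None:
        n = max(a, b) + 1 if max(a, b) >= 1 else 2
        ad = tuple(15 if i in (a, b) else 0 for i in range(n))
    return GenotypeCall((a, b), ad, dp if dp is not None else sum(ad))


def make_site(
    pos: int = 100,
    lvg: Optional[str] = "1/1",
    bio: Optional[str] = "0/0",
    pool: Optional[str] = "1/1",
    ref: str = "A",
    alts: Tuple[str, ...] = ("G",),
    contig: str = "c1",
) -> VariantSite:
    calls = {}
    n = 1 + len(alts)
    for role, spec in (
        (Role.PARENT_LVG, lvg),
        (Role.PARENT_BIO, bio),
        (Role.F2_POOL, pool),
    ):
        if spec is None or spec == "./.":
            calls[role] = GenotypeCall.missing(n, 0)
        else:
            a, b = (int(x) for x in spec.split("/"))
            ad = tuple(15 if i in (a, b) else 0 for i in range(n))
            calls[role] = GenotypeCall((a, b), ad, sum(ad))
    return VariantSite(contig=contig, position=pos, ref_allele=ref, alt_alleles=alts, calls=calls)


@pytest.fixture(scope="session")
def funnel_fixture() -> FunnelDemo:
    return build_funnel_demo()
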