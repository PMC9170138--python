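"""Reading and writing the standard formats the pipeline touches.

VCF 4.2 is read and written through :mod:`pysam`; linked regions are
externalised as 5-column BED (0-based half-open, per the BED standard,
while everything internal stays 1-based closed like VCF).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import pysam

from .model import (
    ConfigurationError,
    FhmapError,
    GenotypeCall,
    Role,
    SampleRoleMap,
    ValidationError,
    VariantSite,
)


class VcfParseError(FhmapError):
    pass


def _call_from_record_sample(sample, n_alleles: int) -> GenotypeCall:
    gt = sample.get("GT")
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        indices = None
    elif len(gt) == 1:
        indices = (int(gt[0]), int(gt[0]))
    else:
        indices = (int(gt[0]), int(gt[1]))
    ad = sample.get("AD")
    if ad is None or all(a is None for a in ad):
        depths: Tuple[int, ...] = (0,) * n_alleles
    else:
        depths = tuple(int(a) if a is not None else 0 for a in ad)
    dp = sample.get("DP")
    total = int(dp) if dp is not None else sum(depths)
    return GenotypeCall(indices, depths, total)


def read_vcf(path: str, roles: SampleRoleMap) -> List[VariantSite]:
    """Read a 3-sample VCF into the internal model.

    ``roles`` maps VCF sample names onto the cross roles; an unknown sample
    name raises :class:`ConfigurationError`. Records are returned in file
    order (sorted by position within each contig in any valid VCF).
    """
    vf = pysam.VariantFile(path)
    header_samples = list(vf.header.samples)
    for name in roles.by_sample:
        if name not in header_samples:
            raise ConfigurationError(
                f"sample {name!r} not found in VCF header (has {header_samples})"
            )
    sites: List[VariantSite] = []
    record_no = 0
    try:
        for rec in vf:
            record_no += 1
            alts = tuple(rec.alts or ())
            if not alts:
                continue  # monomorphic record carries no variant
            n_alleles = 1 + len(alts)
            calls: Dict[Role, GenotypeCall] = {}
            for name, role in roles.by_sample.items():
                calls[role] = _call_from_record_sample(rec.samples[name], n_alleles)
            sites.append(
                VariantSite(
                    contig=rec.contig,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    calls=calls,
                )
            )
    except (ValueError, ValidationError) as exc:
        raise VcfParseError(f"malformed VCF record #{record_no} in {path}: {exc}") from exc
    finally:
        vf.close()
    return sites


def write_vcf(
    sites: Sequence[VariantSite],
    roles: SampleRoleMap,
    path: str,
    contig_lengths: Dict[str, int] | None = None,
) -> None:
    """Write sites as a VCF 4.2 with GT/AD/DP for the three samples."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    contigs: Dict[str, int] = {}
    for s in sites:
        end = s.position + len(s.ref_allele) - 1
        contigs[s.contig] = max(contigs.get(s.contig, 0), end)
    if contig_lengths:
        contigs.update(contig_lengths)
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for name in roles.sample_names:
        header.add_sample(name)
    out = pysam.VariantFile(path, "w", header=header)
    try:
        for s in sites:
            rec = out.new_record(
                contig=s.contig,
                start=s.position - 1,
                alleles=(s.ref_allele,) + s.alt_alleles,
            )
            for name, role in roles.by_sample.items():
                call = s.call(role)
                if call.is_missing:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["GT"] = call.allele_indices
                depths = call.allele_depths or (0,) * s.n_alleles
                rec.samples[name]["AD"] = depths
                rec.samples[name]["DP"] = call.total_depth
            out.write(rec)
    finally:
        out.close()


def filter_by_pool_coverage(
    sites: Sequence[VariantSite], min_depth: int = 5
) -> List[VariantSite]:
    """Keep sites whose pool total depth is >= ``min_depth`` (inclusive).

    This is the study-wide "at least 5x total coverage" rule applied to the
    scanned F2 pool sample. Order is preserved; the filter is idempotent and
    monotone in ``min_depth``.
    """
    if min_depth < 0:
        raise ConfigurationError("min_depth must be >= 0")
    return [s for s in sites if s.call(Role.F2_POOL).total_depth >= min_depth]


def write_regions_bed(regions: Sequence, path: str) -> None:
    """Write linked regions as BED5 (0-based half-open).

    ``name`` is the parental label and ``score`` is round(1000 * mean window
    score). Overlapping same-label regions are rejected.
    """
    by_label: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for r in regions:
        by_label.setdefault((r.contig, r.parent_label.value), []).append((r.start, r.end))
    for (contig, label), ivals in by_label.items():
        ivals.sort()
        for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"overlapping {label} regions on {contig}: [{s1},{e1}] and start {s2}"
                )
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.contig, r.start)):
            score = round(1000 * r.mean_score)
            fh.write(
                f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.parent_label.value}\t{score}\n"
            )


def read_regions_bed(path: str):
    """Read BED5 regions written by :func:`write_regions_bed`."""
    from .mapping import LinkedRegion, ParentLabel

    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start0, end, label = fields[0], int(fields[1]), int(fields[2]), fields[3]
            score = int(fields[4]) if len(fields) > 4 else 0
            regions.append(
                LinkedRegion(
                    contig=contig,
                    start=start0 + 1,
                    end=end,
                    parent_label=ParentLabel(label),
                    n_windows=0,
                    mean_score=score / 1000.0,
                )
            )
    return regions


def vcf_body_lines(path: str) -> List[str]:
    """Non-header lines of a VCF, for round-trip comparisons."""
    with open(path) as fh:
        return [ln for ln in fh if not ln.startswith("#")]
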