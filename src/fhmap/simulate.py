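"""Synthetic intercross generator: the ground truth for the whole pipeline.

Emulates the mapping study design end to end: two divergent inbred parents
with imbalanced unique-marker densities, a fully penetrant recessive causal
mutation (a 1-bp coding deletion) on the mutant parent's haplotype, an
F1 x F1 intercross with Haldane (no-interference) recombination,
phenotype-based selection of a pool of homozygous-mutant F2 offspring, and
depth-limited genotype calls for the pool and both parents.

The planted causal allele is a single-base deletion in codon 193 (Pro) of a
1,788-nt single-exon toy coding gene, so the expected annotation of a
successful run is a frameshift written ``p.P193fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import GeneModel
from .model import (
    ConfigurationError,
    FhmapError,
    GenotypeCall,
    Role,
    SampleRoleMap,
    VariantSite,
)
from .phenotyping import OnsetSeries

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# site kinds
LVG_UNIQUE, BIO_UNIQUE, SHARED, CONFLICT, CAUSAL = range(5)
_KIND_NAMES = {
    LVG_UNIQUE: "lvg_unique",
    BIO_UNIQUE: "bio_unique",
    SHARED: "shared_hom",
    CONFLICT: "conflict_hom",
    CAUSAL: "causal",
}

LVG_ORIGIN, BIO_ORIGIN = 0, 1

#: length of the toy coding gene carrying the causal deletion
_GENE_CDS_LEN = 1788
#: CDS offset of the deleted base (codon 193, second position)
_CAUSAL_CDS_POS = 578


class SimulationError(FhmapError):
    pass


@dataclass(frozen=True)
class CrossConfig:
    """Study-design parameters for the synthetic intercross.

    Defaults mirror the mapping study where stated (pool of 45 homozygous
    mutants, ~30x pool depth, ~1:3 mutant:mapping unique-marker imbalance,
    ~4,000 markers on a 10-Mb scaffold) and field-standard values elsewhere
    (0.1 expected crossovers per 10-Mb contig per meiosis, i.e. ~1 cM/Mb).
    ``n_f2_total`` of 300 keeps a 45-animal mutant pool available in
    essentially every replicate under 25% recessive segregation.
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 10_000_000
    lvg_marker_density: float = 100.0  # unique LVG markers per Mb
    bio_marker_density: float = 300.0  # unique BIO markers per Mb
    shared_site_density: float = 20.0  # both parents hom for the same alt
    conflict_site_density: float = 5.0  # parents hom for different alts
    expected_crossovers: float = 0.1  # per contig per meiosis (Haldane)
    n_f2_total: int = 300
    pool_size: int = 45
    mean_pool_depth: float = 30.0
    mean_parent_depth: float = 30.0
    genotype_error_rate: float = 0.001
    hom_call_max_minor_fraction: float = 0.1
    causal_contig: str = "contig_1"
    causal_position: int = 5_000_000

    def __post_init__(self) -> None:
        if self.pool_size > self.n_f2_total:
            raise ConfigurationError("pool_size must be <= n_f2_total")
        if self.lvg_marker_density <= 0 or self.bio_marker_density <= 0:
            raise ConfigurationError("marker densities must be > 0")
        if self.causal_contig not in self.contig_names:
            raise ConfigurationError(
                f"causal contig {self.causal_contig!r} not among {self.contig_names}"
            )
        gene_start = self.causal_position - _CAUSAL_CDS_POS + 1
        if gene_start < 1 or self.causal_position + _GENE_CDS_LEN > self.contig_length:
            raise ConfigurationError("causal position leaves no room for the toy gene")

    @property
    def contig_names(self) -> Tuple[str, ...]:
        return tuple(f"contig_{i + 1}" for i in range(self.n_contigs))


@dataclass
class SiteTable:
    """Per-contig planted site truth, columnar for vectorised pooling."""

    positions: np.ndarray  # int64, sorted
    kinds: np.ndarray  # int8
    refs: List[str]
    alts: List[Tuple[str, ...]]
    lvg_allele: np.ndarray  # allele index on the LVG haplotype
    bio_allele: np.ndarray


@dataclass
class SimulatedParents:
    config: CrossConfig
    sequences: Dict[str, str]
    tables: Dict[str, SiteTable]
    gene: GeneModel


@dataclass
class Gamete:
    start_origins: Dict[str, int]  # origin (LVG/BIO) at the left end, per contig
    breakpoints: Dict[str, np.ndarray]

    def origin_at(self, contig: str, positions: np.ndarray) -> np.ndarray:
        bp = self.breakpoints[contig]
        return (self.start_origins[contig] + np.searchsorted(bp, positions)) % 2


@dataclass
class SimulatedTruth:
    gametes: List[Tuple[Gamete, Gamete]]
    causal_n_lvg: np.ndarray  # LVG allele count at the causal locus per F2
    phenotype_mutant: np.ndarray  # bool; fully penetrant recessive


def _build_causal_cds(rng: np.random.Generator) -> str:
    n_codons = _GENE_CDS_LEN // 3
    codons = ["ATG"]
    codons += list(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    codons.append("TAA")
    codons[192] = "CCA"  # codon 193 = Pro; deleting its second base frameshifts
    return "".join(codons)


def simulate_parents(
    config: CrossConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedParents:
    """Reference sequences, the toy causal gene and the planted site truth."""
    rng = rng or np.random.default_rng(config.seed)
    L = config.contig_length
    sequences: Dict[str, str] = {}
    for name in config.contig_names:
        sequences[name] = _BASES[rng.integers(0, 4, size=L)].tobytes().decode("ascii")

    gene_start = config.causal_position - _CAUSAL_CDS_POS + 1
    cds = _build_causal_cds(rng)
    chrom = sequences[config.causal_contig]
    sequences[config.causal_contig] = (
        chrom[: gene_start - 1] + cds + chrom[gene_start - 1 + _GENE_CDS_LEN :]
    )
    gene = GeneModel(
        gene_id="gene_causal",
        transcript_id="tx_causal",
        contig=config.causal_contig,
        strand="+",
        exons=((gene_start, gene_start + _GENE_CDS_LEN - 1),),
        cds=((gene_start, gene_start + _GENE_CDS_LEN - 1),),
    )

    densities = {
        LVG_UNIQUE: config.lvg_marker_density,
        BIO_UNIQUE: config.bio_marker_density,
        SHARED: config.shared_site_density,
        CONFLICT: config.conflict_site_density,
    }
    tables: Dict[str, SiteTable] = {}
    anchor = config.causal_position - 1
    for name in config.contig_names:
        seq = sequences[name]
        pos_parts, kind_parts = [], []
        for kind, dens in densities.items():
            n = rng.poisson(dens * L / 1e6)
            if n:
                pos_parts.append(rng.integers(1, L + 1, size=n))
                kind_parts.append(np.full(n, kind, dtype=np.int8))
        positions = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        kinds = np.concatenate(kind_parts) if kind_parts else np.empty(0, dtype=np.int8)
        # drop duplicates and anything colliding with the causal deletion span
        if positions.size:
            order = np.argsort(positions, kind="stable")
            positions, kinds = positions[order], kinds[order]
            keep = np.concatenate([[True], np.diff(positions) > 0])
            if name == config.causal_contig:
                keep &= (positions < anchor - 1) | (positions > config.causal_position + 1)
            positions, kinds = positions[keep], kinds[keep]

        refs: List[str] = []
        alts: List[Tuple[str, ...]] = []
        for p, kind in zip(positions, kinds):
            ref = seq[p - 1]
            others = [b for b in "ACGT" if b != ref]
            if kind == CONFLICT:
                a1, a2 = rng.choice(others, size=2, replace=False)
                alts.append((a1, a2))
            else:
                alts.append((others[rng.integers(0, 3)],))
            refs.append(ref)
        lvg_allele = np.where(kinds == BIO_UNIQUE, 0, 1).astype(np.int8)
        bio_allele = np.select(
            [kinds == BIO_UNIQUE, kinds == SHARED, kinds == CONFLICT],
            [1, 1, 2],
            default=0,
        ).astype(np.int8)

        if name == config.causal_contig:
            # insert the causal 1-bp deletion (anchored VCF-style)
            ref_del = seq[anchor - 1 : anchor + 1]
            idx = int(np.searchsorted(positions, anchor))
            positions = np.insert(positions, idx, anchor)
            kinds = np.insert(kinds, idx, CAUSAL)
            refs.insert(idx, ref_del)
            alts.insert(idx, (ref_del[0],))
            lvg_allele = np.insert(lvg_allele, idx, 1)
            bio_allele = np.insert(bio_allele, idx, 0)

        tables[name] = SiteTable(
            positions=positions.astype(np.int64),
            kinds=kinds,
            refs=refs,
            alts=alts,
            lvg_allele=lvg_allele,
            bio_allele=bio_allele,
        )
    return SimulatedParents(config=config, sequences=sequences, tables=tables, gene=gene)


def _draw_gamete(config: CrossConfig, rng: np.random.Generator) -> Gamete:
    # contigs are independent scaffolds: origin and crossovers drawn per contig
    breakpoints = {}
    starts = {}
    for name in config.contig_names:
        n_xo = rng.poisson(config.expected_crossovers)
        breakpoints[name] = np.sort(rng.uniform(0, config.contig_length, size=n_xo))
        starts[name] = int(rng.integers(0, 2))
    return Gamete(start_origins=starts, breakpoints=breakpoints)


def simulate_f2(
    config: CrossConfig,
    parents: Optional[SimulatedParents] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedTruth:
    """F1 x F1 intercross: every F2 is the union of two recombinant gametes.

    Crossover counts per gamete per contig are Poisson with uniform
    breakpoint placement (Haldane map, no interference). The phenotype is
    fully penetrant recessive: mutant iff both gametes carry the mutant
    parent's origin at the causal locus.
    """
    rng = rng or np.random.default_rng(config.seed)
    gametes: List[Tuple[Gamete, Gamete]] = []
    n_lvg = np.empty(config.n_f2_total, dtype=np.int8)
    cpos = np.array([config.causal_position], dtype=float)
    for i in range(config.n_f2_total):
        g1 = _draw_gamete(config, rng)
        g2 = _draw_gamete(config, rng)
        gametes.append((g1, g2))
        n_lvg[i] = int(g1.origin_at(config.causal_contig, cpos)[0] == LVG_ORIGIN) + int(
            g2.origin_at(config.causal_contig, cpos)[0] == LVG_ORIGIN
        )
    return SimulatedTruth(
        gametes=gametes, causal_n_lvg=n_lvg, phenotype_mutant=(n_lvg == 2)
    )


def _call_from_counts(
    counts: np.ndarray, hom_threshold: float
) -> Optional[Tuple[int, int]]:
    depth = int(counts.sum())
    if depth == 0:
        return None
    order = np.argsort(counts)[::-1]
    top, second = int(order[0]), int(order[1])
    if counts[second] / depth >= hom_threshold:
        a, b = sorted((top, second))
        return (a, b)
    return (top, top)


def _perturb_call(
    gt: Tuple[int, int], n_alleles: int, rng: np.random.Generator
) -> Tuple[int, int]:
    # crude caller error: hom <-> het against another allele of the site
    if gt[0] == gt[1]:
        other = (gt[0] + 1 + int(rng.integers(0, n_alleles - 1))) % n_alleles
        a, b = sorted((gt[0], other))
        return (a, b)
    return (gt[0], gt[0]) if rng.integers(0, 2) == 0 else (gt[1], gt[1])


def select_and_pool(
    config: CrossConfig,
    parents: SimulatedParents,
    truth: SimulatedTruth,
    rng: Optional[np.random.Generator] = None,
) -> List[VariantSite]:
    """Select the mutant pool and emit depth-limited three-sample calls.

    Pool allele depths are multinomial draws on the pool's true allele
    frequency at Poisson total depth; the pool genotype is called
    heterozygous when the minor-allele read fraction reaches the
    ``hom_call_max_minor_fraction`` threshold, homozygous otherwise, and
    missing at zero depth.
    """
    rng = rng or np.random.default_rng(config.seed)
    mutants = np.flatnonzero(truth.phenotype_mutant)
    if mutants.size < config.pool_size:
        raise SimulationError(
            f"only {mutants.size} mutant-phenotype F2 available for a pool of "
            f"{config.pool_size}; increase n_f2_total"
        )
    selected = rng.choice(mutants, size=config.pool_size, replace=False)
    pool_gametes = [g for i in selected for g in truth.gametes[i]]

    sites: List[VariantSite] = []
    for name in config.contig_names:
        table = parents.tables[name]
        n = table.positions.size
        if n == 0:
            continue
        fpos = table.positions.astype(float)
        lvg_frac = np.zeros(n)
        for g in pool_gametes:
            lvg_frac += g.origin_at(name, fpos) == LVG_ORIGIN
        lvg_frac /= len(pool_gametes)

        # allele frequencies in the pool (up to 3 alleles: ref, alt1, alt2)
        freqs = np.zeros((n, 3))
        for a in range(3):
            freqs[:, a] = lvg_frac * (table.lvg_allele == a) + (1 - lvg_frac) * (
                table.bio_allele == a
            )
        depth = rng.poisson(config.mean_pool_depth, size=n)
        c1 = rng.binomial(depth, freqs[:, 1])
        denom = 1.0 - freqs[:, 1]
        p2 = np.where(denom > 1e-12, np.clip(freqs[:, 2] / np.maximum(denom, 1e-12), 0, 1), 0.0)
        c2 = rng.binomial(depth - c1, p2)
        c0 = depth - c1 - c2

        p_depth = rng.poisson(config.mean_parent_depth, size=(2, n))
        err = rng.random(size=(3, n)) < config.genotype_error_rate

        for j in range(n):
            n_alleles = 1 + len(table.alts[j])
            counts = np.array([c0[j], c1[j], c2[j]][:n_alleles])
            pool_gt = _call_from_counts(counts, config.hom_call_max_minor_fraction)
            if pool_gt is not None and err[2, j]:
                pool_gt = _perturb_call(pool_gt, n_alleles, rng)
            pool_call = (
                GenotypeCall.missing(n_alleles)
                if pool_gt is None
                else GenotypeCall(pool_gt, tuple(int(c) for c in counts), int(counts.sum()))
            )
            calls = {Role.F2_POOL: pool_call}
            for k, (role, allele) in enumerate(
                [(Role.PARENT_LVG, int(table.lvg_allele[j])), (Role.PARENT_BIO, int(table.bio_allele[j]))]
            ):
                d = int(p_depth[k, j])
                if d == 0:
                    calls[role] = GenotypeCall.missing(n_alleles)
                    continue
                gt = (allele, allele)
                if err[k, j]:
                    gt = _perturb_call(gt, n_alleles, rng)
                depths = [0] * n_alleles
                depths[allele] = d
                calls[role] = GenotypeCall(gt, tuple(depths), d)
            sites.append(
                VariantSite(
                    contig=name,
                    position=int(table.positions[j]),
                    ref_allele=table.refs[j],
                    alt_alleles=table.alts[j],
                    calls=calls,
                )
            )
    return sites


@dataclass
class SimulationOutput:
    parents: SimulatedParents
    truth: SimulatedTruth
    sites: List[VariantSite]


def run_simulation(config: CrossConfig) -> SimulationOutput:
    """Parents -> F2 -> pooled calls, all driven by the single config seed."""
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    truth = simulate_f2(config, parents, rng)
    sites = select_and_pool(config, parents, truth, rng)
    return SimulationOutput(parents=parents, truth=truth, sites=sites)


DEFAULT_ROLES = SampleRoleMap(
    {"duper_LVG": Role.PARENT_LVG, "wt_Bio14": Role.PARENT_BIO, "f2_pool": Role.F2_POOL}
)


def emit_reference(parents: SimulatedParents, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in parents.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def emit_gene_models(parents: SimulatedParents, path: str) -> None:
    g = parents.gene
    start, end = g.span
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{g.contig}\tfhmap\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        fh.write(
            f"{g.contig}\tfhmap\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={g.transcript_id};Parent={g.gene_id}\n"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            fh.write(
                f"{g.contig}\tfhmap\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}\n"
            )
        for i, (s, e) in enumerate(g.cds, 1):
            fh.write(
                f"{g.contig}\tfhmap\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={g.transcript_id}.cds{i};Parent={g.transcript_id}\n"
            )


def emit_truth(config: CrossConfig, truth: SimulatedTruth, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "individual": np.arange(config.n_f2_total),
            "causal_n_lvg_alleles": truth.causal_n_lvg,
            "phenotype": np.where(truth.phenotype_mutant, "mutant", "wild_type"),
        }
    ).to_csv(path, sep="\t", index=False)


def simulate_onsets(
    period_h: float,
    shift_h: float = 0.0,
    pulse_day: Optional[int] = None,
    n_days: int = 21,
    noise_sd_h: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    onset0_h: float = 1.0,
    pulse_offset_h: float = 3.29,
) -> OnsetSeries:
    """Daily activity onsets drifting at (period - 24) h/day.

    After ``pulse_day`` the onset line is displaced by ``shift_h`` (positive
    = advance = earlier onsets). The pulse is delivered ``pulse_offset_h``
    real hours after the projected onset on ``pulse_day``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    drift = period_h - 24.0
    onsets = onset0_h + drift * days
    if pulse_day is not None:
        if pulse_day < 2 or pulse_day > n_days - 3:
            raise ConfigurationError("need >= 2 onsets before and after the pulse")
        onsets = onsets - shift_h * (days > pulse_day)
    if noise_sd_h > 0:
        onsets = onsets + rng.normal(0.0, noise_sd_h, size=n_days)
    pulse_time = None
    if pulse_day is not None:
        pulse_time = onset0_h + drift * pulse_day + pulse_offset_h
    return OnsetSeries(
        days=tuple(int(d) for d in days),
        onsets=tuple(float(o) for o in onsets),
        pulse_day=pulse_day,
        pulse_time=pulse_time,
    )
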