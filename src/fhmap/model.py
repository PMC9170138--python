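"""Core domain types shared across the pipeline.

The pipeline works on three-sample variant records: the mutant-line parent
(Lakeview, ``parent_lvg``), the mapping-ecotype parent (Bio14.6,
``parent_bio``) and a pool of phenotypically selected F2 offspring
(``f2_pool``). All internal coordinates are 1-based closed, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Tuple


class Role(str, Enum):
    """Sample roles in the mapping cross."""

    PARENT_LVG = "parent_lvg"
    PARENT_BIO = "parent_bio"
    F2_POOL = "f2_pool"


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class FhmapError(Exception):
    """Base class for package errors."""


class ConfigurationError(FhmapError):
    pass


class ValidationError(FhmapError):
    pass


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype call with per-allele read depths.

    ``allele_indices`` is ``None`` for a missing call (``./.``).
    ``allele_depths`` holds one count per site allele (REF first); when the
    source record carried no AD field these are missing-equivalent zeros and
    ``total_depth`` is taken from DP alone.
    """

    allele_indices: Optional[Tuple[int, int]]
    allele_depths: Tuple[int, ...] = ()
    total_depth: int = 0

    def __post_init__(self) -> None:
        if self.total_depth < 0:
            raise ValidationError("total_depth must be >= 0")
        if any(d < 0 for d in self.allele_depths):
            raise ValidationError("allele depths must be >= 0")

    @classmethod
    def missing(cls, n_alleles: int = 2, total_depth: int = 0) -> "GenotypeCall":
        return cls(None, (0,) * n_alleles, total_depth)

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def is_hom(self) -> bool:
        return self.allele_indices is not None and self.allele_indices[0] == self.allele_indices[1]

    @property
    def is_het(self) -> bool:
        return self.allele_indices is not None and self.allele_indices[0] != self.allele_indices[1]

    @property
    def hom_allele(self) -> Optional[int]:
        """Allele index if homozygous, else None."""
        if self.is_hom:
            return self.allele_indices[0]  # type: ignore[index]
        return None

    def carries(self, allele_index: int) -> bool:
        """True if the call includes ``allele_index`` (missing carries nothing)."""
        return self.allele_indices is not None and allele_index in self.allele_indices


@dataclass(frozen=True)
class VariantSite:
    """One multi-sample variant record.

    ``position`` is 1-based. A site is a SNP iff the reference allele and
    every alternate allele are single bases; anything else is an INDEL
    (multi-allelic records are kept as a single site, not split).
    """

    contig: str
    position: int
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    calls: Mapping[Role, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele:
            raise ValidationError("ref allele must be non-empty")
        if not self.alt_alleles or any(not a for a in self.alt_alleles):
            raise ValidationError("alt alleles must be non-empty")
        if any(a == self.ref_allele for a in self.alt_alleles):
            raise ValidationError("every alt allele must differ from ref")
        n = self.n_alleles
        for role, call in self.calls.items():
            if call.allele_indices is not None and any(
                i < 0 or i >= n for i in call.allele_indices
            ):
                raise ValidationError(
                    f"{role}: allele index out of range at {self.contig}:{self.position}"
                )

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def alleles(self) -> Tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles):
            return VariantClass.SNP
        return VariantClass.INDEL

    def call(self, role: Role) -> GenotypeCall:
        c = self.calls.get(role)
        if c is None:
            return GenotypeCall.missing(self.n_alleles)
        return c


@dataclass(frozen=True)
class SampleRoleMap:
    """Maps VCF sample-column names to their role in the cross."""

    by_sample: Mapping[str, Role]

    def __post_init__(self) -> None:
        roles = list(self.by_sample.values())
        for role in Role:
            if roles.count(role) != 1:
                raise ConfigurationError(
                    f"role {role.value} must be assigned to exactly one sample"
                )

    def sample_for(self, role: Role) -> str:
        for name, r in self.by_sample.items():
            if r == role:
                return name
        raise ConfigurationError(f"no sample for role {role}")  # pragma: no cover

    @property
    def sample_names(self) -> Tuple[str, ...]:
        return tuple(self.by_sample)
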