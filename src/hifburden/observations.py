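"""Core domain types for annotated variant observations.

An observation is one annotated variant call in one individual: genomic
identity (chrom, pos, ref, alt on a single declared build), functional
consequence, population minor allele frequency (gnomAD convention, with
"absent from gnomAD" encoded as 0), zygosity, optional read support
(for variant-allele-fraction work), the DNA source the call was made
from, and the inheritance determined by trio segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional


class Consequence(str, Enum):
    """Functional consequence class of a coding/splice variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    SPLICE_SITE_SNV = "splice_site_snv"
    CODING_INDEL = "coding_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: consequence classes counted as "functional" during prioritization
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.STOP_LOSS,
        Consequence.SPLICE_SITE_SNV,
        Consequence.CODING_INDEL,
    }
)

#: SNV-only functional classes used for burden qualification
BURDEN_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.STOP_LOSS,
        Consequence.SPLICE_SITE_SNV,
    }
)


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"


class SampleSource(str, Enum):
    BLOOD = "blood"
    SALIVA = "saliva"
    TUMOR = "tumor"


class Inheritance(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    #: both parents heterozygous -- inherited, ambiguous parental origin
    BIPARENTAL = "maternal+paternal"
    DE_NOVO = "de_novo"
    UNKNOWN = "unknown"


class MosaicStatus(str, Enum):
    CONSISTENT_HET = "consistent_het"
    MOSAIC_CANDIDATE = "mosaic_candidate"
    INSUFFICIENT_DATA = "insufficient_data"


class VariantOrigin(str, Enum):
    GERMLINE = "germline"
    POST_ZYGOTIC_MOSAIC = "post_zygotic_mosaic"
    SOMATIC_TUMOR_ONLY = "somatic_tumor_only"


@dataclass(frozen=True)
class VariantObservation:
    """One annotated variant call in one individual.

    ``maf`` follows the gnomAD convention: a variant absent from the
    population reference is recorded as 0.0.  Variant identity for
    "distinct variant" counting is genomic: ``(chrom, pos, ref, alt)``.
    """

    individual_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    maf: float = 0.0
    zygosity: Zygosity = Zygosity.HET
    transcript: Optional[str] = None
    protein_change: Optional[str] = None
    alt_reads: Optional[int] = None
    total_reads: Optional[int] = None
    sample_source: SampleSource = SampleSource.BLOOD
    inheritance: Inheritance = Inheritance.UNKNOWN
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf < 1.0):
            raise ValueError(f"maf must be in [0, 1), got {self.maf}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.alt_reads is not None and self.total_reads is not None:
            if self.alt_reads < 0 or self.total_reads < 0:
                raise ValueError("read counts must be non-negative")
            if self.alt_reads > self.total_reads:
                raise ValueError(
                    f"alt_reads ({self.alt_reads}) exceeds total_reads "
                    f"({self.total_reads})"
                )

    @property
    def variant_id(self) -> tuple[str, int, str, str]:
        """Genomic identity used for distinct-variant counting."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction, if read support is recorded."""
        if self.alt_reads is None or self.total_reads in (None, 0):
            return None
        return self.alt_reads / self.total_reads

    def with_(self, **changes) -> "VariantObservation":
        return replace(self, **changes)


@dataclass(frozen=True)
class QualifyingCriteria:
    """Filter definition for qualifying variants.

    ``max_maf`` is a strict upper bound (a variant at exactly the
    threshold is excluded).  ``snv_only`` additionally requires single
    nucleotide ref and alt alleles.
    """

    max_maf: float = 0.01
    allowed_consequences: frozenset[Consequence] = FUNCTIONAL_CONSEQUENCES
    snv_only: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_maf <= 1.0):
            raise ValueError(f"max_maf must be in (0, 1], got {self.max_maf}")
        if not self.allowed_consequences:
            raise ValueError("allowed_consequences must be non-empty")

    def admits(self, obs: VariantObservation) -> bool:
        if obs.consequence not in self.allowed_consequences:
            return False
        if obs.maf >= self.max_maf:
            return False
        if self.snv_only and not obs.is_snv:
            return False
        return True


#: discovery preset: rare (MAF < 1%) functional variants, indels included
PRIORITIZATION = QualifyingCriteria(
    max_maf=0.01,
    allowed_consequences=FUNCTIONAL_CONSEQUENCES,
    snv_only=False,
    name="prioritization",
)

#: burden-testing preset: rare functional single-nucleotide variants only
BURDEN = QualifyingCriteria(
    max_maf=0.01,
    allowed_consequences=BURDEN_CONSEQUENCES,
    snv_only=True,
    name="burden",
)

PRESETS = {"prioritization": PRIORITIZATION, "burden": BURDEN}


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (a panel or a regulon)."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)
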