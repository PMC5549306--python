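"""Core domain records shared across the pipeline.

All genomic coordinates are 1-based closed intervals (the PennCNV/PLINK
convention); BED input is converted at the I/O boundary. Chromosome names
are normalized to ``chrN`` on construction, and comparisons are string-exact
after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class CnvState(str, Enum):
    """CNV state of a segment or locus relative to the two-copy reference."""

    DELETION = "deletion"
    DUPLICATION = "duplication"


class CallSource(str, Enum):
    """Provenance of a CNV call: one of the two callers, or their consensus."""

    CALLER_A = "callerA"
    CALLER_B = "callerB"
    CONSENSUS = "consensus"


#: Integer codes used in state matrices and state vectors.
STATE_NORMAL = 0
STATE_DELETION = 1
STATE_DUPLICATION = 2

_STATE_TO_CODE = {CnvState.DELETION: STATE_DELETION, CnvState.DUPLICATION: STATE_DUPLICATION}

_VALID_CHROM_TOKENS = {str(i) for i in range(1, 23)} | {"X", "Y", "XY", "MT", "M"}


def state_code(state: "CnvState | str | int") -> int:
    """Map a state (enum, name, or code) to its integer code."""
    if isinstance(state, int):
        if state not in (STATE_NORMAL, STATE_DELETION, STATE_DUPLICATION):
            raise ValueError(f"unknown state code {state}")
        return state
    if isinstance(state, str) and state == "normal":
        return STATE_NORMAL
    return _STATE_TO_CODE[CnvState(state)]


def normalize_chrom(token: str) -> str:
    """Normalize a chromosome token ('3', 'chr3', 'chrX', ...) to 'chrN'."""
    tok = str(token).strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok == "M":
        tok = "MT"
    if tok not in _VALID_CHROM_TOKENS:
        raise ValueError(f"unknown chromosome token: {token!r}")
    return f"chr{tok}"


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr22 < chrX < chrY < chrXY < chrMT."""
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (int(body), "")
    return (100 + "X Y XY MT".split().index(body), body)


@dataclass(frozen=True)
class CnvCall:
    """One caller-reported (or consensus) CNV segment for one sample."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    state: CnvState
    num_snps: int
    copy_number: Optional[int] = None
    source: CallSource = CallSource.CALLER_A

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"CnvCall {self.sample_id} {self.chrom}: start_bp {self.start_bp} "
                f"> end_bp {self.end_bp}"
            )
        if self.num_snps < 1:
            raise ValueError("CnvCall.num_snps must be >= 1")
        if self.copy_number is not None:
            if self.state is CnvState.DELETION and self.copy_number >= 2:
                raise ValueError("deletion requires copy_number < 2")
            if self.state is CnvState.DUPLICATION and self.copy_number <= 2:
                raise ValueError("duplication requires copy_number > 2")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class SnpLocus:
    """A SNP/probe on the array; CNV states are evaluated at these positions."""

    snp_id: str
    chrom: str
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError("position_bp must be >= 1 (1-based)")


@dataclass
class Family:
    """A sibship: the permutation unit of the family-based test.

    Parental IDs from pedigree files are ignored; every genotyped individual
    listed under one family ID is treated as a member of the sibship.
    """

    family_id: str
    member_ids: list[str]
    sex: dict[str, int] = field(default_factory=dict)  # 1=male, 2=female, 0=unknown

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"family {self.family_id} has no members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError(f"family {self.family_id} has duplicate members")


@dataclass
class PhenotypeRecord:
    """Per-sample trait value and covariates; ``None`` marks a missing field."""

    sample_id: str
    trait_value: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[int] = None  # 1=male, 2=female, 0/None=unknown
    bmi: Optional[float] = None
    ethnicity: Optional[str] = None  # "Chinese" | "Japanese"
    site: Optional[str] = None
    hypertension: Optional[int] = None  # 0/1
    diabetes: Optional[bool] = None  # diagnosed flag, if recorded

    def __post_init__(self) -> None:
        if self.trait_value is not None:
            import math

            if not math.isfinite(self.trait_value):
                raise ValueError(f"non-finite trait value for {self.sample_id}")


@dataclass(frozen=True)
class BlacklistRegion:
    """A region (immunoglobulin, centromeric, telomeric, ...) whose CNV calls
    are treated as artifacts and removed."""

    chrom: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("blacklist region start_bp > end_bp")


@dataclass
class AdjustedPhenotype:
    """Covariate-adjusted trait residual used by all association tests."""

    sample_id: str
    residual: float
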