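"""Core domain types for bioactive peptide profiling.

The unit of analysis is a milk protein sequence (typically one of the
bovine casein fractions) screened against a database of peptides with
experimentally confirmed bioactivity, e.g. angiotensin-converting-enzyme
(ACE) inhibitors or dipeptidyl-peptidase-IV (DPP-IV) inhibitors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "CaseinFraction",
    "Activity",
    "ProteinRecord",
    "BioactivePeptideEntry",
    "SampleIdentificationSet",
    "AssayMeasurement",
    "ChromPeak",
    "SpectrumPeak",
    "SequenceError",
]

#: the 20 canonical amino-acid one-letter codes; profiling is exact
#: substring matching over this alphabet only.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised when a sequence contains non-canonical characters."""


class CaseinFraction(str, enum.Enum):
    """Bovine casein fraction; ``other`` covers non-casein proteins."""

    alphaS1 = "alphaS1"
    alphaS2 = "alphaS2"
    beta = "beta"
    kappa = "kappa"
    other = "other"


class Activity(str, enum.Enum):
    """Bioactivity class of a database peptide."""

    ACE_inhibitor = "ACE_inhibitor"
    DPP4_inhibitor = "DPP4_inhibitor"


def validate_sequence(text: str) -> str:
    """Normalise an amino-acid sequence to canonical uppercase form.

    Whitespace is stripped and lowercase letters are uppercased.  Any
    character outside the 20-letter canonical alphabet (including the
    ambiguity codes B, J, O, U, X, Z) raises :class:`SequenceError`
    naming the 1-based position of the first offending character.
    """
    cleaned = "".join(text.split()).upper()
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {pos} in sequence {cleaned!r}"
            )
    return cleaned


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence against which peptides are matched.

    ``n_residues`` (N) is the denominator of every per-protein frequency;
    it always equals ``len(sequence)``.
    """

    id: str
    name: str
    fraction: CaseinFraction
    variant: str
    sequence: str

    def __post_init__(self) -> None:
        seq = validate_sequence(self.sequence)
        if not seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", seq)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def label(self) -> str:
        """Display label ``fraction/variant`` used in rankings and tables."""
        return f"{self.fraction.value}/{self.variant}" if self.variant else self.fraction.value


@dataclass(frozen=True)
class BioactivePeptideEntry:
    """One row of the bioactive-peptide database.

    Profiling counts start at dipeptides, so entries shorter than two
    residues are invalid.
    """

    sequence: str
    activity: Activity
    db_id: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        seq = validate_sequence(self.sequence)
        if len(seq) < 2:
            raise ValueError(
                f"database peptide {seq!r}: length {len(seq)} < 2"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class SampleIdentificationSet:
    """Peptides experimentally identified in one sample.

    ``peptides`` holds unique ``(sequence, activity)`` pairs; a peptide
    carrying both activities appears once per activity.
    """

    sample_id: str
    peptides: set[tuple[str, Activity]] = field(default_factory=set)

    def sequences(self, activity: Activity) -> set[str]:
        """Unique peptide sequences of one activity in this sample."""
        return {seq for seq, act in self.peptides if act == activity}


@dataclass(frozen=True)
class AssayMeasurement:
    """One spectrophotometric dose point of an inhibition assay.

    The inhibition percentage is derived from the three absorbances:
    ``(a_control - a_inhibitor) / (a_control - a_blank) * 100``.
    """

    sample_id: str
    concentration: float  # mg/mL
    a_control: float
    a_inhibitor: float
    a_blank: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")


@dataclass(frozen=True)
class ChromPeak:
    """A chromatographic peak as a (retention time, area) point."""

    retention_time: float  # minutes
    area: float

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValueError(f"retention time must be >= 0, got {self.retention_time}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class SpectrumPeak:
    """A centroided MS/MS peak."""

    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
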