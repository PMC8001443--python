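"""Ripening-release metrics and presence matrices.

During cheese ripening, proteolysis releases peptides from the casein
fractions.  Mapping the experimentally identified peptides of a sample
back onto each parent protein yields, per (sample, protein, activity):

    d       number of unique identified peptides of the activity that
            occur as substrings of the protein chain
    A_Eexp  d / N          frequency of released bioactive fragments
    W_exp   A_Eexp / A     fraction of the protein's encrypted potential
                           actually released (A is the in-silico
                           occurrence frequency of the same activity)

Because N cancels, the unrounded W_exp equals d / total-occurrences.
Reported tables round half-up to three decimals; an alternative
"rounded intermediate" convention divides the already-rounded A_Eexp by
A, which is how some published tables were evidently computed.  Both
conventions are available and reports state which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._rounding import round_half_up
from .models import (
    Activity,
    BioactivePeptideEntry,
    CaseinFraction,
    ProteinRecord,
    SampleIdentificationSet,
)
from .profiling import ActivityProfile, build_profile

__all__ = [
    "RipeningMetrics",
    "PresenceMatrix",
    "map_identified_to_protein",
    "a_e_exp",
    "w_exp",
    "ripening_table",
    "ripening_frame",
    "presence_matrix",
]


@dataclass(frozen=True)
class RipeningMetrics:
    """One cell of the per-(sample, protein, activity) release table."""

    sample_id: str
    protein_id: str
    protein_label: str
    activity: Activity
    d: int
    n_residues: int
    a_e_exp: float
    A: float
    w_exp: float
    is_max_d: bool = False
    is_max_a_e: bool = False
    is_max_w: bool = False


@dataclass
class PresenceMatrix:
    """Binary peptide-by-category matrix (heatmap input).

    Rows are peptide sequences, columns are categories (activity
    classes, cheese samples, or casein fractions); a cell is 1 iff the
    peptide belongs to / was seen in / maps to that category.
    """

    row_labels: list[str]
    col_labels: list[str]
    cells: list[list[int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels, columns=self.col_labels)


def map_identified_to_protein(
    sample_set: SampleIdentificationSet,
    protein: ProteinRecord,
    activity: Activity,
) -> int:
    """d: unique identified peptides of one activity mapping to a protein.

    Each unique sequence counts once no matter how many times it occurs
    in the chain.
    """
    return sum(1 for seq in sample_set.sequences(activity) if seq in protein.sequence)


def a_e_exp(d: int, n_residues: int) -> float:
    """Frequency of released fragments A_Eexp = d / N, unrounded."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    if d < 0:
        raise ValueError("d must be >= 0")
    return d / n_residues


def w_exp(a_e: float, A: float, convention: str = "unrounded") -> float:
    """Relative release frequency W_exp = A_Eexp / A.

    ``unrounded`` divides the exact values (equivalently d divided by
    the total occurrence count, since N cancels).  ``rounded_intermediate``
    first rounds A_Eexp half-up to three decimals, reproducing tables
    computed from already-rounded intermediates.  The result itself is
    returned unrounded; display rounding is separate.
    """
    if convention not in ("unrounded", "rounded_intermediate"):
        raise ValueError(f"unknown convention {convention!r}")
    if A <= 0:
        if a_e > 0:
            raise ValueError(
                "A = 0 with released peptides present: identified peptides are "
                "absent from the in-silico profile (inconsistent database)"
            )
        return 0.0
    numerator = round_half_up(a_e, 3) if convention == "rounded_intermediate" else a_e
    return numerator / A


def _profiles_for(
    proteins: list[ProteinRecord],
    db: list[BioactivePeptideEntry],
    activities: list[Activity],
) -> dict[tuple[str, Activity], ActivityProfile]:
    return {
        (p.id, act): build_profile(p, db, act) for p in proteins for act in activities
    }


def ripening_table(
    samples: list[SampleIdentificationSet],
    proteins: list[ProteinRecord],
    db: list[BioactivePeptideEntry],
    convention: str = "unrounded",
    activities: list[Activity] | None = None,
) -> list[RipeningMetrics]:
    """Full cross of samples x proteins x activities.

    The rows attaining the per-activity maximum of d, A_Eexp and W_exp
    are flagged (the published tables mark them in bold).
    """
    acts = activities or list(Activity)
    profiles = _profiles_for(proteins, db, acts)
    raw: list[dict] = []
    for sample in samples:
        for protein in proteins:
            for act in acts:
                prof = profiles[(protein.id, act)]
                d = map_identified_to_protein(sample, protein, act)
                ae = a_e_exp(d, protein.n_residues)
                w = w_exp(ae, prof.A, convention=convention)
                raw.append(
                    dict(
                        sample_id=sample.sample_id,
                        protein_id=protein.id,
                        protein_label=protein.label,
                        activity=act,
                        d=d,
                        n_residues=protein.n_residues,
                        a_e_exp=ae,
                        A=prof.A,
                        w_exp=w,
                    )
                )
    maxima = {
        act: {
            key: max((r[key] for r in raw if r["activity"] == act), default=0)
            for key in ("d", "a_e_exp", "w_exp")
        }
        for act in acts
    }
    return [
        RipeningMetrics(
            **r,
            is_max_d=r["d"] == maxima[r["activity"]]["d"] and r["d"] > 0,
            is_max_a_e=r["a_e_exp"] == maxima[r["activity"]]["a_e_exp"] and r["a_e_exp"] > 0,
            is_max_w=r["w_exp"] == maxima[r["activity"]]["w_exp"] and r["w_exp"] > 0,
        )
        for r in raw
    ]


def ripening_frame(metrics: list[RipeningMetrics], decimals: int = 3) -> pd.DataFrame:
    """Long-format report table with half-up display rounding."""
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metrics],
            "protein_id": [m.protein_id for m in metrics],
            "protein_label": [m.protein_label for m in metrics],
            "activity": [m.activity.value for m in metrics],
            "d": [m.d for m in metrics],
            "N": [m.n_residues for m in metrics],
            "A_Eexp": [round_half_up(m.a_e_exp, decimals) for m in metrics],
            "A": [round_half_up(m.A, decimals) for m in metrics],
            "W_exp": [round_half_up(m.w_exp, decimals) for m in metrics],
            "max_d": [m.is_max_d for m in metrics],
            "max_A_Eexp": [m.is_max_a_e for m in metrics],
            "max_W_exp": [m.is_max_w for m in metrics],
        }
    )


def presence_matrix(
    identified: list[SampleIdentificationSet],
    axis: str,
    proteins: list[ProteinRecord] | None = None,
    db: list[BioactivePeptideEntry] | None = None,
) -> PresenceMatrix:
    """Binary presence matrix over all identified peptides.

    ``axis='activity'``: columns are activity classes; 1 iff the peptide
    carries that activity in the database (falling back to the activity
    annotation of the identification lists when no database is given).
    ``axis='sample'``: columns are sample ids; 1 iff identified there.
    ``axis='protein_fraction'``: columns are casein fractions with >= 1
    protein supplied; 1 iff the peptide is a substring of at least one
    protein of the fraction.
    """
    peptides = sorted({seq for s in identified for seq, _ in s.peptides})
    if axis == "activity":
        cols = [a.value for a in Activity]
        if db is not None:
            membership = {
                seq: {e.activity for e in db if e.sequence == seq} for seq in peptides
            }
        else:
            membership = {
                seq: {act for s in identified for q, act in s.peptides if q == seq}
                for seq in peptides
            }
        cells = [
            [1 if Activity(c) in membership[seq] else 0 for c in cols] for seq in peptides
        ]
    elif axis == "sample":
        cols = [s.sample_id for s in identified]
        seen = {s.sample_id: {seq for seq, _ in s.peptides} for s in identified}
        cells = [[1 if seq in seen[c] else 0 for c in cols] for seq in peptides]
    elif axis == "protein_fraction":
        if not proteins:
            raise ValueError("protein_fraction axis requires proteins")
        fractions = [
            f.value for f in CaseinFraction if any(p.fraction == f for p in proteins)
        ]
        cells = [
            [
                1
                if any(
                    seq in p.sequence for p in proteins if p.fraction.value == frac
                )
                else 0
                for frac in fractions
            ]
            for seq in peptides
        ]
        cols = fractions
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return PresenceMatrix(row_labels=peptides, col_labels=cols, cells=cells)
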