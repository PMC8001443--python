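"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from bpp.models import Activity, BioactivePeptideEntry, CaseinFraction, ProteinRecord


def naive_find(peptide: str, sequence: str) -> list[int]:
    """Position-by-position exact-match oracle; 1-based starts."""
    L = len(peptide)
    return [
        i + 1
        for i in range(len(sequence) - L + 1)
        if sequence[i : i + L] == peptide
    ]


def naive_profile_occurrences(
    sequence: str, db: list[BioactivePeptideEntry], activity: Activity
) -> set[tuple[int, str]]:
    """Brute-force scan of every (position, db entry) pair."""
    hits: set[tuple[int, str]] = set()
    for entry in db:
        if entry.activity != activity:
            continue
        for start in naive_find(entry.sequence, sequence):
            hits.add((start, entry.sequence))
    return hits


@pytest.fixture
def wiqp_protein() -> ProteinRecord:
    """A synthetic 222-residue chain with WIQP planted at 208-211,
    mirroring the layout of the alpha-S2-casein A entry."""
    from bpp.synthetic import gen_protein, plant_motifs

    base = gen_protein(222, seed=42, protein_id="syn_as2A",
                       fraction=CaseinFraction.alphaS2, variant="A")
    planted, _ = plant_motifs(base, [("WIQP", 208)])
    # guard against accidental extra copies from the random background
    assert planted.sequence.count("WIQP") == 1
    return planted


@pytest.fixture
def small_db() -> list[BioactivePeptideEntry]:
    ace = Activity.ACE_inhibitor
    dpp = Activity.DPP4_inhibitor
    return [
        BioactivePeptideEntry("QP", ace, "1"),
        BioactivePeptideEntry("QP", dpp, "1b"),
        BioactivePeptideEntry("IQP", ace, "2"),
        BioactivePeptideEntry("IQP", dpp, "2b"),
        BioactivePeptideEntry("IQ", dpp, "3"),
        BioactivePeptideEntry("WI", dpp, "4"),
        BioactivePeptideEntry("WIQP", dpp, "5"),
        BioactivePeptideEntry("VPP", ace, "6"),
        BioactivePeptideEntry("AA", ace, "7"),
    ]
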