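"""Deterministic demo inputs with hand-checkable arithmetic.

The demo protein is the strict alternation (AP)x107 — a synthetic
214-residue chain (the length of alpha-S1-casein genetic variant D)
whose profile against the one-entry database {AP: ACE inhibitor} has
exactly 107 occurrences, hence A = 107/214 = 0.5.  A demo ripening
sample carries 13 distinct ACE-annotated substrings of that chain, so

    A_Eexp = 13/214 -> 0.061 (3-decimal half-up)
    W_exp  = 0.061/0.5 = 0.122  (rounded-intermediate convention)
           = 13/107   -> 0.121  (unrounded convention)

mirroring the released-fragment arithmetic of a 60-day ripened cheese.
The third check is the worked fragment-ion example: the (M+H)+ of the
DPP-IV-inhibitory peptide WIQP is 543.3 Da at one decimal.
"""

from __future__ import annotations

from pathlib import Path

from ._rounding import round_half_up
from .io import write_fasta, write_identified_peptides, write_peptide_db
from .models import (
    Activity,
    BioactivePeptideEntry,
    CaseinFraction,
    ProteinRecord,
    SampleIdentificationSet,
)
from .ions import precursor_mz
from .ripening import ripening_table

__all__ = ["demo_inputs", "write_demo_inputs", "verify_targets"]

DEMO_SAMPLE_ID = "Demo-60"


def _alternating(first: str, length: int) -> str:
    pair = "AP" if first == "A" else "PA"
    return (pair * length)[:length]


def demo_inputs() -> tuple[list[ProteinRecord], list[BioactivePeptideEntry],
                           list[SampleIdentificationSet]]:
    """The demo protein, database and identification set (see module doc)."""
    protein = ProteinRecord(
        id="demo_as1D",
        name="synthetic 214-residue demo chain",
        fraction=CaseinFraction.alphaS1,
        variant="D",
        sequence="AP" * 107,
    )
    db = [BioactivePeptideEntry(sequence="AP", activity=Activity.ACE_inhibitor,
                                db_id="DEMO1")]
    # 13 distinct substrings of the chain, annotated as ACE inhibitors:
    # both alternations at lengths 2..7, plus one at length 8.
    peptides = [_alternating(first, length)
                for length in range(2, 8) for first in "AP"]
    peptides.append(_alternating("A", 8))
    sample = SampleIdentificationSet(
        sample_id=DEMO_SAMPLE_ID,
        peptides={(p, Activity.ACE_inhibitor) for p in peptides},
    )
    return [protein], db, [sample]


def write_demo_inputs(out_dir: str | Path) -> dict[str, Path]:
    """Write the demo fixtures as the standard input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, db, identified = demo_inputs()
    paths = {
        "fasta": out / "demo_proteins.fasta",
        "db": out / "demo_peptide_db.tsv",
        "identified": out / "demo_identified.tsv",
    }
    write_fasta(proteins, paths["fasta"])
    write_peptide_db(db, paths["db"])
    write_identified_peptides(identified, paths["identified"])
    return paths


def verify_targets() -> list[dict]:
    """Recompute the desk-scale anchor values from the demo inputs.

    Returns one row per check with expected and observed values and a
    pass flag; the unrounded W_exp is reported alongside the
    rounded-intermediate one because the two display conventions differ
    at the third decimal (0.121 vs 0.122).
    """
    proteins, db, identified = demo_inputs()
    results = []

    rows = ripening_table(identified, proteins, db,
                          activities=[Activity.ACE_inhibitor])
    cell = rows[0]
    observed_ae = round_half_up(cell.a_e_exp, 3)
    results.append(
        dict(target="A_Eexp (d=13, N=214)", expected=0.061, observed=observed_ae,
             passed=observed_ae == 0.061)
    )

    rounded_rows = ripening_table(identified, proteins, db,
                                  convention="rounded_intermediate",
                                  activities=[Activity.ACE_inhibitor])
    observed_w = round_half_up(rounded_rows[0].w_exp, 3)
    results.append(
        dict(target="W_exp rounded-intermediate (0.061/0.5)", expected=0.122,
             observed=observed_w, passed=observed_w == 0.122)
    )
    results.append(
        dict(target="W_exp unrounded (13/107)", expected=0.121,
             observed=round_half_up(cell.w_exp, 3),
             passed=round_half_up(cell.w_exp, 3) == 0.121)
    )

    observed_mz = round_half_up(precursor_mz("WIQP", 1), 1)
    results.append(
        dict(target="(M+H)+ of WIQP", expected=543.3, observed=observed_mz,
             passed=observed_mz == 543.3)
    )
    return results
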