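"""Seeded generators for every input the pipeline consumes.

Real inputs (casein sequences, the bioactive-peptide database, identified
peptide lists, assay absorbances, peak lists and spectra) come from lab
instruments and curated databases.  These generators produce structurally
equivalent files with *known ground truth*, so every stage can be tested
end to end with no downloads: planted motif positions, true IC50s and
Hill slopes, source ions of each spectrum, expected segment percentages.

The default residue-composition profile mimics bovine beta-casein, the
proline-richest casein fraction (Pro ~16 %, Leu ~11 %, Gln ~10 %, Val
~9 %, Glu ~9 %), with the remaining mass spread uniformly over the other
residues; this gives realistic short-motif match statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ic50 import four_pl
from .ions import ion_series
from .models import (
    Activity,
    AssayMeasurement,
    BioactivePeptideEntry,
    CaseinFraction,
    ChromPeak,
    ProteinRecord,
    SampleIdentificationSet,
    SpectrumPeak,
)

__all__ = [
    "BETA_CASEIN_LIKE_COMPOSITION",
    "SyntheticTruth",
    "gen_protein",
    "plant_motifs",
    "gen_peptide_db",
    "gen_identification_sets",
    "gen_dose_response",
    "gen_spectrum",
    "gen_peak_table",
]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _beta_casein_profile() -> dict[str, float]:
    major = {"P": 0.1625, "L": 0.1075, "Q": 0.1005, "V": 0.091, "E": 0.086}
    rest = (1.0 - sum(major.values())) / (len(_RESIDUES) - len(major))
    return {r: major.get(r, rest) for r in _RESIDUES}


#: Residue frequencies approximating bovine beta-casein.
BETA_CASEIN_LIKE_COMPOSITION: dict[str, float] = _beta_casein_profile()


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside generated data."""

    seed: int
    planted_occurrences: list[tuple[str, str, int]] = field(default_factory=list)
    ic50_by_sample: dict[str, tuple[float, float]] = field(default_factory=dict)
    source_ions: list = field(default_factory=list)
    d_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    segment_percent: tuple[float, ...] = ()


def _check_profile(composition: dict[str, float]) -> tuple[list[str], np.ndarray]:
    letters = sorted(composition)
    if set(letters) - set(_RESIDUES):
        raise ValueError("composition contains non-canonical residues")
    weights = np.array([composition[r] for r in letters], dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("residue frequencies must be non-negative and sum to 1")
    return letters, weights / weights.sum()


def gen_protein(
    length: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    protein_id: str = "synthetic",
    fraction: CaseinFraction = CaseinFraction.other,
    variant: str = "",
) -> ProteinRecord:
    """A random protein drawn i.i.d. from a residue-frequency profile."""
    if length < 1:
        raise ValueError("length must be >= 1")
    letters, weights = _check_profile(composition or BETA_CASEIN_LIKE_COMPOSITION)
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(letters), size=length, p=weights))
    return ProteinRecord(
        id=protein_id,
        name=f"synthetic protein {protein_id}",
        fraction=fraction,
        variant=variant,
        sequence=seq,
    )


def plant_motifs(
    protein: ProteinRecord,
    placements: list[tuple[str, int]],
    seed: int = 0,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Overwrite motifs into a protein at stated 1-based start positions.

    Placements must be non-overlapping and within the chain; the truth
    records every placement (the planted occurrence set is a lower bound
    for what profiling recovers -- random background may add more).
    """
    spans: list[tuple[int, int]] = []
    seq = list(protein.sequence)
    truth = SyntheticTruth(seed=seed)
    for motif, start in placements:
        end = start + len(motif) - 1
        if start < 1 or end > len(seq):
            raise ValueError(f"placement {motif!r}@{start} outside chain of length {len(seq)}")
        for s, e in spans:
            if start <= e and s <= end:
                raise ValueError(f"placement {motif!r}@{start} overlaps a previous one")
        spans.append((start, end))
        seq[start - 1 : end] = list(motif)
        truth.planted_occurrences.append((protein.id, motif, start))
    planted = ProteinRecord(
        id=protein.id,
        name=protein.name,
        fraction=protein.fraction,
        variant=protein.variant,
        sequence="".join(seq),
    )
    return planted, truth


def gen_peptide_db(
    n_entries: int = 40,
    length_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    composition: dict[str, float] | None = None,
) -> list[BioactivePeptideEntry]:
    """A random peptide database split evenly between the two activities.

    Lengths are drawn uniformly from ``length_range``, skewed toward
    dipeptides the way curated inhibitor tables are, by drawing two
    candidates and keeping the shorter.
    """
    letters, weights = _check_profile(composition or BETA_CASEIN_LIKE_COMPOSITION)
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, Activity], BioactivePeptideEntry] = {}
    acts = list(Activity)
    attempts = 0
    while len(entries) < n_entries and attempts < 100 * n_entries:
        attempts += 1
        length = min(rng.integers(length_range[0], length_range[1] + 1),
                     rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(letters), size=int(length), p=weights))
        act = acts[len(entries) % len(acts)]
        key = (seq, act)
        if key in entries:
            continue
        entries[key] = BioactivePeptideEntry(
            sequence=seq, activity=act, db_id=f"SYN{len(entries) + 1:04d}"
        )
    return list(entries.values())


def gen_identification_sets(
    proteins: list[ProteinRecord],
    db: list[BioactivePeptideEntry],
    inclusion_probability: dict[str, float],
    seed: int = 0,
) -> tuple[list[SampleIdentificationSet], SyntheticTruth]:
    """Simulated per-sample identified-peptide lists.

    Every database peptide occurring in at least one protein is included
    in each sample independently with that sample's probability,
    emulating the structure of ripening experiments (peptides shared by
    all samples, early-only and late-only peptides).  The truth records
    the resulting d counts per (sample, protein id, activity).
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    matchable = [
        e for e in db if any(e.sequence in p.sequence for p in proteins)
    ]
    sets: list[SampleIdentificationSet] = []
    for sample_id, prob in inclusion_probability.items():
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"inclusion probability for {sample_id!r} outside [0, 1]")
        chosen = {
            (e.sequence, e.activity)
            for e in matchable
            if rng.random() < prob
        }
        sets.append(SampleIdentificationSet(sample_id=sample_id, peptides=chosen))
        for protein in proteins:
            for act in Activity:
                d = sum(
                    1
                    for seq in {s for s, a in chosen if a == act}
                    if seq in protein.sequence
                )
                truth.d_counts[(sample_id, protein.id, act.value)] = d
    return sets, truth


def gen_dose_response(
    ic50: float,
    hill_slope: float = 1.0,
    concentrations: tuple[float, ...] = (2.5, 5.0, 10.0, 15.0, 25.0),
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    sample_id: str = "synthetic",
    a_blank: float = 0.05,
    a_control: float = 1.05,
) -> tuple[list[AssayMeasurement], SyntheticTruth]:
    """Dose-response absorbance triples from the logistic model.

    Inhibition percentages are drawn from the fixed-asymptote logistic
    plus Gaussian noise, then back-solved into (control, inhibitor,
    blank) absorbance triples so the reader and the inhibition formula
    reproduce the generated responses exactly.  The default grid spans
    2.5-25 mg/mL, the usual working range for cheese extract assays.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, ic50_by_sample={sample_id: (ic50, hill_slope)})
    out: list[AssayMeasurement] = []
    for conc in concentrations:
        model_y = float(four_pl(np.log10(conc), np.log10(ic50), hill_slope))
        for rep in range(1, replicates + 1):
            y = model_y + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            a_inhibitor = a_control - (y / 100.0) * (a_control - a_blank)
            out.append(
                AssayMeasurement(
                    sample_id=sample_id,
                    concentration=conc,
                    a_control=a_control,
                    a_inhibitor=a_inhibitor,
                    a_blank=a_blank,
                    replicate=rep,
                )
            )
    return out, truth


def gen_spectrum(
    peptide: str,
    types: str = "by",
    charges: tuple[int, ...] = (1,),
    jitter_sd: float = 0.0,
    n_noise_peaks: int = 0,
    mz_range: tuple[float, float] = (100.0, 1500.0),
    seed: int = 0,
    decoy_guard: float = 0.6,
) -> tuple[list[SpectrumPeak], SyntheticTruth]:
    """A synthetic MS/MS peak list for a known source peptide.

    Emits one peak per theoretical ion (m/z plus Gaussian jitter) and
    ``n_noise_peaks`` uniform decoys.  Decoys are kept at least
    ``decoy_guard`` Da (default twice the usual 0.3 Da matching
    tolerance) away from every true ion so that identification verdicts
    on the generated spectrum are unambiguous.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ions = ion_series(peptide, types=types, charges=charges)
    truth = SyntheticTruth(seed=seed, source_ions=list(ions))
    peaks = [
        SpectrumPeak(
            mz=ion.mz + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0),
            intensity=float(rng.uniform(50.0, 100.0)),
        )
        for ion in ions
    ]
    true_mzs = np.array([ion.mz for ion in ions])
    added = 0
    attempts = 0
    while added < n_noise_peaks and attempts < 1000 * max(n_noise_peaks, 1):
        attempts += 1
        mz = float(rng.uniform(*mz_range))
        if np.abs(true_mzs - mz).min() < decoy_guard:
            continue
        peaks.append(SpectrumPeak(mz=mz, intensity=float(rng.uniform(1.0, 30.0))))
        added += 1
    peaks.sort(key=lambda p: p.mz)
    return peaks, truth


def gen_peak_table(
    segment_percent: tuple[float, ...] = (55.0, 15.0, 30.0),
    n_peaks_per_segment: int = 8,
    total_area: float = 1000.0,
    seed: int = 0,
) -> tuple[list[ChromPeak], SyntheticTruth]:
    """A chromatographic peak table with known segment-area percentages.

    Peaks are placed strictly inside the default three segments and
    their areas within each segment are Dirichlet-split so the segment
    totals hit the requested percentages exactly.
    """
    from .chromatogram import DEFAULT_SEGMENTS

    if len(segment_percent) != len(DEFAULT_SEGMENTS):
        raise ValueError("one percentage per default segment is required")
    if not np.isclose(sum(segment_percent), 100.0, atol=1e-9):
        raise ValueError("segment percentages must sum to 100")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, segment_percent=tuple(segment_percent))
    peaks: list[ChromPeak] = []
    for seg, pct in zip(DEFAULT_SEGMENTS, segment_percent):
        seg_area = total_area * pct / 100.0
        if seg_area == 0:
            continue
        shares = rng.dirichlet(np.ones(n_peaks_per_segment)) * seg_area
        pad = 0.05 * (seg.end - seg.start)
        times = rng.uniform(seg.start + pad, seg.end - pad, size=n_peaks_per_segment)
        peaks += [ChromPeak(retention_time=float(t), area=float(a))
                  for t, a in zip(times, shares)]
    peaks.sort(key=lambda p: p.retention_time)
    return peaks, truth
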