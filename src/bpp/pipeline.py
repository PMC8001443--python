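"""Orchestration: run every analysis stage over a directory of inputs.

The pipeline stitches the stages in study order: in-silico profiling
and ranking, chromatogram segment summaries, IC50 estimation,
ripening-release metrics, and presence matrices.  Outputs are plain
TSV so runs are diffable; a run log records the package version and
the conventions used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._rounding import round_half_up
from .chromatogram import DEFAULT_SEGMENTS, Segment, segment_area_percentages
from .ic50 import fit_ic50, inhibition_percent
from .io import (
    read_assay_measurements,
    read_chrom_peaks,
    read_fasta,
    read_identified_peptides,
    read_peptide_db,
)
from .models import Activity
from .profiling import build_profile, rank_proteins
from .ripening import presence_matrix, ripening_frame, ripening_table

__all__ = ["RunConfig", "run_all", "profile_frame", "ranking_frame", "ic50_frame",
           "segments_frame"]

_LENGTH_COLUMNS = list(range(2, 20))


@dataclass
class RunConfig:
    """Paths and conventions for a full pipeline run."""

    fasta: Path
    db: Path
    identified: Path
    assay: Path | None = None
    peaks: Path | None = None
    out_dir: Path = Path("bpp_out")
    activities: list[Activity] = field(default_factory=lambda: list(Activity))
    w_exp_convention: str = "unrounded"
    decimals: int = 3
    tolerance: float = 0.3
    segments: tuple[Segment, ...] = DEFAULT_SEGMENTS

    def __post_init__(self) -> None:
        for label in ("fasta", "db", "identified"):
            path = getattr(self, label)
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")


def profile_frame(proteins, db, activities, decimals: int = 3) -> pd.DataFrame:
    """Per-protein profile table: totals, A and counts by peptide length."""
    rows = []
    for protein in proteins:
        for act in activities:
            prof = build_profile(protein, db, act)
            hist = prof.counts_by_length
            row = {
                "protein_id": prof.protein_id,
                "protein_label": prof.protein_label,
                "activity": act.value,
                "N": prof.n_residues,
                "total": prof.total,
                "A": round_half_up(prof.A, decimals),
            }
            row.update({f"len_{k}": hist.get(k, 0) for k in _LENGTH_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows)


def ranking_frame(proteins, db, activities) -> pd.DataFrame:
    """Ranking of proteins by total occurrence count, one block per activity."""
    rows = []
    for act in activities:
        profiles = [build_profile(p, db, act) for p in proteins]
        for entry in rank_proteins(profiles):
            rows.append(
                {
                    "activity": act.value,
                    "rank": entry.rank,
                    "protein_id": entry.protein_id,
                    "protein_label": entry.protein_label,
                    "total": entry.total,
                }
            )
    return pd.DataFrame(rows)


def ic50_frame(measurements, decimals: int = 3) -> pd.DataFrame:
    """Per-sample IC50 table from raw absorbance triples."""
    rows = []
    by_sample: dict[str, list] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)
    for sample_id, ms in by_sample.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            points = [
                (m.concentration, inhibition_percent(m.a_control, m.a_inhibitor, m.a_blank))
                for m in ms
            ]
        fit = fit_ic50(points)
        rows.append(
            {
                "sample_id": sample_id,
                "n_points": fit.n_points,
                "ic50_mg_ml": round_half_up(fit.ic50, decimals) if fit.converged else float("nan"),
                "log_ic50": round_half_up(fit.log_ic50, decimals) if fit.converged else float("nan"),
                "hill_slope": round_half_up(fit.hill_slope, decimals) if fit.converged else float("nan"),
                "ic50_ci_low": round_half_up(10 ** fit.ci95[0][0], decimals) if fit.converged else float("nan"),
                "ic50_ci_high": round_half_up(10 ** fit.ci95[0][1], decimals) if fit.converged else float("nan"),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def segments_frame(peaks, segments=DEFAULT_SEGMENTS, decimals: int = 2) -> pd.DataFrame:
    report = segment_area_percentages(peaks, segments)
    return pd.DataFrame(
        {
            "segment_start_min": [s.start for s in report.segments],
            "segment_end_min": [s.end for s in report.segments],
            "area": [round_half_up(a, decimals) for a in report.areas],
            "percent": [round_half_up(p, decimals) for p in report.percent],
        }
    )


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage the config provides inputs for.

    Returns a mapping of stage name to the TSV it wrote.  Any stage
    error aborts the run with the stage named in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    proteins = _stage("read_fasta", lambda: read_fasta(config.fasta))
    db = _stage("read_peptide_db", lambda: read_peptide_db(config.db))
    identified = _stage("read_identified", lambda: read_identified_peptides(config.identified))

    prof = _stage("profile", lambda: profile_frame(proteins, db, config.activities,
                                                   config.decimals))
    written["profile"] = out / "profile.tsv"
    prof.to_csv(written["profile"], sep="\t", index=False)

    rank = _stage("rank", lambda: ranking_frame(proteins, db, config.activities))
    written["ranking"] = out / "ranking.tsv"
    rank.to_csv(written["ranking"], sep="\t", index=False)

    metrics = _stage(
        "ripening",
        lambda: ripening_table(identified, proteins, db,
                               convention=config.w_exp_convention,
                               activities=config.activities),
    )
    written["ripening"] = out / "ripening.tsv"
    ripening_frame(metrics, config.decimals).to_csv(written["ripening"], sep="\t", index=False)

    for axis, fname in (("activity", "heatmap_activity.tsv"),
                        ("sample", "heatmap_sample.tsv"),
                        ("protein_fraction", "heatmap_fraction.tsv")):
        matrix = _stage(f"heatmap_{axis}",
                        lambda axis=axis: presence_matrix(identified, axis,
                                                          proteins=proteins, db=db))
        written[f"heatmap_{axis}"] = out / fname
        matrix.to_frame().to_csv(written[f"heatmap_{axis}"], sep="\t",
                                 index_label="peptide")

    if config.peaks is not None:
        peaks = _stage("read_peaks", lambda: read_chrom_peaks(config.peaks))
        seg = _stage("segments", lambda: segments_frame(peaks, config.segments))
        written["segments"] = out / "segments.tsv"
        seg.to_csv(written["segments"], sep="\t", index=False)

    if config.assay is not None:
        measurements = _stage("read_assay", lambda: read_assay_measurements(config.assay))
        ic50 = _stage("ic50", lambda: ic50_frame(measurements, config.decimals))
        written["ic50"] = out / "ic50.tsv"
        ic50.to_csv(written["ic50"], sep="\t", index=False)

    log = out / "run_log.txt"
    log.write_text(
        "bpp run log\n"
        f"version: {__version__}\n"
        f"w_exp_convention: {config.w_exp_convention}\n"
        f"decimals: {config.decimals}\n"
        f"tolerance_da: {config.tolerance}\n"
        f"stages: {', '.join(sorted(written))}\n"
    )
    written["log"] = log
    return written
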