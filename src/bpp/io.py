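"""Readers and writers for the plain-text formats the pipeline touches.

Proteins travel as FASTA; everything else (peptide databases,
identification lists, assay readouts, peak tables, spectra) as
tab- or comma-delimited tables with a header row.  The delimiter is
auto-detected between tab and comma.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Activity,
    AssayMeasurement,
    BioactivePeptideEntry,
    CaseinFraction,
    ChromPeak,
    ProteinRecord,
    SampleIdentificationSet,
    SequenceError,
    SpectrumPeak,
    validate_sequence,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peptide_db",
    "write_peptide_db",
    "read_identified_peptides",
    "write_identified_peptides",
    "read_assay_measurements",
    "read_chrom_peaks",
    "read_spectrum",
    "canonical_sample_id",
]

# Shell-safe aliases for the arrow-bearing cheese sample names
# (reduced / normative / increased beta-casein content).
_SAMPLE_ALIASES = {
    "ChCN_dn": "ChCN↓",
    "ChCN_down": "ChCN↓",
    "ChCN_up": "ChCN↑",
    "ChCN-0": "ChCN-0",
}


def canonical_sample_id(sample_id: str) -> str:
    """Map an ASCII sample-id alias to its canonical display name.

    ``ChCN_dn-1`` -> ``ChCN↓-1``, ``ChCN_up-60`` -> ``ChCN↑-60``;
    already-canonical ids and unrecognised ids pass through unchanged.
    """
    sid = sample_id.strip()
    for alias, canon in _SAMPLE_ALIASES.items():
        if sid.startswith(alias + "-") or sid == alias:
            return canon + sid[len(alias):]
    return sid


def _parse_fraction(token: str) -> CaseinFraction:
    try:
        return CaseinFraction(token)
    except ValueError:
        return CaseinFraction.other


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Headers in the ``id|fraction|variant|name`` dialect populate all
    fields; otherwise the first whitespace token is the id, the fraction
    is ``other`` and the variant is empty.  Non-canonical residues raise
    :class:`~bpp.models.SequenceError` naming the record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) >= 4:
            pid, fraction, variant = parts[0].strip(), _parse_fraction(parts[1].strip()), parts[2].strip()
            name = "|".join(parts[3:]).strip()
        else:
            pid = rec.id
            fraction, variant = CaseinFraction.other, ""
            name = rec.description
        try:
            records.append(
                ProteinRecord(id=pid, name=name, fraction=fraction, variant=variant,
                              sequence=str(rec.seq))
            )
        except (SequenceError, ValueError) as exc:
            raise SequenceError(f"FASTA record {pid!r}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write protein records using the ``id|fraction|variant|name`` dialect."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.id}|{r.fraction.value}|{r.variant}|{r.name}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma."""
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise ValueError(f"empty table: {path}")
    try:
        dialect = csv.Sniffer().sniff(sample.splitlines()[0], delimiters="\t,")
        sep = dialect.delimiter
    except csv.Error:
        sep = "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def _parse_activity(label: str) -> Activity:
    try:
        return Activity(label.strip())
    except ValueError:
        raise ValueError(f"unknown activity label {label!r}; "
                         f"expected one of {[a.value for a in Activity]}") from None


def read_peptide_db(path: str | Path) -> list[BioactivePeptideEntry]:
    """Read a bioactive-peptide database table.

    Columns: ``sequence``, ``activity``, ``db_id`` (``reference``
    optional).  Duplicate (sequence, activity) rows collapse to one with
    a warning; single-residue sequences are excluded with a warning
    (profiling counts start at dipeptides).
    """
    df = _read_table(path, {"sequence", "activity", "db_id"})
    entries: dict[tuple[str, Activity], BioactivePeptideEntry] = {}
    for row in df.itertuples(index=False):
        seq = validate_sequence(str(row.sequence))
        activity = _parse_activity(str(row.activity))
        if len(seq) < 2:
            warnings.warn(f"excluding single-residue database entry {seq!r}", stacklevel=2)
            continue
        key = (seq, activity)
        if key in entries:
            warnings.warn(f"duplicate database row {seq!r}/{activity.value} collapsed",
                          stacklevel=2)
            continue
        ref = getattr(row, "reference", "")
        entries[key] = BioactivePeptideEntry(
            sequence=seq,
            activity=activity,
            db_id="" if pd.isna(row.db_id) else str(row.db_id),
            reference="" if pd.isna(ref) else str(ref),
        )
    return list(entries.values())


def write_peptide_db(entries: list[BioactivePeptideEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sequence": [e.sequence for e in entries],
            "activity": [e.activity.value for e in entries],
            "db_id": [e.db_id for e in entries],
            "reference": [e.reference for e in entries],
        }
    ).to_csv(path, sep="\t", index=False)


def read_identified_peptides(path: str | Path) -> list[SampleIdentificationSet]:
    """Read per-sample identified-peptide lists.

    Columns: ``sample_id``, ``sequence``, ``activity``.  One set per
    sample, duplicates deduplicated; sample ids are mapped through
    :func:`canonical_sample_id`.  Sets are returned in first-appearance
    order of the sample id.
    """
    df = _read_table(path, {"sample_id", "sequence", "activity"})
    sets: dict[str, SampleIdentificationSet] = {}
    for row in df.itertuples(index=False):
        sid = canonical_sample_id(str(row.sample_id))
        seq = validate_sequence(str(row.sequence))
        activity = _parse_activity(str(row.activity))
        sets.setdefault(sid, SampleIdentificationSet(sample_id=sid)).peptides.add(
            (seq, activity)
        )
    return list(sets.values())


def write_identified_peptides(sets: list[SampleIdentificationSet], path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "sequence": seq, "activity": act.value}
        for s in sets
        for seq, act in sorted(s.peptides, key=lambda p: (p[0], p[1].value))
    ]
    pd.DataFrame(rows, columns=["sample_id", "sequence", "activity"]).to_csv(
        path, sep="\t", index=False
    )


def read_assay_measurements(path: str | Path) -> list[AssayMeasurement]:
    """Read dose-response absorbance triples.

    Columns: ``sample_id``, ``concentration_mg_ml``, ``a_control``,
    ``a_inhibitor``, ``a_blank``, ``replicate``.
    """
    df = _read_table(
        path,
        {"sample_id", "concentration_mg_ml", "a_control", "a_inhibitor", "a_blank", "replicate"},
    )
    return [
        AssayMeasurement(
            sample_id=canonical_sample_id(str(row.sample_id)),
            concentration=float(row.concentration_mg_ml),
            a_control=float(row.a_control),
            a_inhibitor=float(row.a_inhibitor),
            a_blank=float(row.a_blank),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def read_chrom_peaks(path: str | Path) -> list[ChromPeak]:
    """Read a chromatographic peak table (``retention_time_min``, ``area``)."""
    df = _read_table(path, {"retention_time_min", "area"})
    return [
        ChromPeak(retention_time=float(row.retention_time_min), area=float(row.area))
        for row in df.itertuples(index=False)
    ]


def read_spectrum(path: str | Path) -> list[SpectrumPeak]:
    """Read a centroided spectrum peak list (``mz``, ``intensity``)."""
    df = _read_table(path, {"mz", "intensity"})
    return [
        SpectrumPeak(mz=float(row.mz), intensity=float(row.intensity))
        for row in df.itertuples(index=False)
    ]
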