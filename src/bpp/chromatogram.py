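"""Retention-time segment summaries of chromatographic peak tables.

RP-HPLC runs of cheese water-soluble extracts are compared through the
percentage of total peak area falling into fixed retention-time
segments.  The defaults follow the three-segment layout used for such
separations -- 0.00-14.00, 14.01-40.00 and 40.01-60.00 min -- with the
late column-washing window (60.01-80.00 min) excluded from the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .models import ChromPeak

__all__ = ["Segment", "SegmentReport", "DEFAULT_SEGMENTS", "DEFAULT_EXCLUSION",
           "segment_area_percentages"]


@dataclass(frozen=True)
class Segment:
    """A closed retention-time interval [start, end] in minutes."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} before start {self.start}")

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


DEFAULT_SEGMENTS = (
    Segment(0.00, 14.00),
    Segment(14.01, 40.00),
    Segment(40.01, 60.00),
)
#: Column-washing window dropped from the area total.
DEFAULT_EXCLUSION = Segment(60.01, 80.00)


@dataclass
class SegmentReport:
    segments: tuple[Segment, ...]
    percent: tuple[float, ...]
    areas: tuple[float, ...]
    total_area: float
    n_excluded: int
    n_dropped: int


def segment_area_percentages(
    peaks: list[ChromPeak],
    segments: tuple[Segment, ...] = DEFAULT_SEGMENTS,
    exclusion: Segment | None = DEFAULT_EXCLUSION,
) -> SegmentReport:
    """Percentage of total peak area per retention-time segment.

    Each peak is assigned to the first segment containing its retention
    time (a peak exactly on a shared boundary therefore goes to the
    earlier segment).  Peaks inside the exclusion interval are dropped
    silently; peaks outside every segment and not excluded are dropped
    with a warning.  Percentages are computed over the summed area of
    the included peaks, so they total 100 whenever any peak is included.
    """
    for a, b in zip(segments, segments[1:]):
        if b.start <= a.end:
            raise ValueError("segments must be disjoint and ordered")
    areas = [0.0] * len(segments)
    n_excluded = n_dropped = 0
    for peak in peaks:
        for i, seg in enumerate(segments):
            if seg.contains(peak.retention_time):
                areas[i] += peak.area
                break
        else:
            if exclusion is not None and exclusion.contains(peak.retention_time):
                n_excluded += 1
            else:
                warnings.warn(
                    f"peak at {peak.retention_time:g} min falls outside all "
                    "segments and is dropped",
                    stacklevel=2,
                )
                n_dropped += 1
    total = sum(areas)
    percent = tuple(100.0 * a / total if total > 0 else 0.0 for a in areas)
    return SegmentReport(
        segments=tuple(segments),
        percent=percent,
        areas=tuple(areas),
        total_area=total,
        n_excluded=n_excluded,
        n_dropped=n_dropped,
    )
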