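"""Peptide fragment-ion arithmetic and identification support.

Short peptides (2-5 residues) escape standard proteomic search engines,
so identification on a low-resolution ion trap proceeds by computing the
theoretical a/b/c/x/y/z fragment series of a candidate sequence
(Roepstorff-Fohlman nomenclature), matching them against the acquired
peak list, and accepting the identification only when the matched ions
cover every peptide bond (complete sequence information).

All masses are monoisotopic.  Neutral fragment masses follow the
standard prefix/suffix sums:

    prefix(i) = sum of residues 1..i          b_i = prefix(i)
    a_i = b_i - CO        c_i = b_i + NH3
    suffix(j) = sum of last j residues + H2O  y_j = suffix(j)
    x_j = y_j + CO - H2   z_j = y_j - NH2  (option: - NH3)

and m/z at charge n is (neutral + n * m_proton) / n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .models import SpectrumPeak, validate_sequence

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASS",
    "IonSeries",
    "MatchedIon",
    "IdentificationVerdict",
    "monoisotopic_mass",
    "precursor_mz",
    "ion_series",
    "match_spectrum",
    "coverage_verdict",
    "savitzky_golay",
]

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863
CO_MASS = 27.9949146221
NH3_MASS = 17.0265491015
NH2_MASS = 16.0187240694  # NH3 - H + 2H... i.e. N + 2H

#: Standard monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841392,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841392,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

_N_TERMINAL_TYPES = frozenset("abc")
_C_TERMINAL_TYPES = frozenset("xyz")


@dataclass(frozen=True)
class IonSeries:
    """One theoretical fragment ion of a peptide."""

    peptide: str
    ion_type: str  # one of a, b, c, x, y, z
    index: int  # 1..L-1
    charge: int  # 1..3
    mz: float

    @property
    def bond(self) -> int:
        """The peptide bond (1..L-1, counted from the N-terminus) whose
        cleavage produces this ion."""
        if self.ion_type in _N_TERMINAL_TYPES:
            return self.index
        return len(self.peptide) - self.index


@dataclass(frozen=True)
class MatchedIon:
    ion: IonSeries
    peak: SpectrumPeak
    delta: float  # observed - theoretical, Da


@dataclass
class IdentificationVerdict:
    """Complete-bond-coverage decision for one candidate peptide."""

    peptide: str
    matched: list[MatchedIon]
    bonds_covered: dict[int, bool]
    success: bool


def monoisotopic_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of a peptide: residue masses + water."""
    pep = validate_sequence(peptide)
    if not pep:
        raise ValueError("empty peptide")
    return sum(MONOISOTOPIC_RESIDUE_MASS[ch] for ch in pep) + WATER_MASS


def precursor_mz(peptide: str, charge: int = 1) -> float:
    """(M + nH)^n+ m/z of the intact peptide, charge 1..3."""
    if charge not in (1, 2, 3):
        raise ValueError(f"charge must be 1, 2 or 3, got {charge}")
    return (monoisotopic_mass(peptide) + charge * PROTON_MASS) / charge


def _neutral_fragment(prefix: float, suffix: float, ion_type: str,
                      z_convention: str) -> float:
    if ion_type == "b":
        return prefix
    if ion_type == "a":
        return prefix - CO_MASS
    if ion_type == "c":
        return prefix + NH3_MASS
    if ion_type == "y":
        return suffix
    if ion_type == "x":
        return suffix + CO_MASS - 2 * (PROTON_MASS + 0.00054857990907)  # CO - H2
    if ion_type == "z":
        return suffix - (NH2_MASS if z_convention == "nh2_loss" else NH3_MASS)
    raise ValueError(f"unknown ion type {ion_type!r}")


def ion_series(
    peptide: str,
    types: str = "by",
    charges: tuple[int, ...] = (1, 2, 3),
    z_convention: str = "nh2_loss",
) -> list[IonSeries]:
    """Theoretical fragment ions for the requested types and charges.

    ``types`` is any subset of ``abcxyz``; indices run 1..L-1 so the
    intact peptide is never emitted.  ``z_convention`` selects the z-ion
    offset: ``nh2_loss`` (y - NH2, default) or ``nh3_loss`` (y - NH3,
    the even-electron Biemann z).
    """
    pep = validate_sequence(peptide)
    if len(pep) < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    bad = set(types) - set("abcxyz")
    if bad or not types:
        raise ValueError(f"ion types must be a non-empty subset of 'abcxyz', got {types!r}")
    for ch in charges:
        if ch not in (1, 2, 3):
            raise ValueError(f"charges must be within 1..3, got {ch}")
    L = len(pep)
    residue = [MONOISOTOPIC_RESIDUE_MASS[c] for c in pep]
    prefix = np.cumsum(residue)  # prefix[i-1] = sum residues 1..i
    total = prefix[-1]
    out: list[IonSeries] = []
    for idx in range(1, L):
        pre = prefix[idx - 1]
        for ion_type in types:
            # C-terminal ions of index j use the last j residues
            suf = total - prefix[L - idx - 1] + WATER_MASS
            neutral = _neutral_fragment(pre, suf, ion_type, z_convention)
            for charge in charges:
                out.append(
                    IonSeries(
                        peptide=pep,
                        ion_type=ion_type,
                        index=idx,
                        charge=charge,
                        mz=(neutral + charge * PROTON_MASS) / charge,
                    )
                )
    return out


def match_spectrum(
    peaks: list[SpectrumPeak],
    ions: list[IonSeries],
    tolerance: float = 0.3,
) -> list[MatchedIon]:
    """Assign each theoretical ion to its nearest observed peak.

    An ion matches when its nearest peak lies within +/- ``tolerance``
    Da.  A single observed peak may serve several theoretical ions (a
    low-resolution trap cannot separate near-isobaric fragments), but
    each ion takes at most one peak.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not peaks or not ions:
        return []
    mzs = np.array(sorted(p.mz for p in peaks))
    sorted_peaks = sorted(peaks, key=lambda p: p.mz)
    matched: list[MatchedIon] = []
    for ion in ions:
        pos = np.searchsorted(mzs, ion.mz)
        best = None
        for j in (pos - 1, pos):
            if 0 <= j < len(mzs):
                delta = mzs[j] - ion.mz
                if best is None or abs(delta) < abs(best[0]):
                    best = (delta, j)
        if best is not None and abs(best[0]) <= tolerance:
            matched.append(
                MatchedIon(ion=ion, peak=sorted_peaks[best[1]], delta=float(best[0]))
            )
    return matched


def coverage_verdict(matched: list[MatchedIon], peptide_length: int) -> IdentificationVerdict:
    """Complete-bond-coverage identification decision.

    Bond k (1..L-1) is covered iff some matched N-terminal ion of index
    k or C-terminal ion of index L-k exists at any charge; the
    identification succeeds iff every bond is covered.
    """
    if peptide_length < 2:
        raise ValueError("peptide_length must be >= 2")
    peptide = matched[0].ion.peptide if matched else ""
    covered = {k: False for k in range(1, peptide_length)}
    for m in matched:
        bond = m.ion.bond
        if 1 <= bond < peptide_length:
            covered[bond] = True
    return IdentificationVerdict(
        peptide=peptide,
        matched=matched,
        bonds_covered=covered,
        success=all(covered.values()),
    )


def savitzky_golay(
    trace: list[tuple[float, float]] | np.ndarray,
    window: int = 5,
    poly_order: int = 2,
) -> np.ndarray:
    """Savitzky-Golay smoothing of a uniformly sampled (time, intensity)
    trace; returns an array of (time, smoothed intensity) rows.

    The window must be odd and larger than the polynomial order; edges
    are handled by fitting the edge polynomial to the truncated window.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("trace must be an iterable of (time, intensity) pairs")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= poly_order:
        raise ValueError("window must exceed poly_order")
    times = arr[:, 0]
    steps = np.diff(times)
    if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly spaced in time")
    smoothed = savgol_filter(arr[:, 1], window_length=window, polyorder=poly_order,
                             mode="interp")
    return np.column_stack([times, smoothed])
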