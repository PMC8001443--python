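"""In-silico bioactivity profiling of protein sequences.

A "profile of potential biological activity" is the set of all exact
occurrences of database peptides of one activity class within a protein
chain.  Occurrences are the counting unit: repeated and mutually
overlapping matches all count, so a protein containing a motif twice
contributes two to the total.  The headline statistic is

    A = (number of occurrences) / N

the frequency of occurrence of bioactive fragments per residue, with N
the protein chain length.

Matching is exact multi-pattern substring search over the 20-letter
alphabet, implemented with an Aho-Corasick automaton so a whole database
is matched against a protein in a single pass.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

from .models import Activity, BioactivePeptideEntry, ProteinRecord, validate_sequence

__all__ = [
    "Occurrence",
    "ActivityProfile",
    "RankingEntry",
    "AhoCorasick",
    "find_occurrences",
    "build_profile",
    "frequency_A",
    "length_histogram",
    "rank_proteins",
    "aa_composition",
    "filter_occurrences_by_residues",
    "fragmentomic_scan",
]


@dataclass(frozen=True, order=True)
class Occurrence:
    """One exact match of a peptide in a protein chain.

    Coordinates are 1-based and inclusive, matching the convention used
    for protein fragments ("fragment 208-211" is a tetrapeptide starting
    at residue 208).
    """

    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid coordinates {self.start}-{self.end}")
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"span {self.start}-{self.end} does not fit peptide {self.peptide!r}"
            )


@dataclass
class ActivityProfile:
    """All occurrences of one activity class in one protein."""

    protein_id: str
    protein_label: str
    activity: Activity
    n_residues: int
    occurrences: list[Occurrence] = field(default_factory=list)

    @property
    def total(self) -> int:
        """Occurrence count, repeats and overlaps included."""
        return len(self.occurrences)

    @property
    def unique_total(self) -> int:
        """Number of distinct peptide sequences with >= 1 occurrence."""
        return len({o.peptide for o in self.occurrences})

    @property
    def counts_by_length(self) -> dict[int, int]:
        return length_histogram(self)

    @property
    def A(self) -> float:
        return frequency_A(self)


@dataclass(frozen=True)
class RankingEntry:
    protein_id: str
    protein_label: str
    activity: Activity
    total: int
    rank: int


class AhoCorasick:
    """Multi-pattern exact matcher over amino-acid sequences.

    Builds the classic goto/fail automaton once per pattern set; a text
    of length n is then scanned in O(n + matches) regardless of the
    number of patterns.
    """

    def __init__(self, patterns: list[str]):
        self._patterns = sorted(set(patterns))
        # node 0 is the root; goto maps (node, char) -> node
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._output: list[list[str]] = [[]]
        for pat in self._patterns:
            self._insert(pat)
        self._build_failure_links()

    def _insert(self, pattern: str) -> None:
        node = 0
        for ch in pattern:
            nxt = self._goto[node].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._output.append([])
                self._goto[node][ch] = nxt
            node = nxt
        self._output[node].append(pattern)

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                fallback = self._fail[node]
                while fallback and ch not in self._goto[fallback]:
                    fallback = self._fail[fallback]
                self._fail[child] = self._goto[fallback].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._output[child] += self._output[self._fail[child]]

    def scan(self, text: str) -> list[tuple[int, str]]:
        """All matches as ``(start, pattern)`` with 1-based starts,
        sorted by (start, pattern length)."""
        hits: list[tuple[int, str]] = []
        node = 0
        for i, ch in enumerate(text, start=1):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            for pat in self._output[node]:
                hits.append((i - len(pat) + 1, pat))
        hits.sort(key=lambda h: (h[0], len(h[1])))
        return hits


def find_occurrences(peptide: str, protein: ProteinRecord) -> list[Occurrence]:
    """Every exact occurrence of ``peptide`` in the protein chain.

    Overlapping and self-overlapping matches are all reported, in
    ascending order of start position.  A peptide longer than the
    protein simply yields no occurrences.
    """
    pep = validate_sequence(peptide)
    if not pep:
        raise ValueError("empty peptide")
    seq = protein.sequence
    out: list[Occurrence] = []
    start = seq.find(pep)
    while start != -1:
        out.append(Occurrence(start=start + 1, end=start + len(pep), peptide=pep))
        start = seq.find(pep, start + 1)
    return out


def build_profile(
    protein: ProteinRecord,
    db: list[BioactivePeptideEntry],
    activity: Activity,
) -> ActivityProfile:
    """Profile one protein against all database peptides of one activity."""
    if not db:
        raise ValueError("empty peptide database")
    patterns = [e.sequence for e in db if e.activity == activity]
    occurrences = [
        Occurrence(start=start, end=start + len(pat) - 1, peptide=pat)
        for start, pat in AhoCorasick(patterns).scan(protein.sequence)
    ]
    return ActivityProfile(
        protein_id=protein.id,
        protein_label=protein.label,
        activity=activity,
        n_residues=protein.n_residues,
        occurrences=occurrences,
    )


def frequency_A(profile: ActivityProfile) -> float:
    """Frequency of occurrence A = total occurrences / N, unrounded."""
    if profile.n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return profile.total / profile.n_residues


def length_histogram(profile: ActivityProfile) -> dict[int, int]:
    """Occurrence counts keyed by peptide length; absent lengths omitted."""
    return dict(sorted(Counter(len(o.peptide) for o in profile.occurrences).items()))


def rank_proteins(profiles: list[ActivityProfile]) -> list[RankingEntry]:
    """Rank proteins by total occurrence count, descending.

    Ties share the min-rank ordinal (1, 1, 3, ...) and are listed
    alphabetically by protein label within the tie.
    """
    if not profiles:
        raise ValueError("no profiles to rank")
    activities = {p.activity for p in profiles}
    if len(activities) > 1:
        raise ValueError("rank_proteins expects profiles of a single activity")
    ordered = sorted(profiles, key=lambda p: (-p.total, p.protein_label))
    entries: list[RankingEntry] = []
    for idx, prof in enumerate(ordered, start=1):
        rank = idx if not entries or prof.total != ordered[idx - 2].total else entries[-1].rank
        entries.append(
            RankingEntry(
                protein_id=prof.protein_id,
                protein_label=prof.protein_label,
                activity=prof.activity,
                total=prof.total,
                rank=rank,
            )
        )
    return entries


def aa_composition(protein: ProteinRecord) -> dict[str, float]:
    """Percentage of each residue present in the chain.

    Values are exact count/N*100 (unrounded); only residues that occur
    are reported.  Display rounding to one decimal is the caller's
    concern.
    """
    n = protein.n_residues
    counts = Counter(protein.sequence)
    return {res: 100.0 * c / n for res, c in sorted(counts.items())}


def filter_occurrences_by_residues(
    profile: ActivityProfile,
    residue_set: set[str],
    mode: str = "contains_any",
) -> list[Occurrence]:
    """Occurrences whose peptide satisfies a residue condition.

    Modes: ``contains_any`` (any residue of the set anywhere in the
    peptide), ``n_terminal`` / ``c_terminal`` (first / last residue in
    the set) -- the terminal modes express structure-activity rules such
    as "ideal ACE-inhibitory peptides carry a C-terminal proline".
    """
    if not residue_set:
        raise ValueError("residue_set must be non-empty")
    residues = {validate_sequence(r) for r in residue_set}
    if mode == "contains_any":
        pred = lambda pep: any(r in pep for r in residues)  # noqa: E731
    elif mode == "n_terminal":
        pred = lambda pep: pep[0] in residues  # noqa: E731
    elif mode == "c_terminal":
        pred = lambda pep: pep[-1] in residues  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [o for o in profile.occurrences if pred(o.peptide)]


def fragmentomic_scan(
    peptide: str, db: list[BioactivePeptideEntry]
) -> list[tuple[str, Activity, int]]:
    """Bioactive submotifs encrypted within a peptide of interest.

    Returns every proper substring of length >= 2 that appears in the
    database, as ``(submotif, activity, 1-based start within peptide)``
    triples, deduplicated by (submotif, activity) keeping the first
    (leftmost) start.  The full-length peptide itself is not reported.
    """
    pep = validate_sequence(peptide)
    if len(pep) < 2:
        raise ValueError("peptide must have length >= 2")
    by_seq: dict[str, set[Activity]] = {}
    for e in db:
        by_seq.setdefault(e.sequence, set()).add(e.activity)
    found: dict[tuple[str, Activity], int] = {}
    L = len(pep)
    for length in range(2, L):  # proper substrings only
        for start in range(L - length + 1):
            sub = pep[start : start + length]
            for act in by_seq.get(sub, ()):
                found.setdefault((sub, act), start + 1)
    return sorted(
        [(sub, act, start) for (sub, act), start in found.items()],
        key=lambda t: (t[2], len(t[0]), t[0], t[1].value),
    )
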