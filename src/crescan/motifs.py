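"""IUPAC degenerate motif scanning, motif clusters, and occurrence counting.

Scanning is exact set-membership per position (no position weight matrices):
a window matches when every base lies in the pattern position's allowed set.
An ``N`` in the *subject* sequence is treated as unknown and matches only a
fully degenerate (``N``) pattern position, so ambiguous sequence never
creates spurious hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV-", "TGCAANYRSWMKVHDB-")


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware; gaps pass through."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide pattern, e.g. TAATNN or YCCCNNGGGR."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("empty pattern")
        for ch in pat:
            if ch not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC character: {ch!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def position_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_SETS[c] for c in self.pattern)

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern(reverse_complement(self.pattern))

    @property
    def is_palindromic(self) -> bool:
        """True when the pattern equals its own reverse complement as a
        set of allowed words (position-set equality suffices)."""
        rc = self.reverse_complement()
        return self.position_sets == rc.position_sets

    def matches(self, window: str) -> bool:
        """Exact satisfaction: N in the window only matches a pattern N."""
        window = window.upper()
        if len(window) != len(self.pattern):
            return False
        for ch, allowed in zip(window, self.position_sets):
            if ch == "N":
                if len(allowed) != 4:
                    return False
            elif ch not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifMatch:
    """A located pattern hit; the footprint is always given on the forward
    coordinate system, and ``matched_sequence`` is read 5'->3' on the
    matching strand."""

    interval: GenomicInterval
    strand: str
    matched_sequence: str
    pattern: str


@dataclass(frozen=True)
class MotifCluster:
    """>= k matches whose first-start-to-last-end span fits in a window."""

    matches: tuple[MotifMatch, ...]
    span: int

    @property
    def interval(self) -> GenomicInterval:
        first = self.matches[0].interval
        return GenomicInterval(
            first.chrom,
            min(m.interval.start for m in self.matches),
            max(m.interval.end for m in self.matches),
        )


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, 255, dtype=np.uint8)
    for base, idx in _BASE_CODE.items():
        code[ord(base)] = idx
    enc = code[arr]
    if (enc == 255).any():
        bad = chr(arr[enc == 255][0])
        raise ValueError(f"invalid sequence character: {bad!r}")
    return enc


def _pattern_table(pattern: IUPACPattern) -> np.ndarray:
    """(L, 5) bool: table[j, b] = base b allowed at pattern position j.
    Code 4 (subject N) is allowed only where the pattern position is N."""
    table = np.zeros((len(pattern), 5), dtype=bool)
    for j, allowed in enumerate(pattern.position_sets):
        for base in allowed:
            table[j, _BASE_CODE[base]] = True
        table[j, 4] = len(allowed) == 4
    return table


def _scan_forward(enc: np.ndarray, pattern: IUPACPattern) -> np.ndarray:
    """Start offsets of forward-strand hits, ascending."""
    L = len(pattern)
    n = len(enc)
    if n < L:
        return np.empty(0, dtype=int)
    table = _pattern_table(pattern)
    valid = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        valid &= table[j][enc[j : j + n - L + 1]]
    return np.flatnonzero(valid)


def scan_iupac(
    seq: str,
    pattern: "IUPACPattern | str",
    strands: str = "both",
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifMatch]:
    """All pattern hits in ``seq`` on the requested strand(s).

    A minus-strand hit at footprint [i, i+L) means the reverse complement
    of that window satisfies the pattern.  Hits are sorted by footprint
    start ('+' before '-' on ties); a forward and a reverse hit with the
    same footprint are both reported.  ``offset`` shifts reported
    coordinates (for scanning subsequences in genome coordinates).
    """
    if strands not in ("forward", "reverse", "both"):
        raise ValueError(f"invalid strands: {strands!r}")
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    enc = _encode(seq)
    sequ = seq.upper()
    L = len(pattern)
    hits: list[MotifMatch] = []
    if strands in ("forward", "both"):
        for i in _scan_forward(enc, pattern).tolist():
            hits.append(
                MotifMatch(
                    GenomicInterval(chrom, offset + i, offset + i + L, "+"),
                    "+",
                    sequ[i : i + L],
                    pattern.pattern,
                )
            )
    if strands in ("reverse", "both"):
        # window satisfies pattern on '-' iff it satisfies revcomp(pattern) on '+'
        for i in _scan_forward(enc, pattern.reverse_complement()).tolist():
            hits.append(
                MotifMatch(
                    GenomicInterval(chrom, offset + i, offset + i + L, "-"),
                    "-",
                    reverse_complement(sequ[i : i + L]),
                    pattern.pattern,
                )
            )
    hits.sort(key=lambda m: (m.interval.start, m.strand))
    return hits


def dedupe_footprints(matches: Iterable[MotifMatch]) -> list[MotifMatch]:
    """Collapse matches sharing a footprint (e.g. palindromic patterns hit
    on both strands); the '+' representative is kept."""
    seen: dict[tuple[str, int, int], MotifMatch] = {}
    for m in sorted(matches, key=lambda m: (m.interval.start, m.strand)):
        key = (m.interval.chrom, m.interval.start, m.interval.end)
        seen.setdefault(key, m)
    return sorted(seen.values(), key=lambda m: (m.interval.start, m.strand))


def find_motif_clusters(
    matches: Sequence[MotifMatch],
    k: int,
    window: int,
    semantics: str = "span",
) -> list[MotifCluster]:
    """Maximal groups of >= k matches that fit within ``window``.

    ``semantics='span'`` (default): first footprint start to last footprint
    end <= window.  ``semantics='pairwise'``: every pair of footprint starts
    within ``window`` of each other.  Groups are maximal (no further match
    can be added without breaking the rule) and each is reported once, in
    coordinate order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if semantics not in ("span", "pairwise"):
        raise ValueError(f"invalid semantics: {semantics!r}")
    ms = sorted(matches, key=lambda m: (m.interval.start, m.interval.end))
    n = len(ms)
    if n == 0:
        return []
    starts = [m.interval.start for m in ms]
    # suffix max of ends makes span queries O(1) for contiguous groups
    ends = [m.interval.end for m in ms]
    clusters: list[MotifCluster] = []
    prev_j = -1
    for i in range(n):
        j = i
        max_end = ends[i]
        while j + 1 < n:
            cand_end = max(max_end, ends[j + 1])
            if semantics == "span":
                extent = cand_end - starts[i]
            else:
                extent = starts[j + 1] - starts[i]
            if extent <= window:
                j += 1
                max_end = cand_end
            else:
                break
        if j - i + 1 >= k and j > prev_j:
            span = max_end - starts[i]
            clusters.append(MotifCluster(tuple(ms[i : j + 1]), span))
            prev_j = j
    return clusters


def count_occurrences(
    seqs: Mapping[str, str],
    pattern: "IUPACPattern | str",
    strands: str = "both",
    cluster: "tuple[int, int] | None" = None,
    dedupe: bool = False,
) -> dict[str, int]:
    """Per-sequence counts of pattern hits, or of (k, window) cluster loci
    when ``cluster`` is given.  ``dedupe`` collapses same-footprint hits on
    opposite strands (relevant for self-reverse-complementary patterns)."""
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    out: dict[str, int] = {}
    for name, seq in seqs.items():
        hits = scan_iupac(seq, pattern, strands=strands, chrom=name)
        if dedupe:
            hits = dedupe_footprints(hits)
        if cluster is None:
            out[name] = len(hits)
        else:
            k, window = cluster
            out[name] = len(find_motif_clusters(hits, k, window))
    return out
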