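"""Shared ungapped homology blocks and exact-p-value motif database search.

Two tools live here.  ``find_shared_blocks`` discovers conserved sequence
blocks common to two candidate elements by exact k-mer seeding and ungapped
extension — the operation that surfaces a shared ~30 bp block between two
enhancers.  ``scan_database_with_qvalues`` asks whether such a block (as a
degenerate pattern or a fixed word with mismatches) occurs in a database of
other enhancer sequences, with exact single-window match probabilities
under a 0-order background, Bonferroni correction over scanned windows
within each target, and Benjamini-Hochberg q-values across targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .motifs import IUPACPattern, reverse_complement, scan_iupac


@dataclass(frozen=True)
class HomologyBlock:
    """An ungapped aligned pair of substrings shared by two sequences.

    ``strand`` is '+' when the block matches B on its forward strand, '-'
    when it matches the reverse complement of B (coordinates in B are still
    forward-strand).  ``score = identity * length``.
    """

    interval_in_a: GenomicInterval
    interval_in_b: GenomicInterval
    strand: str
    identity: float
    length: int
    seq_a: str
    seq_b: str

    @property
    def score(self) -> float:
        return self.identity * self.length


def find_shared_blocks(
    seq_a: str,
    seq_b: str,
    seed_len: int = 8,
    min_identity: float = 0.9,
    min_len: int = 30,
    both_strands: bool = True,
    name_a: str = "A",
    name_b: str = "B",
) -> list[HomologyBlock]:
    """Ungapped homology blocks shared by two sequences.

    Exact ``seed_len``-mer matches (optionally on both strands of B) are
    extended without gaps in both directions for as long as the running
    identity of the whole block stays at or above ``min_identity``; blocks
    shorter than ``min_len`` are dropped.  Blocks contained in another
    block on the same diagonal are deduplicated.  Output is sorted by
    descending score (identity x length), ties by coordinates.
    """
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    if seed_len > min_len:
        raise ValueError("seed_len must be <= min_len")
    a = seq_a.upper()
    blocks: list[HomologyBlock] = []
    seeds: dict[str, list[int]] = {}
    for i in range(len(a) - seed_len + 1):
        seeds.setdefault(a[i : i + seed_len], []).append(i)
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        b = seq_b.upper() if strand == "+" else reverse_complement(seq_b)
        # per-diagonal covered spans, to skip seeds inside found blocks
        covered: dict[int, list[tuple[int, int]]] = {}
        for j in range(len(b) - seed_len + 1):
            for i in seeds.get(b[j : j + seed_len], ()):
                diag = j - i
                if any(s <= i and i + seed_len <= e for s, e in covered.get(diag, ())):
                    continue
                ai, aj, matches = _extend(a, b, i, j, seed_len, min_identity)
                length = aj - ai
                covered.setdefault(diag, []).append((ai, aj))
                if length < min_len:
                    continue
                bi = ai + diag
                if strand == "+":
                    b_iv = GenomicInterval(name_b, bi, bi + length, "+")
                    b_sub = seq_b.upper()[bi : bi + length]
                else:
                    # map coordinates on revcomp(B) back to forward B
                    fb_start = len(seq_b) - (bi + length)
                    b_iv = GenomicInterval(name_b, fb_start, fb_start + length, "-")
                    b_sub = b[bi : bi + length]
                blocks.append(
                    HomologyBlock(
                        GenomicInterval(name_a, ai, ai + length, "+"),
                        b_iv,
                        strand,
                        matches / length,
                        length,
                        a[ai : ai + length],
                        b_sub,
                    )
                )
    blocks = _dedupe_blocks(blocks)
    blocks.sort(
        key=lambda blk: (
            -blk.score,
            blk.interval_in_a.start,
            blk.interval_in_b.start,
            blk.strand,
        )
    )
    return blocks


def _extend(
    a: str, b: str, i: int, j: int, seed_len: int, min_identity: float
) -> tuple[int, int, int]:
    """Greedy ungapped extension of an exact seed at (i, j).

    Extends one base at a time, right then left, keeping the block's
    running identity >= min_identity; returns (a_start, a_end, matches).
    """
    ai, aj = i, i + seed_len
    bi, bj = j, j + seed_len
    matches = seed_len
    moved = True
    while moved:
        moved = False
        if aj < len(a) and bj < len(b):
            m = matches + (a[aj] == b[bj])
            if m / (aj - ai + 1) >= min_identity:
                matches = m
                aj += 1
                bj += 1
                moved = True
        if ai > 0 and bi > 0:
            m = matches + (a[ai - 1] == b[bi - 1])
            if m / (aj - ai + 1) >= min_identity:
                matches = m
                ai -= 1
                bi -= 1
                moved = True
    # trim flanking mismatches so blocks start/end on a match
    while aj > ai and a[aj - 1] != b[bj - 1]:
        aj -= 1
        bj -= 1
    while ai < aj and a[ai] != b[bi]:
        ai += 1
        bi += 1
    return ai, aj, matches


def _dedupe_blocks(blocks: list[HomologyBlock]) -> list[HomologyBlock]:
    """Drop blocks contained in a longer block on the same diagonal/strand."""
    out: list[HomologyBlock] = []
    for blk in sorted(blocks, key=lambda b: -b.length):
        diag = blk.interval_in_b.start - blk.interval_in_a.start
        contained = False
        for kept in out:
            if (
                kept.strand == blk.strand
                and kept.interval_in_b.start - kept.interval_in_a.start == diag
                and kept.interval_in_a.start <= blk.interval_in_a.start
                and blk.interval_in_a.end <= kept.interval_in_a.end
            ):
                contained = True
                break
        if not contained:
            out.append(blk)
    return out


# ---------------------------------------------------------------------------
# exact match probabilities and FDR-controlled database search
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def estimate_background(seqs: Mapping[str, str]) -> dict[str, float]:
    """0-order base frequencies pooled over a sequence set (Ns ignored);
    uniform when the set is empty."""
    counts = {b: 0 for b in _BASES}
    for seq in seqs.values():
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        return {b: 0.25 for b in _BASES}
    return {b: counts[b] / total for b in _BASES}


def iupac_match_pvalue(
    pattern: "IUPACPattern | str",
    background: "Mapping[str, float] | None" = None,
) -> float:
    """Probability that one random background window satisfies the pattern.

    Positions are independent under the 0-order background, so the
    probability is the product over positions of the summed frequencies of
    the allowed bases.
    """
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    bg = dict(background) if background is not None else {b: 0.25 for b in _BASES}
    if any(v < 0 for v in bg.values()):
        raise ValueError("negative background frequency")
    total = sum(bg.get(b, 0.0) for b in _BASES)
    if not np.isclose(total, 1.0):
        raise ValueError(f"background frequencies sum to {total}, not 1")
    p = 1.0
    for allowed in pattern.position_sets:
        p *= sum(bg.get(b, 0.0) for b in allowed)
    return p


def match_count_tail_pvalue(
    query: str,
    n_matches: int,
    background: Mapping[str, float],
) -> float:
    """P(#matching positions >= n_matches) for a fixed query word against
    one random background window (Poisson-binomial tail, exact DP)."""
    qs = [background.get(b, 0.0) for b in query.upper()]
    dist = np.zeros(len(qs) + 1)
    dist[0] = 1.0
    for q in qs:
        dist[1:] = dist[1:] * (1 - q) + dist[:-1] * q
        dist[0] *= 1 - q
    return float(dist[max(0, n_matches) :].sum())


@dataclass(frozen=True)
class ScoredMatch:
    """Best hit of a query in one database target with multiplicity-
    corrected p-value and BH q-value across targets."""

    target: str
    offset: int
    strand: str
    score: float
    n_windows: int
    p_value: float
    q_value: float


def scan_database_with_qvalues(
    query: "IUPACPattern | str",
    database: Mapping[str, str],
    background: "Mapping[str, float] | None" = None,
    max_mismatches: "int | None" = None,
    strands: str = "both",
) -> list[ScoredMatch]:
    """Search a query motif against every database sequence with FDR control.

    Two query modes:

    * degenerate mode (default): the query is an IUPAC pattern; a window
      either satisfies it or not, with exact per-window probability from
      :func:`iupac_match_pvalue`.
    * mismatch mode (``max_mismatches`` given): the query is a fixed word
      and the best window is the one with the most matching positions (at
      least ``len(query) - max_mismatches``); its tail probability is the
      exact Poisson-binomial P(matches >= observed).

    Per target, the per-window p-value is Bonferroni-corrected by the number
    of windows scanned (both strands counted); q-values are BH across
    targets.  Output sorted by (q, p, target).
    """
    if not database:
        return []
    bg = dict(background) if background is not None else estimate_background(database)
    if isinstance(query, IUPACPattern) or max_mismatches is None:
        pattern = query if isinstance(query, IUPACPattern) else IUPACPattern(query)
        rows = [
            _scan_target_iupac(pattern, name, seq, bg, strands)
            for name, seq in database.items()
        ]
    else:
        rows = [
            _scan_target_mismatch(str(query), name, seq, bg, max_mismatches, strands)
            for name, seq in database.items()
        ]
    pvals = [r[4] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        ScoredMatch(name, offset, strand, score, nwin, p, float(q))
        for (name, offset, strand, score, p, nwin), q in zip(rows, qvals)
    ]
    out.sort(key=lambda s: (s.q_value, s.p_value, s.target))
    return out


def _n_windows(seq_len: int, qlen: int, strands: str) -> int:
    per_strand = max(0, seq_len - qlen + 1)
    return per_strand * (2 if strands == "both" else 1)


def _scan_target_iupac(pattern, name, seq, bg, strands):
    nwin = _n_windows(len(seq), len(pattern), strands)
    hits = scan_iupac(seq, pattern, strands=strands, chrom=name) if nwin else []
    p_window = iupac_match_pvalue(pattern, bg)
    if hits:
        best = hits[0]
        score = _log_odds(best.matched_sequence, pattern, bg)
        p = min(1.0, nwin * p_window)
        return (name, best.interval.start, best.strand, score, p, nwin)
    return (name, -1, ".", 0.0, 1.0, nwin)


def _window_match_counts(seq: str, query: str) -> np.ndarray:
    """Matching-position count of the query against every window of seq."""
    qlen = len(query)
    s = np.frombuffer(seq.encode(), dtype="S1")
    q = np.frombuffer(query.encode(), dtype="S1")
    n = len(s) - qlen + 1
    counts = np.zeros(n, dtype=np.int32)
    for j in range(qlen):
        counts += s[j : j + n] == q[j]
    return counts


def _scan_target_mismatch(query, name, seq, bg, max_mismatches, strands):
    qlen = len(query)
    nwin = _n_windows(len(seq), qlen, strands)
    if nwin == 0:
        return (name, -1, ".", 0.0, 1.0, 0)
    query = query.upper()
    best = (-1, -1, ".")  # (n_matches, offset, strand)
    variants = [("+", seq.upper())]
    if strands == "both":
        variants.append(("-", reverse_complement(seq)))
    for strand, s in variants:
        counts = _window_match_counts(s, query)
        off = int(np.argmax(counts))
        m = int(counts[off])
        fwd_off = off if strand == "+" else len(seq) - (off + qlen)
        if m > best[0]:
            best = (m, fwd_off, strand)
    n_matches, offset, strand = best
    if n_matches < qlen - max_mismatches:
        return (name, -1, ".", 0.0, 1.0, nwin)
    p_window = match_count_tail_pvalue(query, n_matches, bg)
    p = min(1.0, nwin * p_window)
    # log-odds: matched positions contribute -log2(bg base freq), mismatches 0
    s_full = seq.upper() if strand == "+" else reverse_complement(seq)
    off_local = offset if strand == "+" else len(seq) - (offset + qlen)
    window = s_full[off_local : off_local + qlen]
    score = float(
        sum(
            -np.log2(max(bg.get(qb, 0.0), 1e-300))
            for qb, wb in zip(query, window)
            if qb == wb
        )
    )
    return (name, offset, strand, score, p, nwin)


def _log_odds(window: str, pattern: IUPACPattern, bg: Mapping[str, float]) -> float:
    """log2 odds of the matched window under a uniform-over-allowed-bases
    motif model vs the 0-order background."""
    score = 0.0
    for ch, allowed in zip(window.upper(), pattern.position_sets):
        p_model = 1.0 / len(allowed)
        p_bg = max(bg.get(ch, 0.0), 1e-300)
        score += np.log2(p_model / p_bg)
    return float(score)
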