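"""Per-base conservation tracks, percent-identity profiles, and segment calling.

Conservation evidence enters the pipeline either as an externally computed
per-base score track (phyloP-style) or as a percent-identity profile computed
here from a pairwise alignment, in the spirit of classic percent-identity
plots.  The phyloP statistic itself is never recomputed; tracks are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval


@dataclass
class ConservationTrack:
    """A contiguous span of per-base scores on one chromosome.

    ``scores[i]`` is the score of base ``start + i``.  Bases without
    coverage are NaN, never silently 0.
    """

    chrom: str
    start: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")

    @property
    def end(self) -> int:
        return self.start + len(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        """Scores over an interval; bases outside coverage come back NaN."""
        out = np.full(len(iv), np.nan)
        lo = max(iv.start, self.start)
        hi = min(iv.end, self.end)
        if hi > lo:
            out[lo - iv.start : hi - iv.start] = self.scores[
                lo - self.start : hi - self.start
            ]
        return out

    def smoothed(self, window: int) -> "ConservationTrack":
        """Clamped centered rolling mean (NaN-aware); window 1 is a no-op."""
        if window <= 1:
            return ConservationTrack(self.chrom, self.start, self.scores.copy())
        return ConservationTrack(
            self.chrom, self.start, _clamped_rolling_mean(self.scores, window)
        )


def _clamped_rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Rolling mean over windows of fixed length ``window``, with windows near
    the edges shifted inward (clamped) rather than shrunk, so every position
    is averaged over exactly ``min(window, n)`` bases.  NaNs are ignored in
    each window's mean (all-NaN windows stay NaN)."""
    n = len(values)
    if n == 0:
        return values.copy()
    w = min(window, n)
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccount = np.concatenate(([0], np.cumsum(finite)))
    centers = np.arange(n)
    starts = np.clip(centers - (w - 1) // 2, 0, n - w)
    sums = csum[starts + w] - csum[starts]
    counts = ccount[starts + w] - ccount[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length over {A,C,G,T,N,-}."""

    ref: str
    other: str
    ref_name: str = "ref"
    other_name: str = "other"

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.other = self.other.upper()
        if len(self.ref) != len(self.other):
            raise ValueError("alignment rows must have equal length")
        for a, b in zip(self.ref, self.other):
            if a == "-" and b == "-":
                raise ValueError("column gapped in both rows")

    @property
    def ref_ungapped_length(self) -> int:
        return len(self.ref) - self.ref.count("-")


@dataclass(frozen=True)
class ConservedSegment:
    """A called run of conserved bases with its score summary."""

    interval: GenomicInterval
    mean_score: float
    max_score: float


def percent_identity_profile(
    aln: PairwiseAlignment, window: int
) -> ConservationTrack:
    """Windowed percent identity along the reference, one value per
    reference base.

    Columns where the reference is gapped carry no score and are excluded
    from both numerator and denominator; within a window, a column counts
    as identical only when the other row carries the same (non-gap) base.
    Windows near the sequence ends are clamped to stay fully inside the
    profile, so every position is scored over exactly ``window`` reference
    bases (or the whole profile if it is shorter).  Values are in [0, 100].
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ref_cols = np.frombuffer(aln.ref.encode(), dtype="S1")
    oth_cols = np.frombuffer(aln.other.encode(), dtype="S1")
    keep = ref_cols != b"-"
    if not keep.any():
        raise ValueError("empty alignment: reference row is all gaps")
    ref_b = ref_cols[keep]
    oth_b = oth_cols[keep]
    ident = ((ref_b == oth_b) & (oth_b != b"-")).astype(float)
    if window > len(ident):
        raise ValueError(
            f"window {window} exceeds reference ungapped length {len(ident)}"
        )
    profile = _clamped_rolling_mean(ident, window) * 100.0
    return ConservationTrack(aln.ref_name, 0, profile)


def call_conserved_segments(
    track: ConservationTrack,
    threshold: float,
    min_len: int = 50,
    merge_gap: int = 20,
) -> list[ConservedSegment]:
    """Threshold a track into conserved segments.

    Maximal runs of bases with ``score >= threshold`` are found; runs
    separated by at most ``merge_gap`` sub-threshold (or uncovered) bases
    are merged; merged runs shorter than ``min_len`` are discarded.
    Segment score summaries are computed over covered bases only.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    above = np.zeros(len(track.scores), dtype=bool)
    finite = np.isfinite(track.scores)
    above[finite] = track.scores[finite] >= threshold
    runs = _bool_runs(above)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out: list[ConservedSegment] = []
    for s, e in merged:
        if e - s < min_len:
            continue
        seg = track.scores[s:e]
        seg = seg[np.isfinite(seg)]
        out.append(
            ConservedSegment(
                GenomicInterval(track.chrom, track.start + s, track.start + e),
                float(seg.mean()),
                float(seg.max()),
            )
        )
    return out


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if len(mask) == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
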