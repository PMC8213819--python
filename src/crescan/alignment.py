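"""Multi-species alignments: coordinate projection and motif conservation.

Decides whether a motif instance found in a reference species is
phylogenetically conserved by asking, for each aligned species, whether the
homologous (gap-stripped) window still satisfies the degenerate pattern.
Support is binary per species — no partial credit — which mirrors how
conserved transcription-factor sites are usually called by eye from an
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import IUPACPattern, MotifMatch, reverse_complement, scan_iupac


@dataclass
class MultiAlignment:
    """Equal-length gapped rows over named species, one of which is the
    reference whose ungapped coordinates anchor all motif positions."""

    species: list[str]
    rows: list[str]
    reference: str

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rows):
            raise ValueError("species and rows must have equal length")
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows must have equal length")
        if self.reference not in self.species:
            raise ValueError(f"reference {self.reference!r} not among species")
        self.rows = [r.upper() for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def reference_index(self) -> int:
        return self.species.index(self.reference)

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_index]

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    @property
    def reference_sequence(self) -> str:
        return self.reference_row.replace("-", "")

    def _ref_columns(self) -> np.ndarray:
        return np.flatnonzero(
            np.frombuffer(self.reference_row.encode(), dtype="S1") != b"-"
        )

    def slice_columns(self, col_start: int, col_end: int) -> "MultiAlignment":
        return MultiAlignment(
            list(self.species),
            [r[col_start:col_end] for r in self.rows],
            self.reference,
        )

    def slice_reference(self, pos_start: int, pos_end: int) -> "MultiAlignment":
        """Sub-alignment covering reference positions [pos_start, pos_end)."""
        if pos_start >= pos_end:
            raise ValueError("empty reference slice")
        c0 = project_position(self, pos_start)
        c1 = project_position(self, pos_end - 1) + 1
        return self.slice_columns(c0, c1)


def project_position(aln: MultiAlignment, pos: int) -> int:
    """Alignment column holding the ``pos``-th non-gap reference character."""
    cols = aln._ref_columns()
    if pos < 0 or pos >= len(cols):
        raise IndexError(
            f"reference position {pos} out of range [0, {len(cols)})"
        )
    return int(cols[pos])


def column_to_position(aln: MultiAlignment, col: int) -> int:
    """Inverse of :func:`project_position`; errors on reference-gap columns."""
    if col < 0 or col >= aln.width:
        raise IndexError(f"column {col} out of range [0, {aln.width})")
    if aln.reference_row[col] == "-":
        raise ValueError(f"column {col} is a gap in the reference row")
    row = np.frombuffer(aln.reference_row.encode(), dtype="S1")
    return int(np.count_nonzero(row[:col] != b"-"))


@dataclass(frozen=True)
class ConservedMotifInstance:
    """A reference motif hit together with the species that retain it."""

    match: MotifMatch
    supporting_species: tuple[str, ...]
    support_fraction: float


def conserved_motif_instances(
    aln: MultiAlignment,
    pattern: "IUPACPattern | str",
    min_support: float = 0.8,
    exact_variant: bool = False,
    strands: str = "forward",
) -> list[ConservedMotifInstance]:
    """Reference-strand motif hits whose homologous windows satisfy the
    pattern in at least ``min_support`` of the aligned species.

    For each reference hit, every species' aligned window is the set of
    alignment columns under the footprint with gaps dropped; the species
    supports the instance only if that window has the pattern's length and
    satisfies it exactly (``exact_variant=True`` additionally requires the
    identical word the reference carries).  The reference always supports
    its own hit; ``support_fraction`` is over all species including the
    reference.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    ref_seq = aln.reference_sequence
    cols = aln._ref_columns()
    out: list[ConservedMotifInstance] = []
    for match in scan_iupac(ref_seq, pattern, strands=strands, chrom=aln.reference):
        c0 = int(cols[match.interval.start])
        c1 = int(cols[match.interval.end - 1]) + 1
        supporting: list[str] = []
        for sp, row in zip(aln.species, aln.rows):
            window = row[c0:c1].replace("-", "")
            if match.strand == "-":
                window = reverse_complement(window)
            if sp == aln.reference:
                supporting.append(sp)
                continue
            if exact_variant:
                ok = window == match.matched_sequence
            else:
                ok = pattern.matches(window)
            if ok:
                supporting.append(sp)
        fraction = len(supporting) / aln.n_species
        if fraction >= min_support:
            out.append(
                ConservedMotifInstance(match, tuple(supporting), fraction)
            )
    return out
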