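"""The integrated enhancer-candidate caller.

One operation reproduces the discovery procedure end to end: bases of a
gene cluster that are (1) conserved, (2) intergenic, and (3) non-repetitive
are segmented into candidate elements, which are then annotated with their
degenerate-motif content (homeodomain TAATNN sites, extended HD words,
O/E-like YCCCNNGGGR sites, and k-within-window motif clusters such as a
TAATGA triad), with cross-species motif conservation when an alignment is
supplied, and ranked deterministically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .alignment import MultiAlignment, conserved_motif_instances
from .conservation import ConservationTrack, call_conserved_segments
from .intervals import (
    AnnotationSet,
    GenomicInterval,
    MaskTrack,
    format_interval,
    intergenic_regions,
    subtract_intervals,
    subtract_mask,
)
from .motifs import (
    IUPACPattern,
    dedupe_footprints,
    find_motif_clusters,
    scan_iupac,
)


@dataclass
class PipelineConfig:
    """Every knob of a discovery run; serializable so that a config + inputs
    fully determine the output.

    Conservation: the track is smoothed with a ``smooth_window`` bp clamped
    rolling mean, then thresholded.  The default threshold is robust —
    median + ``conservation_mad_k`` scaled MADs of the smoothed track — so
    it adapts to the track's noise level rather than marking a fixed
    fraction of bases; a percentile rule (``conservation_mode =
    'percentile'``) and an absolute cutoff (``conservation_absolute``) are
    available as overrides.
    """

    bounds: "str | None" = None  # "chrom:start-end" in bounds_convention
    bounds_convention: str = "zero_based_half_open"
    conservation_mode: str = "mad"  # mad | percentile
    conservation_mad_k: float = 6.0
    conservation_percentile: float = 99.0
    conservation_absolute: "float | None" = None
    smooth_window: int = 25
    min_len: int = 50
    merge_gap: int = 20
    hd_pattern: str = "TAATNN"
    hd_extended_pattern: str = "CTTTTTAATGA"
    oe_pattern: str = "YCCCNNGGGR"
    cluster_pattern: str = "TAATGA"
    cluster_k: int = 3
    cluster_window: int = 206
    min_support: float = 0.8
    require_hd: bool = False
    output_convention: str = "zero_based_half_open"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class CandidateElement:
    """A called candidate element with its evidence."""

    interval: GenomicInterval
    mean_conservation: float
    max_conservation: float
    hd_count_forward: int
    hd_count_both: int
    conserved_hd_count: "int | None"
    oe_count: int
    cluster_hits: int
    filters: dict = field(default_factory=dict)

    @property
    def rank_key(self) -> tuple:
        chd = -1 if self.conserved_hd_count is None else self.conserved_hd_count
        return (-chd, -self.mean_conservation, self.interval.start)


def call_candidates(
    genome: Mapping[str, str],
    ann: AnnotationSet,
    mask: MaskTrack,
    track: ConservationTrack,
    bounds: GenomicInterval,
    aln: "MultiAlignment | None" = None,
    cfg: "PipelineConfig | None" = None,
) -> list[CandidateElement]:
    """Run the three-filter discovery procedure and annotate motif content.

    ``aln``, when given, must be an alignment whose reference ungapped
    coordinates coincide with ``bounds.chrom`` genome coordinates (as the
    ortholog simulator produces); it supplies the conserved-HD counts.
    Candidate boundaries are conserved-segment boundaries clipped to the
    intergenic, unmasked search space; clipped pieces shorter than
    ``cfg.min_len`` are dropped.
    """
    cfg = cfg or PipelineConfig()
    if bounds.chrom not in genome:
        raise ValueError(f"bounds chromosome {bounds.chrom!r} not in genome")
    seq = genome[bounds.chrom]

    smoothed = track.smoothed(cfg.smooth_window)
    if cfg.conservation_absolute is not None:
        threshold = cfg.conservation_absolute
    else:
        finite = smoothed.scores[np.isfinite(smoothed.scores)]
        if len(finite) == 0:
            raise ValueError("conservation track has no covered bases")
        if cfg.conservation_mode == "percentile":
            threshold = float(
                np.percentile(finite, cfg.conservation_percentile)
            )
        elif cfg.conservation_mode == "mad":
            med = float(np.median(finite))
            mad = float(np.median(np.abs(finite - med))) * 1.4826
            threshold = med + cfg.conservation_mad_k * mad
        else:
            raise ValueError(
                f"unknown conservation_mode: {cfg.conservation_mode!r}"
            )
    segments = call_conserved_segments(
        smoothed, threshold, min_len=cfg.min_len, merge_gap=cfg.merge_gap
    )

    intergenic = intergenic_regions(ann, bounds)
    allowed = subtract_mask(intergenic, mask)

    candidates: list[CandidateElement] = []
    for seg in segments:
        pieces = subtract_intervals(
            [seg.interval],
            _complement_list(allowed, bounds),
        )
        for piece in pieces:
            if len(piece) < cfg.min_len:
                continue
            candidates.append(
                _annotate(piece, seq, track, aln, cfg, seg_interval=seg.interval)
            )
    if cfg.require_hd:
        candidates = [c for c in candidates if c.hd_count_both > 0]
    candidates.sort(key=lambda c: c.rank_key)
    return candidates


def _complement_list(allowed, bounds):
    """Intervals of ``bounds`` NOT in the allowed list (for subtraction)."""
    return subtract_intervals([bounds], allowed)


def _annotate(
    piece: GenomicInterval,
    seq: str,
    track: ConservationTrack,
    aln: "MultiAlignment | None",
    cfg: PipelineConfig,
    seg_interval: GenomicInterval,
) -> CandidateElement:
    sub = seq[piece.start : piece.end]
    hd = IUPACPattern(cfg.hd_pattern)
    oe = IUPACPattern(cfg.oe_pattern)
    hd_fwd = scan_iupac(sub, hd, strands="forward", chrom=piece.chrom,
                        offset=piece.start)
    hd_both = scan_iupac(sub, hd, strands="both", chrom=piece.chrom,
                         offset=piece.start)
    oe_hits = dedupe_footprints(
        scan_iupac(sub, oe, strands="both", chrom=piece.chrom, offset=piece.start)
    )
    cluster_hits = find_motif_clusters(
        scan_iupac(sub, IUPACPattern(cfg.cluster_pattern), strands="both",
                   chrom=piece.chrom, offset=piece.start),
        cfg.cluster_k,
        cfg.cluster_window,
    )
    conserved_hd: "int | None" = None
    if aln is not None:
        sub_aln = aln.slice_reference(piece.start, piece.end)
        conserved_hd = len(
            conserved_motif_instances(sub_aln, hd, min_support=cfg.min_support)
        )
    scores = track.slice(piece)
    scores = scores[np.isfinite(scores)]
    mean_c = float(scores.mean()) if len(scores) else float("nan")
    max_c = float(scores.max()) if len(scores) else float("nan")
    return CandidateElement(
        interval=piece,
        mean_conservation=mean_c,
        max_conservation=max_c,
        hd_count_forward=len(hd_fwd),
        hd_count_both=len(hd_both),
        conserved_hd_count=conserved_hd,
        oe_count=len(oe_hits),
        cluster_hits=len(cluster_hits),
        filters={
            "conserved_segment": [seg_interval.start, seg_interval.end],
            "intergenic": True,
            "non_repetitive": True,
        },
    )


def report(
    candidates: "list[CandidateElement]",
    cfg: "PipelineConfig | None" = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-candidate table plus a machine-readable dict (config echoed).

    The dict is JSON-serializable and byte-stable for fixed inputs, so runs
    can be diffed.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for rank, c in enumerate(candidates, 1):
        rows.append(
            {
                "rank": rank,
                "coords": format_interval(c.interval, cfg.output_convention),
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "length_bp": len(c.interval),
                "mean_conservation": round(c.mean_conservation, 6),
                "max_conservation": round(c.max_conservation, 6),
                "hd_forward": c.hd_count_forward,
                "hd_both": c.hd_count_both,
                "conserved_hd": c.conserved_hd_count,
                "oe_sites": c.oe_count,
                "cluster_hits": c.cluster_hits,
            }
        )
    columns = [
        "rank", "coords", "chrom", "start", "end", "length_bp",
        "mean_conservation", "max_conservation", "hd_forward", "hd_both",
        "conserved_hd", "oe_sites", "cluster_hits",
    ]
    df = pd.DataFrame(rows, columns=columns)
    machine = {
        "config": cfg.to_dict(),
        "n_candidates": len(candidates),
        "candidates": rows,
    }
    return df, machine


def report_json(machine: dict) -> str:
    return json.dumps(machine, indent=2, sort_keys=True)
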