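"""Readers and writers for the standard text formats the pipeline consumes.

FASTA goes through Biopython; BED and bedGraph through pandas.  The GFF3
subset handled here (gene / pseudogene features with mRNA + exon children)
is read and written directly and round-trip tested against the writer.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence
from urllib.parse import quote, unquote

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import MultiAlignment
from .conservation import ConservationTrack
from .intervals import AnnotationSet, GeneModel, GenomicInterval, MaskTrack


# --------------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    """Name -> sequence (uppercased); order preserved."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment_fasta(path, reference: "str | None" = None) -> MultiAlignment:
    """Aligned FASTA -> MultiAlignment; the first record is the reference
    unless one is named."""
    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"no records in {path}")
    species = list(seqs)
    return MultiAlignment(species, [seqs[s] for s in species],
                          reference or species[0])


def write_alignment_fasta(aln: MultiAlignment, path) -> None:
    write_fasta(dict(zip(aln.species, aln.rows)), path)


# ----------------------------------------------------------------------- BED


def read_bed(path, chrom: "str | None" = None) -> list[GenomicInterval]:
    """BED3+ -> intervals (0-based half-open, as BED is defined)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    ivs = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in df.itertuples(index=False)
        if chrom is None or r.chrom == chrom
    ]
    return sorted(ivs)


def write_bed(
    intervals: Iterable[GenomicInterval], path, names: "Sequence[str] | None" = None
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields += [names[i], "0", iv.strand if iv.strand != "." else "+"]
            fh.write("\t".join(fields) + "\n")


def read_mask_bed(path, chrom: "str | None" = None) -> MaskTrack:
    return MaskTrack(read_bed(path, chrom=chrom), source=str(path))


# ---------------------------------------------------------------------- GFF3


def read_gff3(path) -> AnnotationSet:
    """Parse gene/pseudogene features (with optional mRNA/exon children)
    into an AnnotationSet.  GFF3 is 1-based fully closed; coordinates are
    converted on read."""
    genes: dict[str, GeneModel] = {}
    transcript_parent: dict[str, str] = {}
    exon_rows: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            iv = GenomicInterval(
                chrom, int(start) - 1, int(end), strand if strand in "+-" else "."
            )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = unquote(attr.get("ID", ""))
            parent = unquote(attr.get("Parent", ""))
            if ftype in ("gene", "pseudogene"):
                biotype = attr.get(
                    "biotype",
                    "pseudogene" if ftype == "pseudogene" else "protein_coding",
                )
                genes[fid] = GeneModel(fid or f"gene{len(genes)}", biotype, iv)
            elif ftype in ("mRNA", "transcript", "pseudogenic_transcript"):
                transcript_parent[fid] = parent
            elif ftype == "exon":
                gene_id = transcript_parent.get(parent, parent)
                exon_rows.append((gene_id, iv))
    for gene_id, exon in exon_rows:
        if gene_id in genes:
            genes[gene_id].exons.append(exon)
    for g in genes.values():
        g.exons.sort()
    return AnnotationSet(list(genes.values()), source=str(path))


def write_gff3(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            t = g.transcript
            strand = t.strand if t.strand != "." else "+"
            ftype = "pseudogene" if g.biotype == "pseudogene" else "gene"
            fh.write(
                "\t".join(
                    [
                        t.chrom, "crescan", ftype, str(t.start + 1), str(t.end),
                        ".", strand, ".",
                        f"ID={quote(g.gene_id)};biotype={g.biotype}",
                    ]
                )
                + "\n"
            )
            if g.exons:
                tid = f"{g.gene_id}.t1"
                fh.write(
                    "\t".join(
                        [
                            t.chrom, "crescan", "mRNA", str(t.start + 1),
                            str(t.end), ".", strand, ".",
                            f"ID={quote(tid)};Parent={quote(g.gene_id)}",
                        ]
                    )
                    + "\n"
                )
                for i, ex in enumerate(g.exons, 1):
                    fh.write(
                        "\t".join(
                            [
                                ex.chrom, "crescan", "exon", str(ex.start + 1),
                                str(ex.end), ".", strand, ".",
                                f"ID={quote(tid)}.e{i};Parent={quote(tid)}",
                            ]
                        )
                        + "\n"
                    )


# ------------------------------------------------------------ score tracks


def read_bedgraph(path, chrom: "str | None" = None) -> ConservationTrack:
    """bedGraph -> per-base track; uncovered bases inside the span are NaN."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str, "start": int, "end": int, "score": float},
        skiprows=_bedgraph_header_rows(path),
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    if df.empty:
        raise ValueError(f"no bedGraph records in {path}")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"multiple chromosomes in track: {list(chroms)}")
    start = int(df["start"].min())
    end = int(df["end"].max())
    scores = np.full(end - start, np.nan)
    for r in df.itertuples(index=False):
        scores[r.start - start : r.end - start] = r.score
    return ConservationTrack(str(chroms[0]), start, scores)


def _bedgraph_header_rows(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(track: ConservationTrack, path, precision: int = 6) -> None:
    """Per-base track -> bedGraph with equal-score runs collapsed; NaN
    (uncovered) bases are omitted."""
    with open(path, "w") as fh:
        scores = track.scores
        i = 0
        n = len(scores)
        while i < n:
            if not np.isfinite(scores[i]):
                i += 1
                continue
            j = i + 1
            while j < n and np.isfinite(scores[j]) and scores[j] == scores[i]:
                j += 1
            fh.write(
                f"{track.chrom}\t{track.start + i}\t{track.start + j}\t"
                f"{round(float(scores[i]), precision):g}\n"
            )
            i = j


def read_wiggle(path) -> ConservationTrack:
    """fixedStep / variableStep wiggle (span=1) -> per-base track."""
    chrom = None
    mode = None
    step = span = 1
    pos = None
    values: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                mode = line.split()[0]
                chrom = fields["chrom"]
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                if span != 1:
                    raise ValueError("only span=1 wiggle is supported")
                if mode == "fixedStep":
                    pos = int(fields["start"]) - 1  # wiggle is 1-based
                continue
            if mode == "fixedStep":
                values[pos] = float(line)
                pos += step
            elif mode == "variableStep":
                p, v = line.split()
                values[int(p) - 1] = float(v)
            else:
                raise ValueError(f"value line before wiggle header: {line!r}")
    if not values:
        raise ValueError(f"no wiggle values in {path}")
    start = min(values)
    end = max(values) + 1
    scores = np.full(end - start, np.nan)
    for p, v in values.items():
        scores[p - start] = v
    return ConservationTrack(chrom, start, scores)


def read_track(path) -> ConservationTrack:
    """Dispatch on content: wiggle if a step header is present, else bedGraph."""
    with open(path) as fh:
        for line in fh:
            if line.startswith(("fixedStep", "variableStep")):
                return read_wiggle(path)
            if line.strip() and not line.startswith(("track", "browser", "#")):
                break
    return read_bedgraph(path)


# ------------------------------------------------------------- motif files


def read_motif_file(path) -> dict[str, str]:
    """Plain-text motif list: one 'name IUPAC' pair per line ('#' comments)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                out[parts[0]] = parts[0]
            else:
                out[parts[0]] = parts[1]
    return out
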