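"""Synthetic study generator: gene cluster, orthologs, conservation, qPCR.

Emulates the structure of a ~200 kb olfactory receptor-family gene cluster:
15 intact two-exon genes plus a pseudogene fragment, two intergenic
enhancer-like elements carrying planted homeodomain (TAATNN) sites — one
element with a TAATGA triad inside a 206 bp span — O/E-like sites, and a
shared ~30 bp homology block present in both elements; repeat-masked
intervals; orthologous sequences across 16 species with elevated
conservation inside the elements; and qPCR Ct tables with housekeeping
genes and genotype-dependent fold changes.  Every planted feature is
recorded in a truth object so downstream calls can be checked closed-loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import MultiAlignment
from .conservation import ConservationTrack
from .intervals import AnnotationSet, GeneModel, GenomicInterval, MaskTrack
from .motifs import reverse_complement, scan_iupac

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: constant 30 bp shared block: the two tandem words plus fixed flanks
SHARED_BLOCK = "G" + "TTGCATCA" + "TAAAGTTTTC" + "ACGGTCATTCG"
assert len(SHARED_BLOCK) == 30

#: the four HD words designated as phylogenetically conserved in element 1
ELEMENT1_CONSERVED_HD = ("TAATAG", "TAATGA", "TAATTA", "TAATCA")
#: element 2 carries one conserved TAATCC plus a TAATGA triad
ELEMENT2_CONSERVED_HD = ("TAATCC", "TAATGA", "TAATGA", "TAATGA")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated cluster."""

    chrom: str
    cluster_len: int
    elements: list[dict] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)
    shared_block: dict = field(default_factory=dict)
    seed: "int | None" = None
    config: dict = field(default_factory=dict)

    def element_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, e["start"], e["end"])
            for e in self.elements
        ]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedCluster:
    chrom: str
    sequence: str
    annotation: AnnotationSet
    mask: MaskTrack
    truth: PlantedTruth

    @property
    def bounds(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, 0, len(self.sequence))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    from .motifs import IUPAC_SETS

    return "".join(
        rng.choice(sorted(IUPAC_SETS[c])) if len(IUPAC_SETS[c]) > 1 else c
        for c in pattern.upper()
    )


def _build_element(
    rng: np.random.Generator,
    length: int,
    hd_plan: Sequence[tuple[int, "str | None", bool]],
    oe_offsets: Sequence[int],
    block_offset: int,
) -> tuple[str, list[dict]]:
    """Element sequence with planted motifs; returns (seq, motif records).

    ``hd_plan`` is (offset, word, frozen) per HD site; ``word=None`` draws a
    random TAATNN variant other than TAATGA (so no accidental extra triad
    copies arise).  Motif records carry element-relative offsets; 'frozen'
    marks instances the ortholog simulator must keep substitution-free.
    """
    seq = list(_random_seq(rng, length))
    records: list[dict] = []

    def plant(offset: int, word: str, kind: str, frozen: bool) -> None:
        if offset + len(word) > length:
            raise ValueError("infeasible packing: motif exceeds element")
        seq[offset : offset + len(word)] = list(word)
        records.append(
            {"kind": kind, "word": word, "offset": offset,
             "strand": "+", "frozen": frozen}
        )

    plant(block_offset, SHARED_BLOCK, "shared_block", True)
    for offset, word, frozen in hd_plan:
        if word is None:
            nn = "GA"
            while nn == "GA":
                nn = _instantiate_iupac(rng, "NN")
            word = "TAAT" + nn
        plant(offset, word, "hd", frozen)
    for offset in oe_offsets:
        plant(offset, _instantiate_iupac(rng, "YCCCNNGGGR"), "oe", False)
    return "".join(seq), records


def _scrub_pattern(
    rng: np.random.Generator,
    seq: list,
    pattern: "str | list[tuple[str, str]]",
    keep: list[tuple[int, int]],
    strands: str = "both",
    max_rounds: int = 20,
) -> None:
    """Mutate accidental pattern hits (outside ``keep`` footprints) until
    none remain; keeps recorded truth exact.  ``pattern`` may be a list of
    (pattern, strands) pairs scrubbed jointly, so fixing one cannot
    silently reintroduce another."""
    specs = pattern if isinstance(pattern, list) else [(pattern, strands)]
    for _ in range(max_rounds):
        text = "".join(seq)
        hits = [
            m
            for pat, strd in specs
            for m in scan_iupac(text, pat, strands=strd)
            if not any(
                s <= m.interval.start and m.interval.end <= e for s, e in keep
            )
        ]
        if not hits:
            return
        for m in hits:
            # mutate a base of the hit that lies outside every kept footprint
            free = [
                p
                for p in range(m.interval.start, m.interval.end)
                if not any(s <= p < e for s, e in keep)
            ]
            if not free:
                continue
            pos = free[int(rng.integers(len(free)))]
            current = seq[pos]
            choices = [b for b in "ACGT" if b != current]
            seq[pos] = choices[int(rng.integers(3))]
    raise RuntimeError(f"could not scrub accidental {pattern} hits")


def simulate_cluster(
    n_genes: int = 15,
    cluster_len: int = 200_000,
    n_elements: int = 2,
    element_lengths: Sequence[int] = (700, 350),
    element_after_gene: "Sequence[int] | None" = None,
    n_hd_per_element: int = 7,
    cluster_rule: tuple[str, int, int] = ("TAATGA", 3, 206),
    repeat_density: float = 0.1,
    include_pseudogene: bool = True,
    chrom: str = "cluster",
    seed: int = 0,
) -> SimulatedCluster:
    """Simulate the cluster FASTA, annotation, repeat mask and truth.

    Genes are two-exon models (1 kb exons flanking a 2 kb intron) spaced
    evenly; elements are dropped into the intergenic gap following the
    genes named by ``element_after_gene`` (0-based gene index).  Element 1
    carries four designated-conserved HD words, element 2 a conserved
    TAATCC plus a TAATGA triad within the cluster-rule window.  Accidental
    copies of the cluster-rule word outside elements — and accidental
    forward-strand TAATNN inside elements — are scrubbed so that the truth
    is exact.  Repeats fill ``repeat_density`` of the cluster in intergenic,
    non-element space.
    """
    if element_after_gene is None:
        # echo the real layout: one element early, one mid-cluster
        element_after_gene = (0, min(5, max(1, n_genes - 2)))
    if n_elements > len(element_lengths) or n_elements > len(element_after_gene):
        raise ValueError("need a length and anchor gene per element")
    rng = np.random.default_rng(seed)
    exon_len, intron_len = 1000, 2000
    gene_len = 2 * exon_len + intron_len
    margin = 4000
    if n_genes * gene_len + 2 * margin > cluster_len:
        raise ValueError("infeasible packing: genes do not fit in cluster")
    spacing = (cluster_len - 2 * margin - n_genes * gene_len) / max(n_genes - 1, 1)

    seq = list(_random_seq(rng, cluster_len))
    genes: list[GeneModel] = []
    gene_starts = [
        margin + round(i * (gene_len + spacing)) for i in range(n_genes)
    ]
    for i, gs in enumerate(gene_starts):
        transcript = GenomicInterval(chrom, gs, gs + gene_len, "+")
        exons = [
            GenomicInterval(chrom, gs, gs + exon_len, "+"),
            GenomicInterval(chrom, gs + exon_len + intron_len, gs + gene_len, "+"),
        ]
        genes.append(GeneModel(f"Gene{i + 1}", "protein_coding", transcript, exons))

    truth = PlantedTruth(
        chrom=chrom,
        cluster_len=cluster_len,
        seed=seed,
        config={
            "n_genes": n_genes,
            "n_elements": n_elements,
            "element_lengths": list(element_lengths[:n_elements]),
            "n_hd_per_element": n_hd_per_element,
            "cluster_rule": list(cluster_rule),
            "repeat_density": repeat_density,
        },
    )

    element_ivs: list[GenomicInterval] = []
    hd_footprints: list[tuple[int, int]] = []  # absolute, for scrubbing
    rule_word, rule_k, rule_window = cluster_rule
    for ei in range(n_elements):
        length = element_lengths[ei]
        anchor = element_after_gene[ei]
        if anchor + 1 >= n_genes:
            raise ValueError("element anchor gene must have a following gene")
        gap_lo = gene_starts[anchor] + gene_len
        gap_hi = gene_starts[anchor + 1]
        if gap_hi - gap_lo < length + 200:
            raise ValueError("infeasible packing: element exceeds intergenic gap")
        estart = (gap_lo + gap_hi - length) // 2
        if ei == 0:
            # four designated-conserved variants, three random extras
            hd_offsets = [80, 150, 220, 290, 360, 430, 500]
            hd_plan = [
                (hd_offsets[j], ELEMENT1_CONSERVED_HD[j], True) for j in range(4)
            ] + [(o, None, False) for o in hd_offsets[4:]]
            oe_offsets = [560, 590, 620]
            block_offset = 20
        else:
            # conserved TAATCC plus a TAATGA triad spanning 141 bp (<= 206)
            hd_offsets = [45, 75, 105, 150, 195, 240, 270]
            hd_plan = [
                (45, "TAATCC", True),
                (75, None, False),
                (105, "TAATGA", True),
                (150, None, False),
                (195, "TAATGA", True),
                (240, "TAATGA", True),
                (270, None, False),
            ]
            oe_offsets = [285, 300, 320]
            block_offset = 5
        extra = n_hd_per_element - len(hd_plan)
        if extra > 0:
            step = 8
            last = max(o for o, _, _ in hd_plan)
            hd_plan += [(last + 8 + step * j, None, False) for j in range(extra)]
        elif extra < 0:
            hd_plan = hd_plan[:n_hd_per_element]
        max_needed = max(
            max(o + 6 for o, _, _ in hd_plan),
            max(o + 10 for o in oe_offsets),
            block_offset + len(SHARED_BLOCK),
        )
        if max_needed > length:
            raise ValueError("infeasible packing: motifs exceed element length")
        eseq, records = _build_element(
            rng, length, hd_plan, oe_offsets, block_offset
        )
        # scrub accidental forward TAATNN and both-strand O/E hits inside
        # the element so the planted counts are the true counts
        eseq_list = list(eseq)
        keep = [(r["offset"], r["offset"] + len(r["word"])) for r in records]
        _scrub_pattern(
            rng, eseq_list,
            [("TAATNN", "forward"), ("YCCCNNGGGR", "both")],
            keep,
        )
        eseq = "".join(eseq_list)
        seq[estart : estart + length] = list(eseq)
        iv = GenomicInterval(chrom, estart, estart + length)
        element_ivs.append(iv)
        truth.elements.append(
            {"name": f"element{ei + 1}", "start": estart, "end": estart + length}
        )
        for r in records:
            truth.motifs.append(
                {
                    "element": f"element{ei + 1}",
                    "kind": r["kind"],
                    "word": r["word"],
                    "offset": estart + r["offset"],
                    "strand": r["strand"],
                    "frozen": r["frozen"],
                }
            )
            if r["kind"] == "hd":
                hd_footprints.append(
                    (estart + r["offset"], estart + r["offset"] + 6)
                )
    truth.shared_block = {
        "sequence": SHARED_BLOCK,
        "offsets": {
            e["element"]: e["offset"]
            for e in truth.motifs
            if e["kind"] == "shared_block"
        },
    }

    # scrub accidental cluster-rule words outside planted copies so the
    # triad locus is unique in the cluster by construction
    keep_abs = [
        (m["offset"], m["offset"] + len(m["word"]))
        for m in truth.motifs
        if m["word"] == rule_word
    ]
    # protect all element bases from mutation side effects by keeping every
    # planted footprint
    keep_abs += [
        (m["offset"], m["offset"] + len(m["word"])) for m in truth.motifs
    ]
    _scrub_pattern(rng, seq, rule_word, keep_abs, strands="both")

    # pseudogene fragment in a later gap
    if include_pseudogene and n_genes >= 12:
        frag_anchor = min(10, n_genes - 2)
        frag_lo = gene_starts[frag_anchor] + gene_len
        frag_start = frag_lo + 500
        frag = GenomicInterval(chrom, frag_start, frag_start + 800, "+")
        genes.append(GeneModel("PsGene1", "pseudogene", frag))

    ann = AnnotationSet(genes, source=f"simulate_cluster(seed={seed})")

    # repeats: intergenic, away from elements
    mask_ivs: list[GenomicInterval] = []
    target = repeat_density * cluster_len
    covered = 0
    forbidden = [
        GenomicInterval(chrom, max(0, iv.start - 100), min(cluster_len, iv.end + 100))
        for iv in element_ivs
    ]
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        rl = int(rng.integers(200, 2000))
        rs = int(rng.integers(0, cluster_len - rl))
        cand = GenomicInterval(chrom, rs, rs + rl)
        if any(cand.overlaps(f) for f in forbidden):
            continue
        mask_ivs.append(cand)
        covered += rl
    mask = MaskTrack(mask_ivs, source=f"simulate_cluster(seed={seed})")

    return SimulatedCluster(chrom, "".join(seq), ann, mask, truth)


# ------------------------------------------------------------- orthologs


_DEFAULT_SPECIES = [
    "mouse", "rat", "human", "chimp", "rhesus", "marmoset", "dog", "cat",
    "horse", "cow", "pig", "sheep", "rabbit", "squirrel", "elephant", "shrew",
]


def simulate_orthologs(
    ref: str,
    n_species: int = 16,
    substitution_prob: float = 0.25,
    conserved: Sequence[GenomicInterval] = (),
    conserved_multiplier: float = 0.1,
    frozen: Sequence[tuple[int, int]] = (),
    species_names: "Sequence[str] | None" = None,
    reference_name: str = "mouse",
    seed: int = 0,
) -> MultiAlignment:
    """Evolve ``n_species - 1`` rows from the reference on a star phylogeny.

    Each non-reference species substitutes every site independently with
    probability ``substitution_prob`` (uniform over the three alternative
    bases, Jukes-Cantor style), reduced by ``conserved_multiplier`` inside
    the ``conserved`` intervals and to zero inside ``frozen`` spans (used
    for designated-conserved motif cores).  No indels, so the alignment is
    positional: reference coordinates equal column indices.
    """
    if not 0 <= substitution_prob < 0.75:
        raise ValueError("substitution_prob must be in [0, 0.75)")
    if not 0 <= conserved_multiplier <= 1:
        raise ValueError("conserved_multiplier must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(ref)
    p = np.full(n, substitution_prob)
    for iv in conserved:
        p[iv.start : iv.end] = substitution_prob * conserved_multiplier
    for s, e in frozen:
        p[s:e] = 0.0
    if species_names is None:
        pool = [s for s in _DEFAULT_SPECIES if s != reference_name]
        pool += [f"species{i}" for i in range(len(pool), n_species)]
        species_names = [reference_name] + pool[: n_species - 1]
    if len(species_names) != n_species:
        raise ValueError("need one name per species")
    ref_arr = np.frombuffer(ref.upper().encode(), dtype="S1")
    base_idx = np.searchsorted(_BASES, ref_arr)
    rows = [ref.upper()]
    for _ in range(n_species - 1):
        mutate = rng.random(n) < p
        shift = rng.integers(1, 4, size=n)
        new_idx = np.where(mutate, (base_idx + shift) % 4, base_idx)
        rows.append(_BASES[new_idx].tobytes().decode())
    return MultiAlignment(list(species_names), rows, species_names[0])


def derive_conservation(aln: MultiAlignment) -> ConservationTrack:
    """Per reference base, the fraction of species (reference included)
    whose aligned base equals the reference base — a simple identity-based
    stand-in for a phylogenetic conservation score, in [0, 1]."""
    ref_row = np.frombuffer(aln.reference_row.encode(), dtype="S1")
    keep = ref_row != b"-"
    if not keep.any():
        raise ValueError("reference row is all gaps")
    ref_b = ref_row[keep]
    counts = np.zeros(keep.sum())
    for row in aln.rows:
        arr = np.frombuffer(row.encode(), dtype="S1")[keep]
        counts += arr == ref_b
    return ConservationTrack(aln.reference, 0, counts / aln.n_species)


def simulate_study(
    seed: int = 0,
    n_species: int = 16,
    substitution_prob: float = 0.25,
    conserved_multiplier: float = 0.1,
    **cluster_kwargs,
) -> tuple[SimulatedCluster, MultiAlignment, ConservationTrack]:
    """One full synthetic study: cluster + orthologs + conservation track.

    Seeds for the two simulators are derived from ``seed`` so one integer
    reproduces the whole study.
    """
    sim = simulate_cluster(seed=seed, **cluster_kwargs)
    frozen = [
        (m["offset"], m["offset"] + len(m["word"]))
        for m in sim.truth.motifs
        if m["frozen"]
    ]
    aln = simulate_orthologs(
        sim.sequence,
        n_species=n_species,
        substitution_prob=substitution_prob,
        conserved=sim.truth.element_intervals(),
        conserved_multiplier=conserved_multiplier,
        frozen=frozen,
        reference_name="mouse",
        seed=(seed * 7919 + 1) % (2**31),
    )
    track = derive_conservation(aln)
    track.chrom = sim.chrom
    return sim, aln, track


# ------------------------------------------------------------------ qPCR


ABOLISHED_FLOOR = 2.0**-10


def simulate_qpcr(
    fold_by_gene: Mapping[str, Mapping[str, float]],
    housekeeping: Sequence[str] = ("Bgus", "Gnal", "Ncam"),
    genotypes: Sequence[str] = ("wt", "mutant"),
    control: str = "wt",
    n_mice: int = 5,
    n_replicates: int = 3,
    sigma: float = 0.2,
    mouse_sigma: float = 0.5,
    baseline_range: tuple[float, float] = (20.0, 26.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a Ct table with known true fold changes.

    ``fold_by_gene[gene][genotype]`` is the true expression of the gene in
    that genotype relative to the control (control fold is 1; abolished
    genes should use a finite floor such as ``ABOLISHED_FLOOR`` since the
    Ct of an absent transcript is censored in practice).  Each mouse gets a
    shared RNA-quantity offset (SD ``mouse_sigma``) that housekeeping
    normalization removes; each measurement adds Gaussian Ct noise
    ``sigma``.  Housekeeping genes have fold 1 everywhere.
    Returns (table, truth dict).
    """
    if sigma < 0 or mouse_sigma < 0:
        raise ValueError("noise SDs must be >= 0")
    if control not in genotypes:
        raise ValueError("control genotype must be among genotypes")
    rng = np.random.default_rng(seed)
    genes = list(fold_by_gene) + [g for g in housekeeping if g not in fold_by_gene]
    baselines = {
        g: float(rng.uniform(*baseline_range)) for g in genes
    }
    rows = []
    truth_folds: dict[str, dict[str, float]] = {}
    for genotype in genotypes:
        for mouse in range(n_mice):
            sample = f"{genotype}_m{mouse + 1}"
            offset = float(rng.normal(0.0, mouse_sigma))
            for gene in genes:
                if gene in housekeeping:
                    fold = 1.0
                elif genotype == control:
                    fold = 1.0
                else:
                    fold = float(fold_by_gene[gene].get(genotype, 1.0))
                if fold <= 0:
                    raise ValueError("true folds must be positive")
                truth_folds.setdefault(gene, {})[genotype] = fold
                mu = baselines[gene] - np.log2(fold) + offset
                for rep in range(n_replicates):
                    ct = mu + float(rng.normal(0.0, sigma))
                    rows.append(
                        {
                            "sample": sample,
                            "genotype": genotype,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct": ct,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "folds": truth_folds,
        "baselines": baselines,
        "control": control,
        "housekeeping": list(housekeeping),
        "n_mice": n_mice,
        "sigma": sigma,
        "seed": seed,
    }
    return table, truth
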