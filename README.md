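# crescan

Discovery of candidate *cis*-acting enhancers in receptor gene clusters,
and quantification of what deleting them does to cluster gene expression.

Olfactory receptor-family genes — including the 15-gene trace
amine-associated receptor (TAAR) cluster, which spans roughly 200 kb of
mouse chromosome 10 — depend on distal enhancer elements for singular gene
choice in sensory neurons. `crescan` implements, as a tested and reusable
pipeline, the computational procedure for finding such elements and
characterizing them:

1. **Three-filter candidate discovery.** Search a cluster for sequence that
   is (i) conserved across species (an input phyloP-style score track, or a
   percent-identity profile computed from a pairwise alignment), (ii)
   non-repetitive, and (iii) intergenic — outside every gene, UTR, intron
   and pseudogene fragment. Conserved segments surviving both masks become
   ranked candidate elements.
2. **Degenerate-motif content.** Exact IUPAC scanning on both strands for
   homeodomain (HD) sites `TAATNN`, the extended HD word `CTTTTTAATGA`,
   O/E-like sites `YCCCNNGGGR`, and *k*-within-window motif clusters such
   as a TAATGA triad inside 206 bp.
3. **Cross-species motif conservation.** Positions are projected through a
   multi-species alignment; a motif instance is conserved when the
   gap-stripped homologous window satisfies the pattern in a configurable
   fraction of species.
4. **Shared-homology discovery.** Ungapped k-mer-seeded block finding
   between two elements (how a shared ~30 bp block is detected), and a
   FIMO-style search of a motif against an enhancer database with exact
   single-window match probabilities under a 0-order background,
   Bonferroni correction over windows within each target, and
   Benjamini–Hochberg *q*-values across targets.
5. **qPCR deletion-effect analysis.** The 2^−ΔΔCt relative-expression
   estimator with geometric-mean housekeeping normalization
   (ΔCt = Ct(gene) − mean Ct(housekeeping), equivalently normalization by
   the geometric mean of the housekeeping quantities 2^−Ct), one-way ANOVA
   on ΔCt with Dunn–Šidák family-wise correction
   (p_adj = 1 − (1 − p)^m), and classification of each gene as abolished,
   reduced, or spared.
6. **Synthetic studies.** A generator that emits every input the pipeline
   consumes — cluster FASTA, GFF3 gene models, repeat BED, conservation
   bedGraph, aligned ortholog FASTA, and Ct tables — with recorded ground
   truth, so every stage is testable closed-loop without downloads.

## Worked example

```python
import crescan as cs
from crescan.candidates import PipelineConfig, call_candidates, report

# printed coordinates parse under an explicit convention
iv = cs.parse_interval("chr10: 23,806,280-23,806,978", "one_based_end_exclusive")
print(cs.interval_length(iv))        # 698

# a full synthetic study: cluster + orthologs + conservation track
sim, aln, track = cs.simulate_study(seed=1)
cands = call_candidates({sim.chrom: sim.sequence}, sim.annotation,
                        sim.mask, track, sim.bounds, aln, PipelineConfig())
print(report(cands)[0].to_string(index=False))
```

Output:

```
698
 rank               coords   chrom  start   end  length_bp  mean_conservation  max_conservation  hd_forward  hd_both  conserved_hd  oe_sites  cluster_hits
    1 cluster: 79686-80030 cluster  79686 80030        344           0.983648               1.0           7        8             7         3             1
    2 cluster: 12362-13060 cluster  12362 13060        698           0.978779               1.0           7       10             6         3             0
```

The two rows are the two planted elements, recovered to within a few bases
of their true boundaries (79682–80032 and 12364–13064). Each carries seven
forward-strand HD sites and three O/E-like sites; the top-ranked candidate
additionally holds the cluster's unique TAATGA triad (`cluster_hits = 1`),
mirroring the second, triad-bearing element. `conserved_hd` counts the
instances whose homologous windows still match `TAATNN` in ≥ 80% of the 16
simulated species.

The same analyses are available from a shell:

```sh
crescan simulate --outdir study --seed 1
crescan call --fasta study/cluster.fa --gff3 study/genes.gff3 \
             --mask study/repeats.bed --track study/conservation.bedGraph \
             --aln study/orthologs.aln.fa --out-bed candidates.bed
crescan qpcr --ct table.csv --housekeeping Bgus,Gnal,Ncam --control wt
```

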