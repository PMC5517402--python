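# circlife

Circular RNAs (circRNAs) arise when a downstream splice donor joins an
upstream acceptor, producing a covalently closed transcript whose back-splice
junction (BSJ) uniquely identifies it. In plants they are candidate miRNA
sponges: a circRNA carrying binding sites for a miRNA can sequester it and
relieve repression of that miRNA's mRNA targets. `circlife` implements a
desk-scale reanalysis pipeline for circRNAs across the lifespan of
*Arabidopsis thaliana* rosette leaves — a 14-sample RNA-seq time course at
two-day intervals (days 4–30 after emergence) split into a
growth-to-maturation window (days 4–18, reference day 4) and a
maturation-to-senescence window (days 16–30, reference day 16).

It is aimed at plant transcriptomics researchers who already have BSJ calls
(from MapSplice, CIRCexplorer, CIRI, ...) plus linear gene and miRNA count
matrices, and want the downstream analysis: annotation, differential
expression over developmental stages, host-gene independence, and
circRNA–miRNA–mRNA sponge networks.

## What it computes

**Classification.** Each BSJ is placed against a GFF3 annotation into one of
six categories — exonic with both breakpoints at exon boundaries, both
internal, exactly one at a boundary, intronic, intergenic, or ambiguous —
with host gene, spanned exon count, organelle origin (nuclear / chloroplast /
mitochondrial) and novelty against a PlantcircBase-style catalogue.

**Quantification and DE.** Expression is the pseudo-counted library-size
ratio

    E_fs = (n_fs + 1) / N_s × 10⁶

(`n` supporting reads, `N` the sample's library size). Within each stage,
log₂ fold changes are taken against the stage's reference day,
`FC_ft = log₂(E_ft / E_f,ref)`, and a feature is differentially expressed
when `|FC| ≥ 2` (4-fold) at any stage day — a pure threshold rule; the
design has one library per time point, so there is no dispersion model and
no p-value.

**Sponge targets.** miRNA sites are scored with a plant-style gapless
penalty scheme (Watson–Crick 0, G:U wobble 0.5, mismatch 1, doubled at seed
positions 2–13 from the miRNA 5′ end); hits are kept at score ≤ 4.0 on
mRNAs and ≤ 4.5 on circRNAs, and must be expression-anti-correlated with
their miRNA (Spearman ρ ≤ −0.5 over the 14 points). Circular targets are
also scanned across the back-splice seam.

**Networks.** A (circRNA, miRNA, mRNA) triplet requires one miRNA with
retained, anti-correlated hits on both molecules, and stage fold-change
gates of 2-fold for the miRNA and 4-fold for the circRNA and mRNA. Networks
export as Cytoscape-loadable SIF/TSV.

**Synthetic data.** `simulate_dataset` draws internally consistent inputs
(genome, GFF3, BSJ table, count matrices, miRNA FASTA, known-circRNA list)
with negative-binomial counts over logistic time courses, planted target
sites and planted anti-correlation; `make_paper_fixture` deterministically
constructs a 168-circRNA dataset whose summary statistics take the exact
values reported for this system.

## Worked example

```python
import circlife as cl

fx = cl.make_paper_fixture()
records = [cl.classify_bsj(j, fx.annotation) for j in fx.junctions]
records = cl.flag_novel(records, fx.known_list)
summary = cl.summarize_classes(records)
print(summary.total, summary.exonic_count, summary.exonic_pct)
print({c.value: p for c, p in summary.percentages.items()})

det = cl.detection_summary(fx.circ_counts, fx.stage_config)
print(det.n_singletons, det.pct_singletons, len(det.retained))
print({k: len(v) for k, v in det.stage_sets.items()}, det.intersection)
```

prints

```
168 158 94.1
{'EXONIC_BOTH_BOUNDARY': 79.8, 'EXONIC_BOTH_INTERNAL': 4.8,
 'EXONIC_ONE_BOUNDARY': 9.5, 'INTRONIC': 0.0, 'INTERGENIC': 5.9,
 'AMBIGUOUS': 0.0}
104 61.9 64
{'G-to-M': 66, 'M-to-S': 144} 42
```

— of 168 circRNAs, 158 (94.1%) are exonic and 134 (79.8% of all) have both
breakpoints exactly on exon boundaries; 104 (61.9%) are seen in a single
sample, leaving 64 detected in ≥ 2 samples for DE analysis; 66 circRNAs are
detected during growth-to-maturation and 144 during
maturation-to-senescence, 42 in both.

The same dataset through the whole pipeline (`circlife run --config
config.yaml`, or `circlife.pipeline.run_all`) additionally reports 6 DE
circRNAs at G-to-M (5 up, 1 down) and 35 at M-to-S (34 up, 1 down) with 3
shared; 9 of the 34 senescence-upregulated circRNAs have a concomitantly
upregulated host gene (the rest are host-independent); and sponge networks
of 20 and 220 triplets in the two stages.

A random dataset instead of the fixture:

```bash
circlife simulate --seed 7 --outdir sim/
circlife classify --gff3 sim/annotation.gff3 --bsj sim/bsj.tsv \
    --known sim/known_circs.tsv --out summary.tsv --records records.tsv
```

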