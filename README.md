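# strlineage

Somatic short-tandem-repeat (STR / microsatellite) lineage tracing for single
cells, built for studies of clonal evolution in hematopoietic malignancies:
given per-cell, per-locus read-count histograms over STR repeat lengths, the
package calls repeat genotypes despite PCR/WGA stutter, reconstructs a rooted
cell-lineage tree, attaches bootstrap confidence to its branches, and scores
which clades are enriched for a sampling wave (diagnosis vs. relapse) or a
stem/progenitor subpopulation (HSC-MPP, MLP, GMP, CMP-MEP, ...). A
ground-truthed synthetic-data generator stands in for patient sequencing data,
so every stage is testable end to end.

## The method

STR loci mutate by replication slippage — the repeat count takes ±1 unit steps
at a per-division rate far above the point-mutation rate — which makes them
natural barcodes of cell ancestry. The analysis chain is:

1. **Stutter-aware genotyping.** Amplified single-cell STRs yield *stutter
   patterns*: read histograms smeared mostly toward shorter repeats. Model
   patterns are calibrated per (repeat-unit length, true repeat count) from a
   labeled synthetic library, on an offset window of 5 units below to 2 above
   the true repeat. A cell×locus histogram is genotyped by the candidate
   repeat count whose model pattern minimizes the Euclidean distance to the
   window-normalized observation (exact nearest-neighbor scan; ties go to the
   smaller repeat).
2. **Tree reconstruction.** Called genotypes are translated to characters and
   concatenated in fixed panel order (exported as FASTA for external tools).
   Natively, pairwise distances d(a,b) = fraction of co-genotyped loci with
   different repeat counts feed an exact neighbor-joining; the tree is rooted
   by a pseudo-leaf at the average genotype of the HSC-MPP cells — the least
   diverged compartment anchors the founder.
3. **Branch support.** Loci are resampled with replacement (panel size kept,
   so ≈ (1−1/L)^L ≈ 37% of distinct loci drop out of each replicate) and the
   reconstruction repeats; branches get transfer bootstrap expectation
   support, TBE = 1 − mean(transfer index)/(p−1).
4. **Clade enrichment.** Each internal node is scored by the exact
   hypergeometric upper tail P[X ≥ k] for X ~ Hypergeom(N, K, n): the chance
   a clade of its size catches at least the observed number of same-labeled
   leaves under uniform sampling. Widths for plotting scale with −log10(p).
   Root-to-leaf depths of the diagnosis and relapse waves are compared with a
   two-sided Mann–Whitney U test.

Categorical rules from the accompanying functional assays are included:
xenograft engraftment (overt leukemia at hCD45 > 5% with CD33 > 60%;
detection at ≥ 0.1% for bulk transplants, ≥ 0.02% for single HSPCs) and ex
vivo chemo-resistance (resistant at ≥ 60% viability).

## Worked example

The standard planted-relapse experiment: 20 diagnosis cells sampled mid
expansion, 20 relapse cells (80% forced into one late subclone), 60 STR loci,
stutter-noised reads at 50× with 5% dropout.

```python
import strlineage as sl
from strlineage.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, simulation=sl.SimConfig(seed=1),
                     bootstrap_replicates=200)
manifest = run_pipeline(cfg, "demo_run")
```

or, equivalently, `strlineage run --config config.yaml --seed 1 --out demo_run`.
The manifest (excerpt) reads:

```
"bootstrap":        {"replicates_used": 200, "mean_distinct_locus_dropout": 0.3653, ...}
"genotype":         {"calls": 2260, "cells_retained": 40, "cells_dropped": 0}
"enrichment":       {"best_relapse_clade_p": 7.708e-08, "significant": true}
"depth_comparison": {"mean_depth_diagnosis": 0.134, "mean_depth_relapse": 0.206,
                     "p_value": 3.9e-09}
```

Reading: genotyping retained all 40 cells; each bootstrap replicate lost
36.5% of distinct loci (the analytic (1−1/60)^60 ≈ 36.4%); the relapse wave
concentrates in one clade far beyond chance (best hypergeometric p ≈ 8e-08,
well under 0.05); and diagnosis cells sit significantly shallower in the tree
than relapse cells, as expected for an earlier sampling wave. The run
directory holds the genotype matrix (`matrix.tsv`), the TBE-annotated tree
(`tree.nwk`), the FASTA export (`alignment.fasta`), per-node enrichment
(`enrichment.tsv`), QC and depth reports, and a `manifest.json` that makes
the run byte-reproducible under the same config and seed.

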