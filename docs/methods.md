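# Methods

## Scope and model

`strlineage` analyzes clonal cell ancestry through somatic microsatellite
(STR) mutations. The package has two halves: a generative model of the data
(used for validation and as a stand-in for patient sequencing data) and the
analysis chain itself (genotyping → tree → support → enrichment). This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## Generative model

**Lineage.** A clonal expansion is a complete binary division history of
`n_divisions` generations. Sampled cells are lineages (root-to-node paths);
the true tree over a sample is the induced subtree with edge lengths in cell
divisions. Two sampling waves are drawn: the *diagnosis* wave at an earlier
generation (`diagnosis_divisions`, default 65% of `n_divisions`) and the
*relapse* wave at the final generation. At least
`ceil(relapse_clade_fraction × n_relapse)` relapse cells descend from one
designated subclone (the planted clade, marked `planted` in the true tree's
NEWICK); all other cells are placed outside it, so the planted clade is pure
relapse by construction. Sampling a diagnosis cell removes its lineage from
the later wave — a sequenced cell cannot also be an ancestor of a later
sample.

**Mutation.** Stepwise mutation model: at each division each locus mutates
independently with probability `mu` by a signed step drawn from `step_probs`
(default symmetric ±1, the standard slippage model), clamped to the locus's
modeled repeat range. Clamping (rather than reflecting or resampling) keeps
the boundary policy trivial to state and test. Genotypes are haploid — one
repeat count per locus per cell — matching an analysis that treats each
locus's amplified signal as a single stutter pattern; diploid allele pairs
are out of scope for the default build.

**Reads.** A non-dropped locus draws its reads multinomially from the stutter
pattern of the true repeat count — fixed `depth_reads` total by default so
that read conservation is exactly testable (`poisson_depth` switches to a
Poisson depth). Each locus independently drops out (yields zero reads) with
probability `dropout_rate`, emulating single-cell WGA locus failure.

**Stutter.** The built-in generating model is geometric and
contraction-biased: relative to weight 1 at the true repeat, offset −j
carries weight `rho_down^j` (j ≤ 5) and +j carries `rho_up^j` (j ≤ 2), with
`rho_down = min(base + slope·r, 0.35)` increasing in the repeat count r —
longer runs slip more — and mononucleotide parameters (base 0.06, slope
0.012, up 0.04) noisier than dinucleotide ones (0.04, 0.008, 0.02). These
rates are a design choice tuned to be *moderate*: realistic enough that
naive peak-calling would err at long runs, while 50× depth supports accurate
pattern matching.

**Labels.** Subpopulations are drawn from a configurable scheme table;
the default gives the planted clade MLP/GMP in equal parts and mixes the
background (HSC-MPP 0.28, MLP 0.22, GMP 0.22, CMP-MEP 0.14, bulk 0.07,
CD34 0.07). At least `min_root_group` (default 2) background cells are
guaranteed the HSC-MPP label so the rooting group is never empty.

## Analysis chain

**Calibration.** Model patterns are the per-label mean of window-normalized
library histograms, re-normalized; labels pool across loci sharing a
repeat-unit length. The window is 5 repeat units below to 2 above the true
repeat — stutter is predominantly contraction — and mass outside it is
truncated before normalization. Missing label coverage is a hard error
listing the absent genotypes.

**Genotyping.** For each candidate repeat in the locus range, the observed
histogram is re-aligned and re-normalized on the candidate's window and
compared to the candidate's model pattern by Euclidean distance; the minimum
wins, ties resolving to the smaller repeat count. Because the normalization
is per-candidate, the search is implemented as an exact linear scan — there
is no shared embedding in which an approximate index could operate, and the
candidate set per locus is small (tens). The Euclidean criterion is a
documented substitution for likelihood-based stutter scoring; at the depths
and stutter rates modeled here the two agree except on near-degenerate
histograms. Default QC masks calls under 20 reads and drops cells genotyped
at fewer than half the panel; both thresholds are exposed in configuration.

**Distances and tree.** d(a,b) = mismatch fraction over co-genotyped loci
(pairwise deletion of missing entries); a pair with no shared locus is a
hard error naming the pair. Neighbor joining is implemented in-repo, exact
and deterministic: Q-criterion ties break by lexicographic node id, negative
branch-length estimates clamp to zero. The rooting profile is the per-locus
mean over the designated root group, rounded half-up, falling back to the
panel reference where the group has no call; it joins the NJ input as a
pseudo-leaf, the tree is rooted at its attachment node, and the pseudo-leaf
is removed. NJ replaces the approximate-ML search a practitioner might run
on the encoded characters; the encoded alignment is exported as FASTA
precisely so such a tool can be used instead. On well-marked lineages (every
division carrying mutations) both approaches recover the true topology; the
tests verify this for the NJ path.

**Bootstrap and TBE.** Replicates resample panel-size locus multisets with
replacement, deterministic per (seed, replicate index); distances, root
profile and NJ are recomputed per replicate, and replicates with an
uncomputable pair are skipped and reported. The transfer index is computed
by exhaustive scan over all replicate splits (trivial ones included),
minimizing Hamming distance over both orientations — linear-time transfer
algorithms exist but exactness-by-inspection wins at the few-hundred-leaf
scale this package targets. Supports are written as internal-node labels so
they survive NEWICK round trips.

**Enrichment and depths.** Per internal node, the exact hypergeometric upper
tail (scipy) for the node's label count; raw p-values are reported by
default — per-branch display conventionally shows uncorrected p — with
Benjamini–Hochberg available as an option. Branch width is
`w_min + min(−log10 p, cap) × scale`. Depth comparisons use a two-sided
Mann–Whitney U: exact when both groups are ≤ 20 and tie-free, the
tie-corrected normal approximation otherwise. A rank test is used because
no distributional form for depths is defended; the "density" contrast
sometimes reported alongside depth has no agreed definition and is
deliberately not implemented.

## Defaults that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `n_divisions` | 14 | divisions | hosts 40 distinct sampled lineages with room for a late subclone |
| `diagnosis_divisions` | 9 (65%) | divisions | earlier wave: diagnosis cells carry fewer mutations, sit shallower |
| `mu` | 0.02 | per locus per division | free parameter (no measured rate is assumed); with 60 loci gives ≈1.2 mutations per division, enough to mark most branchings |
| `relapse_clade_fraction` | 0.8 | — | strong but not total clonal origin of relapse |
| `depth_reads` | 50 | reads/locus | supports >95% genotyping accuracy under the default stutter |
| `dropout_rate` | 0.05 | — | mild WGA locus failure |
| panel | 60 loci, half mono / half di | — | desk-scale stand-in for a targeted STR capture panel |
| QC | ≥20 reads, ≥50% loci | — | unmeasured in the motivating assays; exposed in config |
| bootstrap `B` | 1000 | replicates | convention for stable TBE estimates |

## What the synthetic experiments show — and don't

Passing tests demonstrate internal correctness (every accelerated or
vectorized path equals its brute-force oracle; exact recovery in noiseless
limits; calibration round-trips) and sensitivity under the *modeled* noise:
multinomial stutter, independent dropout, haploid genotypes, no homoplasy
correction. Real single-cell WGA data additionally exhibit allele-specific
amplification bias, locus-correlated dropout, chimeric reads, mosaic
aneuploidy and diploid allele mixtures, none of which are generated here.
Mismatch distances also saturate on long time horizons (back-mutation), so
deep histories compress; within the simulated regime this is negligible, on
real data it biases deep branch lengths downward.

## Problem sizes used in validation

The shipped tests and the acceptance script run the standard experiment at
40 cells × 60 loci with 30 calibration replicates per genotype, bootstrap
checks at 100 loci × 1000 resamples, TBE oracles at 8–12 leaves × 20
replicates, and topology-recovery runs at 12 leaves × 500 loci — sizes
chosen so the full validation cycle completes in well under a minute while
each check retains its statistical power.

## Known limitations

Haploid calls only; Euclidean (not likelihood) pattern matching; NJ rather
than ML tree search; no multiple-testing correction by default; transfer
index by exhaustive scan (quadratic in tree size, fine below ~500 leaves);
bulk samples, if present, are treated as ordinary leaves.
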