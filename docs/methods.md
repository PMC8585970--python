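# Methods

## The measurement model

The analysis targets dual-color allele reporter experiments: in each cell,
two alleles of the same gene produce spectrally distinct fluorescent
signals, imaged as a two-channel confocal z-stack. Per cell we obtain a
pair (x, y) of allele intensities; systematic acquisition differences
(channel gain, bit depth, laser power per session) are removed by dividing
each channel by its per-experiment mean, after which stochastic allele bias
is scored per cell as

    η²(cell) = (x − y)² / (2⟨x⟩⟨y⟩),

with ⟨x⟩, ⟨y⟩ the allele means over all cells of the group. By default the
means are pooled across experiments after normalization, because per-cell
values from several experiments are summarized and plotted together; a
`means="per_experiment"` switch computes them within each experiment
instead (where they equal 1 by construction, reducing the statistic to
(x−y)²/2). The two conventions differ only when group composition varies
across experiments; pooled is the default because it matches how grouped
per-cell distributions are reported.

Cells with x = y = 0 are scored 0 (the numerator limit) and flagged
(`zero_pair`), since the formula is otherwise indeterminate for them.

The population decomposition
intrinsic² = ⟨(x−y)²⟩/(2⟨x⟩⟨y⟩), extrinsic² = (⟨xy⟩−⟨x⟩⟨y⟩)/(⟨x⟩⟨y⟩)
is used as an internal consistency oracle: the mean of the per-cell values
equals intrinsic² identically, and simulations with only shared
fluctuations must put all variance in the extrinsic term.

## The silencing simulator

The generator implements the minimal stochastic model that reproduces the
observed continuum from biallelic to monoallelic expression and the
buffering of noise by ploidy. Per cell:

* shared cell-state factor `E ~ lognormal(0, σ_ext)` (unit median);
* active copy counts `a, b ~ Binomial(N, 1−q)` drawn independently per
  allele — N gene copies per allele per nucleus, each silenced
  independently with probability q;
* per-allele factors `I_x, I_y ~ lognormal(0, σ_int)` (unit median);
* `x = gain_red·E·I_x·base·(a/N) + ε`, ε Gaussian detector noise, negatives
  clipped to 0 (detectors report nonnegative signal); y analogous.

Per-copy, independent silencing is a modeling choice, not an established
mechanism: nothing in the per-cell data identifies how silencing is
coordinated among copies, and this is the simplest model with the right
limits (q→0 biallelic, q→1 silent, 1/N noise scaling). Under pure silencing
(all other sources off) the mean per-cell intrinsic noise is exactly

    E[η²] = q / (N(1−q)),

derived from E[(a−b)²] = 2Nq(1−q) and normalization by N(1−q); the test
suite verifies the simulator against this closed form over
N ∈ {1,2,8,32} × q ∈ {0.05,0.2,0.5} within 3 Monte-Carlo standard errors.

Defaults describe a realistic study condition: three independent
experiments of 60 cells (180 cells/group, the scale of the muscle-cell
datasets), diploid N = 2, base expression 1000 detector units (comfortably
inside a 16-bit range), σ_ext = 0.3 (dominant shared cell-state
fluctuation), σ_int = 0.1 (residual per-allele variation other than
silencing), detector noise SD 5 (0.5% of base). The two canonical group
presets are q = 0.02 for intron-bearing alleles and q = 0.30 for intronless
alleles, which reproduce both the near-diagonal scatter of the intron
groups and the strong bias continuum of the intronless groups at the
study's sample sizes.

Log-normal factors use unit median (log-mean 0) so that dispersion
parameters do not shift the silencing closed form; the corresponding means
are e^{σ²/2}, which matters only for absolute-intensity checks.

A note on medians: under *pure* silencing with N = 2, q = 0.2, the median
per-cell noise is exactly 0 (P(a = b) > 0.5), so median-based ploidy
comparisons are made under the realistic defaults, where the strict
decrease of the median over N = 2 → 8 → 32 holds.

## Image rendering and cytometry

Rendered scenes place each cell as a spherical nucleus (default radius 4
voxels) on a regular 3-D grid with guaranteed separation, on a constant
background (default 5), with interior voxels set to the cell's x (red
channel) and y (green), plus Gaussian rendering noise (SD 1) and
quantization to 8- or 16-bit. There is no point-spread blur or
photophysics: quantification uses interior means on the equatorial slice,
for which blur is a second-order effect, so the renderer tests the
measurement logic, not optics. Real stacks differ in exactly those
respects — anisotropic voxels, PSF, autofluorescence, touching nuclei — so
passing recovery tests validates the quantification pipeline, not
segmentation robustness on real tissue.

Segmentation thresholds the per-voxel channel sum with a global two-class
(Otsu) split computed on log-transformed intensities — the log compresses
the spread among bright nuclei so the split lands between background and
foreground even when nuclei occupy a tiny voxel fraction — followed by 3-D
connected components (26-connectivity) and a minimum-size filter (default
10 voxels). Constant images yield zero nuclei rather than an error.
Quantification takes the arithmetic mean voxel value per channel over the
ROI's voxels in its equatorial slice (the z of maximal cross-sectional
area; ties break toward smaller z), with no background subtraction. ROIs
are relabelled in centroid (z, y, x) order for deterministic output; tests
match measured nuclei to ground truth by nearest centroid, since a single
above-threshold noise voxel can perturb a centroid enough to permute a
lexicographic ordering.

## Group comparisons

Per-cell noise distributions are non-normal by construction, so all
comparisons are rank-based. Two groups: Mann–Whitney U, two-tailed; the
p-value is the exact permutation tail when n₁+n₂ ≤ 12 and the data are
tie-free, otherwise the tie-corrected normal approximation with continuity
correction (the method used is recorded on every result). Three or more
groups: Kruskal–Wallis with tie correction and chi-square reference,
followed by Dunn's pairwise z comparisons; the multiplicity correction is
Bonferroni over all pairs — the classical form of Dunn's procedure — since
commercial packages do not document their choice. When all pooled values
are tied, Dunn's variance term is exactly zero and the comparison is
defined as z = 0, p = 1. Significance labels use the strict thresholds
*** p<0.001, ** p<0.01, * p<0.05, else ns.

Exactness is enforced by oracle tests: full enumeration of all tie-free
rank configurations with n₁+n₂ ≤ 10 for Mann–Whitney, and full
hypergeometric enumeration of every 2×2 table with total ≤ 40 for Fisher's
test.

## Enrichment

GFF3 gene models are parsed by a purpose-built line reader whose contract
is line-accurate diagnostics (missing `##gff-version 3` pragma, malformed
rows, end < start, orphan exons). A gene is intronless when every
transcript has exactly one exon (strict rule, default); a lenient
any-single-exon-transcript rule is available, because annotation-based
definitions of "intronless" genuinely vary. The intronless set is
cross-tabulated against gene-level monoallelic calls and tested with
Fisher's exact test (sample odds ratio; Haldane 0.5 correction flagged when
a cell is zero). Term-level over-representation uses the hypergeometric
upper tail per term with Benjamini–Hochberg adjustment across terms
(Bonferroni available). The synthetic annotation fixture plants a known
intronless fraction (deterministic nearest-integer count), class-specific
MAE rates (64% intronless vs 20% background by default), and one enriched
term, so classification, cross-tabulation and both tests can be verified
against ground truth at genome scale (20,390 genes).

## Pipeline and determinism

All randomness flows through `numpy.random.Generator` objects seeded from a
single master seed; per-stage child seeds are spawned with
`SeedSequence.spawn` in canonical stage order and recorded in the run
manifest together with input/output paths and SHA-256 checksums, so any
stage can be re-run in isolation and fixed-seed runs are byte-identical.
Configuration is YAML with a versioned schema; schema violations and
missing input paths fail before any stage executes.

The reader for figure-wise X,Y workbooks (one sheet per figure; group,
experiment, x, y columns) is layout-configurable because deposited
workbooks do not follow a single convention; `reproduce_published` applies
the standard chain (normalize → per-cell noise → percentile summary →
percent decrease of the treated group's median) and, when the workbook
carries its own noise column, reports the maximal absolute deviation from
the recomputed values. Its correctness is established by a round-trip test:
a workbook written from simulated data reproduces the percent decrease
computed directly on that dataset.

## Problem sizes

Validation uses 10⁵ cells per grid point for closed-form recovery,
3×10⁴ cells per ploidy for median comparisons, 200 replicates of
180-cells-per-group contrasts for power, a 20-nucleus rendered scene for
cytometry recovery, and a 20,390-gene fixture for enrichment — sizes chosen
to make Monte-Carlo error small relative to the tested tolerances while
keeping the full suite fast on a single CPU.

## Known limitations

* The per-copy binomial silencing model is a stand-in; real silencing may
  be coordinated across copies or time-dependent (initiation during
  development, maintenance through endoreduplication), none of which is
  modeled.
* The renderer omits optics (PSF, chromatic aberration, bleaching,
  fluorophore maturation); segmentation performance on real stacks is out
  of scope.
* Protein-level measurements only; no transcriptional-bursting or
  mRNA-level inference.
* Enrichment results on fixtures validate machinery, not biology: real
  intronless/MAE catalogs depend on genome annotation and database
  versions.
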