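# allelenoise

Quantitative analysis of **stochastic allele expression bias** from
dual-color reporter data.

Most autosomal genes are expressed from both alleles, but in many cells one
allele is partially or completely silenced at random — a continuum that runs
from balanced biallelic expression to monoallelic expression (MAE). When the
two alleles of a gene carry differently colored fluorescent reporters, this
bias is directly measurable in single cells: each cell contributes a pair
(x, y) of allele intensities, and deviation from the 1:1 diagonal quantifies
bias. `allelenoise` implements the full analysis path for such experiments —
and a synthetic-data generator with known ground truth so every stage can be
validated without microscope data.

## The statistic

For a group of cells with per-experiment-mean-normalized allele intensities
x and y, the per-cell **intrinsic noise** is

    η²(cell) = (x − y)² / (2⟨x⟩⟨y⟩)

where ⟨x⟩ and ⟨y⟩ are the allele means over the cells of the group. Cells on
the diagonal score 0; a monoallelic cell scores high. At the population
level the dual-reporter decomposition splits total variability into an
uncorrelated (intrinsic) and a correlated (extrinsic, shared cell state)
part:

    intrinsic² = ⟨(x−y)²⟩ / (2⟨x⟩⟨y⟩)
    extrinsic² = (⟨xy⟩ − ⟨x⟩⟨y⟩) / (⟨x⟩⟨y⟩)

and the mean of the per-cell values equals intrinsic² exactly.

The generator models stochastic silencing per gene copy: each allele has N
copies (ploidy), each copy is independently silenced with probability q, and
expression is proportional to the active fraction, modulated by log-normal
extrinsic/intrinsic factors, channel gains and detector noise. Under pure
silencing the mean per-cell intrinsic noise has the closed form

    E[η²] = q / (N (1 − q))

which the simulator recovers and which explains why polyploid tissues
(N = 32) are buffered against silencing noise relative to diploid tissues
(N = 2).

## Modules

| module | what it does |
| --- | --- |
| `synthetic` | silencing-model simulator, two-channel z-stack renderer, GFF3/MAE/term fixtures with planted ground truth |
| `cytometry` | nucleus segmentation (Otsu on log channel sum + 3-D connected components), equatorial-slice selection, mean-voxel quantification |
| `noise` | per-experiment normalization, per-cell intrinsic noise, population decomposition, Spearman R², boxplot summaries |
| `comparisons` | Mann–Whitney U (exact for small tie-free samples), Kruskal–Wallis, Dunn's pairwise z with Bonferroni, star labels |
| `enrichment` | GFF3 parsing, intronless classification, MAE cross-tabulation, Fisher's exact test, hypergeometric term over-representation with BH |
| `pipeline` / `cli` | YAML-configured orchestration with deterministic per-stage seeding and a checksummed run manifest |

## Worked example

Simulate the canonical contrast — intron-bearing alleles (rarely silenced,
q = 0.02) versus intronless alleles (q = 0.30) in a diploid tissue, 180
cells per group over three experiments — then normalize, score each cell and
compare groups:

```python
import pandas as pd
import allelenoise as an

pa, pb = an.two_group_params(seed=1, n_experiments=3, cells_per_experiment=60)
cells = pd.concat([an.simulate_population(p)[0] for p in (pa, pb)], ignore_index=True)
norm = an.normalize_per_experiment(cells)
introns = an.per_cell_intrinsic_noise(norm, "introns")["intrinsic_noise"]
intronless = an.per_cell_intrinsic_noise(norm, "intronless")["intrinsic_noise"]
print("median intrinsic noise, introns:    %.4f" % introns.median())
print("median intrinsic noise, intronless: %.4f" % intronless.median())
print("percent decrease caused by introns: %.1f%%"
      % an.percent_decrease(intronless.median(), introns.median()))
r = an.mann_whitney_u(introns, intronless)
print("Mann-Whitney U = %.0f, p = %.3g (%s)"
      % (r.statistic, r.p_value, an.significance_label(r.p_value)))
```

prints

```
median intrinsic noise, introns:    0.0046
median intrinsic noise, intronless: 0.1280
percent decrease caused by introns: 96.4%
Mann-Whitney U = 6846, p = 2.69e-21 (***)
```

— the intron-bearing alleles sit tightly on the 1:1 diagonal (median noise
near zero) while the intronless group shows strong stochastic bias, and the
contrast is overwhelmingly significant.

The same analysis is available from the shell:

```sh
allelenoise run --config run.yaml          # simulate → noise → compare (+ manifest)
allelenoise cytometry --in stack.tif --experiment-id E1 \
    --group introns --tissue intestine --min-voxels 10 --out cells.csv
allelenoise enrich --gff genes.gff3 --mae mae.tsv --terms map.tsv --out enrich.tsv
```

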