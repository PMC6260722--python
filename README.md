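# smrlink

Linked single-cell **buoyant mass**, **growth rate**, and **gene expression**
analysis.

A serial suspended-microchannel-resonator (sSMR) array measures one cell's
buoyant mass repeatedly as it transits a chain of cantilever sensors: each
transit depresses the cantilever's resonant frequency in proportion to the
cell's buoyant mass. The slope of mass over time is the cell's **mass
accumulation rate** (MAR, pg/h), and MAR divided by mass is its **growth
efficiency** (1/h). When each cell is then captured into a well for
single-cell RNA-seq, the collection log links every transcriptome to the
biophysical record of the same cell — and the interesting questions become
statistical: *which genes track mass? which track growth efficiency? which
gene programs are enriched at the extremes?*

`smrlink` implements that full workflow as a tested, reusable pipeline:

- **`smrlink.smr`** — peak detection on frequency traces (supra-threshold
  below-baseline excursions; mass = calibration × peak depth), greedy
  in-order trajectory matching across cantilevers with `doublet_suspect` /
  `failed_match` flagging, and OLS fitting of MAR with standard errors.
- **`smrlink.linking`** — nearest-release-time joining of trajectories to
  collection-log wells; wells with zero or multiple trajectories are
  excluded and reported.
- **`smrlink.qc`** — TPM scaling, strict complexity filtering (a cell must
  *exceed* its dataset's detected-gene threshold: 4000 for lymphoblast
  lines, 2000 for CD8+ T cells, 1000 for glioblastoma PDCL cells), the
  strict >5% gene-detection filter, and the ln(TPM+1) transform.
- **`smrlink.stats`** — gene-wise Spearman/Pearson correlation against
  mass, MAR or growth efficiency; an empirical **shuffle null** (permute
  the biophysical covariate across cells, 10,000 iterations) with the
  two-standard-deviation significance rule; PC-vs-biophysics testing; and
  a self-contained Mann-Whitney U engine (exact enumeration for small
  groups, Edgeworth-corrected approximation otherwise) powering Wilcoxon
  differential expression with Bonferroni correction.
- **`smrlink.scoring`** — cell-cycle phase scores (per-cell mean of
  z-scored panel genes; G1/S vs G2/M phase calls by argmax with margin)
  and a preranked gene-set enrichment engine (weighted Kolmogorov–Smirnov
  running sum; ES, permutation-normalized NES, p and FDR q).
- **`smrlink.synthdata`** — a generative model of the whole experiment
  (cells along the cycle with a linear mass–MAR coupling, per-cantilever
  frequency traces, collection log with co-release doublets, and a
  gamma-Poisson expression matrix with phase-modulated G1/S / G2/M /
  mitosis panels, dropout and library-size variation), so every stage has
  a known-answer input.

The core statistic, for gene *g* with expression **x**<sub>g</sub> and
covariate **m** over cells: rank coefficient ρ<sub>g</sub> = Spearman(ln(TPM+1)<sub>g</sub>, **m**);
null moments (μ₀, σ₀) pooled over genes × 10,000 covariate permutations;
gene *g* is significant iff |ρ<sub>g</sub> − μ₀| > 2σ₀, with direction
sign(ρ<sub>g</sub> − μ₀).

## Worked example

```python
import smrlink as sl
from smrlink.scoring import GenePanel, panel_score
from smrlink.stats import spearman

run = sl.run_synthetic_pipeline(sl.SimConfig(seed=0))
print(f"linked cells: {len(run.linked)}  (excluded: {len(run.exclusions)})")

model = sl.CorrelationModel(run.matrix, run.covariates["mass"].to_numpy(),
                            covariate_name="mass")
results = model.fit(n_iterations=10_000, seed=0)
print(results.summary(top=5))

g2m = GenePanel.from_list("G2/M", run.panels["G2/M"])
scores = panel_score(run.matrix, g2m)
rho = spearman(scores["score"].to_numpy(), run.covariates["mass"].to_numpy())
print(f"G2/M score vs measured mass: Spearman rho = {rho:.2f}")
```

prints

```
linked cells: 194  (excluded: 9)
Gene-covariate correlation analysis
===================================================
covariate:      mass
method:         spearman
genes tested:   1000
cells:          194
null:           10000 shuffles (seed 0)
null mean (sd): -0.0002 (0.0719)
significant:    357 (82 positive, 275 negative)
---------------------------------------------------
top 5 by coefficient:
         rho  significant direction
gene
g0112 +0.516         True         +
g0062 +0.516         True         +
...
G2/M score vs measured mass: Spearman rho = 0.61
```

194 of 200 simulated cells survive device matching, well linking and QC;
the pooled shuffle null is centered with SD ≈ 1/√(n−1); the genes topping
the ranking are planted cycle-regulated genes; and the G2/M phase score
rises with measured mass (ρ ≈ 0.6), as it does in proliferating
lymphoblasts. (The many significant-*negative* background genes are the
compositional shadow of the planted positive program: TPM normalization
makes unmodulated genes shrink as cycle-regulated transcripts grow.)

A thin CLI mirrors the stages: `smrlink simulate`, `correlate`, `de`,
`pctest`, `score`, `enrich` (see `smrlink --help`).

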