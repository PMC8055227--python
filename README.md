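# hdxdiff

Differential hydrogen–deuterium exchange mass spectrometry (HDX-MS)
analysis as a scriptable Python library and command-line tool.

HDX-MS monitors protein structure and dynamics: backbone amide hydrogens
exchange with solvent deuterium at rates that reflect hydrogen bonding and
solvent accessibility, and the incorporated deuterium is detected as a
peptide-level mass increase. In a *differential* experiment, the same
protein is measured in two states (apo vs ligand-bound, wild type vs
mutant, …) and regions whose uptake changes between states report on
binding sites and conformational changes. `hdxdiff` takes the
replicate-level "cluster" CSV exported by Waters DynamX — one row per
protein × state × peptide × exposure time × charge state × replicate, with
centroid m/z and intensity — and carries it through to statistically
classified uptake differences, publication-style plot tables and
structure-coloring scripts. It is aimed at HDX-MS practitioners who want
the interactive point-and-click workflow as a reproducible batch pipeline.

## What it computes

For every peptide, state and exposure time *t* (minutes), centroids are
deconvoluted to neutral mass, the intensity-weighted mean mass of the
non-deuterated (t = 0) reference is subtracted, redundant or poor-quality
charge states are filtered out, and replicate rows are pooled into an
intensity-weighted mean uptake and standard deviation

    D̄ = Σᵢ Iᵢ Dᵢ / Σᵢ Iᵢ ,    s² = [Σᵢ Iᵢ (Dᵢ − D̄)² / Σᵢ Iᵢ] · n/(n−1)

with *n* the number of distinct replicate raw files. A maximally-labelled
control state, when provided, yields a per-peptide back-exchange
correction factor `N·f / D_max_obs` (N exchangeable amides, f the
deuterium fraction of the labelling buffer) that rescales uptake.

Peptides common to two states give ΔD = D̄_B − D̄_A per exposure, with
propagated standard error. Two significance models are available:

* **Peptide-level linear model** — replicate uptake is fit per peptide to
  `D = β₀ + βₛ·s + βₜ·t + βₛₜ·s·t + ε` with state `s` and time `t` as
  categorical factors; each term gets an extra-sum-of-squares F test, and
  p-values are adjusted across peptides by the Benjamini–Hochberg step-up
  `p* = p·m/i` (with the cumulative-minimum monotonicity pass). A peptide
  is significant when the adjusted state or interaction p-value falls
  below α.
* **Hybrid test** — a global |ΔD| threshold
  `t₍₁₋α/₂,df₎ · √(σ̄²_A/n_A + σ̄²_B/n_B)` from the pooled per-state
  variances, combined with a per-cell Welch's t-test; both prongs must
  pass.

Significant peptides are classed *deprotected* (ΔD > 0, red) or
*protected* (ΔD < 0, blue). Outputs include Woods, volcano and barcode
plot tables (and PNG renderings), per-residue coverage/redundancy tracks,
a data-quality summary, and PyMOL/Chimera coloring scripts.

A synthetic-data generator (`hdxdiff.synthetic_fixtures`) produces
DynamX-dialect cluster files with exponential exchange kinetics, known
injected state effects, back-exchange factors and noise — every statistic
in the package is validated against this ground truth.

## Worked example

Simulate a two-state experiment (40 peptides on a 120-residue protein,
3 replicates, exposures 0/0.5/5/30 min, 0.8 Da deprotection injected into
5 peptides) and run the full pipeline with the hybrid test:

```sh
hdxdiff simulate --seed 7 --effect-size 0.8 --n-affected 5 --out fixtures
hdxdiff run --input fixtures/cluster.csv --state-a APO --state-b HOLO \
            --model hybrid --alpha 0.05 --out results
hdxdiff summary fixtures/cluster.csv
```

The summary prints the community-guideline data-quality table:

```
| quantity                  | value |
|---------------------------|-------|
| peptides                  | 40 |
| protein length (residues) | 120 |
| sequence coverage (%)     | 100.0 |
| mean peptide length       | 9.78 |
| mean redundancy           | 3.26 |
| exposures (min)           | 0, 0.5, 5, 30 |
| replicates [APO]          | 3 |
| replicates [HOLO]         | 3 |
```

and `results/test_results.csv` holds one row per peptide × exposure; the
significant cells are exactly the injected deprotected peptides:

```
 start  end  exposure  delta_d  p_value  threshold   direction
     1    9       0.5 0.603270 0.001049   0.101773 deprotected
     1    9       5.0 0.524149 0.002057   0.101773 deprotected
     1    9      30.0 0.503561 0.002986   0.101773 deprotected
     2   16       0.5 0.625577 0.003073   0.101773 deprotected
     ...
```

Here `threshold` is the global hybrid |ΔD| critical value (0.102 Da at
α = 0.05 with 3 + 3 replicates), `p_value` the per-cell Welch p, and a
cell is significant only when |ΔD| exceeds the threshold *and* p < α.
`results/` also contains `woods_sum.{csv,png}`, `volcano.{csv,png}`,
`barcode.{csv,png}`, `back_exchange.csv` (with a control state),
per-residue tracks, and a `run_record.json` documenting parameters and
artifacts. `hdxdiff export-structure --program pymol …` writes a `.pml`
that paints the significance classes onto a structure.

Every stage is also callable as a library function — see
`hdxdiff.uptake_core`, `hdxdiff.differential`, `hdxdiff.stats_tests`,
`hdxdiff.summaries`, `hdxdiff.structure_export` — and as an individual
subcommand (`import`, `aggregate`, `correct`, `diff`, `test`, `summary`,
`plot`, `export-structure`).

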