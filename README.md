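# geneflux

Quantification of prokaryote genome dynamics: infer gene-family gain, loss,
expansion and reduction events on a rooted species tree under a
gain–loss–duplication birth-and-death model, convert them to per-substitution
rates, flux and balance statistics, and estimate the supergenome (gene-pool)
size by maximum-likelihood pool-sampling models. A forward simulator with a
complete ground-truth event ledger makes every inference stage testable
without external data.

## What is in here

| module | purpose |
| --- | --- |
| `geneflux.trees` | Newick I/O, least-squares midpoint rooting, branch/depth geometry |
| `geneflux.phyletic` | gene-family copy-number matrices (TSV), pangenome summaries (F, P, singletons) |
| `geneflux.gene_flux_inference` | truncated birth–death–immigration model: ML fitting (pruning algorithm), per-family per-branch event posteriors (inside–outside) |
| `geneflux.gde_rates` | rates per substitution per site / per gene, flux, balance, genomic-clock and depth-dependence diagnostics, per-COG-category flux |
| `geneflux.supergenome` | gain-multiplicity spectrum; uniform-pool and power-law-pool ML estimators with profile CIs and open/closed calls |
| `geneflux.comparative_stats` | Spearman + permutation tests, PCA of log rates, bootstrap medians, contingency chi-squared, Mann–Whitney group comparisons, synteny shuffling-rate regression |
| `geneflux.synthetic_data` | exact (Gillespie) forward simulator of gene content on Yule trees, scenario presets, ground truth |
| `geneflux.cli` | `geneflux` command-line interface |
| `geneflux.datasets` | bundled reference table of published rates for 35 prokaryote genome clusters |

## Command line

Every stochastic stage takes an explicit `--seed`; identical configuration and
seeds produce byte-identical outputs.

```bash
# synthetic data with known truth
geneflux simulate --preset chlamydia-like --seed 1 --out out/sim

# fit the birth-and-death model, export event posteriors
geneflux infer --tree out/sim/tree.nwk --matrix out/sim/matrix.tsv --out out/inf

# rate table + genomic-clock diagnostics
geneflux rates --tree out/sim/tree.nwk --matrix out/sim/matrix.tsv \
    --mean-gene-length 1000 --out out/rates --seed 1

# gain spectrum + supergenome-size estimates (uniform and power-law pools)
geneflux supergenome --tree out/sim/tree.nwk --matrix out/sim/matrix.tsv --out out/sg

# cross-dataset statistics over a rate panel
geneflux stats --panel panel.tsv --out out/stats --seed 1

# everything at once (simulated or provided inputs)
geneflux run --preset chlamydia-like --seed 1 --out out/run
```

Matrix format: TSV with header `family_id<TAB><genome>...`, non-negative
integer copy numbers, one row per family; rows absent from every genome are
rejected. Trees are Newick with branch lengths in nucleotide substitutions
per site.

## Model notes

- The copy number `n` of a family evolves with down-rate `n·mu` and up-rate
  `kappa + n·lambda`, truncated at `n_max` (default: max observed + 5).
  Parameters are global across families and branches (optionally scaled by a
  2-category discrete-gamma multiplier), fitted by Nelder–Mead over
  log-rates from 5 fixed multi-starts, with each family's likelihood
  conditioned on presence in at least one genome.
- Branch events are endpoint-state transitions (gain 0→≥1, loss ≥1→0,
  expansion up, reduction down), so multiple flips inside one branch are not
  counted separately — on purpose: the resulting depth-dependent undercount
  is a documented diagnostic (`gde_rates.depth_dependence`).
- The uniform pool estimator maximizes `ln C(S, P) − K ln S` over `S ≥ P`
  with a 95% profile-likelihood CI (1.92 log-unit drop); the power-law
  estimator maximizes the Poisson likelihood of the gain-multiplicity
  spectrum `O_m` against expectations `g_m = C(K,m) Σ_i p_i^m (1−p_i)^{K−m}`
  with `p_i ∝ i^{−α}`. Families whose root-presence posterior exceeds 0.5
  are treated as ancestral: excluded from the spectrum and added back to
  closed estimates. A likelihood still rising at `S_cap = 1000·P` yields an
  "open" call.
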