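# epochmk

Epoch (time-shifted) Mk models for binary traits on time-calibrated
phylogenies, plus the surrounding comparative toolkit: constant-rate Mk
fitting, Pagel's λ phylogenetic-signal tests, marginal ancestral state
reconstruction, ordered (Sankoff) parsimony with polymorphic tips, a
constant-rate null-simulation study, and a synthetic-data generator for
chronograms, pseudo-posterior tree sets and simulated trait matrices.

The central model is an Mk process whose gain (q01) and loss (q10) rates are
multiplied by r01 and r10 at a single phylogeny-wide shift age `t_shift`.
Ages run backward (tips at 0 Ga, root at `root_age`); the multipliers apply
to the epoch *younger* than the shift. Branches spanning the shift use the
forward-ordered product of the two epoch transition matrices.

## Library quick tour

```python
import epochmk as em

cfg   = em.SynthConfig(n_tips=134, root_age=2.7, seed=1)
tree  = em.generate_chronogram(cfg)                     # ultrametric, in Ga
truth = em.EpochParams(base=em.MkRates(1.0, 1.0), t_shift=1.7,
                       r01=0.1, r10=0.1)                # 10x slowdown
states = em.simulate_trait(tree, truth, seed=2)

fit  = em.fit_epoch(tree, states)                       # free shift, 5 params
prof = em.profile_scan(tree, states, n_grid=38)         # fixed-shift profile
lam  = em.phylo_signal_test(tree, states)               # Pagel's λ LRT
asr  = em.epoch_asr(tree, states, fit)                  # marginal ASR
```

Key entry points per module:

- `treeio` — `read_chronogram`, `read_tree_set`, `read_trait_matrix`
  (Newick/NEXUS trees, CSV/NEXUS matrices), `match_tree_and_traits`.
- `mk_core` — `transition_matrix`, `pruning_lnL`, `fit_mk` (Mk1/Mk2),
  `lambda_transform`, `phylo_signal_test`, `marginal_asr`.
- `epoch` — `epoch_lnL`, `fit_epoch` (free/fixed shift; `equal_rates=True`
  ties q01=q10 and r01=r10), `profile_scan`, `cumulative_support`,
  `fit_joint` (shared shift and multipliers across traits), `epoch_asr`.
- `parsimony` — `sankoff_ordered` (linear step costs, polymorphic tips),
  `fitch_binary`.
- `simstudy` — `harvest_parameter_pool`, `run_null_study`,
  `shift_magnitude_density`.
- `synthetic_data` — `generate_chronogram`, `generate_pseudo_posterior`,
  `simulate_trait`, `generate_trait_matrix`.

## CLI

The `epochmk` console script (or `python -m epochmk.cli`) exposes the
pipeline stage by stage:

```sh
epochmk simulate --n-tips 134 --root-age 2.7 --n-traits 25 --out synthetic/
epochmk fit-mk    --tree synthetic/chronogram.nwk --traits synthetic/traits.csv --trait trait01
epochmk fit-epoch --tree synthetic/chronogram.nwk --traits synthetic/traits.csv --trait trait01
epochmk profile   --tree synthetic/chronogram.nwk --traits synthetic/traits.csv --out profiles.csv
epochmk joint     --tree synthetic/chronogram.nwk --traits synthetic/traits.csv
epochmk signal    --tree synthetic/chronogram.nwk --traits synthetic/traits.csv --trait trait01
epochmk asr       --tree synthetic/chronogram.nwk --traits synthetic/traits.csv --trait trait01
epochmk parsimony --tree synthetic/chronogram.nwk --traits synthetic/traits.csv --trait trait01
epochmk simstudy  --traits synthetic/traits.csv --tree-sets synthetic/set1.nwk --tree-sets synthetic/set2.nwk
epochmk report    config.yaml --out report/
```

`epochmk report` runs the full analysis (per-trait epoch fits over a tree
sample, 38-point likelihood profiles, thresholded cumulative support, the
joint shared-shift model, signal tests, ASR tables and optionally the null
study) from a single YAML config and writes CSV/JSON tables plus a resolved
config and a structured log. Outputs are deterministic functions of
(inputs, config, seed). See `tests/test_report_cli.py` for a minimal config.

## Conventions

- Rates are events per Ga; optimisation is multi-start L-BFGS-B on the
  log10-rate scale with bounds [1e-6, 1e3] per Ga.
- Root prior defaults to flat (½, ½); stationary or user-supplied priors via
  `FitSettings`. Missing tips are marginalised by default (`drop_taxon`
  available).
- ΔAIC is reported so that positive values favour the shift model.
- The λ likelihood-ratio test uses plain χ²(1) p-values by default (matching
  the usual practice); `p_mixture=True` applies the 50:50 boundary mixture.
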