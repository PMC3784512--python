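# dyncore

Dynamic community structure and core-periphery organization of multilayer
functional networks, built end-to-end on synthetic data with planted ground
truth.

The pipeline:

1. **netbuild** — decompose windowed multichannel time series with the
   maximal overlap discrete wavelet transform (MODWT), estimate band-averaged
   magnitude-squared coherence (Welch) between all region pairs per time
   window, and stack the matrices into an N x N x L adjacency tensor.
2. **community** — multilayer modularity (Newman–Girvan intra-layer null,
   resolution `gamma`, ordinal inter-layer coupling `omega`), a Louvain-like
   locally greedy optimizer on the supra-modularity matrix, and the dynamic
   diagnostics: Q, number of communities, per-node flexibility.
3. **temporal** — a nodal null model that rewires inter-layer edge ends
   uniformly at random; nodes are classified as temporal core / bulk /
   periphery against the 2.5%/97.5% confidence bounds of the null
   flexibility distribution.
4. **geomcore** — continuous geometrical core scores per layer: a
   two-parameter (alpha = boundary sharpness, beta = core size) transition
   vector, core quality `R = sum A_ij C_i C_j` maximized over node
   orderings by simulated annealing, (alpha, beta) landscapes, and
   per-node score summaries.
5. **behavior** — movement times and robust (least-absolute-residual)
   exponential learning-curve fits `MT(t) = A exp(kappa t) + B`, plus the
   training-design arithmetic (cumulative practiced trials).
6. **linkstats** — flexibility-distribution moments (skewness, non-excess
   kurtosis) and Spearman/Pearson machinery linking flexibility to the
   learning parameter and to geometrical core scores.
7. **synth** — generators with planted structure: evolving community labels
   with stiff-core / switching-periphery strata, band-limited latent
   signals, block-structured adjacency tensors, and behavioral cohorts with
   a planted flexibility-moment → kappa effect.

## CLI

```sh
dyncore simulate   --config cfg.yaml --seed 1 --out ts_prefix
dyncore build      --timeseries ts_prefix --out tensor_dir
dyncore communities --tensor tensor_dir --out comm
dyncore nullband   --tensor tensor_dir --flexibility comm.json --out nb
dyncore corescore  --tensor tensor_dir --out cs
dyncore behavior   --trials trials.tsv --out fits.json
dyncore link       --flexibility flex.json --kappas fits.json --out link.json
dyncore run-all    --config cfg.yaml --seed 1 --out run_dir
```

Configs are YAML or JSON; every result file records the parameters and
seeds that produced it. Exit codes: 0 success, 2 config error, 3 data
error, 4 numerical failure.

All file formats are plain text: TSV matrices/tables with JSON sidecars
and manifests (see `dyncore.io`).

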