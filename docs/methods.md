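# Methods

## Co-dependency overlap screen

**Model.** The screen treats a gene-effect matrix (cell lines × genes of
real-valued CRISPR dependency scores; more negative = stronger fitness
dependence) as a set of gene profiles and measures co-dependency as the
Pearson correlation of two profiles over the cell lines where both are
observed (pairwise-complete). For each seed gene the top-*k* partners are
ranked, by default by |r| so that strong negative co-dependencies (e.g.
a pathway's inhibitor) remain rankable; `signed_positive` (r descending)
is available because portal ranking conventions vary. Ties are broken by
(symbol, Entrez id) ascending so top-*k* boundaries are reproducible. The
overlap score of a gene is the number of distinct seed lists containing
it; the score universe is the set of genes appearing in at least one
list, not the whole matrix.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| k (list length) | 100 | the conventional portal top-100 list |
| ranking | absolute | negative correlates must be rankable |
| min_pairs | 25 | guards degenerate correlations on sparse columns |
| cutoff | 3 | conventional candidate threshold; ≈ top 5% of scored outputs |
| top_fraction | 0.05 | used only when no explicit cutoff is given |

An explicit cutoff takes precedence over the fraction; the achieved top
fraction is always reported rather than asserted, since a discrete score
distribution rarely lands on 5% exactly. The fraction-derived cutoff is
the smallest *achieved* score whose tail (S ≥ c) is at most the target
fraction; if none qualifies (e.g. all scores equal) the cutoff is
max(S)+1 with a warning and the candidate set is empty. Duplicate
symbols with distinct Entrez ids are scored separately; seed lookup is a
case-sensitive symbol match with Entrez id as tie-breaker.

**Numerics.** Correlations are computed from masked sums arranged so that
swapping the two genes gives bitwise-identical results (exact symmetry);
a profile is treated as constant — correlation undefined, entry skipped —
when its variance falls below 1e-12 of its mean square. Values are
clipped to [-1, 1] to absorb one-ulp overshoot.

Precomputed per-seed top-k lists can be supplied in place of the
correlation engine (`load_precomputed_table`) to reproduce portal-era
outputs exactly.

## BLI 1:1 kinetics

**Model.** For a 1:1 interaction at analyte concentration C (molar):
association `R(t) = Req·(1 − exp(−kobs·t))` with `kobs = kon·C + koff`
and `Req = Rmax·C/(KD + C)`; dissociation `R(t) = R_end·exp(−koff·t)`;
`KD = koff/kon`. Equilibrium responses follow the rectangular hyperbola
`Response(C) = Rmax·C/(KD + C)`, evaluated as `Rmax·(C/(KD+C))` so that
`Response(KD) = Rmax/2` holds exactly in floating point.

**Processing chain.** Double reference subtraction
`(sample − reference) − (zero-analyte sample − zero-analyte reference)`
removes sensor-specific nonspecific signal and plate-common drift; curves
are then baseline-aligned (pre-association mean to zero) and smoothed
with a Savitzky–Golay filter (window 11 points, order 3 by default —
mild, configurable), applied per phase so the kink at the phase boundary
is not blurred into the fit windows. Time grids must match exactly;
nothing is interpolated silently.

Inter-step alignment (removing the vertical jump when the sensor changes
wells) is implemented as a shift of the dissociation segment onto the
association end, with the boundary response estimated from each side by
least-squares quadratics over the adjacent samples. It is **off by
default** in `analyze_sensorgram_set`: on a continuous trace the step is
zero and estimating it only injects noise into the dissociation fit
(measured to break 5% rate-constant recovery at 1% noise), and the
simulator does not generate step artifacts. Enable `interstep=True` (CLI
`--interstep`) for instrument exports with visible jumps.

**Fitting.** Three routes are computed and reported:

* *Per-curve*: nonlinear least squares of the exponential models over the
  first 20 s of association and dissociation (the classical short-window
  analysis), with analytic Jacobians and a small multi-start ladder;
  nonpositive rates are flagged, never clipped. kon is the OLS slope of
  kobs versus C (intercept kept as a koff cross-check); the reported
  per-curve koff averages the dissociation fits, precision-weighted by
  their standard errors by default (`koff_weighting="uniform"` for the
  plain mean) because low-concentration curves dissociate from a small
  amplitude and carry little information.
* *Global* (headline values): one least-squares fit of (kon, koff, Rmax)
  in log space across all curves' fit windows, with each dissociation
  anchored at the response the model reaches at the end of the full
  association phase. At the simulated design (five concentrations
  12.5–200 nM, 1% noise) the short-window per-curve route is
  ill-conditioned (kobs·20 s ≈ 0.2–0.6), while the global fit attains the
  Cramér–Rao bound (≈1% relative on kon and koff).
* *Steady state*: (KD, Rmax) of the hyperbola over equilibrium responses,
  initialized at KD₀ = median(C), Rmax₀ = 1.1·max(Req), with a restart
  ladder. Because slow kinetics never reach equilibrium inside the 20-s
  window, equilibrium responses are extrapolated from an exponential fit
  of the **entire** association phase.

Units are molar, seconds and nm shift throughout; mixing nM/µM/mM is the
caller's responsibility at the I/O boundary, where concentrations are
always labelled in molar.

## NSAF / enrichment

`NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j)` within a run; `pNSAF = 100·NSAF`.
The normalized ratio is evaluated in exact rational arithmetic so that
multiplying every count in a run by a common integer (sequencing depth)
leaves NSAF values bit-identical, and each run sums to 1 up to float
conversion (< 1e-9). Zero-count proteins get NSAF 0; an all-zero run is
an error.

Enrichment against controls is `log2((bait + ε)/(mean control + ε))` with
pseudocount ε defaulting to half the smallest nonzero NSAF across runs
(scale-aware); proteins absent from a run contribute 0 there, and a
protein is flagged when its fold is ≥ 2 (configurable) and it is present
in the bait. This is a deliberately simple, clearly-labelled ranking
statistic — it makes no significance claims and does not reproduce any
formal enrichment test.

## Synthetic data

* **Effect matrices** use a latent-factor (spiked covariance) model:
  value(line, gene) = Σ_m loading(gene,m)·f_m(line) + noise, with factors
  and noise standard normal. Within-module correlation is
  loading²/(loading² + noise_sd²) — loading 1.0 with noise 0.5 gives
  r = 0.8, a strong but not degenerate module. Missing cells are masked
  uniformly. The generator is **not** a DepMap release emulator: no
  screen-quality artifacts, copy-number effects or lineage structure, so
  passing tests demonstrate the engine's correctness, not robustness to
  real-portal confounders.
* **Sensorgrams** follow the 1:1 model exactly plus optional Gaussian
  noise and a deterministic linear drift shared with the matched
  reference curves (so double referencing cancels it, as on a plate
  where all sensors see the same buffer evolution). Defaults — 300 s
  association/dissociation at 10 Hz with a 10 s baseline — are what a
  practitioner would choose for koff = 1e-2 1/s (t½ ≈ 69 s). Not
  modelled: mass-transport limitation, heterogeneous ligand, sensor
  decay, step artifacts.
* **Spectral counts** are multinomial with probability ∝ abundance ×
  length per run (controls drawn from a separate background abundance),
  so counts in a run sum exactly to the requested depth.

All generators are bit-reproducible from their integer seed.

## Design choices and limitations

* The screen's brute-force oracles (per-pair correlation + full sort;
  set-intersection counting) are kept independent of the vectorized
  engine and run on every small matrix in the suite.
* The BLI acceptance condition (kon/koff within 5%, KD/Rmax within 10%,
  ≥ 18/20 seeds at 1% noise) is evaluated on the global-fit and
  steady-state outputs, which are the pipeline's headline values.
* Simulation sizes in the test suite (matrices up to 50 genes, 20-seed
  kinetic studies, 100-seed recovery rates) were chosen as the smallest
  designs at which the measured rates are stable.
* Real-data caveats: the screen's input quality (batch effects, lineage
  confounding) and ranking-convention differences between portal releases
  can move top-k boundaries; both ranking conventions are exposed so the
  sensitivity can be reported alongside any result.
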