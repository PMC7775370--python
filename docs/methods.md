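# Methods

This note documents the models, estimators, defaults and numerical choices
behind flapskit, and what the synthetic-data generators do and do not
emulate.

## Chain-scission kinetics and the simulated chromatograms

Chains are tracked as integer-DP multisets; `n_chains` identical parent
chains of DP *P* (default 2,000 in analyses, 800 in the default pipeline
config) are followed per incubation.

* **endo_random** — every glycosidic linkage carries an independent
  exponential cleavage clock with per-linkage rate *k* (h⁻¹), so at time
  *t* each original linkage is cut with probability 1 − e^(−kt). Sampling
  the clock once per linkage makes the time series internally consistent
  (a linkage cut at 24 h stays cut at 72 h) and makes the closed form
  exactly the expectation of the simulation.
* **exo_monomer** — terminal monomers are removed at per-end rate *k*
  (two active ends while DP > 2, one cut finishes a DP-2 chain). Complete
  depolymerization of one chain therefore takes exactly *P* − 1 cuts,
  i.e. (P−1)/P cuts per monomer-equivalent, which is the anchor used in
  tests.
* **killed** — the autoclaved-control flag forces the effective rate to 0
  regardless of the nominal rate.

The ground-truth record stores the realized cumulative cleavages per
monomer-equivalent at every timepoint, so every downstream estimate can be
scored against the same realization rather than against the ensemble mean.

**Elution model.** Each DP class elutes as a Gaussian of constant width
(default σ = 0.15 elution units) centered at the calibrated position of its
MW (anhydro-hexose residue mass 162.14 Da + 18.02 Da water). The default
calibration maps log₁₀ MW linearly onto elution 5–15 (large molecules
early), i.e. ≈ 5 elution units per decade. True column physics (peak
tailing, resolution loss at high MW, calibration drift) is not modeled;
the elution layer exists to exercise calibration, binning and integration.

**Noise.** `noise_sd` is additive Gaussian noise *relative to the t₀ peak
height*, applied per grid point. Under this definition the integral of the
noise over the profile has standard deviation noise_sd · peak₀ · √n · Δx,
which is the tolerance the label-conservation property uses.

## MW binning and the rate estimator

Bins are expressed in DP with strictly decreasing edges; each bin carries a
representative DP *dᵢ* used as its cut-weight. Two constructors:

* `MWBinning.default(P)` — six display classes (parent, 0.5 P, 0.1 P,
  DP 10, DP 2–3, monomer), representatives on the class centers (monomer
  exactly 1) and edges at geometric midpoints of adjacent representatives.
  When representatives are not supplied explicitly, the geometric mean of
  the bin edges is used as the fallback.
* `MWBinning.log_spaced(P, n)` — *n* geometrically spaced classes from the
  parent to the monomer. Quantitative rate work uses this fine binning
  (default 16 classes): the per-class weight 1/dᵢ − 1/P is exact only when
  fragments sit at the representative DP, so the discretization bias of the
  estimator shrinks with bin width. With 16 classes for P = 100, noise-free
  recovery of the realized cleavage rate is better than 1–5 % wherever the
  parent class holds < 50 % of the label.

The rate estimator (see README formula) floors negative per-bin integrals
at zero, counts only fraction increases in non-parent classes, and divides
by elapsed time against t₀. Consequences worth knowing:

* the rate is invariant to uniform rescaling of the raw signal;
* it is bounded by C·(1 − 1/P)/Δt (complete depolymerization);
* once the distribution stops changing, the estimate decays exactly as
  1/t — the late-timepoint underestimation mechanism;
* replicate aggregation (mean, sd) happens after per-replicate rate
  computation, matching triplicate incubation reporting. Under 2 %
  integration noise, single-replicate estimates at early timepoints can
  deviate up to ~20–25 %; triplicate means stay within ~15 %.

Killed-control correction subtracts the control's rate and floors at 0; it
is optional because not every dataset includes a control, and it requires
matching substrate and elapsed time.

## Imaging

Scenes are rendered as filled discs (uniform area within
`cell_area_range`, default 0.25–0.6 µm²) convolved with a Gaussian blur
(σ = 0.6 px) on a flat background (level 100 counts, additive Gaussian
noise, default 5 % of background), written as 16-bit TIFF pairs. Selfish
cells receive a concentric green disc drawn smaller than the cell, so true
overlap is 100 % of the label area. The nominal green disc area defaults to
0.20–0.26 µm²: pixelation and blur move *measured* (thresholded) areas by
roughly ±1–2 px, and this nominal window keeps measurements inside the
fixed 0.17–0.3 µm² detection window. Pixel pitch defaults to 0.1 µm/px so
1 px = 0.01 µm² and the pixel/area equivalence holds.

Detection thresholds the image at `sbr_min ×` background (background =
per-image median — robust to sparse bright objects; no rolling-ball
correction), takes 8-connected components and filters by area. The FLA
criteria are fixed at SBR ≥ 2.5 and 0.17–0.3 µm²; the DAPI thresholds are
not published anywhere authoritative, so they are declared defaults
(SBR ≥ 2.0, 0.1–1.5 µm²), both configurable. The 30 % overlap criterion
does not name a denominator; flapskit divides the shared pixel area by the
**FLA object's** area (the smaller, substrate-signal object), configurable
via `DetectionParams`. Matching is greedy, largest overlap first, ties
broken by lower object id; each green object matches at most one cell.

Counts convert to abundance as mean(count/FOV) × (effective filtration
area / FOV area) / volume filtered, with the per-FOV standard deviation
scaled the same way. Manual curation of false-positive green signals is out
of scope; an exclusion list can be applied upstream of the counts.

What passing the imaging tests does *not* show about real micrographs:
crowded or touching cells, non-disc morphologies, uneven illumination,
autofluorescence and out-of-focus light are not simulated, so the ≥ 0.95
precision/recall demonstrated on well-separated synthetic scenes at SBR 5
is an upper bound on real performance.

## In situ corrections

`temperature_adjust` *evaluates* the linear temperature–rate regression
(slope 0.5644 nmol monomer L⁻¹ h⁻¹ °C⁻¹, intercept 0.5098, r² = 0.7695,
diagnostic only) at the in situ temperature and clamps at zero below the
x-intercept. Direct evaluation, rather than ratio rescaling of the measured
rate, is the default because it reproduces the reference worked value
(2.31 ≈ 2.3 at 3.19 °C); a ratio variant (`temperature_rescale`) is
provided for sensitivity analysis. Note the regression's own rounding
behavior: at 1.5 °C it evaluates to 1.36, and 2.31 × 9.1 % ≈ 210 pmol;
tests pin only values the equation itself reproduces.

`growth_adjust` multiplies by the initial/reference (day-3) cell ratio and
converts nmol → pmol (factor exactly 1000). Both corrections are scalar
multiplications, so their composition is order-independent.

## Community statistics

* Normalization is total-sum only (no rarefaction or variance-stabilizing
  transform). Samples under 10,000 reads are flagged and retained.
* Bray–Curtis is computed from the formula Σ|x−y| / Σ(x+y) (vectorized);
  a pair of all-zero samples is rejected as undefined.
* The dendrogram uses average linkage (UPGMA) via scipy — the common
  default for community dendrograms; heights are monotone.
* ANOSIM R = (r̄_between − r̄_within) / (n(n−1)/4) over mid-ranked pairwise
  dissimilarities, so R ∈ [−1, 1] and maximal separation gives exactly 1.
* PERMANOVA: SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within summed per group over
  within-group pairs divided by group size; pseudo-F with (a−1, n−a)
  degrees of freedom. A degenerate SS_within = 0 reports an infinite F with
  the p-value still taken from permutations.
* p-values use the add-one estimator (1+b)/(1+m) (never zero); permuted
  statistics are compared to the observed one with a 10⁻¹² tie tolerance.
  `n_perm="exhaustive"` enumerates all label orderings (small n), treated
  as the permutation sample under the same estimator. One-factor designs
  only; crossed factors are analyzed factor-by-factor.

The count-table generator draws per-sample proportions from a Dirichlet
(concentration 500) centered on the expected composition — a power-law
baseline plus one opportunist whose share follows
plateau/(1 + e^(−s(day − midpoint))) (defaults: plateau 0.65, midpoint day
2, steepness 2 day⁻¹, reaching the 50–80 % band from day 3) — then reads
multinomially at a lognormal depth (median 65,000, ≥ 1,000). It does not
simulate taxonomy assignment, chimeras, or compositional artifacts of
amplification.

## Cell-count dynamics

Mean curves are logistic growth toward a plateau (default: 1.5 × 10⁴ →
3 × 10⁵ cells ml⁻¹ at 2 day⁻¹, near the plateau by day 3), exponential
decline toward a floor (emulating the ~50 % crash near the deep chlorophyll
maximum), or constant; observation noise is lognormal, and replicates
(default 3) share the noiseless mean exactly when noise is zero.

## Problem sizes and determinism

Default analysis sizes — 2,000 chains, 16 MW classes, 20 FOVs of 50 cells
for round-trip scoring, 18-sample count tables, 199–999 permutations, 1,000
null simulations for the type-I-error check — keep any stage to seconds on
one core while holding Monte-Carlo error well inside the tolerances quoted
above. Every generator and permutation test takes an explicit integer seed
(no global RNG state); identical spec + seed is bit-identical, and the
pipeline derives stage seeds from the single config seed, stamping the seed
and a config hash into every report.

## Known limitations

* The cut-weight scheme (1/dᵢ − 1/P) is a counting-based default, exact
  for complete depolymerization and zero for no change; it is isolated in
  one function (`chrom.cut_weights`) so an alternative weighting can be
  swapped in.
* The GPC bin structure of any particular laboratory is configuration, not
  a constant; results are reported per binning.
* The temperature regression applies to laminarin; applying it to other
  substrates is extrapolation.
* No deconvolution of overlapping elution peaks; heavily overlapping MW
  classes bias fractions toward their shared boundary.
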