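# Methods

## Problem

Vessels in photoacoustic and similar grayscale biomedical images appear as
bright tubular structures on a darker, noisy background. `metathresh`
segments such images by **multilevel histogram thresholding**: k ordered
gray-level thresholds t_1 < … < t_k partition the intensity range [0, L−1]
into k+1 classes, the brightest class is taken as vessel, and the thresholds
are chosen by maximizing a histogram criterion with a population
metaheuristic.

## Thresholding criteria

Let h(i) = f_i / N be the normalized histogram (f_i pixels at level i, N
total). Classes use inclusive left boundaries: class 0 is [0, t_1], class j
is [t_j + 1, t_{j+1}], class k is [t_k + 1, L−1]; a pixel equal to a
threshold joins the lower class. This one convention is shared by the
objectives and the label maps so they can never disagree.

**Shannon entropy (SEF).** With class mass w_c = Σ_{i∈c} h(i) and
within-class distribution p_c(i) = h(i)/w_c,

    H(t_1..t_k) = Σ_c [ − Σ_{i∈c} p_c(i) ln p_c(i) ]  →  max.

0·ln 0 ≡ 0 throughout; an empty class contributes 0. Maximizing H favours
classes that are internally uniform.

**Multilevel Otsu (MLOT).** With class probability ω_j, class mean μ_j and
global mean μ_T = Σ_j ω_j μ_j,

    σ_B²(t_1..t_k) = Σ_j ω_j (μ_j − μ_T)²  →  max,

the between-class variance, bounded above by the total variance σ_T²
(variance decomposition). Empty classes contribute 0 (ω_j = 0, μ_j := 0).

Both criteria are evaluated in O(k) per threshold vector from prefix sums of
h(i), i·h(i) and h(i)·ln h(i), which keeps exhaustive enumeration and the
metaheuristics cheap. `brute_force_optimum` enumerates every strictly
increasing combination (budget-capped) with lexicographically-smallest
tie-breaking and serves as the independent reference throughout the tests.

## Optimizers

All three algorithms maximize `objective(thresholds)` over the box
[1, L−2]^k. Internally positions are continuous so the update equations
apply verbatim; `decode` rounds, sorts, and repairs duplicates (upward, then
downward at the upper bound) only at evaluation time. One seeded
`numpy.random.Generator` per run makes every result bitwise reproducible;
the best-so-far trace is elitist and non-decreasing by construction.

- **Cuckoo search (CS).** Trial nests X_i + α·Levy(β)·(X_i − X_best) with
  Mantegna's Levy step u/|v|^{1/β}, σ_u from the Gamma-ratio formula
  (σ_u ≈ 0.6966 at β = 1.5); a trial greedily replaces a *randomly chosen*
  nest; each generation a fraction pa of the worst nests is re-drawn by a
  bounded random walk between two random nests. Defaults pa = 0.25, α = 1,
  β = 1.5.
- **Equilibrium optimizer (EO).** A pool of the 4 best candidates plus
  their component-wise mean; each particle moves toward a uniformly drawn
  pool member with F = a1·sign(r−0.5)(e^{−λt} − 1),
  t = (1 − Iter/Max)^{a2·Iter/Max}, plus a generation-rate term
  G = GCP(Ceq − λC)F with GCP = 0.5·r1 when r2 ≥ GP else 0; update
  C ← Ceq + (C − Ceq)F + G/(λV)(1 − F). Defaults a1 = 2, a2 = 1, GP = 0.5,
  V = 1. λ components are floored at 1e−12 to keep G/λ finite; positions are
  clamped to the box.
- **Harmony search (HS).** Each improvisation builds one new vector
  component-wise: copy from a random memory row with probability HMCR, then
  pitch-adjust by ±rand·BW with probability PAR; otherwise redraw uniformly.
  The new harmony replaces the worst row when fitter. Defaults HMCR = 0.9,
  PAR = 0.3, BW = (upper − lower)/20. HS spends exactly one evaluation per
  improvisation, so iteration counts are not comparable across algorithms;
  evaluation counts are: CS = pop + iters·(pop + round(pa·pop)),
  EO = pop·(iters + 1), HS = pop + iters.

Population defaults are 30 candidates × 100 iterations. Termination is the
fixed iteration budget only — no stall detection — so run-to-run variation
comes solely from the seed.

## Evaluation

Pixelwise against a ground-truth mask (True = vessel): Dice =
2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), sensitivity = TP/(TP+FN), accuracy =
(TP+TN)/total, all in percent, with Dice = 2·IoU/(1+IoU) as a built-in
cross-check. Degenerate conventions: both masks empty → Dice = IoU =
sensitivity = 100; truth empty with predictions present → sensitivity = 0.
Multi-run reports carry one row per run plus an arithmetic-mean Average row;
rounding to two decimals happens only at presentation.

## Synthetic phantoms

The generator emulates the structure both criteria assume — a multimodal
histogram from bright tubes on a darker background. Each vessel is a
bounded-turning random-walk centerline (per-step heading change uniform in
±`curvature` radians; 0 = straight) started on a random border heading
inward, dilated to a tube of width drawn from `width_range` via a Euclidean
distance transform. Vessel pixels take `vessel_intensity` (default 200),
background `background_intensity` (default 60), then clipped additive
Gaussian noise of `noise_sigma` (default 20) gray levels is applied and the
image is rounded to integers in [0, 255]. The mask is the exact pre-noise
tube support, so scores against it have no annotation error. Defaults: 64×64
field, 3 vessels, widths 2–5 px, curvature 0.25 — a sparse (~10–20% vessel
area), moderately tortuous field.

Deliberately not modelled: light transport and reconstruction artifacts,
speckle, limited-view streaks, 3-D geometry, intensity inhomogeneity.
Passing the recovery tests therefore shows the pipeline separates a
well-contrasted bimodal intensity mixture under Gaussian noise; it does not
certify performance on real photoacoustic reconstructions.

`sample_histogram` draws histograms directly from a Gaussian mixture
(multinomial mode counts, clipped normal draws) for tests whose optimal
thresholds are predictable from the mode layout.

## Numerical and design notes

- **Entropy degeneracy on two-level images.** On a noiseless two-value
  histogram every separating threshold yields H = 0 while merging both
  levels into one class yields ln 2 > 0, so the entropy optimum *lumps* the
  modes and the top-class mask is degenerate. Exact noiseless recovery is
  therefore an Otsu property only; with noise present the entropy criterion
  behaves normally. Relatedly, on strongly imbalanced histograms the entropy
  optimum sits in the dominant mode's upper shoulder, admitting some false
  positives — on sparse-vessel phantoms its Dice averages ≈ 91% where Otsu
  reaches ≈ 99.9%.
- **Tie plateaus.** Otsu's criterion is piecewise constant over empty-bin
  gaps; the brute-force reference breaks ties by the lexicographically
  smallest vector, and optimizer-vs-oracle comparisons are made on fitness,
  not on threshold identity.
- **Problem sizes.** Oracle-equivalence experiments run at L = 16 (random
  2–3 mode mixtures, 512 samples) where exhaustive enumeration is exact and
  instant; recovery experiments use 64×64 phantoms; CS/EO use 15×200 and HS
  10×300 budgets in the small-L experiments, library defaults (30×100)
  elsewhere. These sizes make the full validation suite run in well under a
  minute while every claim is still checked against an exact reference.
- **Grid seeding.** Run r of every grid cell uses seed base+r, so the six
  cells see identical stochastic conditions and differ only in
  objective/optimizer — a controlled comparison.

## Known limitations

- Thresholding is global: spatially varying background or intensity
  inhomogeneity breaks the single-histogram assumption.
- The vessel rule "brightest class" presumes bright vessels; dark-vessel
  modalities need an explicit `vessel_labels` set.
- The entropy criterion's imbalance bias (above) is inherent to the
  criterion, not fixable by a better optimizer.
- Metaheuristic guarantees are empirical (oracle-equivalence rates), not
  proofs of convergence.
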