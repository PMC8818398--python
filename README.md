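# metathresh

Metaheuristic multilevel thresholding for vessel segmentation in grayscale
biomedical images (photoacoustic-style vascular imagery in particular).

Bright tubular vessels on a darker noisy background produce a multimodal
intensity histogram. `metathresh` picks k ordered gray-level thresholds
t_1 < … < t_k by maximizing one of two histogram criteria

- **SEF** — summed within-class Shannon entropy
  H = Σ_c [ −Σ_{i∈c} p_c(i) ln p_c(i) ],
- **MLOT** — multilevel Otsu between-class variance
  σ_B² = Σ_j ω_j (μ_j − μ_T)²,

using one of three population metaheuristics — **cuckoo search** (Lévy
flights via Mantegna's method), the **equilibrium optimizer** (4-candidate
pool + mean), and **harmony search** (memory consideration / pitch
adjustment) — then converts the resulting (k+1)-class label map into a
binary vessel mask (brightest class = vessel) and scores it against ground
truth with Dice, IoU, sensitivity and accuracy.

Because real benchmark data of this kind is generally unavailable, the
package ships a synthetic **vessel-phantom generator** (curvilinear tubes,
controllable contrast/width/noise, exact ground-truth masks) and an
exhaustive **brute-force reference** so every component can be validated
against an exact optimum.

## Worked example

```python
from metathresh import (PhantomConfig, RunConfig, OptimizerConfig,
                        generate_phantom, segment, build_report,
                        run_grid, comparison_table)

image, truth = generate_phantom(PhantomConfig(seed=1))  # 64x64, vessels 200 on 60, noise 20
out = segment(image, RunConfig(objective="otsu", optimizer="hs", k=1,
              optimizer_config=OptimizerConfig(algorithm="hs",
                  population_size=10, max_iterations=300, seed=1)))
print("thresholds:", out.thresholds.tolist())
print(build_report([(out.mask, truth)]).to_dataframe())
```

prints

```
thresholds: [130]
             Dice coefficient    IoU  Sensitivity  Accuracy
No. of runs
Run-1                   99.87  99.73        100.0     99.95
Average                 99.87  99.73        100.0     99.95
```

Harmony search placed the single threshold at 130, between the background
(60) and vessel (200) modes; against the exact phantom mask the predicted
vessels overlap almost perfectly (Dice 99.87%), with every true vessel pixel
found (sensitivity 100%). The full 2×3 method grid, five seed-varied runs
per cell under identical seeds:

```python
reports = run_grid(image, truth,
                   base=RunConfig(k=1, optimizer_config=OptimizerConfig(seed=1)),
                   n_runs=5)
print(comparison_table(reports).round(2))
```

```
         Dice coefficient    IoU  Sensitivity  Accuracy
Methods
SEF-CS              91.56  84.43        100.0     96.62
SEF-EO              91.25  83.91        100.0     96.48
SEF-HS              93.02  86.99        100.0     97.24
MLOT-CS             99.87  99.73        100.0     99.95
MLOT-EO             99.87  99.73        100.0     99.95
MLOT-HS             99.87  99.73        100.0     99.95
```

Otsu's criterion is near-exact on this well-contrasted phantom; the entropy
criterion admits some false positives on sparse-vessel images (its optimum
sits in the background mode's shoulder — see `docs/methods.md`), which is
why its Dice/IoU trail while its sensitivity stays perfect.

## Command line

```sh
metathresh phantom --seed 1 --out data/           # phantom + exact mask + config sidecar
metathresh segment --input data/phantom.png --objective otsu --optimizer cs \
    --k 2 --pop 30 --iters 100 --seed 0 --truth data/mask.png --out run/
metathresh grid --input data/phantom.png --truth data/mask.png --runs 5 --out grid/
metathresh oracle --input data/phantom.png --objective otsu --k 2   # exhaustive reference
```

`segment` writes the label map and mask PNGs, a convergence CSV and a JSON
run manifest; `grid` writes one 5-runs-plus-average CSV table per
objective×optimizer cell and a combined comparison table.

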