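# goldilocks-rna

Magnesium is a double-edged sword for RNA: Mg²⁺ catalyzes in-line cleavage
of the phosphodiester backbone, but it also drives RNA folding, and folded
RNA is far less likely to adopt the in-line geometry that cleavage requires.
When folding outpaces catalysis, the chemical lifetime of an RNA develops a
local maximum — a **Goldilocks peak** — at the Mg²⁺ concentrations where the
molecule folds: too little Mg²⁺ and the RNA is unfolded and labile, too much
and cleavage catalysis wins again.

This package is for researchers who model or measure Mg²⁺-dependent RNA
degradation. It provides:

* **Model evaluation** (`goldilocks.models`): one-, two-, and three-state
  coupled folding/cleavage models. Folding follows the Hill equation

  $$f_f = \frac{1}{1 + (K_D/[\mathrm{Mg^{2+}}])^n},$$

  the observed pseudo-first-order cleavage rate constant is the
  occupancy-weighted convolution

  $$k_{obs} = \sum_s f_s\,k_s\,[\mathrm{Mg^{2+}}]$$

  over states $s \in \{u, i, f\}$ with per-bond second-order rate constants
  $k_s$ (s⁻¹M⁻¹), and the chemical lifetime is $1/k_{obs}$. Absolute (mM,
  s) and relative ([Mg²⁺]_rel, t_rel) unit systems are supported with exact
  round-trip conversion.
* **Landscape analysis** (`goldilocks.landscape`): extremum detection by
  root-finding on the analytic lifetime derivative, peak intensity
  (max/min lifetime ratio), half-height width, area above the flank chord,
  factor-ladder parameter sweeps, the (n, k_u/k_f) intensity survey, and
  three-state intermediate scenarios.
* **Fitting** (`goldilocks.fitting`): deterministic multi-start nonlinear
  least squares for lifetime titrations (log-lifetime loss) and
  fraction-folded titrations (linear loss), with nested two- vs three-state
  model comparison.
* **Experiment reduction** (`goldilocks.reduction`): CD ellipticity →
  fraction folded (linear-baseline stripping), endpoint gel fraction-intact
  → per-bond lifetime, fragment intensities → extent of cleavage,
  Δcleavage vs a baseline Mg²⁺ condition, and paired/unpaired dispersion
  summaries.
* **Synthetic data** (`goldilocks.synth`): generators for every input class
  with ground truth returned beside the data, plus presets carrying the
  fitted parameter sets of yeast tRNA-Phe, the *Tetrahymena* P4–P6 domain,
  and a non-folding rU₂₀-like control.

## Worked example

```python
import numpy as np
from goldilocks import (ModelSpec, FoldingTwoState, CleavageRates,
                        goldilocks_peaks, fit_lifetime)
from goldilocks.synth import SyntheticConfig, gen_lifetime_titration, preset_spec

# a two-state RNA in relative units: folds at 1 Mg_rel, 5x protection
spec = ModelSpec(states=2, folding=FoldingTwoState(K_D=1.0, n=4.1),
                 rates=CleavageRates(k_u=1.0, k_f=0.2), units="relative")
(peak,) = goldilocks_peaks(spec)
print(f"peak at {peak.maximum.mg:.3f} Mg_rel, intensity {peak.intensity:.3f}")

# refit synthetic tRNA lifetimes and recover the protection ratios
true = preset_spec("trna_lifetime_3state")
data, _ = gen_lifetime_titration(
    SyntheticConfig(generating_spec=true, mg_grid=np.geomspace(0.5, 10, 30)))
r = fit_lifetime(data, states=3, tie_n=True).spec.rates
print(f"k_u/k_i = {r.k_u/r.k_i:.2f}, k_u/k_f = {r.k_u/r.k_f:.2f}")
```

prints

```
peak at 1.749 Mg_rel, intensity 1.295
k_u/k_i = 3.22, k_u/k_f = 2.23
```

The first line locates the Goldilocks maximum of the reference landscape
(the RNA lives ~1.3× longer on the peak than at the preceding lifetime
minimum). The second line shows that a 30-point endpoint titration
constrains the fitted unfolded-state cleavage rate constant to ~3.2× the
intermediate's and ~2.2× the folded state's — the tRNA-Phe protection
hierarchy ($k_u > k_f > k_i$).

The `examples/` directory holds one narrative script per capability
(landscape simulation, sweeps, fitting, experiment reduction, site-level
Δcleavage); each prints the numbers it computes and what they mean.

## Command line

A thin CLI wraps the library:

```sh
goldilocks synth --preset trna_lifetime_3state --grid 0.5:10:log:30 --out data.csv
goldilocks fit --data data.csv --kind lifetime --states 3 --tie-n --out fit.json
goldilocks peaks --spec spec.json
goldilocks map --n 1:20:20 --ratio 1:50:20 --out map.csv
```

Every run writes a JSON manifest recording inputs, hashes, seed and package
version.

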