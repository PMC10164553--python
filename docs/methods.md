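# Methods

## Model

An RNA at equilibrium distributes over 1–3 conformational states — unfolded
(u), an optional intermediate (i), and folded (f) — as a function of Mg²⁺.
Each state is cleaved with its own second-order rate constant k_s per
phosphodiester bond (s⁻¹M⁻¹ in absolute units). The observed
pseudo-first-order cleavage rate constant at concentration c (mM) is

    k_obs(c) = Σ_s f_s(c) · k_s · c·10⁻³

and the chemical lifetime is 1/k_obs. Folding occupancies come from Hill
transitions: the two-state fraction folded is φ(c) = 1/(1 + (K_D/c)^n).

Key assumptions, inherited from the systems this models:

* **Folding is fast relative to cleavage.** Folding relaxes in seconds to
  hours; in-line cleavage at these conditions operates over days. The
  cleavage integrates over an equilibrium folding ensemble, so no folding
  kinetics appear anywhere in the package.
* **Cleavage is first order in Mg²⁺** (the k_obs = k·[Mg²⁺] proportionality
  of in-line cleavage catalysis).
* **Per-bond homogeneity** at the whole-molecule level: endpoint gel
  reduction treats all n_bonds phosphodiester bonds as equivalent. Site
  heterogeneity is handled separately by the fragment-table analysis.

### Three-state occupancies

The two sequential transitions (u→i with K_D1, n1; i→f with K_D2, n2) are
combined in product form:

    f_u = 1 − φ₁,  f_i = φ₁(1 − φ₂),  f_f = φ₁φ₂

with φ_k the Hill fraction of transition k. This form is normalised by
construction for *any* overlap of the transitions in Mg²⁺-space, including
inverted midpoint order, which matters because fitted transitions of real
RNAs can overlap heavily. Other parameterisations (e.g. a Boltzmann-weighted
sum of species) are algebraically equivalent only for well-separated
transitions; the product form was chosen as the one that always yields
valid fractions.

### Units

Concentrations are mM at every interface; the mM→M conversion happens once,
inside the observed-rate evaluation, because tabulated rate constants are
s⁻¹M⁻¹. Relative units ([Mg²⁺]_rel = c/K_D_ref, t_rel = t/t_ref) bypass the
conversion; spec conversion transforms rate constants as
k_rel = k_abs · 10⁻³ · K_D_ref · t_ref so that converted models reproduce
absolute lifetimes exactly (round trips are identity to machine precision).

Hill coefficients are accepted up to n = 1000; larger values are clamped
with a warning (the Hill term is evaluated in log space with the exponent
clipped at ±700, so clamping only standardises behaviour far outside the
fitted range — the largest cooperativity encountered in practice is ~35).

Lifetime at c = 0 is undefined (no catalyst, infinite lifetime): the
package raises rather than returning infinity, and the gel reducer records
such lanes as censored instead of emitting non-finite values.

## Landscape analysis

Because lifetime = 1/k_obs with k_obs > 0, lifetime extrema coincide with
k_obs extrema, and d k_obs/dc is available in closed form (Hill derivative
φ' = nφ(1−φ)/c). Extrema are located by bracketing sign changes of the
analytic derivative on a 2048-point log grid over the analysis window and
refining each bracket with Brent's method (relative tolerance 1e-12). A
(−,+) sign pattern of the k_obs slope is a lifetime maximum, (+,−) a
minimum; consecutive extrema therefore alternate. The default window is
[min midpoint/100, max midpoint·100], wide enough to contain all folding
transitions.

* **Intensity** is the exact maximum lifetime divided by the exact lifetime
  of the immediately preceding minimum; each maximum is paired with its
  immediately preceding minimum only.
* **Half-height width** is the concentration span where lifetime exceeds
  min + (max−min)/2, measured on the peak's own rise and fall (None if the
  falling flank never reaches half height inside the window).
* **Area** integrates lifetime above the straight chord joining the peak's
  flanking minima (window edge standing in when there is no second
  minimum), trapezoidal rule on a 4096-point log grid, clipped below at
  zero. No standard baseline exists for this quantity; the chord is this
  package's definition and areas should only be compared within it. Note
  that at fixed k_u/k_f, raising n *increases* chord area (the maximum
  climbs toward 1/(k_f·K_D)) while shrinking the width: "concentration of
  protection" is the area/width density, not total area.
* **Intensity map**: per-cell two-state peak detection over (n, k_u/k_f)
  grids; cells without a peak are reported as present=False with intensity
  1.0 (a flag plus a neutral value, so the map is numeric everywhere).
* **Three-state scenarios** classify the dominant peak as early (below
  K_D2 — a protected intermediate puts the peak just past transition 1) or
  late (beyond K_D2 — a hyper-labile intermediate defers protection to the
  second transition).
* The sharp-transition limit of two-state intensity is k_u/k_f, but the
  approach is slow: at k_u/k_f = 5 the intensity is 1.30 at n = 4.1, 4.67
  at n = 200, and reaches within 2% of the limit only near n = 1000. The
  test suite asserts the brute-force-verified finite-n values, not the
  idealised limit at small n.

## Fitting

Lifetime fits minimise squared residuals of **log lifetime**: titration
lifetimes span decades, and unweighted linear loss would fit only the
longest-lived points. Folding fits use linear loss on the fraction folded.
Parameters are optimised in log space (positivity for free) with scipy's
trust-region reflective `least_squares` under box bounds: K_D within
[min(c)/10, 10·max(c)], n ∈ [0.3, 50].

Multi-start initialisation is deterministic: K_D seeds at the 25/50/75%
data quantiles, n seeds {1, 4, 15}, rate seeds from the titration
envelopes (1/(c·lifetime·10⁻³) at the first and last point, which estimate
k_u and k_f when the ends of the titration are dominated by one state).
All seed combinations run; the lowest loss wins, ties to the lowest start
index — so identical data give bit-identical fits.

Options:

* `tie_n` (default on for three-state lifetime fits) constrains n1 = n2.
  Sharp titrations constrain the product of the transitions far better than
  the individual cooperativities.
* A soft ridge (weight 0.01 per unit above 15) discourages Hill
  coefficients beyond 15 in three-state lifetime fits, where they are
  typically unconstrained plateau directions; it is inactive at and below
  the knee and off entirely in nested model comparisons.
* The three-state observable for folding data assumes the intermediate
  contributes half the optical amplitude (equal amplitudes per transition):
  signal = f_f + f_i/2. CD amplitudes of intermediates are rarely known;
  equal amplitude is the symmetric default and is isolated in one function.

Model comparison fits both state counts on identical data. The three-state
multi-start includes the fitted two-state optimum embedded exactly (setting
k_i = k_f collapses the sequential three-state rate convolution to the
two-state one identically, independent of the second transition; for
folding, a sub-window second transition with steep n does the same), so the
nesting inequality ssr₃ ≤ ssr₂ holds by construction. Three states are
preferred only when ssr improves by more than 20%; no significance test is
synthesised from residuals.

Degenerate inputs (constant observations, all-zero folding signal) are
rejected with a specific non-identifiability error before any optimiser
runs. The one-state fit uses its closed form (a mean in log space) rather
than an iterative optimiser.

## Experiment reduction

* **Analysis wavelength**: argmax over wavelengths of the smoothed
  |θ_high − θ_low| spectral difference (moving average, default width 5
  points), ties to the lowest wavelength; identical spectra are an error.
* **CD reduction** fits the full observation model
  θ = lower(c) + (upper(c) − lower(c))·φ(c) with linear pre-/post-transition
  baselines by multi-start least squares, then normalises
  (θ − lower)/(upper − lower). A titration is flagged **non-folding** when
  the sigmoid model fails to beat a plain straight line by at least 2× in
  ssr or the fitted amplitude is negligible — the behaviour of a
  non-folding single strand, which must not silently produce a fraction
  folded.
* **Gel reduction** assumes intact molecules decay first order with total
  rate n_bonds·k_bond: per-bond lifetime = −n_bonds·t / ln(fraction intact).
  Fractions of exactly 1 (no measurable cleavage) or 0 (complete
  degradation) are censored records, never numbers. Default bond counts:
  75 (76-nt tRNA), 19 (20-nt rU₂₀); otherwise sequence length − 1,
  always explicit.
* **Extent of cleavage** divides each site's fragment signal by the total
  lane signal (all sites + full-length band). Other normalisations exist
  (full-length only, ladder-referenced); the denominator choice is isolated
  in one function so it can be swapped against a known reference.
* **Δcleavage** is elementwise extent difference against a baseline
  condition (zero at the baseline, antisymmetric under baseline exchange).
  Dispersion summaries report per-condition, per-class (paired/unpaired)
  mean and SD, flagging hot spots above mean + 2 SD within the condition.

## Synthetic data

Generators invert each reduction step's forward model under a known
ModelSpec and return ground truth beside the data; test-suite round trips
assert recovery against that truth, never against copied numbers. All
randomness flows from one per-call seed (numpy `default_rng`); a seed is
mandatory whenever noise is on.

Default noise models: lognormal multiplicative (σ = 0.05) for lifetimes and
fractions intact (positive observables with roughly constant relative
error), additive Gaussian for CD ellipticity. Site tables draw per-site
extents log-normally with class-dependent coefficient of variation; a
partially folded condition is emulated by a large unpaired-class CV
(defaults 0.9 vs 0.15 paired), a folded condition by small CVs, matching
the qualitative structure of site-resolved cleavage: duplex positions
cleave uniformly, flexible positions unevenly.

The presets embed the fitted study parameter sets exactly as tabulated
(e.g. tRNA three-state lifetime: k_u = 8.7×10⁻⁵, k_i = 2.7×10⁻⁵,
k_f = 3.9×10⁻⁵ s⁻¹M⁻¹ per bond; K_D1 = 2.2 mM, K_D2 = 3.3 mM,
n1 = n2 = 15). The rU₂₀-like control has no tabulated one-state rate
constant; k_u = 1.0×10⁻⁴ s⁻¹M⁻¹ per bond was fixed once, at the labile end
of the unstructured-RNA range.

What the generators do *not* emulate: correlated noise between lanes or
sites, sequence-dependent cleavage preferences, ladder misalignment,
partial reverse-transcription drop-off, and base modifications. Passing
round-trip tests therefore demonstrate correctness of the inference
machinery under the stated noise models, not robustness to every artefact
of real capillary or gel data.

## Problem sizes and numerical choices

Refit protocols use 30 log-spaced concentrations (0.5–10 mM for the
tRNA-like set, 0.1–20 mM for the P4–P6-like set) — comparable to a dense
experimental titration and sufficient for exact noiseless recovery. The
brute-force extremum oracle in the tests uses 10⁶-point log grids; the
randomized oracle suite covers 50 specs drawn from k_u/k_f ∈ [1.5, 50],
n ∈ [1, 30], midpoints over two and a half decades. The intensity survey
runs 20×20 cells over n ∈ [1, 20], k_u/k_f ∈ [1, 50].

Known limitations: models with more than three states are out of scope;
time-resolved (kinetic) folding is out of scope by assumption; fitted Hill
coefficients at the n = 50 bound or rate constants at the envelope bounds
indicate non-identifiable directions and should be read as constraints, not
estimates; the area metric depends on the window through its right flank
when no second minimum exists.
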