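"""Reduction of raw-style experimental observations to fit-ready datasets.

Three data streams are supported:

* circular dichroism titrations — pick the analysis wavelength, strip linear
  pre-/post-transition baselines and normalise ellipticity to fraction
  folded;
* endpoint cleavage gels — convert the fraction of intact full-length RNA
  after a fixed incubation into a per-phosphodiester-bond chemical lifetime,
  assuming first-order loss with total rate n_bonds x per-bond k_obs;
* per-site fragment intensities — extent of cleavage per nucleotide,
  Δcleavage against a baseline Mg2+ condition, and paired/unpaired
  dispersion summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fitting import TitrationDataset
from .models import _hill

__all__ = [
    "CDTitration",
    "GelObservation",
    "CensoredObservation",
    "SiteCleavageTable",
    "DeltaCleavage",
    "FoldingReduction",
    "select_analysis_wavelength",
    "theta_to_fraction_folded",
    "lifetime_from_fraction_intact",
    "reduce_gel_observations",
    "extent_of_cleavage",
    "delta_cleavage",
    "dispersion_by_structure",
]

# defaults from the study systems: 76-nt tRNA -> 75 bonds, 20-nt rU20 -> 19
DEFAULT_N_BONDS = {"trna": 75, "ru20": 19}
SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class CDTitration:
    """Ellipticity (theta, mdeg) at the analysis wavelength vs [Mg2+] (mM)."""

    mg: np.ndarray
    theta: np.ndarray
    analysis_wavelength: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        mg = np.asarray(self.mg, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if mg.ndim != 1 or mg.shape != theta.shape or mg.size == 0:
            raise ValueError("mg and theta must be matching non-empty 1-D arrays")
        if np.any(mg < 0):
            raise ValueError("mg must be non-negative")
        order = np.argsort(mg)
        object.__setattr__(self, "mg", mg[order])
        object.__setattr__(self, "theta", theta[order])


@dataclass(frozen=True)
class GelObservation:
    """One endpoint gel lane: fraction of intact RNA after an incubation."""

    mg: float
    fraction_intact: float
    incubation_time: float
    n_bonds: int

    def __post_init__(self):
        if not 0.0 <= self.fraction_intact <= 1.0:
            raise ValueError("fraction_intact must lie in [0, 1]")
        if self.incubation_time <= 0:
            raise ValueError("incubation_time must be positive")
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be >= 1")
        if self.mg < 0:
            raise ValueError("mg must be non-negative")


@dataclass(frozen=True)
class CensoredObservation:
    """An observation excluded from fitting (no measurable cleavage, or
    complete degradation)."""

    observation: GelObservation
    reason: str


@dataclass(frozen=True)
class FoldingReduction:
    """Outcome of CD reduction: the normalised dataset (None when no folding
    transition was detected), the detection flag, and the fitted baselines."""

    dataset: Optional[TitrationDataset]
    folding_detected: bool
    lower_baseline: tuple[float, float]
    upper_baseline: tuple[float, float]
    K_D: Optional[float]
    n: Optional[float]


class SiteCleavageTable:
    """Per-nucleotide extent of cleavage across Mg2+ conditions.

    Stored as a wide DataFrame: index = 1-based positions (unique, sorted),
    one column per Mg2+ condition (mM), values = fraction of molecules
    cleaved at that site.  ``structure_mask`` optionally labels each position
    'paired' or 'unpaired'.
    """

    def __init__(
        self,
        extent: pd.DataFrame,
        structure_mask: Optional[pd.Series] = None,
    ):
        extent = extent.copy()
        extent.index = extent.index.astype(int)
        if extent.index.has_duplicates:
            raise ValueError("positions must be unique")
        extent = extent.sort_index()
        vals = extent.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("extents must be non-negative")
        if np.any(vals.sum(axis=0) > 1.0 + 1e-9):
            raise ValueError("per-condition extents must sum to <= 1")
        self.extent = extent
        if structure_mask is not None:
            structure_mask = structure_mask.reindex(extent.index)
            if structure_mask.isna().any():
                raise ValueError("structure mask must cover all positions")
            bad = ~structure_mask.isin(["paired", "unpaired"])
            if bad.any():
                raise ValueError("structure mask entries must be 'paired' or 'unpaired'")
        self.structure_mask = structure_mask

    @property
    def positions(self) -> np.ndarray:
        return self.extent.index.to_numpy()

    @property
    def conditions(self) -> np.ndarray:
        return np.asarray(self.extent.columns, dtype=float)

    def condition_means(self) -> pd.Series:
        """Average extent of cleavage over positions, per condition."""
        return self.extent.mean(axis=0)


@dataclass(frozen=True)
class DeltaCleavage:
    """Extent-of-cleavage differences against a baseline condition; positive
    values mean more cleavage than at the baseline."""

    baseline_condition: float
    delta: pd.DataFrame

    def __post_init__(self):
        base_col = self.delta[self.baseline_condition]
        if not np.allclose(base_col.to_numpy(dtype=float), 0.0):
            raise ValueError("delta at the baseline condition must be identically zero")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def select_analysis_wavelength(
    wavelengths: np.ndarray,
    theta_low_mg: np.ndarray,
    theta_high_mg: np.ndarray,
    smooth_window: int = SMOOTH_WINDOW,
) -> float:
    """Wavelength maximising |theta_high - theta_low| after smoothing.

    Both spectra must share the wavelength grid; ties break to the lowest
    wavelength; identical spectra carry no folding signal and raise.
    """
    wl = np.asarray(wavelengths, dtype=float)
    lo = np.asarray(theta_low_mg, dtype=float)
    hi = np.asarray(theta_high_mg, dtype=float)
    if wl.shape != lo.shape or wl.shape != hi.shape:
        raise ValueError("spectra must share one wavelength grid")
    diff = np.abs(_smooth(hi - lo, smooth_window))
    if np.max(diff) == 0:
        raise ValueError("spectra are identical: no informative wavelength")
    return float(wl[int(np.argmax(diff))])  # argmax returns the first (lowest) tie


def theta_to_fraction_folded(
    titration: CDTitration,
    improvement_factor: float = 2.0,
) -> FoldingReduction:
    """Baseline-correct a CD titration and normalise to fraction folded.

    The full observation model
    ``theta = lower(mg) + (upper(mg) - lower(mg)) * phi(mg; K_D, n)``
    with linear baselines ``lower``/``upper`` is fitted by multi-start least
    squares; the fraction folded is then
    ``(theta - lower(mg)) / (upper(mg) - lower(mg))`` clipped to the
    dataset's [-0.1, 1.1] slack.  When the sigmoid model does not beat a
    plain straight line by at least ``improvement_factor`` in ssr the
    titration is flagged non-folding (the rU20 case) and no dataset is
    produced.
    """
    mg, theta = titration.mg, titration.theta
    if mg.size < 6:
        raise ValueError("need at least 6 points to separate baselines from a transition")
    # straight-line reference
    lin_coef = np.polyfit(mg, theta, 1)
    ssr_lin = float(np.sum((np.polyval(lin_coef, mg) - theta) ** 2))

    span = np.ptp(theta) if np.ptp(theta) > 0 else 1.0
    pos = mg[mg > 0]
    kd_seeds = [float(np.quantile(pos, q)) for q in (0.25, 0.5, 0.75)]

    def model(p, mg_):
        a0, a1, b0, b1, log_kd, log_n = p
        phi = _hill(mg_, float(np.exp(log_kd)), float(np.exp(log_n)))
        lower = a0 + a1 * mg_
        upper = b0 + b1 * mg_
        return lower + (upper - lower) * phi

    best = None
    for kd in kd_seeds:
        for n0 in (1.0, 4.0, 15.0):
            p0 = np.array(
                [theta[0], 0.0, theta[-1], 0.0, np.log(kd), np.log(n0)]
            )
            try:
                res = least_squares(lambda p: model(p, mg) - theta, p0, xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            ssr = float(np.sum(res.fun**2))
            if best is None or ssr < best[1] - 1e-15:
                best = (res.x, ssr)
    if best is None:
        raise RuntimeError("baseline fit failed to converge from any start")
    p, ssr_full = best
    a0, a1, b0, b1, log_kd, log_n = p
    amplitude_mid = abs((b0 + b1 * np.median(mg)) - (a0 + a1 * np.median(mg)))
    folding = ssr_full * improvement_factor < ssr_lin and amplitude_mid > 0.01 * span
    if not folding:
        return FoldingReduction(
            dataset=None,
            folding_detected=False,
            lower_baseline=(float(a0), float(a1)),
            upper_baseline=(float(b0), float(b1)),
            K_D=None,
            n=None,
        )
    lower = a0 + a1 * mg
    upper = b0 + b1 * mg
    frac = np.clip((theta - lower) / (upper - lower), -0.1, 1.1)
    keep = mg > 0
    dataset = TitrationDataset(
        kind="folding", mg=mg[keep], value=frac[keep], metadata=dict(titration.metadata)
    )
    return FoldingReduction(
        dataset=dataset,
        folding_detected=True,
        lower_baseline=(float(a0), float(a1)),
        upper_baseline=(float(b0), float(b1)),
        K_D=float(np.exp(log_kd)),
        n=float(np.exp(log_n)),
    )


def lifetime_from_fraction_intact(obs: GelObservation):
    """Per-bond chemical lifetime from an endpoint fraction intact.

    Intact molecules decay first order with total rate n_bonds x k_bond, so
    per-bond lifetime = -n_bonds * t / ln(fraction_intact).  A lane with no
    measurable cleavage (fraction 1) or complete degradation (fraction 0) is
    censored: a :class:`CensoredObservation` is returned instead of a number,
    so non-finite lifetimes can never enter a dataset.
    """
    if obs.fraction_intact >= 1.0:
        return CensoredObservation(obs, "no measurable cleavage (fraction_intact = 1)")
    if obs.fraction_intact <= 0.0:
        return CensoredObservation(obs, "complete degradation (fraction_intact = 0)")
    return float(-obs.n_bonds * obs.incubation_time / np.log(obs.fraction_intact))


def reduce_gel_observations(
    observations: Sequence[GelObservation], metadata: Optional[dict] = None
) -> tuple[TitrationDataset, list[CensoredObservation]]:
    """Reduce a set of gel lanes to a lifetime titration, collecting censored
    lanes (and lanes at mg = 0, where lifetime is undefined) separately."""
    mg, lt, censored = [], [], []
    for obs in observations:
        if obs.mg == 0:
            censored.append(CensoredObservation(obs, "lifetime undefined at [Mg2+] = 0"))
            continue
        out = lifetime_from_fraction_intact(obs)
        if isinstance(out, CensoredObservation):
            censored.append(out)
        else:
            mg.append(obs.mg)
            lt.append(out)
    if not mg:
        raise ValueError("all observations were censored; nothing to fit")
    return (
        TitrationDataset(kind="lifetime", mg=np.asarray(mg), value=np.asarray(lt), metadata=metadata or {}),
        censored,
    )


def extent_of_cleavage(site_intensities, full_length_signal: float) -> np.ndarray:
    """Fraction of molecules cleaved at each site from fragment intensities.

    Denominator is the total lane signal (all fragment sites plus the
    full-length band): extent_i = site_i / (sum_j site_j + full_length).
    """
    sites = np.asarray(site_intensities, dtype=float)
    if np.any(sites < 0) or full_length_signal < 0:
        raise ValueError("signals must be non-negative")
    total = sites.sum() + full_length_signal
    if total <= 0:
        raise ValueError("all signals are zero")
    return sites / total


def delta_cleavage(table: SiteCleavageTable, baseline_mg: float) -> DeltaCleavage:
    """Per-site extent differences relative to a baseline condition.

    Positive Δcleavage marks sites cleaved more than at the baseline (the
    Goldilocks-peak condition in the study design); the baseline column is
    identically zero.
    """
    cols = np.asarray(table.extent.columns, dtype=float)
    match = np.isclose(cols, float(baseline_mg))
    if not match.any():
        raise KeyError(f"baseline condition {baseline_mg} mM not present in table")
    base_col = table.extent.columns[int(np.argmax(match))]
    delta = table.extent.sub(table.extent[base_col], axis=0)
    return DeltaCleavage(baseline_condition=base_col, delta=delta)


def dispersion_by_structure(
    table: SiteCleavageTable,
    mask: Optional[pd.Series] = None,
    hotspot_sd: float = 2.0,
) -> pd.DataFrame:
    """Mean/SD of extent per condition for paired vs unpaired positions.

    Returns a tidy frame (condition, structure class, mean, sd, n_sites,
    hotspots) where hotspots are positions with extent above the condition's
    overall mean + ``hotspot_sd`` standard deviations.  Partial folding shows
    up as a larger unpaired-class sd: flexible nucleotides sample cleavable
    geometries unevenly, while duplex positions cleave uniformly.
    """
    if mask is None:
        mask = table.structure_mask
    if mask is None:
        raise ValueError("a paired/unpaired structure mask is required")
    mask = mask.reindex(table.extent.index)
    if mask.isna().any():
        raise ValueError("structure mask must cover all positions")
    rows = []
    for cond in table.extent.columns:
        col = table.extent[cond]
        thresh = col.mean() + hotspot_sd * col.std(ddof=0)
        for cls in ("paired", "unpaired"):
            vals = col[mask == cls]
            rows.append(
                {
                    "condition": float(cond),
                    "structure": cls,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=0)) if len(vals) else np.nan,
                    "n_sites": int(len(vals)),
                    "hotspots": tuple(int(p) for p in vals.index[vals > thresh]),
                }
            )
    return pd.DataFrame(rows)
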