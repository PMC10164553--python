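"""Detection and quantification of Goldilocks peaks on lifetime landscapes.

A Goldilocks peak is a local maximum of chemical lifetime versus [Mg2+],
flanked by conditions of shorter lifetime.  It appears when Mg2+-driven
folding protects the RNA (k_f < k_u) faster than added Mg2+ accelerates
cleavage.  Extrema are located by solving for the concentrations where the
lifetime derivative vanishes; since lifetime = 1/k_obs with k_obs > 0, the
zero-slope points of the lifetime are exactly those of k_obs, whose
derivative is available in closed form.  Peak intensity is the ratio of the
lifetime at a local maximum to the lifetime at the immediately preceding
local minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import (
    CleavageRates,
    FoldingTwoState,
    LifetimeCurve,
    ModelSpec,
    _hill,
    _weighted_rate,
    lifetime,
    lifetime_curve,
)

__all__ = [
    "Extremum",
    "GoldilocksPeak",
    "IntensityMap",
    "SweepResult",
    "ScenarioResult",
    "default_window",
    "find_extrema",
    "goldilocks_peaks",
    "peak_width_half_height",
    "peak_area",
    "parameter_sweep",
    "sweep_factors",
    "intensity_map",
    "three_state_scenarios",
]

_BRACKET_POINTS = 2048


@dataclass(frozen=True)
class Extremum:
    mg: float
    lifetime: float
    kind: Literal["minimum", "maximum"]


@dataclass(frozen=True)
class GoldilocksPeak:
    """A lifetime maximum paired with its immediately preceding minimum.

    ``intensity = maximum.lifetime / preceding_minimum.lifetime`` (> 1 by
    construction).  ``width_half_height`` and ``area`` are filled in on
    request by :func:`peak_width_half_height` / :func:`peak_area`.
    """

    maximum: Extremum
    preceding_minimum: Extremum
    intensity: float
    width_half_height: Optional[float] = None
    area: Optional[float] = None


@dataclass(frozen=True)
class IntensityMap:
    """Peak presence/intensity over a (Hill coefficient, k_u/k_f) grid.

    ``intensity[i, j]`` corresponds to ``n_values[i]`` and ``ratio_values[j]``;
    cells without a peak carry intensity 1.0 and ``peak_present`` False.
    """

    n_values: np.ndarray
    ratio_values: np.ndarray
    peak_present: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class SweepResult:
    varied_parameter: str
    factors: list[float]
    specs: list[ModelSpec]
    curves: list[LifetimeCurve]


@dataclass(frozen=True)
class ScenarioResult:
    spec: ModelSpec
    peaks: list[GoldilocksPeak]
    dominant_position: Optional[Literal["early", "late"]]


def default_window(spec: ModelSpec) -> tuple[float, float]:
    """[min midpoint / 100, 100 * max midpoint]; spans all folding
    transitions.  A one-state model (no midpoint) gets a fixed two-decade
    window around 1 concentration unit."""
    mids = spec.midpoints
    if not mids:
        return (0.01, 100.0)
    return (min(mids) / 100.0, max(mids) * 100.0)


def _dkobs_sign(mg: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """d k_obs / d mg up to the positive concentration-unit factor.

    With kbar(mg) the occupancy-weighted rate constant,
    k_obs = c * mg * kbar, so  d k_obs/d mg  ~  kbar + mg * kbar'.
    Hill derivative: phi' = n phi (1 - phi) / mg.
    """
    kbar = _weighted_rate(mg, spec)
    if spec.states == 1:
        dkbar = np.zeros_like(np.asarray(mg, dtype=float))
    elif spec.states == 2:
        f = spec.folding
        phi = _hill(mg, f.K_D, f.n)
        dkbar = (spec.rates.k_f - spec.rates.k_u) * f.n * phi * (1.0 - phi) / mg
    else:
        f = spec.folding
        phi1 = _hill(mg, f.K_D1, f.n1)
        phi2 = _hill(mg, f.K_D2, f.n2)
        dphi1 = f.n1 * phi1 * (1.0 - phi1) / mg
        dphi2 = f.n2 * phi2 * (1.0 - phi2) / mg
        k_u, k_i, k_f = spec.rates.k_u, spec.rates.k_i, spec.rates.k_f
        dkbar = (
            -k_u * dphi1
            + k_i * (dphi1 * (1.0 - phi2) - phi1 * dphi2)
            + k_f * (dphi1 * phi2 + phi1 * dphi2)
        )
    return kbar + mg * dkbar


def _check_window(window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = float(window[0]), float(window[1])
    if lo <= 0 or hi <= 0:
        raise ValueError("window bounds must be positive")
    if hi <= lo:
        raise ValueError("window must be non-degenerate (hi > lo)")
    return lo, hi


def find_extrema(
    spec: ModelSpec, window: Optional[tuple[float, float]] = None
) -> list[Extremum]:
    """All zero-slope points of the lifetime inside ``window``, in order.

    Sign changes of the analytic k_obs derivative are bracketed on a
    2048-point log grid and refined by bisection (brentq, rtol 1e-12).  A
    falling-then-rising k_obs slope (-,+) is a lifetime *maximum*; (+,-) a
    minimum; consecutive extrema therefore alternate.  Monotone landscapes
    yield an empty list.
    """
    if window is None:
        window = default_window(spec)
    lo, hi = _check_window(window)
    grid = np.geomspace(lo, hi, _BRACKET_POINTS)
    s = _dkobs_sign(grid, spec)
    out: list[Extremum] = []
    sign = np.sign(s)
    for j in np.nonzero(np.diff(sign) != 0)[0]:
        if sign[j] == 0:  # exact zero on the grid: treat grid point as root
            root = grid[j]
        else:
            root = brentq(
                lambda x: float(_dkobs_sign(np.asarray([x]), spec)[0]),
                grid[j],
                grid[j + 1],
                rtol=1e-12,
                maxiter=200,
            )
        kind = "maximum" if sign[j] < 0 else "minimum"
        out.append(Extremum(mg=float(root), lifetime=float(lifetime(root, spec)), kind=kind))
    return out


def goldilocks_peaks(
    spec: ModelSpec, window: Optional[tuple[float, float]] = None
) -> list[GoldilocksPeak]:
    """Pair each lifetime maximum with its immediately preceding minimum.

    Intensity is computed from the exact extremal lifetimes (the refined
    zero-slope concentrations substituted back into the lifetime equation).
    Returns an empty list — never an error — when the landscape is monotone.
    """
    extrema = find_extrema(spec, window)
    peaks: list[GoldilocksPeak] = []
    for prev, cur in zip(extrema, extrema[1:]):
        if cur.kind == "maximum" and prev.kind == "minimum":
            peaks.append(
                GoldilocksPeak(
                    maximum=cur,
                    preceding_minimum=prev,
                    intensity=cur.lifetime / prev.lifetime,
                )
            )
    return peaks


def peak_width_half_height(
    spec: ModelSpec,
    peak: GoldilocksPeak,
    window: Optional[tuple[float, float]] = None,
) -> Optional[float]:
    """Concentration span where lifetime >= min + (max - min)/2, measured on
    the peak's own rise and fall.  Returns None when the falling flank never
    drops to half height inside the window."""
    if window is None:
        window = default_window(spec)
    lo, hi = _check_window(window)
    level = peak.preceding_minimum.lifetime + 0.5 * (
        peak.maximum.lifetime - peak.preceding_minimum.lifetime
    )

    def g(x):
        return lifetime(x, spec) - level

    left = brentq(g, peak.preceding_minimum.mg, peak.maximum.mg, rtol=1e-12)
    # falling flank: scan from the maximum to the next minimum or window edge
    extrema = find_extrema(spec, (lo, hi))
    right_bound = hi
    for e in extrema:
        if e.kind == "minimum" and e.mg > peak.maximum.mg:
            right_bound = e.mg
            break
    if g(right_bound) > 0:
        return None
    right = brentq(g, peak.maximum.mg, right_bound, rtol=1e-12)
    return float(right - left)


def peak_area(
    spec: ModelSpec,
    peak: GoldilocksPeak,
    window: Optional[tuple[float, float]] = None,
    num: int = 4096,
) -> float:
    """Area of the lifetime curve above the chord joining the peak's flanks.

    The left flank is the preceding minimum; the right flank is the next
    minimum, or the window edge when the peak has no second minimum.  The
    baseline is the straight chord between the two flank points and the area
    is the integral of (lifetime - chord) between them (trapezoidal rule on a
    dense log grid), clipped below at zero.
    """
    if window is None:
        window = default_window(spec)
    lo, hi = _check_window(window)
    if not (lo < peak.maximum.mg < hi):
        raise ValueError("window does not span the peak")
    x1 = peak.preceding_minimum.mg
    x2 = hi
    for e in find_extrema(spec, (lo, hi)):
        if e.kind == "minimum" and e.mg > peak.maximum.mg:
            x2 = e.mg
            break
    xs = np.geomspace(x1, x2, num)
    ys = lifetime(xs, spec)
    y1, y2 = lifetime(x1, spec), lifetime(x2, spec)
    chord = y1 + (y2 - y1) * (xs - x1) / (x2 - x1)
    return float(np.trapezoid(np.clip(ys - chord, 0.0, None), xs))


def sweep_factors(i_max: int = 8) -> list[float]:
    """Multiplicative factor ladder 1 + 0.1 * 2^i for i = 1..i_max
    (1.2, 1.4, 1.8, 2.6, 4.2, 7.4, 13.8, 26.6)."""
    return [1.0 + 0.1 * 2**i for i in range(1, i_max + 1)]


_SWEEPABLE = {"K_D", "n", "k_u", "k_i", "k_f", "K_D1", "K_D2", "n1", "n2"}


def _with_parameter(spec: ModelSpec, name: str, value: float) -> ModelSpec:
    if name in ("k_u", "k_i", "k_f"):
        return replace(spec, rates=replace(spec.rates, **{name: value}))
    return replace(spec, folding=replace(spec.folding, **{name: value}))


def _get_parameter(spec: ModelSpec, name: str) -> float:
    if name in ("k_u", "k_i", "k_f"):
        val = getattr(spec.rates, name)
    else:
        if spec.folding is None or not hasattr(spec.folding, name):
            raise ValueError(f"parameter {name!r} not present in this spec")
        val = getattr(spec.folding, name)
    if val is None:
        raise ValueError(f"parameter {name!r} not present in this spec")
    return val


def parameter_sweep(
    base: ModelSpec,
    parameter: str,
    directions: Iterable[str] = ("multiply", "divide"),
    grid: Optional[np.ndarray] = None,
) -> SweepResult:
    """Vary one parameter by the factor ladder of :func:`sweep_factors`.

    Each factor is applied as a multiplier and/or divisor of the base value
    (per ``directions``); the base spec itself (factor 1) is always included
    first.  One lifetime curve is evaluated per resulting spec on ``grid``
    (default: 500 log-spaced points over the base spec's default window).
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"unknown parameter {parameter!r}; one of {sorted(_SWEEPABLE)}")
    base_value = _get_parameter(base, parameter)
    directions = list(directions)
    for d in directions:
        if d not in ("multiply", "divide"):
            raise ValueError(f"unknown direction {d!r}")
    factors: list[float] = [1.0]
    for f in sweep_factors():
        if "multiply" in directions:
            factors.append(f)
        if "divide" in directions:
            factors.append(1.0 / f)
    if grid is None:
        lo, hi = default_window(base)
        grid = np.geomspace(lo, hi, 500)
    specs = [_with_parameter(base, parameter, base_value * f) if f != 1.0 else base for f in factors]
    curves = [lifetime_curve(grid, s) for s in specs]
    return SweepResult(varied_parameter=parameter, factors=factors, specs=specs, curves=curves)


def intensity_map(
    n_grid: Sequence[float],
    ratio_grid: Sequence[float],
    base: Optional[ModelSpec] = None,
    window: Optional[tuple[float, float]] = None,
) -> IntensityMap:
    """Survey Goldilocks intensity over cooperativity and protection ratio.

    For each (n, k_u/k_f) cell a two-state model is built from ``base``
    (default: relative units, K_D = 1, k_u = 1) with the cell's Hill
    coefficient and folded-state rate ``k_f = k_u / ratio``; peak detection
    runs per cell.  Cells without a peak carry intensity 1.0.  Cells with
    ratio = 1 can never have a peak (equal rate constants give a strictly
    decreasing lifetime).
    """
    n_values = np.asarray(list(n_grid), dtype=float)
    ratio_values = np.asarray(list(ratio_grid), dtype=float)
    if np.any(n_values <= 0) or np.any(ratio_values < 1):
        raise ValueError("n must be positive and ratios >= 1")
    if base is None:
        base = ModelSpec(
            states=2,
            folding=FoldingTwoState(K_D=1.0, n=4.0),
            rates=CleavageRates(k_u=1.0, k_f=0.2),
            units="relative",
        )
    present = np.zeros((n_values.size, ratio_values.size), dtype=bool)
    inten = np.ones((n_values.size, ratio_values.size))
    for i, n in enumerate(n_values):
        for j, r in enumerate(ratio_values):
            spec = replace(
                base,
                folding=replace(base.folding, n=n),
                rates=replace(base.rates, k_f=base.rates.k_u / r),
            )
            peaks = goldilocks_peaks(spec, window)
            if peaks:
                present[i, j] = True
                inten[i, j] = max(p.intensity for p in peaks)
    return IntensityMap(
        n_values=n_values, ratio_values=ratio_values, peak_present=present, intensity=inten
    )


def three_state_scenarios(
    k_i_values: Sequence[float],
    base: ModelSpec,
    window: Optional[tuple[float, float]] = None,
) -> list[ScenarioResult]:
    """Scan the intermediate's cleavage rate constant in a three-state model.

    For each k_i the dominant (most intense) peak is classified as ``early``
    (below the second folding midpoint K_D2: the k_i < k_f scenario, where
    the protected intermediate's plateau carries the peak just past
    transition 1) or ``late`` (beyond K_D2: the k_i > k_u scenario, where
    protection only arrives with the second transition).
    """
    if base.states != 3:
        raise ValueError("three_state_scenarios requires a three-state base spec")
    split = float(base.folding.K_D2)
    out: list[ScenarioResult] = []
    for k_i in k_i_values:
        spec = replace(base, rates=replace(base.rates, k_i=float(k_i)))
        peaks = goldilocks_peaks(spec, window)
        if peaks:
            dom = max(peaks, key=lambda p: p.intensity)
            pos = "early" if dom.maximum.mg < split else "late"
        else:
            pos = None
        out.append(ScenarioResult(spec=spec, peaks=peaks, dominant_position=pos))
    return out
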