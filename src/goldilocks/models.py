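"""Closed-form folding occupancies, observed cleavage rate and chemical lifetime.

The model couples Mg2+-driven RNA folding (Hill-equation transitions) to
Mg2+-catalyzed in-line cleavage.  Each conformational state s (unfolded,
optional intermediate, folded) cleaves with its own second-order rate
constant ``k_s`` per phosphodiester bond, and the observed pseudo-first-order
rate constant at a given Mg2+ concentration is the occupancy-weighted sum

    k_obs = sum_s f_s(mg) * k_s * [Mg2+]

The chemical lifetime is ``1 / k_obs``.  Because folding is fast relative to
cleavage for the RNAs modelled here, occupancies are equilibrium Hill
fractions and no folding kinetics enter the model.

Units
-----
Two unit systems are supported.  In ``absolute`` units concentrations are in
mM at every interface and rate constants in s^-1 M^-1 (per bond); the mM->M
conversion happens inside :func:`observed_rate`.  In ``relative`` units the
concentration axis is scaled so that 1 [Mg2+]_rel sits at the folding
midpoint and rates are in t_rel^-1 [Mg2+]_rel^-1; no conversion is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional, Union

import numpy as np

__all__ = [
    "FoldingTwoState",
    "FoldingThreeState",
    "CleavageRates",
    "ModelSpec",
    "Occupancies",
    "RelativeUnitSystem",
    "LifetimeCurve",
    "LifetimeUndefinedError",
    "fraction_folded_two_state",
    "occupancies",
    "observed_rate",
    "lifetime",
    "lifetime_curve",
    "to_relative",
    "to_absolute",
]

MM_TO_M = 1e-3

# Hill exponents above this are clamped: exp(+-n*log ratio) overflows long
# before, and fitted cooperativities in practice stay below ~35.
N_MAX = 1000.0

_EXP_CLIP = 700.0


class LifetimeUndefinedError(ValueError):
    """Lifetime requested at [Mg2+] = 0, where no cleavage occurs."""


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return value


def _clamp_n(name: str, value: float) -> float:
    value = _positive(name, value)
    if value > N_MAX:
        warnings.warn(
            f"{name}={value} exceeds the supported Hill-coefficient range; "
            f"clamping to {N_MAX}",
            RuntimeWarning,
            stacklevel=3,
        )
        value = N_MAX
    return value


@dataclass(frozen=True)
class FoldingTwoState:
    """Single Hill transition: ``K_D`` is [Mg2+] at the folding midpoint (mM
    or [Mg2+]_rel), ``n`` the Hill coefficient (cooperativity; values < 1 are
    permitted)."""

    K_D: float
    n: float

    def __post_init__(self):
        object.__setattr__(self, "K_D", _positive("K_D", self.K_D))
        object.__setattr__(self, "n", _clamp_n("n", self.n))


@dataclass(frozen=True)
class FoldingThreeState:
    """Two sequential Hill transitions, unfolded -> intermediate
    (``K_D1``, ``n1``) and intermediate -> folded (``K_D2``, ``n2``).
    No ordering of the midpoints is imposed; transitions may overlap."""

    K_D1: float
    n1: float
    K_D2: float
    n2: float

    def __post_init__(self):
        object.__setattr__(self, "K_D1", _positive("K_D1", self.K_D1))
        object.__setattr__(self, "n1", _clamp_n("n1", self.n1))
        object.__setattr__(self, "K_D2", _positive("K_D2", self.K_D2))
        object.__setattr__(self, "n2", _clamp_n("n2", self.n2))


@dataclass(frozen=True)
class CleavageRates:
    """State-specific second-order cleavage rate constants per phosphodiester
    bond.  ``k_i`` only exists for three-state models, ``k_f`` for two- and
    three-state models.  No ordering is enforced: an intermediate may be more
    labile than the unfolded state or better protected than the folded one."""

    k_u: float
    k_i: Optional[float] = None
    k_f: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "k_u", _positive("k_u", self.k_u))
        if self.k_i is not None:
            object.__setattr__(self, "k_i", _positive("k_i", self.k_i))
        if self.k_f is not None:
            object.__setattr__(self, "k_f", _positive("k_f", self.k_f))


Units = Literal["absolute", "relative"]


@dataclass(frozen=True)
class ModelSpec:
    """A complete one-, two- or three-state lifetime model.

    ``states=1`` means a non-folding RNA (no ``folding`` block, only ``k_u``);
    ``states=2`` pairs a :class:`FoldingTwoState` with ``k_u``/``k_f``;
    ``states=3`` pairs a :class:`FoldingThreeState` with ``k_u``/``k_i``/``k_f``.
    """

    states: int
    rates: CleavageRates
    folding: Union[FoldingTwoState, FoldingThreeState, None] = None
    units: Units = "absolute"

    def __post_init__(self):
        if self.states not in (1, 2, 3):
            raise ValueError(f"states must be 1, 2 or 3, got {self.states}")
        if self.units not in ("absolute", "relative"):
            raise ValueError(f"units must be 'absolute' or 'relative', got {self.units!r}")
        if self.states == 1:
            if self.folding is not None:
                raise ValueError("a one-state model has no folding block")
            if self.rates.k_f is not None or self.rates.k_i is not None:
                raise ValueError("a one-state model has only k_u")
        elif self.states == 2:
            if not isinstance(self.folding, FoldingTwoState):
                raise ValueError("a two-state model requires FoldingTwoState folding")
            if self.rates.k_f is None:
                raise ValueError("a two-state model requires k_f")
            if self.rates.k_i is not None:
                raise ValueError("a two-state model has no k_i")
        else:
            if not isinstance(self.folding, FoldingThreeState):
                raise ValueError("a three-state model requires FoldingThreeState folding")
            if self.rates.k_f is None or self.rates.k_i is None:
                raise ValueError("a three-state model requires k_i and k_f")

    @property
    def midpoints(self) -> tuple[float, ...]:
        """Folding midpoints, empty for a one-state model."""
        if self.states == 1:
            return ()
        if self.states == 2:
            return (self.folding.K_D,)
        return (self.folding.K_D1, self.folding.K_D2)


@dataclass(frozen=True)
class Occupancies:
    """Equilibrium state fractions; always sums to 1 (``f_i`` = 0 below three
    states)."""

    f_u: float
    f_i: float
    f_f: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_u, self.f_i, self.f_f])


@dataclass(frozen=True)
class RelativeUnitSystem:
    """Anchors for relative units: ``K_D_ref`` (mM) defines 1 [Mg2+]_rel and
    ``t_ref`` (s) defines 1 t_rel."""

    K_D_ref: float
    t_ref: float

    def __post_init__(self):
        object.__setattr__(self, "K_D_ref", _positive("K_D_ref", self.K_D_ref))
        object.__setattr__(self, "t_ref", _positive("t_ref", self.t_ref))


@dataclass(frozen=True)
class LifetimeCurve:
    """Lifetime evaluated on a strictly increasing concentration grid."""

    mg: np.ndarray
    lifetime: np.ndarray
    units: Units = "absolute"

    def __post_init__(self):
        mg = np.asarray(self.mg, dtype=float)
        lt = np.asarray(self.lifetime, dtype=float)
        if mg.ndim != 1 or mg.size == 0:
            raise ValueError("mg grid must be a non-empty 1-D array")
        if np.any(mg <= 0):
            raise ValueError("mg grid must be strictly positive")
        if mg.size > 1 and np.any(np.diff(mg) <= 0):
            raise ValueError("mg grid must be strictly increasing")
        if lt.shape != mg.shape:
            raise ValueError("lifetime and mg must have the same shape")
        object.__setattr__(self, "mg", mg)
        object.__setattr__(self, "lifetime", lt)

    def __len__(self) -> int:
        return self.mg.size


def _hill(mg, K_D: float, n: float):
    """Stable Hill fraction 1 / (1 + (K_D/mg)^n); 0 at mg = 0 by limit."""
    arr = np.atleast_1d(np.asarray(mg, dtype=float))
    out = np.zeros(arr.shape)
    pos = arr > 0
    expo = np.clip(n * (np.log(K_D) - np.log(arr[pos])), -_EXP_CLIP, _EXP_CLIP)
    out[pos] = 1.0 / (1.0 + np.exp(expo))
    return out.reshape(np.shape(mg))


def _check_mg(mg) -> np.ndarray:
    mg = np.asarray(mg, dtype=float)
    if np.any(mg < 0) or not np.all(np.isfinite(mg)):
        raise ValueError("mg must be finite and non-negative")
    return mg


def fraction_folded_two_state(mg, folding: FoldingTwoState):
    """Hill fraction folded, ``1 / (1 + (K_D/mg)^n)``.

    Returns 0 at ``mg = 0`` (the unfolded limit).  Accepts scalars or arrays
    of concentrations; negative concentrations raise ``ValueError``.
    """
    mg = _check_mg(mg)
    out = _hill(mg, folding.K_D, folding.n)
    return float(out) if out.ndim == 0 else out


def occupancies(mg: float, spec: ModelSpec) -> Occupancies:
    """Equilibrium occupancies (f_u, f_i, f_f) at one concentration.

    The three-state form is sequential: with phi_k the Hill fraction of
    transition k, ``f_u = 1 - phi1``, ``f_i = phi1 (1 - phi2)``,
    ``f_f = phi1 phi2``, which is normalised by construction even when the
    transitions overlap in Mg2+-space.
    """
    mg = float(_check_mg(mg))
    if spec.states == 1:
        return Occupancies(1.0, 0.0, 0.0)
    if spec.states == 2:
        phi = _hill(mg, spec.folding.K_D, spec.folding.n)
        return Occupancies(float(1.0 - phi), 0.0, float(phi))
    phi1 = _hill(mg, spec.folding.K_D1, spec.folding.n1)
    phi2 = _hill(mg, spec.folding.K_D2, spec.folding.n2)
    return Occupancies(float(1.0 - phi1), float(phi1 * (1.0 - phi2)), float(phi1 * phi2))


def _weighted_rate(mg, spec: ModelSpec):
    """Occupancy-weighted mean cleavage rate constant at each mg (vectorized)."""
    if spec.states == 1:
        return np.broadcast_to(spec.rates.k_u, np.shape(np.asarray(mg))).astype(float)
    if spec.states == 2:
        phi = _hill(mg, spec.folding.K_D, spec.folding.n)
        return spec.rates.k_u * (1.0 - phi) + spec.rates.k_f * phi
    phi1 = _hill(mg, spec.folding.K_D1, spec.folding.n1)
    phi2 = _hill(mg, spec.folding.K_D2, spec.folding.n2)
    return (
        spec.rates.k_u * (1.0 - phi1)
        + spec.rates.k_i * phi1 * (1.0 - phi2)
        + spec.rates.k_f * phi1 * phi2
    )


def _conc_factor(spec: ModelSpec) -> float:
    return MM_TO_M if spec.units == "absolute" else 1.0


def observed_rate(mg, spec: ModelSpec):
    """Observed pseudo-first-order cleavage rate constant at ``mg``.

    ``k_obs = sum_s f_s k_s [Mg2+]`` with the concentration in M for absolute
    units (input is mM) and in [Mg2+]_rel for relative units.  Linear in mg
    at fixed occupancies.  Units: s^-1 (absolute) or t_rel^-1 (relative),
    per phosphodiester bond.
    """
    mg = _check_mg(mg)
    out = _weighted_rate(mg, spec) * mg * _conc_factor(spec)
    return float(out) if np.ndim(out) == 0 else out


def lifetime(mg, spec: ModelSpec):
    """Chemical lifetime, the reciprocal of :func:`observed_rate`.

    Undefined at ``mg = 0`` (no catalyst, infinite lifetime):
    raises :class:`LifetimeUndefinedError` rather than returning infinity.
    """
    mg = _check_mg(mg)
    if np.any(mg == 0):
        raise LifetimeUndefinedError("lifetime is undefined (infinite) at [Mg2+] = 0")
    out = 1.0 / (_weighted_rate(mg, spec) * mg * _conc_factor(spec))
    return float(out) if np.ndim(out) == 0 else out


def lifetime_curve(grid, spec: ModelSpec) -> LifetimeCurve:
    """Vectorized lifetime on a strictly increasing, positive grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(grid <= 0):
        raise ValueError("grid concentrations must be strictly positive")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return LifetimeCurve(mg=grid, lifetime=lifetime(grid, spec), units=spec.units)


def _scale_folding(folding, c: float):
    if folding is None:
        return None
    if isinstance(folding, FoldingTwoState):
        return FoldingTwoState(K_D=folding.K_D * c, n=folding.n)
    return FoldingThreeState(
        K_D1=folding.K_D1 * c, n1=folding.n1, K_D2=folding.K_D2 * c, n2=folding.n2
    )


def _scale_rates(rates: CleavageRates, c: float) -> CleavageRates:
    return CleavageRates(
        k_u=rates.k_u * c,
        k_i=None if rates.k_i is None else rates.k_i * c,
        k_f=None if rates.k_f is None else rates.k_f * c,
    )


def to_relative(obj, units: RelativeUnitSystem):
    """Convert a ModelSpec or LifetimeCurve from absolute to relative units.

    Concentrations scale by ``1 / K_D_ref`` and lifetimes by ``1 / t_ref``.
    Rate constants transform so that the relative-unit model reproduces the
    absolute model's lifetimes exactly: ``k_rel = k_abs * 1e-3 * K_D_ref * t_ref``.
    """
    if isinstance(obj, LifetimeCurve):
        if obj.units != "absolute":
            raise ValueError("curve is already in relative units")
        return LifetimeCurve(
            mg=obj.mg / units.K_D_ref, lifetime=obj.lifetime / units.t_ref, units="relative"
        )
    if isinstance(obj, ModelSpec):
        if obj.units != "absolute":
            raise ValueError("spec is already in relative units")
        c_rate = MM_TO_M * units.K_D_ref * units.t_ref
        return replace(
            obj,
            folding=_scale_folding(obj.folding, 1.0 / units.K_D_ref),
            rates=_scale_rates(obj.rates, c_rate),
            units="relative",
        )
    raise TypeError(f"cannot convert object of type {type(obj).__name__}")


def to_absolute(obj, units: RelativeUnitSystem):
    """Inverse of :func:`to_relative`; the round trip is the identity to
    machine precision."""
    if isinstance(obj, LifetimeCurve):
        if obj.units != "relative":
            raise ValueError("curve is already in absolute units")
        return LifetimeCurve(
            mg=obj.mg * units.K_D_ref, lifetime=obj.lifetime * units.t_ref, units="absolute"
        )
    if isinstance(obj, ModelSpec):
        if obj.units != "relative":
            raise ValueError("spec is already in absolute units")
        c_rate = MM_TO_M * units.K_D_ref * units.t_ref
        return replace(
            obj,
            folding=_scale_folding(obj.folding, units.K_D_ref),
            rates=_scale_rates(obj.rates, 1.0 / c_rate),
            units="absolute",
        )
    raise TypeError(f"cannot convert object of type {type(obj).__name__}")
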