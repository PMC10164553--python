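"""Synthetic generators for every input class the pipeline consumes.

Each generator evaluates the forward model of the corresponding reduction
step under a known :class:`~goldilocks.models.ModelSpec` and returns the
ground truth beside the data, so reduction + fitting round trips can be
asserted against the generating parameters rather than hard-coded numbers.
All randomness flows from the per-call seed (numpy ``default_rng``); no
global state is touched.

Presets carry the fitted parameter sets of the study systems verbatim:
yeast tRNA-Phe (three-state lifetime: k_u = 8.7e-5, k_i = 2.7e-5,
k_f = 3.9e-5 s^-1 M^-1 per bond, K_D1 = 2.2 mM, K_D2 = 3.3 mM, n1 = n2 = 15),
the Tetrahymena P4-P6 domain, and a non-folding rU20-like control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fitting import TitrationDataset
from .models import (
    CleavageRates,
    FoldingThreeState,
    FoldingTwoState,
    ModelSpec,
    fraction_folded_two_state,
    lifetime,
    observed_rate,
)
from .reduction import CDTitration, GelObservation, SiteCleavageTable

__all__ = [
    "NoiseModel",
    "SyntheticConfig",
    "PRESETS",
    "preset_spec",
    "gen_lifetime_titration",
    "gen_cd_titration",
    "gen_gel_observations",
    "gen_site_table",
    "SiteCondition",
]


@dataclass(frozen=True)
class NoiseModel:
    """`none`, `gaussian_additive(sigma)` (sigma on the observable's scale)
    or `lognormal_multiplicative(sigma)` (sigma of log-normal factor)."""

    kind: Literal["none", "gaussian_additive", "lognormal_multiplicative"] = "none"
    sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian_additive", "lognormal_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none" and self.sigma <= 0:
            raise ValueError("sigma must be positive for a noisy model")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return values.copy()
        if self.kind == "gaussian_additive":
            return values + rng.normal(0.0, self.sigma, size=values.shape)
        return values * rng.lognormal(0.0, self.sigma, size=values.shape)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating model, concentration grid, noise model and seed.

    A seed is mandatory whenever noise is requested, so every noisy dataset
    is reproducible bit for bit.
    """

    generating_spec: ModelSpec
    mg_grid: np.ndarray
    noise: NoiseModel = NoiseModel()
    seed: Optional[int] = None

    def __post_init__(self):
        grid = np.asarray(self.mg_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(grid <= 0):
            raise ValueError("mg_grid must be a non-empty positive 1-D array")
        if grid.size > 1 and np.any(np.diff(grid) <= 0):
            raise ValueError("mg_grid must be strictly increasing")
        if self.noise.kind != "none" and self.seed is None:
            raise ValueError("a seed is mandatory when noise is requested")
        object.__setattr__(self, "mg_grid", grid)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _preset_specs() -> dict[str, ModelSpec]:
    # Fitted study parameters; lifetime-model rates in s^-1 M^-1 per bond,
    # midpoints in mM.  Folding presets carry unit placeholder rates (folding
    # data constrain no rates).
    trna_l3 = ModelSpec(
        states=3,
        folding=FoldingThreeState(K_D1=2.2, n1=15.0, K_D2=3.3, n2=15.0),
        rates=CleavageRates(k_u=8.7e-5, k_i=2.7e-5, k_f=3.9e-5),
    )
    trna_l2 = ModelSpec(
        states=2,
        folding=FoldingTwoState(K_D=2.3, n=33.5),
        rates=CleavageRates(k_u=8.2e-5, k_f=3.1e-5),
    )
    trna_f3 = ModelSpec(
        states=3,
        folding=FoldingThreeState(K_D1=0.2, n1=1.1, K_D2=1.3, n2=3.8),
        rates=CleavageRates(k_u=1.0, k_i=1.0, k_f=1.0),
    )
    trna_f2 = ModelSpec(
        states=2,
        folding=FoldingTwoState(K_D=1.2, n=3.4),
        rates=CleavageRates(k_u=1.0, k_f=1.0),
    )
    p4p6_l3 = ModelSpec(
        states=3,
        folding=FoldingThreeState(K_D1=0.5, n1=3.9, K_D2=4.9, n2=3.4),
        rates=CleavageRates(k_u=6.1e-4, k_i=2.8e-5, k_f=3.5e-6),
    )
    p4p6_l2 = ModelSpec(
        states=2,
        folding=FoldingTwoState(K_D=4.8, n=3.4),
        rates=CleavageRates(k_u=8.7e-5, k_f=3.9e-6),
    )
    p4p6_f3 = ModelSpec(
        states=3,
        folding=FoldingThreeState(K_D1=2.3, n1=0.9, K_D2=3.8, n2=2.9),
        rates=CleavageRates(k_u=1.0, k_i=1.0, k_f=1.0),
    )
    p4p6_f2 = ModelSpec(
        states=2,
        folding=FoldingTwoState(K_D=2.7, n=2.0),
        rates=CleavageRates(k_u=1.0, k_f=1.0),
    )
    # non-folding single-strand control; no one-state rate is tabulated for
    # rU20, so a per-bond constant on the 1e-4 s^-1 M^-1 scale typical of
    # unstructured RNA is fixed here once
    ru20 = ModelSpec(states=1, rates=CleavageRates(k_u=1.0e-4))
    return {
        "trna_lifetime_3state": trna_l3,
        "trna_lifetime_2state": trna_l2,
        "trna_folding_3state": trna_f3,
        "trna_folding_2state": trna_f2,
        "p4p6_lifetime_3state": p4p6_l3,
        "p4p6_lifetime_2state": p4p6_l2,
        "p4p6_folding_3state": p4p6_f3,
        "p4p6_folding_2state": p4p6_f2,
        "ru20_1state": ru20,
    }


PRESETS: dict[str, ModelSpec] = _preset_specs()


def preset_spec(name: str) -> ModelSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; one of {sorted(PRESETS)}") from None


def gen_lifetime_titration(config: SyntheticConfig) -> tuple[TitrationDataset, dict]:
    """Lifetime titration from the forward model (reciprocal observed rate),
    with optional noise.  Returns (dataset, ground truth)."""
    spec = config.generating_spec
    clean = lifetime(config.mg_grid, spec)
    noisy = config.noise.apply(np.atleast_1d(clean), config.rng())
    data = TitrationDataset(
        kind="lifetime",
        mg=config.mg_grid,
        value=noisy,
        metadata={"generator": "gen_lifetime_titration", "seed": config.seed},
        units=spec.units,
    )
    truth = {"spec": spec, "clean_values": np.atleast_1d(clean), "noise": config.noise}
    return data, truth


def gen_cd_titration(
    config: SyntheticConfig,
    lower_baseline: tuple[float, float] = (0.0, 0.0),
    upper_baseline: tuple[float, float] = (-10.0, 0.0),
) -> tuple[CDTitration, dict]:
    """CD titration: theta = lower(mg) + (upper(mg) - lower(mg)) * f_folded.

    Baselines are (intercept, slope) in mdeg and mdeg/mM, emulating dilution
    and evaporation drift.  The generating fraction folded is the two-state
    Hill curve for two-state specs and the equal-amplitude observable
    f_f + f_i/2 for three-state specs; a one-state spec yields a pure
    straight line (no transition — the rU20 case).
    """
    spec = config.generating_spec
    mg = config.mg_grid
    if spec.states == 1:
        frac = np.zeros_like(mg)
    elif spec.states == 2:
        frac = fraction_folded_two_state(mg, spec.folding)
    else:
        from .fitting import _predict_folding

        frac = _predict_folding(mg, spec)
    lower = lower_baseline[0] + lower_baseline[1] * mg
    upper = upper_baseline[0] + upper_baseline[1] * mg
    theta = lower + (upper - lower) * frac
    theta = config.noise.apply(theta, config.rng())
    titration = CDTitration(
        mg=mg, theta=theta, metadata={"generator": "gen_cd_titration", "seed": config.seed}
    )
    truth = {
        "spec": spec,
        "fraction_folded": frac,
        "lower_baseline": lower_baseline,
        "upper_baseline": upper_baseline,
    }
    return titration, truth


def gen_gel_observations(
    config: SyntheticConfig, incubation_time: float, n_bonds: int
) -> tuple[list[GelObservation], dict]:
    """Endpoint gel lanes: fraction intact = exp(-n_bonds * k_obs * t).

    The per-bond observed rate comes from the generating spec; noise is
    applied to the fraction intact and the result re-clipped to (0, 1].
    """
    if incubation_time <= 0:
        raise ValueError("incubation_time must be positive")
    spec = config.generating_spec
    k_obs = np.atleast_1d(observed_rate(config.mg_grid, spec))
    frac = np.exp(-n_bonds * k_obs * incubation_time)
    frac = np.clip(config.noise.apply(frac, config.rng()), np.finfo(float).tiny, 1.0)
    obs = [
        GelObservation(
            mg=float(m), fraction_intact=float(f), incubation_time=incubation_time, n_bonds=n_bonds
        )
        for m, f in zip(config.mg_grid, frac)
    ]
    truth = {
        "spec": spec,
        "clean_fraction_intact": np.exp(-n_bonds * k_obs * incubation_time),
        "per_bond_lifetime": 1.0 / k_obs,
    }
    return obs, truth


@dataclass(frozen=True)
class SiteCondition:
    mg: float
    mean_extent: float
    paired_cv: float
    unpaired_cv: float


def gen_site_table(
    sequence_length: int,
    structure_mask: Sequence[str],
    conditions: Sequence[Union[SiteCondition, dict]],
    seed: int,
) -> tuple[SiteCleavageTable, dict]:
    """Per-site extents with class-dependent dispersion.

    For each condition, site extents are drawn log-normally around
    ``mean_extent`` with coefficient of variation ``paired_cv`` at paired
    positions and ``unpaired_cv`` at unpaired positions (zero CV gives
    exactly uniform extents).  A partially folded condition is emulated by a
    large unpaired CV.  Ground truth records the per-class parameters.
    """
    mask = list(structure_mask)
    if len(mask) != sequence_length:
        raise ValueError("structure mask length must equal sequence_length")
    if any(m not in ("paired", "unpaired") for m in mask):
        raise ValueError("mask entries must be 'paired' or 'unpaired'")
    conds = [c if isinstance(c, SiteCondition) else SiteCondition(**c) for c in conditions]
    rng = np.random.default_rng(seed)
    positions = np.arange(1, sequence_length + 1)
    data = {}
    for c in conds:
        extents = np.empty(sequence_length)
        for i, cls in enumerate(mask):
            cv = c.paired_cv if cls == "paired" else c.unpaired_cv
            if cv == 0:
                extents[i] = c.mean_extent
            else:
                sigma = np.sqrt(np.log1p(cv**2))
                extents[i] = c.mean_extent * rng.lognormal(-0.5 * sigma**2, sigma)
        # keep the lane physical: per-condition extents must sum to <= 1
        total = extents.sum()
        if total > 0.95:
            extents *= 0.95 / total
        data[c.mg] = extents
    extent = pd.DataFrame(data, index=positions)
    mask_series = pd.Series(mask, index=positions)
    table = SiteCleavageTable(extent, structure_mask=mask_series)
    truth = {"conditions": conds, "mask": mask_series, "seed": seed}
    return table, truth
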