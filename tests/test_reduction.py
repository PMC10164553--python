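"""Reduction of CD, gel and per-site fragment data to fit-ready form."""

import numpy as np
import pandas as pd
import pytest

from goldilocks.fitting import fit_lifetime
from goldilocks.models import fraction_folded_two_state, FoldingTwoState
from goldilocks.reduction import (
    CDTitration,
    CensoredObservation,
    GelObservation,
    SiteCleavageTable,
    delta_cleavage,
    dispersion_by_structure,
    extent_of_cleavage,
    lifetime_from_fraction_intact,
    reduce_gel_observations,
    select_analysis_wavelength,
    theta_to_fraction_folded,
)
from goldilocks.synth import (
    NoiseModel,
    SyntheticConfig,
    gen_gel_observations,
    gen_site_table,
    preset_spec,
    SiteCondition,
)


class TestAnalysisWavelength:
    def test_engineered_maximum_difference(self):
        wl = np.arange(220.0, 320.0, 0.2)
        low = np.zeros_like(wl)
        high = np.exp(-((wl - 260.0) ** 2) / 18.0)  # difference peaks at 260
        assert select_analysis_wavelength(wl, low, high) == pytest.approx(260.0, abs=0.5)

    def test_identical_spectra_rejected(self):
        wl = np.arange(220.0, 320.0, 1.0)
        with pytest.raises(ValueError):
            select_analysis_wavelength(wl, np.sin(wl), np.sin(wl))

    def test_tie_breaks_to_lowest_wavelength(self):
        wl = np.array([240.0, 260.0, 280.0])
        low = np.zeros(3)
        high = np.array([0.0, 1.0, 1.0])
        assert select_analysis_wavelength(wl, low, high, smooth_window=1) == 260.0


class TestThetaReduction:
    def test_recovers_embedded_hill_within_one_percent_rms(self):
        true = FoldingTwoState(K_D=1.5, n=4.0)
        mg = np.geomspace(0.05, 20, 40)
        frac = fraction_folded_two_state(mg, true)
        theta = (2.0 + 0.05 * mg) + ((-12.0 - 0.02 * mg) - (2.0 + 0.05 * mg)) * frac
        red = theta_to_fraction_folded(CDTitration(mg=mg, theta=theta))
        assert red.folding_detected
        rms = np.sqrt(np.mean((red.dataset.value - frac) ** 2))
        assert rms < 0.01
        assert red.K_D == pytest.approx(1.5, rel=0.05)

    def test_endpoints_normalise_to_zero_and_one(self):
        true = FoldingTwoState(K_D=1.0, n=8.0)
        mg = np.geomspace(0.01, 100, 30)
        theta = -10.0 * fraction_folded_two_state(mg, true)
        red = theta_to_fraction_folded(CDTitration(mg=mg, theta=theta))
        assert red.dataset.value[0] == pytest.approx(0.0, abs=0.01)
        assert red.dataset.value[-1] == pytest.approx(1.0, abs=0.01)

    def test_pure_linear_theta_flagged_non_folding(self):
        mg = np.linspace(0.0, 10, 25)
        red = theta_to_fraction_folded(CDTitration(mg=mg, theta=3.0 - 0.4 * mg))
        assert not red.folding_detected
        assert red.dataset is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            theta_to_fraction_folded(CDTitration(mg=[1, 2, 3], theta=[1, 2, 3]))


class TestGelReduction:
    def test_definition_anchor(self):
        obs = GelObservation(
            mg=1.0, fraction_intact=np.exp(-1), incubation_time=172800.0, n_bonds=1
        )
        assert lifetime_from_fraction_intact(obs) == pytest.approx(172800.0)

    def test_multi_bond_hand_value(self):
        # 75 bonds, 48 h, half the molecules intact:
        # 75 * 172800 / ln 2 = 1.8698e7 s per bond
        obs = GelObservation(
            mg=1.0, fraction_intact=0.5, incubation_time=172800.0, n_bonds=75
        )
        assert lifetime_from_fraction_intact(obs) == pytest.approx(1.86976e7, rel=1e-4)

    @pytest.mark.parametrize("frac", [1.0, 0.0])
    def test_extreme_fractions_censored(self, frac):
        obs = GelObservation(mg=1.0, fraction_intact=frac, incubation_time=100.0, n_bonds=10)
        out = lifetime_from_fraction_intact(obs)
        assert isinstance(out, CensoredObservation)

    def test_round_trip_through_forward_model(self):
        lt = 2.3e7
        n_bonds, t = 75, 172800.0
        frac = np.exp(-n_bonds * t / lt)
        obs = GelObservation(mg=2.0, fraction_intact=frac, incubation_time=t, n_bonds=n_bonds)
        assert lifetime_from_fraction_intact(obs) == pytest.approx(lt, rel=1e-12)

    def test_reduce_excludes_censored_and_zero_mg(self):
        obs = [
            GelObservation(mg=0.0, fraction_intact=0.9, incubation_time=100.0, n_bonds=5),
            GelObservation(mg=1.0, fraction_intact=1.0, incubation_time=100.0, n_bonds=5),
            GelObservation(mg=2.0, fraction_intact=0.5, incubation_time=100.0, n_bonds=5),
        ]
        data, censored = reduce_gel_observations(obs)
        assert len(data) == 1 and len(censored) == 2
        assert np.all(np.isfinite(data.value))

    def test_end_to_end_gel_fit_recovers_ratios(self):
        """Gel lanes generated from the tRNA model, reduced to per-bond
        lifetimes and refit, recover the generating rate-constant ratios
        within 10% at 5% multiplicative noise."""
        true = preset_spec("trna_lifetime_3state")
        cfg = SyntheticConfig(
            generating_spec=true,
            mg_grid=np.geomspace(0.5, 10, 30),
            noise=NoiseModel("lognormal_multiplicative", 0.05),
            seed=42,
        )
        obs, _ = gen_gel_observations(cfg, incubation_time=172800.0, n_bonds=75)
        data, _ = reduce_gel_observations(obs)
        fit = fit_lifetime(data, states=3, tie_n=True)
        r = fit.spec.rates
        assert r.k_u / r.k_i == pytest.approx(true.rates.k_u / true.rates.k_i, rel=0.10)
        assert r.k_u / r.k_f == pytest.approx(true.rates.k_u / true.rates.k_f, rel=0.10)


class TestSiteAnalysis:
    def _table(self):
        extent = pd.DataFrame(
            {5.0: [0.1, 0.2, 0.05], 10.0: [0.05, 0.05, 0.05], 15.0: [0.08, 0.12, 0.05]},
            index=[1, 2, 3],
        )
        mask = pd.Series(["unpaired", "unpaired", "paired"], index=[1, 2, 3])
        return SiteCleavageTable(extent, structure_mask=mask)

    def test_extent_single_site_half(self):
        assert extent_of_cleavage([10.0], 10.0) == pytest.approx([0.5])
        assert extent_of_cleavage([0.0, 5.0], 5.0) == pytest.approx([0.0, 0.5])
        with pytest.raises(ValueError):
            extent_of_cleavage([0.0, 0.0], 0.0)

    def test_extent_recovers_probabilities_monte_carlo(self):
        rng = np.random.default_rng(17)
        probs = np.array([0.05, 0.15, 0.30])  # per-molecule cleavage site probs
        n = 200_000
        draws = rng.choice(4, size=n, p=[*probs, 1 - probs.sum()])
        counts = np.bincount(draws, minlength=4).astype(float)
        est = extent_of_cleavage(counts[:3], counts[3])
        assert est == pytest.approx(probs, abs=0.005)

    def test_delta_vs_itself_is_zero_and_antisymmetric(self):
        table = self._table()
        d10 = delta_cleavage(table, 10.0)
        assert np.allclose(d10.delta[10.0], 0.0)
        d5 = delta_cleavage(table, 5.0)
        assert np.allclose(
            d10.delta[5.0].to_numpy(), -d5.delta[10.0].to_numpy()
        )

    def test_constructed_offpeak_shift(self):
        """Unpaired positions given +0.1 extent off-peak show ~+0.1 Δcleavage;
        paired positions stay near zero."""
        positions = list(range(1, 21))
        mask = pd.Series(
            ["paired" if p % 2 else "unpaired" for p in positions], index=positions
        )
        base = pd.Series(0.05, index=positions)
        off = base + 0.1 * (mask == "unpaired")
        table = SiteCleavageTable(
            pd.DataFrame({5.0: off / 10, 10.0: base / 10}), structure_mask=mask
        )
        d = delta_cleavage(table, 10.0)
        assert np.allclose(d.delta[5.0][mask == "unpaired"], 0.01)
        assert np.allclose(d.delta[5.0][mask == "paired"], 0.0)

    def test_condition_means(self):
        table = self._table()
        means = table.condition_means()
        assert means[10.0] == pytest.approx(0.05)
        assert means[5.0] > means[10.0]

    def test_uniform_extents_have_zero_sd(self):
        positions = [1, 2, 3, 4]
        mask = pd.Series(["paired", "paired", "unpaired", "unpaired"], index=positions)
        table = SiteCleavageTable(
            pd.DataFrame({5.0: [0.1] * 4}, index=positions), structure_mask=mask
        )
        summary = dispersion_by_structure(table)
        assert summary["sd"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_partial_folding_inflates_unpaired_dispersion(self):
        mask = ["paired"] * 30 + ["unpaired"] * 30
        table, _ = gen_site_table(
            60,
            mask,
            [
                SiteCondition(mg=5.0, mean_extent=0.004, paired_cv=0.1, unpaired_cv=0.8),
                SiteCondition(mg=10.0, mean_extent=0.003, paired_cv=0.1, unpaired_cv=0.15),
            ],
            seed=8,
        )
        summary = dispersion_by_structure(table).set_index(["condition", "structure"])
        assert summary.loc[(5.0, "unpaired"), "sd"] > summary.loc[(5.0, "paired"), "sd"]

    def test_hotspot_flagging(self):
        positions = list(range(1, 11))
        vals = [0.01] * 9 + [0.2]
        mask = pd.Series(["unpaired"] * 10, index=positions)
        table = SiteCleavageTable(
            pd.DataFrame({5.0: vals}, index=positions), structure_mask=mask
        )
        summary = dispersion_by_structure(table)
        assert summary.iloc[1]["hotspots"] == (10,)

    def test_mask_must_cover_positions(self):
        table = self._table()
        short_mask = pd.Series(["paired"], index=[1])
        with pytest.raises(ValueError):
            dispersion_by_structure(table, short_mask)
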