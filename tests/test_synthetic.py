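"""Generator contracts: template geometry, coupling arithmetic,
reproducibility, and the statistical properties of the planted cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcmech.containers import SCENARIO_CODES, validate_design
from fcmech.synthetic import (
    CohortConfig,
    PlacementError,
    ScenarioEffect,
    all_scenario_effects,
    bandlimited_timecourse,
    jitter_for_target_correlation,
    make_rsn_templates,
    simulate_cohort,
    simulate_subject,
    t2ll_distribution_sd,
)


class TestTemplates:
    def test_suprathreshold_masks_disjoint(self):
        tpls = make_rsn_templates((10, 10, 10), 2, seed=1)
        overlap = tpls[0].suprathreshold() & tpls[1].suprathreshold()
        assert not overlap.any()

    def test_deterministic_given_seed(self):
        a = make_rsn_templates((12, 12, 12), 3, seed=7)
        b = make_rsn_templates((12, 12, 12), 3, seed=7)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.map, tb.map)
            assert ta.name == tb.name

    def test_peak_weight_is_one(self):
        for t in make_rsn_templates((12, 12, 12), 4, seed=3):
            assert t.map.max() == 1.0
            assert t.map.min() >= 0.0

    def test_too_small_grid_raises_with_dimension(self):
        with pytest.raises(PlacementError, match="[xyz]"):
            make_rsn_templates((8, 8, 4), 2, seed=0)

    def test_crowded_grid_raises(self):
        with pytest.raises(PlacementError):
            make_rsn_templates((9, 9, 9), 30, seed=0)


def _ms_row(t2ll=10.0, msss=3.0):
    return pd.Series(
        {"subject_id": "s0", "group": "MS", "subgroup": "MS_short", "age": 35.0,
         "gender": "F", "education": 13.0, "gm_ratio": 0.45, "t2ll": t2ll,
         "msss": msss, "disease_duration": 2.0}
    )


def _hc_row():
    row = _ms_row()
    row["group"], row["subgroup"] = "HC", "none"
    row["t2ll"] = row["msss"] = row["disease_duration"] = np.nan
    return row


class TestSimulateSubject:
    def test_noiseless_single_network_is_rank_one_at_blob(self):
        tpls = make_rsn_templates((12, 12, 10), 2, seed=2)[:1]
        vol = simulate_subject(tpls, _hc_row(), [], T=60, TR=2.5, noise_sd=0.0, seed=5)
        blob = tpls[0].suprathreshold()
        series = vol.data[blob]
        s = np.linalg.svd(series, compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_null_ms_equals_hc_bitwise(self):
        """With zero planted effects the MS and HC generative models agree."""
        tpls = make_rsn_templates((12, 12, 10), 2, seed=2)
        region = tpls[0].suprathreshold()
        spec_kwargs = dict(region_mask=region, fc_effect=0.0, t2ll_slope=0.0,
                           msss_slope=0.0, network=tpls[0].name)
        from fcmech.containers import ScenarioRegionSpec

        scen = [ScenarioRegionSpec(scenario_id="1", **spec_kwargs)]
        kw = dict(T=60, TR=2.5, noise_sd=0.2, seed=9, coupling_jitter_sd=0.0)
        v_ms = simulate_subject(tpls, _ms_row(), scen, **kw)
        v_hc = simulate_subject(tpls, _hc_row(), scen, **kw)
        assert np.array_equal(v_ms.data, v_hc.data)

    def test_coupling_linear_in_t2ll(self):
        """t2ll_slope=+0.05 with t2ll 20 vs 0 shifts in-region coupling by 1."""
        from fcmech.containers import ScenarioRegionSpec
        from fcmech.synthetic import _subject_couplings

        tpls = make_rsn_templates((12, 12, 10), 2, seed=2)
        scen = [ScenarioRegionSpec(
            scenario_id="3b", region_mask=tpls[0].suprathreshold(),
            fc_effect=0.5, t2ll_slope=0.05, msss_slope=0.1, network=tpls[0].name)]
        cs = []
        for t2 in (20.0, 0.0):
            rng = np.random.default_rng(3)
            _, reg = _subject_couplings(
                _ms_row(t2ll=t2), tpls, scen, rng, baseline=1.0,
                network_jitter_sd=0.0, coupling_jitter_sd=0.0,
                t2ll_center=0.0, msss_center=0.0)
            cs.append(reg[0])
        assert cs[0] - cs[1] == pytest.approx(1.0, abs=1e-12)

    def test_missing_metadata_raises(self):
        from fcmech.containers import ScenarioRegionSpec

        tpls = make_rsn_templates((12, 12, 10), 2, seed=2)
        scen = [ScenarioRegionSpec(
            scenario_id="2", region_mask=tpls[0].suprathreshold(),
            fc_effect=0.5, t2ll_slope=-0.05, msss_slope=0.0, network=tpls[0].name)]
        with pytest.raises(ValueError, match="t2ll/msss"):
            simulate_subject(tpls, _ms_row(t2ll=np.nan), scen, T=60, TR=2.5,
                             noise_sd=0.1, seed=1)

    def test_timecourse_band_limits(self):
        rng = np.random.default_rng(0)
        s = bandlimited_timecourse(240, 2.5, rng)
        freqs = np.fft.rfftfreq(240, 2.5)
        spec = np.abs(np.fft.rfft(s)) ** 2
        out_of_band = spec[(freqs < 0.01) | (freqs > 0.1)].sum()
        assert out_of_band / spec.sum() < 1e-20
        assert s.std() == pytest.approx(1.0)


class TestSimulateCohort:
    def test_six_scenarios_yield_six_distinct_labels(self):
        names = ["DMNa", "PNsup", "SMNm1", "MVN", "LVN", "ECN"]
        cfg = CohortConfig(
            n_hc=3, n_ms_short=3, n_ms_long=2, grid=(22, 22, 14), T=60,
            n_networks=6, scenario_effects=all_scenario_effects(names))
        _, _, truth = simulate_cohort(cfg, seed=5, make_volumes=False)
        assert set(truth.scenario_map.present_codes()) == set(SCENARIO_CODES.values())

    def test_null_cohort_keeps_scenario_map(self):
        cfg = CohortConfig(
            n_hc=3, n_ms_short=2, n_ms_long=2, grid=(14, 14, 10), T=60,
            n_networks=4,
            scenario_effects=[ScenarioEffect("1", "DMNa", 0.0, 0.0, 0.0)])
        _, design, truth = simulate_cohort(cfg, seed=3, make_volumes=False)
        assert truth.scenario_map.present_codes() == [1]

    def test_bit_identical_given_config_and_seed(self):
        cfg = CohortConfig(n_hc=2, n_ms_short=2, n_ms_long=2, grid=(12, 12, 10),
                           T=48, n_networks=2)
        v1, d1, t1 = simulate_cohort(cfg, seed=11)
        v2, d2, t2 = simulate_cohort(cfg, seed=11)
        pd.testing.assert_frame_equal(d1, d2)
        for a, b in zip(v1, v2):
            assert np.array_equal(a.data, b.data)
        assert np.array_equal(t1.scenario_map.labels, t2.scenario_map.labels)

    def test_design_satisfies_invariants(self):
        cfg = CohortConfig(n_hc=10, n_ms_short=12, n_ms_long=9, n_networks=2)
        _, design, _ = simulate_cohort(cfg, seed=2, make_volumes=False)
        validate_design(design)
        ms = design[design.group == "MS"]
        assert (ms.loc[ms.subgroup == "MS_short", "disease_duration"] <= 5).all()
        assert (ms.loc[ms.subgroup == "MS_long", "disease_duration"] > 5).all()
        assert design.loc[design.group == "HC", "t2ll"].isna().all()

    def test_planted_t2ll_coupling_correlation(self):
        """Planting r=+0.6 between in-region coupling and lesion load is
        recovered (mean sample r over 100 seeds within 0.15 of 0.6)."""
        base = CohortConfig(n_networks=2)
        sd = t2ll_distribution_sd(base)
        slope = 0.025
        jit = jitter_for_target_correlation(slope, 0.6, sd)
        eff = [ScenarioEffect("3b", "DMNa", 0.6, slope, 1e-6)]
        cfg = CohortConfig(n_networks=2, scenario_effects=eff, coupling_jitter_sd=jit)
        rs = []
        for s in range(100):
            _, design, truth = simulate_cohort(cfg, seed=3000 + s, make_volumes=False)
            ms = (design.group == "MS").to_numpy()
            col = [c for c in truth.couplings.columns if c.startswith("region0_")][0]
            rs.append(np.corrcoef(truth.couplings.loc[ms, col],
                                  design.loc[ms, "t2ll"])[0, 1])
        assert abs(np.mean(rs) - 0.6) < 0.15

    def test_coupling_linearity_recovers_slope(self):
        """OLS of true in-region coupling on t2ll recovers the planted slope
        within two standard errors."""
        eff = [ScenarioEffect("2", "DMNa", 0.6, -0.025, 0.0)]
        cfg = CohortConfig(n_networks=2, scenario_effects=eff, coupling_jitter_sd=0.1)
        _, design, truth = simulate_cohort(cfg, seed=77, make_volumes=False)
        ms = (design.group == "MS").to_numpy()
        col = [c for c in truth.couplings.columns if c.startswith("region0_")][0]
        y = truth.couplings.loc[ms, col].to_numpy()
        x = design.loc[ms, "t2ll"].to_numpy()
        res = stats.linregress(x, y)
        assert abs(res.slope - (-0.025)) < 2 * res.stderr

    def test_null_soundness_group_t_follows_t_distribution(self):
        """With all effects zero, voxelwise two-sample t statistics on
        subject mean maps follow the t distribution (KS test)."""
        cfg = CohortConfig(n_hc=12, n_ms_short=6, n_ms_long=6, grid=(25, 25, 16),
                           T=60, n_networks=4, scenario_effects=[])
        vols, design, _ = simulate_cohort(cfg, seed=101)
        means = np.stack([v.data.mean(axis=-1)[v.mask] for v in vols])
        grp = (design.group == "MS").to_numpy()
        a, b = means[grp], means[~grp]
        na, nb = len(a), len(b)
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        t = (a.mean(0) - b.mean(0)) / (sp * np.sqrt(1 / na + 1 / nb))
        ks = stats.kstest(t, stats.t(df=na + nb - 2).cdf)
        assert t.size == 10000
        assert ks.pvalue > 0.01

    def test_region_overlapping_two_templates_rejected(self):
        from fcmech.containers import ScenarioRegionSpec
        from fcmech.synthetic import _validate_region

        tpls = make_rsn_templates((14, 14, 10), 2, seed=4)
        both = tpls[0].suprathreshold() | tpls[1].suprathreshold()
        spec = ScenarioRegionSpec(scenario_id="2", region_mask=both,
                                  fc_effect=0.5, t2ll_slope=-0.02, msss_slope=0.0)
        with pytest.raises(ValueError, match="exactly one|overlaps"):
            _validate_region(spec, tpls)

    def test_scenario_sign_table_enforced(self):
        from fcmech.containers import ScenarioRegionSpec

        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="fc_effect"):
            ScenarioRegionSpec(scenario_id="1", region_mask=mask, fc_effect=+0.5,
                               t2ll_slope=-0.01, msss_slope=0.0)
        with pytest.raises(ValueError, match="msss_slope"):
            ScenarioRegionSpec(scenario_id="3a", region_mask=mask, fc_effect=+0.5,
                               t2ll_slope=+0.01, msss_slope=+0.1)
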