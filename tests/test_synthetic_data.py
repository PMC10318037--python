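import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microstab import (
    SimulationScenario,
    build_pool_truth,
    scenario_from_yaml,
    scenario_to_yaml,
    simulate_communities,
    simulate_processes,
)


def _richness_by_level(counts, meta):
    rich = (counts.counts > 0).sum(axis=1)
    return meta.frame.assign(rich=rich).groupby(
        ["land_use", "diversity_level"], observed=True
    )["rich"].mean()


class TestSimulateCommunities:
    def test_reproducible_bit_identical(self, small_scenario):
        c1, m1 = simulate_communities(small_scenario)
        c2, m2 = simulate_communities(small_scenario)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        pd.testing.assert_frame_equal(m1.frame, m2.frame)

    def test_default_design_size_and_monotone_richness(self):
        scn = SimulationScenario(seed=1)
        counts, meta = simulate_communities(scn)
        assert len(counts.sample_ids) == 60
        by_level = _richness_by_level(counts, meta)
        for lu in scn.land_uses:
            assert by_level[lu]["D0"] > by_level[lu]["D1"] > by_level[lu]["D2"]

    def test_stepwise_richness_losses_near_calibration_target(self):
        scn = SimulationScenario(seed=2)
        counts, meta = simulate_communities(scn)
        m = meta.frame.assign(rich=(counts.counts > 0).sum(axis=1)).groupby(
            "diversity_level", observed=True
        )["rich"].mean()
        loss1 = 1 - m["D1"] / m["D0"]
        loss2 = 1 - m["D2"] / m["D1"]
        assert 0.38 <= loss1 <= 0.54
        assert 0.36 <= loss2 <= 0.52

    def test_monotone_dilution_across_seeds(self, small_scenario):
        ok = 0
        for seed in range(20):
            scn = dataclasses.replace(small_scenario, seed=seed)
            counts, meta = simulate_communities(scn)
            by_level = _richness_by_level(counts, meta)
            ok += all(
                by_level[lu]["D0"] > by_level[lu]["D1"] > by_level[lu]["D2"]
                for lu in scn.land_uses
            )
        assert ok >= 19

    def test_equal_cell_counts_no_richness_gradient(self, small_scenario):
        scn = dataclasses.replace(
            small_scenario, dilution_cells={"D0": 10_000, "D1": 10_000, "D2": 10_000}
        )
        counts, meta = simulate_communities(scn)
        rich = (counts.counts > 0).sum(axis=1)
        groups = [
            rich[meta.frame["diversity_level"] == lvl].to_numpy() for lvl in ("D0", "D1", "D2")
        ]
        assert stats.f_oneway(*groups).pvalue > 0.01

    def test_neutral_stress_multipliers_exchangeable(self, small_scenario):
        nonsig = 0
        for seed in range(20):
            scn = dataclasses.replace(
                small_scenario,
                seed=100 + seed,
                sensitive_multiplier=1.0,
                tolerant_multiplier=1.0,
                nitrifier_multiplier=1.0,
            )
            counts, meta = simulate_communities(scn)
            truth = build_pool_truth(scn)
            sens = truth.guild.index[truth.guild == "sensitive"]
            rel = counts.counts.div(counts.sample_totals(), axis=0)[sens].sum(axis=1)
            d2 = meta.frame["diversity_level"] == "D2"
            ctl = rel[d2 & (meta.frame["stress"] == "control")]
            strs = rel[d2 & (meta.frame["stress"] == "stressed")]
            p = stats.mannwhitneyu(ctl, strs, alternative="two-sided").pvalue
            nonsig += p > 0.01
        assert nonsig >= 19

    def test_stress_effect_confined_to_lowest_diversity(self, small_scenario):
        counts, meta = simulate_communities(small_scenario)
        truth = build_pool_truth(small_scenario)
        sens = truth.guild.index[truth.guild == "sensitive"]
        rel = counts.counts.div(counts.sample_totals(), axis=0)[sens].sum(axis=1)
        mf = meta.frame
        d2_ctl = rel[(mf["diversity_level"] == "D2") & (mf["stress"] == "control")].mean()
        d2_strs = rel[(mf["diversity_level"] == "D2") & (mf["stress"] == "stressed")].mean()
        d0_ctl = rel[(mf["diversity_level"] == "D0") & (mf["stress"] == "control")].mean()
        d0_strs = rel[(mf["diversity_level"] == "D0") & (mf["stress"] == "stressed")].mean()
        assert d2_strs < 0.5 * d2_ctl  # guild crashes under stress at D2
        assert abs(d0_strs - d0_ctl) < 0.5 * d0_ctl  # no planted effect at D0

    def test_zero_cell_count_rejected(self, small_scenario):
        with pytest.raises(ValueError, match="cell counts"):
            dataclasses.replace(small_scenario, dilution_cells={"D0": 100, "D1": 0, "D2": 10})

    def test_depth_independence_of_relative_abundance(self, small_scenario):
        scn1 = dataclasses.replace(small_scenario, depth_mean=30_000.0, depth_dispersion=1e6)
        scn2 = dataclasses.replace(small_scenario, depth_mean=60_000.0, depth_dispersion=1e6)
        c1, m1 = simulate_communities(scn1)
        c2, m2 = simulate_communities(scn2)
        r1 = c1.counts.div(c1.sample_totals(), axis=0).mean(axis=0)
        r2 = c2.counts.div(c2.sample_totals(), axis=0).mean(axis=0)
        common = r1[r1 > 0.01].index
        assert (np.abs(r1[common] - r2[common]) / r1[common]).max() < 0.1


class TestSimulateProcesses:
    def test_noiseless_nitrification_perfectly_correlated(self, small_scenario):
        scn = dataclasses.replace(
            small_scenario,
            beta={"nitrification": {"nitrifier_abundance": 5e-8}},
            noise_sd={k: 0.0 for k in ("respiration", "sir", "enzyme", "n_mineralization", "nitrification")},
        )
        counts, meta = simulate_communities(scn)
        proc, _ = simulate_processes(counts, meta, scn)
        f = proc.frame
        nitrif = (f["no3_t1"] - f["no3_t0"]) / f["interval_days"]
        r = np.corrcoef(nitrif, f["aoa"] + f["aob"])[0, 1]
        assert r > 0.999

    def test_truth_lists_generating_coefficients(self, small_experiment, small_scenario):
        _, _, _, truth = small_experiment
        betas = truth[truth["kind"] == "beta"]
        for fn, coefs in small_scenario.beta.items():
            for drv, coef in coefs.items():
                row = betas[(betas["name"] == fn) & (betas["detail"] == drv)]
                assert len(row) == 1 and row["value"].iloc[0] == coef
        assert (truth["kind"] == "guild").any()
        assert truth[truth["kind"] == "seed"]["value"].iloc[0] == small_scenario.seed

    def test_unknown_driver_rejected(self, small_scenario):
        scn = dataclasses.replace(small_scenario, beta={"sir": {"not_a_driver": 1.0}})
        counts, meta = simulate_communities(small_scenario)
        with pytest.raises(ValueError, match="unknown driver"):
            simulate_processes(counts, meta, scn)

    def test_biomass_inflated_in_stressed_lowest_dilution(self, small_experiment):
        counts, meta, proc, _ = small_experiment
        f = meta.frame.assign(biomass=proc.frame["biomass"])
        d2 = f[f["diversity_level"] == "D2"]
        ratio = (
            d2[d2["stress"] == "stressed"]["biomass"].mean()
            / d2[d2["stress"] == "control"]["biomass"].mean()
        )
        assert 1.2 < ratio < 2.4  # calibrated ~1.69x inflation

    def test_its_near_zero_when_diluted(self, small_experiment):
        counts, meta, proc, _ = small_experiment
        f = meta.frame.assign(its=proc.frame["abund_its"])
        assert f[f["diversity_level"] != "D0"]["its"].max() < 0.01 * f[f["diversity_level"] == "D0"]["its"].mean()


class TestScenarioIO:
    def test_yaml_round_trip(self, small_scenario, tmp_path):
        scenario_to_yaml(small_scenario, tmp_path / "scn.yaml")
        back = scenario_from_yaml(tmp_path / "scn.yaml")
        assert back == small_scenario

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("not_a_field: 3\n")
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_from_yaml(tmp_path / "bad.yaml")
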