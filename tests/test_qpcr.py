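"""ΔΔCT quantification and the dosage-validation statistics."""

import numpy as np
import pandas as pd
import pytest

import cghscreen as cg
from cghscreen.qpcr import INTERNAL_CONTROL, round_copy_number
from cghscreen.synthetic_data import simulate_qpcr_plate


def make_plate(doses, ct0=26.0, sigma_ct=0.0, region="striatum", seed=0):
    """Plate for {sample: (group, dose)} at a single target assay."""
    df = pd.DataFrame(
        [
            {
                "sample": s,
                "group": grp,
                "region": region,
                "assay": "tgt",
                "dose": d,
            }
            for s, (grp, d) in doses.items()
        ]
    )
    return simulate_qpcr_plate(df, ct0=ct0, sigma_ct=sigma_ct, seed=seed)


class TestDeltaDeltaCt:
    def test_identical_cts_zero_everywhere(self):
        plate = make_plate({"s1": ("case", 1.0), "c1": ("control", 1.0)})
        out = cg.delta_delta_ct(plate, "tgt")
        assert np.all(out["ddct"] == 0.0)

    def test_one_extra_cycle_gives_ddct_one(self):
        plate = make_plate(
            {"s1": ("case", 0.5), "c1": ("control", 1.0), "c2": ("control", 1.0)}
        )
        out = cg.delta_delta_ct(plate, "tgt").set_index("sample")
        assert out.loc["s1", "ddct"] == pytest.approx(1.0)
        assert out.loc["c1", "ddct"] == pytest.approx(0.0)

    def test_missing_internal_control_excluded(self, caplog):
        plate = make_plate({"s1": ("case", 1.0), "c1": ("control", 1.0)})
        plate = plate[
            ~((plate["sample"] == "s1") & (plate["assay"] == INTERNAL_CONTROL))
        ]
        with caplog.at_level("WARNING"):
            out = cg.delta_delta_ct(plate, "tgt")
        assert "s1" in caplog.text
        assert list(out["sample"]) == ["c1"]

    def test_calibrator_is_control_median(self):
        plate = make_plate(
            {
                "s1": ("case", 1.0),
                "c1": ("control", 0.5),
                "c2": ("control", 1.0),
                "c3": ("control", 2.0),
            }
        )
        out = cg.delta_delta_ct(plate, "tgt").set_index("sample")
        # control ΔCTs are (1, 0, -1); median 0 -> c2 is the reference
        assert out.loc["c2", "ddct"] == pytest.approx(0.0)
        assert out.loc["s1", "ddct"] == pytest.approx(0.0)


class TestCopyNumber:
    @pytest.mark.parametrize("ddct,cn", [(0.0, 2.0), (1.0, 1.0), (-1.0, 4.0)])
    def test_doubling_rule(self, ddct, cn):
        assert cg.copy_number(ddct) == cn

    def test_strictly_decreasing(self):
        grid = np.linspace(-3, 3, 50)
        assert np.all(np.diff(cg.copy_number(grid)) < 0)

    def test_recovers_planted_dose_noiselessly(self):
        plate = make_plate({"s1": ("case", 0.5), "c1": ("control", 1.0)})
        cn = cg.sample_copy_numbers(plate, "tgt").set_index("sample")
        assert cn.loc["s1", "cn"] == pytest.approx(1.0)
        assert cn.loc["c1", "cn"] == pytest.approx(2.0)

    def test_recovers_dose_within_propagated_noise(self):
        sigma_ct = 0.05
        doses = {f"c{i}": ("control", 1.0) for i in range(12)}
        doses.update({f"s{i}": ("case", 0.75) for i in range(12)})
        plate = make_plate(doses, sigma_ct=sigma_ct, seed=3)
        cn = cg.sample_copy_numbers(plate, "tgt")
        cases = cn[cn["group"] == "case"]["cn"]
        # ΔΔCT error ~ sigma_ct * sqrt(2/4 reps * 2 diffs); generous 2x bound
        tol = 2 * 1.5 * np.log(2) * sigma_ct
        assert cases.mean() == pytest.approx(1.5, abs=tol)


class TestPairAnova:
    def _cn(self, case_cn, ctrl_cn, n_pairs=4, reps=4, sigma=0.02, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_pairs):
            for disease, base in (("scz", case_cn), ("ctl", ctrl_cn)):
                for _ in range(reps):
                    rows.append(
                        {
                            "pair": f"P{p}",
                            "disease": disease,
                            "cn": base + rng.normal(0, sigma),
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_response_p_one(self):
        cn = self._cn(2.0, 2.0, sigma=0.0)
        table = cg.pair_anova(cn)
        assert table.loc["disease", "p"] == 1.0

    def test_planted_disease_effect_detected(self):
        table = cg.pair_anova(self._cn(1.0, 2.0))
        assert table.loc["disease", "p"] < 0.001

    def test_type_one_error_calibrated(self):
        hits = 0
        n_rep = 400
        for seed in range(n_rep):
            table = cg.pair_anova(self._cn(2.0, 2.0, sigma=0.1, seed=seed))
            hits += table.loc["disease", "p"] < 0.05
        rate = hits / n_rep
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_rep))

    def test_empty_cell_named(self):
        cn = self._cn(1.0, 2.0)
        cn = cn[~((cn["pair"] == "P1") & (cn["disease"] == "scz"))]
        with pytest.raises(ValueError, match="P1"):
            cg.pair_anova(cn)


class TestGroupCompare:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        cn = pd.DataFrame(
            {
                "group": ["case"] * 48 + ["control"] * 48,
                "cn": np.concatenate(
                    [2 + rng.normal(0, 0.05, 48), 2 + rng.normal(0, 0.05, 48)]
                ),
            }
        )
        res = cg.group_compare(cn)
        assert res["mwu_p"] > 0.05

    def test_extreme_separation(self):
        cn = pd.DataFrame(
            {"group": ["case"] * 30 + ["control"] * 30, "cn": [1.0] * 30 + [2.0] * 30}
        )
        res = cg.group_compare(cn)
        assert res["chi2_p"] < 1e-6 and res["mwu_p"] < 1e-6

    def test_rounding_half_away_from_zero(self):
        assert list(round_copy_number([0.4, 0.5, 1.49, 1.5, 2.5])) == [0, 1, 1, 2, 3]

    def test_rounding_documented_in_output(self):
        cn = pd.DataFrame(
            {"group": ["case"] * 5 + ["control"] * 5, "cn": [1.2] * 5 + [2.1] * 5}
        )
        res = cg.group_compare(cn)
        assert res["rounding"] == "half away from zero"
        assert sorted(res["contingency"].index) == [1, 2]

    def test_single_class_degenerate(self):
        cn = pd.DataFrame(
            {"group": ["case"] * 5 + ["control"] * 5, "cn": [2.0] * 10}
        )
        res = cg.group_compare(cn)
        assert res["chi2_degenerate"] is True and np.isnan(res["chi2_p"])
        assert res["mwu_p"] == 1.0

    def test_rare_classes_pooled(self):
        cn = pd.DataFrame(
            {
                "group": ["case"] * 20 + ["control"] * 20,
                "cn": [1.0] * 19 + [6.0] + [2.0] * 20,
            }
        )
        res = cg.group_compare(cn)
        expected = res["contingency"].to_numpy()
        grand = expected.sum()
        exp = np.outer(expected.sum(1), expected.sum(0)) / grand
        assert exp.min() >= 1.0 or len(res["contingency"]) == 2


class TestRegionRatio:
    def _two_region_plate(self, striatum_dose, cortex_dose, sigma_ct=0.0, seed=0):
        frames = []
        pairing = [(f"s{i}", f"c{i}") for i in range(4)]
        for region, case_dose in (
            ("striatum", striatum_dose),
            ("prefrontal_cortex", cortex_dose),
        ):
            doses = {}
            for case_id, ctrl_id in pairing:
                doses[case_id] = ("case", case_dose)
                doses[ctrl_id] = ("control", 1.0)
            frames.append(
                make_plate(doses, region=region, sigma_ct=sigma_ct, seed=seed)
            )
        return pd.concat(frames, ignore_index=True), pairing

    def test_identical_regions_no_effect(self):
        plate, pairing = self._two_region_plate(0.5, 0.5, sigma_ct=0.01)
        rep = cg.replicate_copy_numbers(plate, "tgt")
        res = cg.region_ratio_test(rep, pairing)
        assert res["anova"].loc["region", "p"] > 0.05
        # deletion shared by both regions: every pair ratio well below 1
        assert (res["summary"]["ratio"] < 0.75).all()

    def test_striatum_only_event_detected(self):
        plate, pairing = self._two_region_plate(0.5, 1.0, sigma_ct=0.05, seed=2)
        rep = cg.replicate_copy_numbers(plate, "tgt")
        res = cg.region_ratio_test(rep, pairing)
        assert res["anova"].loc["region", "p"] < 0.001
        by_region = res["summary"].groupby("region")["ratio"].mean()
        assert by_region["striatum"] < 0.7 < by_region["prefrontal_cortex"]

    def test_missing_region_pair_skipped(self, caplog):
        plate, pairing = self._two_region_plate(0.5, 0.5)
        plate = plate[~((plate["sample"] == "s0") & (plate["region"] == "striatum"))]
        rep = cg.replicate_copy_numbers(plate, "tgt")
        with caplog.at_level("WARNING"):
            res = cg.region_ratio_test(rep, pairing)
        assert "skipped" in caplog.text
        assert len(res["summary"]) == 7  # 4 pairs x 2 regions minus one


class TestEndToEndValidation:
    def test_demo_loci_confirmed_by_pair_anova(self, demo):
        # planted aCGH events must also separate disease groups on
        # simulated qPCR of the same loci (paired design, 8 pairs)
        from cghscreen.pipeline import _event_doses

        doses = _event_doses(demo)
        plate = simulate_qpcr_plate(doses, sigma_ct=0.05, seed=7)
        pair_of = {}
        for case_id, ctrl_id in demo.pairing:
            pair_of[case_id] = pair_of[ctrl_id] = f"{case_id}:{ctrl_id}"
        for ev in demo.events:
            assay = f"locus_chr{ev.chromosome}_{ev.start}"
            rep = cg.replicate_copy_numbers(plate, assay)
            rep["pair"] = rep["sample"].map(pair_of)
            rep["disease"] = rep["group"]
            table = cg.pair_anova(rep[["pair", "disease", "cn"]])
            assert table.loc["disease", "p"] < 0.001

    def test_group_screen_confirms_recurrent_event(self):
        # a germline case-only deletion carried by 30/48 cases is
        # confirmed by the group-level tests in (almost) every replicate
        confirmed = 0
        n_rep = 10
        for seed in range(n_rep):
            doses = {f"ctrl_{i:02d}": ("control", 1.0) for i in range(48)}
            doses.update(
                {
                    f"case_{i:02d}": ("case", 0.5 if i < 30 else 1.0)
                    for i in range(48)
                }
            )
            plate = make_plate(doses, sigma_ct=0.05, seed=seed)
            cn = cg.sample_copy_numbers(plate, "tgt")
            res = cg.group_compare(cn[["group", "cn"]])
            confirmed += (res["mwu_p"] < 0.05) and (res["chi2_p"] < 0.05)
        assert confirmed >= 9
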