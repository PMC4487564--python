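"""Two-stage selection: penetrance tallies, the probe-wise global test,
locus cumulation and Bonferroni control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cghscreen as cg
from cghscreen.core import AberrationCall
from cghscreen.selection import PenetranceSummary, fisher_combined_p

from conftest import make_flat_map


def call(pair, i, j, direction="gain"):
    return AberrationCall(
        pair_id=pair,
        chromosome="1",
        first_probe_index=i,
        last_probe_index=j,
        direction=direction,
        score=10.0,
        mean_log2=0.5 if direction == "gain" else -0.5,
    )


class TestPenetranceSummary:
    def test_no_calls(self):
        pm = make_flat_map(10)
        s = cg.penetrance_summary([], pm)
        assert np.all(s.gain_count == 0) and np.all(s.loss_count == 0)

    def test_single_gain_call(self):
        pm = make_flat_map(12)
        s = cg.penetrance_summary([call("p1", 5, 9)], pm)
        expected = np.zeros(12, dtype=int)
        expected[5:10] = 1
        assert np.array_equal(s.gain_count, expected)
        assert np.all(s.loss_count == 0)

    def test_out_of_range_call_rejected(self):
        pm = make_flat_map(5)
        with pytest.raises(ValueError):
            cg.penetrance_summary([call("p1", 3, 7)], pm)

    def test_recurrent_planted_loss_counted(self, demo):
        calls = cg.detect_all_pairs(demo.matrix)
        s = cg.penetrance_summary(calls, demo.matrix.probe_map)
        ev = demo.events[0]  # chr1 deletion, 5 carriers
        pm = demo.matrix.probe_map
        inside = (
            (pm.chromosome == ev.chromosome)
            & (pm.position >= ev.start)
            & (pm.position <= ev.end)
        )
        # interior probes are covered by (almost) every carrier's call
        assert s.loss_count[inside].max() == len(ev.subject_ids)


class TestSelect1:
    def _loci(self, G, L, **kw):
        pm = make_flat_map(len(G))
        s = PenetranceSummary(np.array(G), np.array(L))
        return cg.select1_candidates(s, pm, **kw)

    @pytest.mark.parametrize(
        "G,L,expect",
        [
            (4, 0, 1),  # boundary: |4-0| >= 4
            (3, 0, 0),  # below threshold
            (5, 2, 0),  # |5-2| = 3, not flagged
            (0, 6, 1),
            (5, 1, 1),
        ],
    )
    def test_differential_rule(self, G, L, expect):
        assert len(self._loci([G], [L])) == expect

    def test_exclusive_rule(self):
        # >= 4 calls in one direction and none in the other
        assert len(self._loci([4], [0], rule="exclusive")) == 1
        assert len(self._loci([6], [1], rule="exclusive")) == 0
        assert len(self._loci([6], [1])) == 1  # differential rule accepts it

    def test_runs_merge_and_split(self):
        G = [0, 5, 5, 0, 5, 5, 0]
        L = [0] * 7
        loci = self._loci(G, L)
        assert [(min(l.probe_indices), max(l.probe_indices)) for l in loci] == [
            (1, 2),
            (4, 5),
        ]
        merged = self._loci(G, L, gap_probes=1)
        assert [(min(l.probe_indices), max(l.probe_indices)) for l in merged] == [
            (1, 5)
        ]

    def test_loci_never_span_chromosomes(self):
        pm = cg.make_probe_map(40, {"1": 10e6, "2": 10e6}, seed=1)
        G = np.full(40, 5)
        loci = cg.select1_candidates(PenetranceSummary(G, np.zeros(40, int)), pm)
        assert sorted(l.chromosome for l in loci) == ["1", "2"]


class TestProbeGlobalTest:
    def test_degenerate_identical_values(self):
        row = cg.probe_global_test(np.zeros(48))
        assert row["degenerate"] is True and np.isnan(row["p_t"])

    def test_type_one_error_rate(self):
        # quick check at 2000 replicates; the 10^4-replicate calibration
        # runs in the acceptance suite
        rng = np.random.default_rng(9)
        V = rng.normal(0, 0.2, size=(2000, 48))
        res = cg.global_test(_matrix_from(V))
        rate = np.mean(res["p_t"] < 0.05)
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_power_against_shifted_null(self):
        rng = np.random.default_rng(10)
        v = rng.normal(-0.3, 0.2, size=48)
        row = cg.probe_global_test(v)
        assert row["p_t"] < 1e-8

    def test_extreme_probes_do_not_underflow(self):
        v = np.full(48, -1.0) + np.linspace(-0.01, 0.01, 48)
        row = cg.probe_global_test(v)
        assert row["p_t"] < 1e-100
        assert np.isfinite(row["neglog10_p_t"])  # log-domain value survives
        assert row["neglog10_p_t"] > 100

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            cg.probe_global_test(np.array([0.1, 0.2]))


def _matrix_from(V):
    pm = make_flat_map(V.shape[0])
    return cg.PairRatioMatrix(
        probe_map=pm,
        pair_ids=[f"pair_{k}" for k in range(V.shape[1])],
        values=V,
    )


class TestCumulateLocus:
    def _rows(self, ps, means=None):
        ps = np.asarray(ps, dtype=float)
        means = np.zeros_like(ps) if means is None else np.asarray(means)
        return pd.DataFrame(
            {
                "mean_log2": means,
                "p_t": ps,
                "neglog10_p_t": -np.log10(ps),
                "degenerate": [False] * len(ps),
            }
        )

    def test_single_probe(self):
        mean, cum = cg.cumulate_locus(self._rows([0.001]))
        assert cum == pytest.approx(3.0)

    def test_additivity(self):
        mean, cum = cg.cumulate_locus(self._rows([0.01, 0.01]))
        assert cum == pytest.approx(4.0)

    def test_strong_locus_reaches_extreme_magnitudes(self):
        # ten probes at p ~ 1e-10 cumulate to ~100 on the -log10 scale
        mean, cum = cg.cumulate_locus(self._rows([1e-10] * 10))
        assert cum == pytest.approx(100.0)

    def test_mean_is_unweighted(self):
        mean, _ = cg.cumulate_locus(self._rows([0.5, 0.5], means=[-1.0, 0.5]))
        assert mean == pytest.approx(-0.25)

    def test_degenerate_probes_excluded(self):
        rows = self._rows([0.001, 0.01])
        rows.loc[1, "degenerate"] = True
        _, cum = cg.cumulate_locus(rows)
        assert cum == pytest.approx(3.0)

    def test_all_degenerate_raises(self):
        rows = self._rows([0.5])
        rows["degenerate"] = True
        with pytest.raises(ValueError):
            cg.cumulate_locus(rows)

    def test_fisher_p_is_calibrated_combination(self):
        from scipy import stats

        rows = self._rows([0.01, 0.02, 0.3])
        chi2 = -2 * np.log(np.array([0.01, 0.02, 0.3])).sum()
        assert fisher_combined_p(rows) == pytest.approx(stats.chi2.sf(chi2, 6))


class TestBonferroni:
    def test_threshold_for_1381_loci(self):
        assert round(cg.bonferroni_threshold(0.05, 1381), 2) == 4.44

    def test_single_locus_no_correction(self):
        assert cg.bonferroni_threshold(0.05, 1) == pytest.approx(1.301, abs=5e-4)

    def test_boundary_locus_passes(self):
        pm = make_flat_map(1)
        locus = cg.CandidateLocus(
            chromosome="1", start=1000, end=1000, probe_indices=[0]
        )
        locus.cum_neglog10p = cg.bonferroni_threshold(0.05, 1)
        out = cg.bonferroni_select([locus], alpha=0.05)
        assert out[0].stage == "both"

    def test_denominator_is_locus_count(self):
        loci = []
        for i in range(10):
            l = cg.CandidateLocus(
                chromosome="1", start=1 + i, end=1 + i, probe_indices=[i]
            )
            l.cum_neglog10p = 2.0  # passes alpha=0.05 alone, not over 10 loci
            loci.append(l)
        out = cg.bonferroni_select(loci, alpha=0.05)
        assert all(l.stage == "selection1" for l in out)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "m,expected", [(0.63, 1.55), (-1.46, 0.36), (0.0, 1.00)]
    )
    def test_reported_conversions(self, m, expected):
        assert round(cg.odds_ratio(m), 2) == expected

    @given(st.floats(min_value=-5, max_value=5))
    @settings(deadline=None, derandomize=True)
    def test_reciprocal_symmetry(self, m):
        assert cg.odds_ratio(m) * cg.odds_ratio(-m) == pytest.approx(1.0)


class TestEndToEndSelection:
    def test_demo_loci_match_planted_truth(self, demo):
        calls = cg.detect_all_pairs(demo.matrix)
        loci = cg.select_candidates(demo.matrix, calls)
        positive = [l for l in loci if l.stage == "both"]
        assert len(positive) == 2
        for locus, ev in zip(sorted(positive, key=lambda l: l.chromosome), demo.events):
            assert locus.chromosome == ev.chromosome
            assert locus.start >= ev.start and locus.end <= ev.end
            carriers = len(ev.subject_ids)
            pred = carriers / 8 * np.log2(
                cg.effective_dose(ev.copy_state, ev.carrier_cell_fraction)
            )
            assert locus.mean_log2 == pytest.approx(pred, abs=0.08)
            assert locus.odds_ratio == pytest.approx(2**locus.mean_log2)

    def test_null_screen_fwer(self):
        # fully null runs should essentially never yield a stage-2 locus;
        # stage 1 already requires a 4-pair call coincidence
        hits = 0
        for seed in range(20):
            study = cg.simulate_study(
                n_probes=300,
                n_pairs=48,
                chromosome_lengths={"1": 50e6},
                seed=100 + seed,
            )
            calls = cg.detect_all_pairs(study.matrix)
            loci = cg.select_candidates(study.matrix, calls)
            hits += any(l.stage == "both" for l in loci)
        assert hits <= 1  # 0.05 * 20 = 1 expected at the nominal level

    def test_frac_gaussian_reported(self, demo):
        calls = cg.detect_all_pairs(demo.matrix)
        loci = cg.select_candidates(demo.matrix, calls)
        for l in loci:
            assert 0.0 <= l.frac_gaussian <= 1.0
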