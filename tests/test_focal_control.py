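import math

import numpy as np
import pytest

from dhewscan.focal_control import (
    GenePairing,
    call_adaptive_divergence,
    call_sweep,
    comparison_score,
    group_test,
    rank_against_null,
    rank_scores,
    validate_controls,
)


def _gene(gid, length, start):
    return {"gene_id": gid, "cds_length": length, "start": start}


class TestValidateControls:
    FOCAL = _gene("f", 900, 1_000_000)

    def test_length_ratio_rule(self):
        cands = [_gene(f"c{i}", 360, 1_000_000 + i) for i in range(4)]  # 0.4x
        assert validate_controls(self.FOCAL, cands) is None

    def test_distance_rule(self):
        cands = [_gene(f"c{i}", 900, 1_070_000 + i) for i in range(4)]  # 70 kb
        assert validate_controls(self.FOCAL, cands) is None

    def test_boundaries_inclusive(self):
        cands = [
            _gene("half", 450, 1_060_000),   # exactly 0.5x, exactly 60 kb
            _gene("double", 1800, 940_000),  # exactly 2.0x
            _gene("same", 900, 1_000_100),
        ]
        pairing = validate_controls(self.FOCAL, cands)
        assert pairing is not None and len(pairing.control_ids) == 3

    def test_fewer_than_three_drops_focal(self):
        cands = [_gene("a", 900, 1_001_000), _gene("b", 900, 999_000)]
        assert validate_controls(self.FOCAL, cands) is None

    def test_mixed_candidates_filtered(self):
        cands = [
            _gene("good1", 900, 1_010_000),
            _gene("good2", 1200, 990_000),
            _gene("good3", 600, 1_050_000),
            _gene("far", 900, 1_900_000),
            _gene("short", 100, 1_000_500),
        ]
        pairing = validate_controls(self.FOCAL, cands)
        assert pairing.control_ids == ["good1", "good2", "good3"]


class TestComparisonScore:
    def test_arithmetic(self):
        assert comparison_score(-1.9, [-0.5, 0.1, -0.2]) == pytest.approx(-1.7)

    def test_zero_when_focal_equals_median(self):
        assert comparison_score(0.1, [0.0, 0.1, 0.5]) == 0.0

    def test_even_count_median(self):
        assert comparison_score(3.0, [1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.5)

    def test_nan_controls_dropped(self):
        assert comparison_score(1.0, [float("nan"), 0.5]) == pytest.approx(0.5)

    def test_undefined_when_no_controls_or_focal_nan(self):
        assert math.isnan(comparison_score(1.0, [float("nan")]))
        assert math.isnan(comparison_score(float("nan"), [0.5]))

    def test_translation_equivariance(self, rng):
        for _ in range(10):
            f = rng.normal()
            ctrl = rng.normal(size=4)
            c = rng.normal()
            assert comparison_score(f + c, (ctrl + c).tolist()) == pytest.approx(
                comparison_score(f, ctrl.tolist()), abs=1e-9
            )


class TestGroupTest:
    # reference values from R: t.test(x); wilcox.test(x, conf.int=TRUE, exact=TRUE)
    X = [0.12, -0.45, 0.33, 0.08, -0.21, 0.55, -0.02, 0.19, 0.41, -0.13, 0.27, 0.06]

    def test_matches_r_t_test(self):
        r = group_test(self.X)
        assert r["mean"] == pytest.approx(0.1)
        assert r["p_t"] == pytest.approx(0.2403435368, abs=1e-9)
        assert r["ci_t"][0] == pytest.approx(-0.0773249629, abs=1e-9)
        assert r["ci_t"][1] == pytest.approx(0.2773249629, abs=1e-9)

    def test_matches_r_wilcoxon(self):
        r = group_test(self.X)
        assert r["p_wilcoxon"] == pytest.approx(0.2661132813, abs=1e-9)
        assert r["pseudomedian"] == pytest.approx(0.1, abs=1e-9)
        assert r["ci_w"][0] == pytest.approx(-0.075, abs=1e-9)
        assert r["ci_w"][1] == pytest.approx(0.3, abs=1e-9)

    def test_symmetric_scores_not_significant(self):
        x = [-0.3, -0.2, -0.1, 0.1, 0.2, 0.3]
        r = group_test(x)
        assert r["p_t"] > 0.5 and r["p_wilcoxon"] > 0.5
        assert r["ci_t"][0] < 0 < r["ci_t"][1]

    def test_degenerate_all_identical(self):
        r = group_test([0.0] * 6)
        assert r["degenerate"] and math.isnan(r["p_t"])

    def test_nan_scores_dropped(self):
        r = group_test(self.X + [float("nan")])
        assert r["n"] == 12

    def test_requires_two_scores(self):
        with pytest.raises(ValueError):
            group_test([0.1])


class TestRankScores:
    def test_distinct_scores_full_permutation(self):
        scores = {f"g{i}": float(i) for i in range(5)}
        out = rank_scores(scores)
        assert sorted(r for r, _ in out.values()) == [1, 2, 3, 4, 5]
        assert out["g4"] == (5, 100.0)  # most extreme

    def test_orientation_flip(self):
        scores = {"a": -2.0, "b": 0.0, "c": 1.0}
        out = rank_scores(scores, higher_is_extreme=False)
        assert out["a"] == (3, 100.0)

    def test_ties_share_smaller_rank(self):
        out = rank_scores({"a": 1.0, "b": 1.0, "c": 0.0})
        assert out["a"] == out["b"] == (2, pytest.approx(200 / 3))

    def test_nan_excluded(self):
        out = rank_scores({"a": 1.0, "b": float("nan")})
        assert "b" not in out and out["a"] == (1, 100.0)


def _exchangeable_setup(rng, n_pairs=40, n_ctrl=4):
    values, pairings = {}, []
    for i in range(n_pairs):
        ids = [f"f{i}"] + [f"f{i}c{j}" for j in range(n_ctrl)]
        for g in ids:
            values[g] = float(rng.normal())
        pairings.append(GenePairing(ids[0], ids[1:]))
    return values, pairings


class TestRankAgainstNull:
    def test_extreme_true_score_is_percentile_100(self):
        values = {"f0": 100.0, "a": 0.1, "b": 0.2, "c": 0.15}
        pairings = [GenePairing("f0", ["a", "b", "c"])]
        out = rank_against_null(values, pairings)
        assert out["f0"] == 100.0

    def test_enumerate_mode_deterministic(self, rng):
        values, pairings = _exchangeable_setup(rng)
        a = rank_against_null(values, pairings, seed=1)
        b = rank_against_null(values, pairings, seed=2)  # no randomness used
        assert a == b

    def test_montecarlo_mode_deterministic_given_seed(self, rng):
        values, pairings = _exchangeable_setup(rng)
        a = rank_against_null(values, pairings, mode="montecarlo", n_perm=50, seed=9)
        b = rank_against_null(values, pairings, mode="montecarlo", n_perm=50, seed=9)
        assert a == b

    def test_pool_size_enumerates_every_control(self, rng):
        values, pairings = _exchangeable_setup(rng, n_pairs=10, n_ctrl=4)
        # 10 pairings x 4 controls = 40 pseudo-scores; check via a sentinel
        values2 = dict(values)
        values2[pairings[0].focal_id] = 1e9
        out = rank_against_null(values2, pairings)
        assert out[pairings[0].focal_id] == 100.0

    def test_nan_true_score_propagates(self):
        values = {"f0": float("nan"), "a": 0.1, "b": 0.2, "c": 0.3}
        out = rank_against_null(values, [GenePairing("f0", ["a", "b", "c"])])
        assert math.isnan(out["f0"])


class TestCallSweep:
    GOOD = dict(
        p_dhew=0.002,
        corrected_pvals={"D": 0.048, "H": 0.41, "EW": 0.013},
        rank_percentiles={"TajD": 100.0, "nFWH": 95.6, "DoS": 50.0},
        null_percentiles={"TajD": 99.6, "nFWH": 96.7, "DoS": 50.0},
    )

    def test_full_profile_called(self):
        # full evidence profile: significant DHEW, two significant
        # corrected statistics, top-ranked D comparison score
        assert call_sweep(**self.GOOD) is True

    def test_nonsignificant_dhew_blocks(self):
        args = dict(self.GOOD, p_dhew=0.2)
        assert call_sweep(**args) is False

    def test_single_corrected_statistic_blocks(self):
        args = dict(self.GOOD, corrected_pvals={"D": 0.048, "H": 0.41, "EW": 0.41})
        assert call_sweep(**args) is False

    def test_rank_criterion_blocks(self):
        args = dict(
            self.GOOD,
            rank_percentiles={"TajD": 50.0, "nFWH": 60.0, "DoS": 70.0},
            null_percentiles={"TajD": 50.0, "nFWH": 60.0, "DoS": 70.0},
        )
        assert call_sweep(**args) is False

    def test_missing_dhew_not_callable(self):
        args = dict(self.GOOD, p_dhew=float("nan"))
        assert call_sweep(**args) is None

    def test_monotone_in_evidence(self, rng):
        # strengthening evidence never flips True -> False
        for _ in range(20):
            p = float(rng.uniform(0, 0.2))
            pv = {k: float(rng.uniform(0, 0.2)) for k in ("D", "H", "EW")}
            rp = {k: float(rng.uniform(80, 100)) for k in ("TajD", "nFWH", "DoS")}
            np_ = {k: float(rng.uniform(80, 100)) for k in ("TajD", "nFWH", "DoS")}
            before = call_sweep(p, pv, rp, np_)
            stronger = call_sweep(
                p / 2,
                {k: v / 2 for k, v in pv.items()},
                {k: min(100, v + 1) for k, v in rp.items()},
                {k: min(100, v + 1) for k, v in np_.items()},
            )
            if before is True:
                assert stronger is True


class TestCallAdaptiveDivergence:
    def test_significant_positive_dos_called(self):
        assert call_adaptive_divergence(0.047, 0.396) is True

    def test_negative_dos_never_called(self):
        assert call_adaptive_divergence(0.0005, -0.373) is False

    def test_nonsignificant_p_not_called(self):
        assert call_adaptive_divergence(0.14, 0.4) is False

    def test_undefined_dos_not_callable(self):
        assert call_adaptive_divergence(0.01, float("nan")) is None
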