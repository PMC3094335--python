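"""Differential-regulation callers: percentile rule, geometric methods,
legacy platform rules, degenerate-ratio handling."""

import math

import numpy as np
import pandas as pd
import pytest

from wormtx import regulation as reg
from wormtx import simulate


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "control", "infected"])


@pytest.fixture(scope="module")
def null_cloud():
    """Symmetric scatter about y = x on log axes, n = 10,000."""
    rng = np.random.default_rng(5)
    x = rng.normal(1.0, 0.8, 10_000)
    y = x + rng.normal(0.0, 0.2, 10_000)
    return pairs_frame(
        list(zip([f"n{i}" for i in range(10_000)], 10.0**x, 10.0**y))
    )


class TestLog2FoldChanges:
    def test_statuses_and_values(self):
        fc = reg.log2_fold_changes(
            pairs_frame(
                [("a", 10, 40), ("b", 5, 5), ("c", 0, 7), ("d", 3, 0), ("e", 0, 0)]
            )
        )
        by = fc.set_index("transcript_id")
        assert by.loc["a", "log2_fc"] == pytest.approx(2.0)
        assert by.loc["b", "log2_fc"] == pytest.approx(0.0)
        assert by.loc["c", "status"] == "plus_infinite"
        assert by.loc["d", "status"] == "minus_infinite"
        assert by.loc["e", "status"] == "undefined"

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            reg.log2_fold_changes(pairs_frame([("a", -1, 2)]))


class TestPercentileCall:
    def test_sixteen_value_worked_example(self):
        """81.25th percentile of {0.1..1.6} is 1.31875; exactly the top
        three values (18.75 %) exceed it."""
        fc = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(16)],
                "log2_fc": [0.1 * (i + 1) for i in range(16)],
                "status": ["finite"] * 16,
            }
        )
        assert np.percentile(fc["log2_fc"], 81.25) == pytest.approx(1.31875)
        calls = reg.percentile_fc_call(fc)
        assert reg.up_set(calls) == {"t13", "t14", "t15"}
        assert reg.down_set(calls) == set()

    def test_all_zero_fold_changes_yield_no_calls(self):
        fc = reg.log2_fold_changes(
            pairs_frame([(f"t{i}", 5.0, 5.0) for i in range(10)])
        )
        calls = reg.percentile_fc_call(fc)
        assert reg.up_set(calls) == set() and reg.down_set(calls) == set()

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(11)
        c = rng.lognormal(1, 1, 200)
        i = c * np.exp2(rng.normal(0, 1, 200))
        fwd = reg.percentile_fc_call(
            reg.log2_fold_changes(pairs_frame(list(zip(map(str, range(200)), c, i))))
        )
        rev = reg.percentile_fc_call(
            reg.log2_fold_changes(pairs_frame(list(zip(map(str, range(200)), i, c))))
        )
        assert reg.up_set(fwd) == reg.down_set(rev)
        assert reg.down_set(fwd) == reg.up_set(rev)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_called_fraction_near_18_75_percent(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        fc = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "log2_fc": rng.lognormal(0, 1, n),  # all positive
                "status": ["finite"] * n,
            }
        )
        n_up = len(reg.up_set(reg.percentile_fc_call(fc)))
        assert math.floor(0.1875 * n) - 1 <= n_up <= math.ceil(0.1875 * n) + 1

    def test_monotonicity_of_up_calls(self):
        rng = np.random.default_rng(3)
        c = rng.lognormal(1, 1, 100)
        i = c * np.exp2(rng.normal(0, 1, 100))
        table = pairs_frame(list(zip([f"t{k}" for k in range(100)], c, i)))
        ups = reg.up_set(reg.percentile_fc_call(reg.log2_fold_changes(table)))
        assert ups
        target = sorted(ups)[0]
        boosted = table.copy()
        boosted.loc[boosted.transcript_id == target, "infected"] *= 10
        ups2 = reg.up_set(reg.percentile_fc_call(reg.log2_fold_changes(boosted)))
        assert target in ups2

    def test_infinite_records_flagged_not_called(self):
        fc = reg.log2_fold_changes(
            pairs_frame([("a", 0, 7), ("b", 1, 2), ("c", 2, 1), ("d", 1, 8)])
        )
        calls = reg.percentile_fc_call(fc)
        a = next(c for c in calls if c.transcript_id == "a")
        assert a.verdict == "none" and "plus_infinite" in a.flags


class TestInfectionSpecific:
    def test_flags(self):
        out = reg.infection_specific(
            pairs_frame([("a", 0, 12.4), ("b", 0, 0), ("c", 3, 0), ("d", 1, 1)])
        ).set_index("transcript_id")["flag"]
        assert out["a"] == "infection_specific"
        assert out["b"] == ""
        assert out["c"] == "lost_on_infection"
        assert out["d"] == ""


class TestEnvelopeCall:
    def test_pure_diagonal_yields_no_calls(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(1, 1, 200)
        table = pairs_frame(list(zip(map(str, range(200)), v, v)))
        calls = reg.envelope_call(table, reg.EnvelopeConfig(n_bins=5))
        assert reg.up_set(calls) == set() and reg.down_set(calls) == set()

    def test_planted_outlier_called_up(self, null_cloud):
        planted = pd.concat(
            [
                null_cloud,
                pairs_frame([("planted", 10.0, 10.0 * 1000)]),  # y = x + 3 in log10
            ],
            ignore_index=True,
        )
        calls = reg.envelope_call(planted, reg.EnvelopeConfig(n_bins=20, cutoff_percent=2))
        assert "planted" in reg.up_set(calls)

    def test_scale_invariance(self, null_cloud):
        scaled = null_cloud.copy()
        scaled[["control", "infected"]] *= 10.0
        a = reg.envelope_call(null_cloud)
        b = reg.envelope_call(scaled)
        assert reg.up_set(a) == reg.up_set(b)
        assert reg.down_set(a) == reg.down_set(b)

    def test_swap_symmetry(self, null_cloud):
        swapped = null_cloud.rename(
            columns={"control": "infected", "infected": "control"}
        )
        a = reg.envelope_call(null_cloud)
        b = reg.envelope_call(swapped)
        assert reg.up_set(a) == reg.down_set(b)


class TestBandCall:
    def test_null_cloud_tail_fraction(self, null_cloud):
        """The threshold line is built from local 99th percentiles, so a
        null cloud should yield roughly 1 % up calls."""
        frac = len(reg.up_set(reg.band_call(null_cloud))) / len(null_cloud)
        assert 0.005 <= frac <= 0.02

    def test_planted_outliers_recovered(self, null_cloud):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 0.8, 20)
        extra = pairs_frame(
            [(f"p{i}", 10.0 ** x[i], 10.0 ** (x[i] + 2)) for i in range(20)]
        )
        table = pd.concat([null_cloud, extra], ignore_index=True)
        ups = reg.up_set(reg.band_call(table))
        assert sum(f"p{i}" in ups for i in range(20)) >= 19

    def test_scale_invariance(self, null_cloud):
        scaled = null_cloud.copy()
        scaled[["control", "infected"]] *= 10.0
        assert reg.up_set(reg.band_call(null_cloud)) == reg.up_set(reg.band_call(scaled))

    def test_swap_symmetry(self, null_cloud):
        swapped = null_cloud.rename(
            columns={"control": "infected", "infected": "control"}
        )
        a = reg.band_call(null_cloud)
        b = reg.band_call(swapped)
        assert reg.up_set(a) == reg.down_set(b)


class TestOutlierDistance:
    line = ((0.0, 0.0), (1.0, 1.0))  # y = x

    def test_point_on_line_is_zero(self):
        assert reg.outlier_distance((0.5, 0.5), self.line) == pytest.approx(0.0)

    def test_unit_point_above_diagonal(self):
        assert reg.outlier_distance((0.0, 1.0), self.line) == pytest.approx(
            math.sqrt(2) / 2
        )

    def test_reflection_negates_sign(self):
        d1 = reg.outlier_distance((0.0, 1.0), self.line)
        d2 = reg.outlier_distance((1.0, 0.0), self.line)
        assert d1 == pytest.approx(-d2)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            reg.outlier_distance((0, 0), ((1, 1), (1, 1)))


class TestLegacyOligo:
    def _matrix(self, rows):
        return pd.DataFrame(rows)

    def test_eligibility_ten_of_fourteen(self):
        ratios = [1.05] * 10 + [1.0] * 4
        m = pd.DataFrame([ratios, [1.05] * 9 + [1.0] * 5], index=["eligible", "not"])
        calls = reg.legacy_oligo_call(m)
        by = {c.transcript_id: c for c in calls}
        assert "ineligible" not in by["eligible"].flags
        assert "ineligible" in by["not"].flags

    def test_top_18_75_percent_of_32_is_6(self):
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(32):
            med = 1.0 + (i + 1) * 0.01
            rows[f"g{i}"] = [med] * 14
        m = pd.DataFrame.from_dict(rows, orient="index")
        calls = reg.legacy_oligo_call(m)
        ups = reg.up_set(calls)
        assert len(ups) == 6
        assert ups == {f"g{i}" for i in range(26, 32)}

    def test_wrong_array_count_rejected_unless_overridden(self):
        m = pd.DataFrame({"g1": [1.05] * 10}).T
        with pytest.raises(ValueError):
            reg.legacy_oligo_call(m)
        calls = reg.legacy_oligo_call(m, min_arrays=8, allow_any_array_count=True)
        assert calls


class TestLegacyCdna:
    def test_detected_in_both_uses_mean_fold_change(self):
        i_set = pairs_frame([("g", 50, 60)])     # FC 1.2
        ii_set = pairs_frame([("g", 45, 90)])    # FC 2.0
        calls = reg.legacy_cdna_call(i_set, ii_set)
        g = next(c for c in calls if c.transcript_id == "g")
        assert g.score == pytest.approx(math.log2((60 / 50 + 90 / 45) / 2))

    def test_detected_in_one_uses_that_fold_change(self):
        i_set = pairs_frame([("g", 50, 100)])    # detected, FC 2
        ii_set = pairs_frame([("g", 10, 20)])    # below 40 PSL
        calls = reg.legacy_cdna_call(i_set, ii_set)
        g = next(c for c in calls if c.transcript_id == "g")
        assert g.score == pytest.approx(1.0)

    def test_undetected_in_both_excluded_from_base_set(self):
        i_set = pairs_frame([("g", 10, 20), ("h", 100, 200)])
        ii_set = pairs_frame([("g", 5, 30), ("h", 90, 150)])
        calls = reg.legacy_cdna_call(i_set, ii_set)
        assert {c.transcript_id for c in calls} == {"h"}


class TestLowExpressionFalsePositives:
    def test_geometric_callers_beat_percentile_in_lowest_decile(self):
        """With planted 4-fold induction and noise that inflates at low
        expression, the geometric callers (rate-matched to the percentile
        caller's call count) put a smaller fraction of their calls on
        low-expression false positives."""
        table, labels = simulate.simulate_expression(
            simulate.ExpressionSimConfig(seed=17)
        )
        pos = table[table.control > 0]
        low = set(
            pos.loc[pos.control < np.quantile(pos.control, 0.1), "transcript_id"]
        )
        null = set(labels[labels != "up"].index)
        pct = reg.percentile_fc_call(reg.log2_fold_changes(table))
        n_target = len(reg.up_set(pct))

        def fp_low(calls):
            s = reg.up_set(calls)
            return len(s & null & low) / len(s)

        env = _match_envelope(pos, n_target)
        band = _match_band(pos, n_target)
        assert fp_low(env) < fp_low(pct)
        assert fp_low(band) < fp_low(pct)


def _match_envelope(pos, target):
    lo, hi = 0.5, 49.0
    for _ in range(16):
        mid = (lo + hi) / 2
        n = len(reg.up_set(reg.envelope_call(pos, reg.EnvelopeConfig(cutoff_percent=mid))))
        lo, hi = (mid, hi) if n < target else (lo, mid)
    return reg.envelope_call(pos, reg.EnvelopeConfig(cutoff_percent=(lo + hi) / 2))


def _match_band(pos, target):
    lo, hi = 50.0, 99.9
    for _ in range(16):
        mid = (lo + hi) / 2
        n = len(reg.up_set(reg.band_call(pos, reg.BandConfig(tail_percentile=mid))))
        lo, hi = (mid, hi) if n > target else (lo, mid)
    return reg.band_call(pos, reg.BandConfig(tail_percentile=(lo + hi) / 2))
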