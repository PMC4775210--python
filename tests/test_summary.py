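"""Study-level aggregation: two-level means, layers, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatmap import (capillary_summary, classify_layer, frequency_distribution,
                    pooled_vs_capillary_means, spearman, stratify_low_po2,
                    study_report, summarize_capillaries)
from eatmap.exceptions import EatmapError, InvariantError
from eatmap.summary import QUANTITIES


def make_results(groups: dict, **extra) -> pd.DataFrame:
    """Minimal results table: {capillary: [po2_inter values]}; other
    quantities filled with copies unless overridden via extra."""
    rows = []
    for cap, values in groups.items():
        for i, v in enumerate(values):
            row = {q: float(v) for q in QUANTITIES}
            row.update(measurement_id=f"{cap}_m{i}", capillary_id=cap,
                       region="cortex", depth_um=100.0, session_id="s")
            for key, per_cap in extra.items():
                row[key] = per_cap[cap]
            rows.append(row)
    return pd.DataFrame(rows)


class TestCapillarySummary:
    def test_hand_arithmetic(self):
        df = make_results({"c1": [20, 22, 24]})
        s = capillary_summary(df)
        assert s.means["po2_inter_rbc"] == pytest.approx(22.0)
        assert s.sds["po2_inter_rbc"] == pytest.approx(2.0)
        assert s.n_measurements == 3

    def test_single_measurement_sd_flagged(self):
        s = capillary_summary(make_results({"c1": [20]}))
        assert np.isnan(s.sds["po2_inter_rbc"])

    def test_empty_input_rejected(self):
        with pytest.raises(EatmapError):
            capillary_summary(make_results({}))

    def test_mean_of_sds_recovers_injected_noise(self):
        """Within-capillary scatter with SD 2.6 shows up as a mean
        per-capillary SD near 2.6."""
        rng = np.random.default_rng(8)
        groups = {f"c{i}": list(rng.normal(25, 2.6, 8)) for i in range(40)}
        caps = summarize_capillaries(make_results(groups))
        assert caps["po2_inter_rbc_sd"].mean() == pytest.approx(2.6, abs=0.5)


class TestPooledVsCapillaryMeans:
    def test_balanced_design_identity(self):
        rng = np.random.default_rng(3)
        groups = {f"c{i}": list(rng.uniform(10, 40, 5)) for i in range(6)}
        out = pooled_vs_capillary_means(make_results(groups))
        assert out["pooled_mean"]["po2_inter_rbc"] == pytest.approx(
            out["capillary_mean"]["po2_inter_rbc"], abs=1e-12)

    def test_unbalanced_toy(self):
        out = pooled_vs_capillary_means(
            make_results({"capA": [10, 10, 10, 10], "capB": [20]}))
        assert out["pooled_mean"]["po2_inter_rbc"] == pytest.approx(12.0)
        assert out["capillary_mean"]["po2_inter_rbc"] == pytest.approx(15.0)

    def test_mildly_unbalanced_study_levels_agree(self):
        """With 4-8 measurements per capillary the pooled and capillary-
        level means differ by well under 1 mm Hg."""
        rng = np.random.default_rng(10)
        groups = {f"c{i}": list(rng.normal(rng.uniform(15, 35), 2.6,
                                           rng.integers(4, 9)))
                  for i in range(38)}
        out = pooled_vs_capillary_means(make_results(groups))
        assert abs(out["pooled_mean"]["po2_inter_rbc"]
                   - out["capillary_mean"]["po2_inter_rbc"]) < 1.0


class TestClassifyLayer:
    @pytest.mark.parametrize("depth,layer", [
        (0, "I"), (50, "I"), (59.9, "I"),
        (60, "unclassified"), (75, "unclassified"), (89.9, "unclassified"),
        (90, "II/III"), (150, "II/III"), (260, "II/III"),
        (260.1, "unclassified"), (300, "unclassified"), (340, "unclassified"),
        (340.1, "IV"), (410, "IV"),
    ])
    def test_depth_rules(self, depth, layer):
        assert classify_layer(depth) == layer

    def test_total_function_on_grid(self):
        """Exhaustive grid: exactly one of the four labels everywhere."""
        grid = np.arange(0, 500.25, 0.25)
        labels = classify_layer(grid)
        assert set(np.unique(labels)) <= {"I", "II/III", "IV", "unclassified"}
        # band edges
        assert classify_layer(59.75) == "I" and classify_layer(60.0) != "I"
        assert classify_layer(340.0) != "IV" and classify_layer(340.25) == "IV"

    def test_negative_depth_rejected(self):
        with pytest.raises(InvariantError):
            classify_layer(-1.0)


def rank_then_pearson(x, y):
    """Independent oracle: explicit mid-rank assignment by sorting, then
    the textbook Pearson formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_example_matches_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert spearman(x, y) == pytest.approx(rank_then_pearson(x, y),
                                               abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=3, max_size=30))
    def test_matches_oracle_with_ties(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = rng.integers(0, 5, len(xs)).tolist()
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return  # correlation undefined
        assert spearman(xs, ys) == pytest.approx(rank_then_pearson(xs, ys),
                                                 abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(InvariantError):
            spearman([1, 2], [1, 2])
        with pytest.raises(InvariantError):
            spearman([1, 2, 3], [1, 2])


class TestFrequencyDistribution:
    def test_hand_binning(self):
        out = frequency_distribution([2, 5, 7], bin_width=5)
        assert list(out["bin_left"]) == [0.0, 5.0]
        assert list(out["count"]) == [1, 2]

    def test_empty_input(self):
        assert len(frequency_distribution([])) == 0

    def test_counts_conserved_and_translation_consistent(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 80, 500)
        w = 5.0
        out = frequency_distribution(vals, w)
        assert out["count"].sum() == 500
        shifted = frequency_distribution(vals + w, w)
        assert list(shifted["count"]) == list(out["count"])
        assert shifted["bin_left"].iloc[0] == out["bin_left"].iloc[0] + w


class TestStratifyLowPo2:
    def _caps(self, inter_means, hcts):
        df = make_results({f"c{i}": [v] * 2 for i, v in enumerate(inter_means)})
        for i, h in enumerate(hcts):
            df.loc[df.capillary_id == f"c{i}", "hematocrit"] = h
        return summarize_capillaries(df)

    def test_all_above_threshold(self):
        out = stratify_low_po2(self._caps([20, 30], [40, 40]))
        assert out["low"]["n"] == 0 and out["rest"]["n"] == 2

    def test_toy_split(self):
        out = stratify_low_po2(self._caps([10, 20], [30, 40]))
        assert out["low"]["n"] == 1 and out["rest"]["n"] == 1

    def test_planted_low_hematocrit_structure_recovered(self):
        """Capillaries planted with low interstitial Po2 AND low hematocrit
        come back as a low group with lower mean hematocrit."""
        rng = np.random.default_rng(12)
        inter = list(rng.uniform(5, 12, 5)) + list(rng.uniform(20, 35, 15))
        hct = list(rng.uniform(10, 24, 5)) + list(rng.uniform(30, 50, 15))
        out = stratify_low_po2(self._caps(inter, hct))
        assert out["low"]["n"] == 5
        assert out["low"]["hematocrit_mean"] < out["rest"]["hematocrit_mean"]


def test_study_report_is_json_serializable():
    import json
    rng = np.random.default_rng(5)
    groups = {f"c{i}": list(rng.normal(25, 3, 4)) for i in range(5)}
    report = study_report(make_results(groups))
    json.dumps(report)
    assert report["n_capillaries"] == 5
    assert "po2_inter_rbc" in report["two_level_means"]
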