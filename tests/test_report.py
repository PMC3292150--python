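import numpy as np
import pandas as pd
import pytest

from emgfatigue.core import FatigueClass, FeatureSeries, LabelSeries, ValidationError
from emgfatigue.report import (
    ConfusionMatrix,
    dbi,
    dbi_canonical,
    dbi_window_sweep,
    improvements,
    rates,
    round_half_up,
    summarize,
)

NF, TF, F = FatigueClass


def dbi_bruteforce(cluster_a, cluster_b):
    """Explicit-loop reimplementation of the two-cluster index."""
    total_sd = 0.0
    centroids = []
    for members in (cluster_a, cluster_b):
        members = [np.atleast_1d(np.asarray(m, dtype=float)) for m in members]
        dim = members[0].size
        centroid = [sum(m[j] for m in members) / len(members) for j in range(dim)]
        centroids.append(np.array(centroid))
        dists = [np.sqrt(sum((m[j] - centroid[j]) ** 2 for j in range(dim)))
                 for m in members]
        if len(dists) > 1:
            mean_d = sum(dists) / len(dists)
            var = sum((d - mean_d) ** 2 for d in dists) / (len(dists) - 1)
            total_sd += np.sqrt(var)
    sep = np.sqrt(sum((centroids[0][j] - centroids[1][j]) ** 2
                      for j in range(centroids[0].size)))
    return total_sd / sep


class TestRoundHalfUp:
    @pytest.mark.parametrize("x,expected", [
        (0.005, 0.01), (2.675, 2.68), (20.585, 20.59), (-0.005, -0.01),
        (81.583, 81.58), (5.3201, 5.32),
    ])
    def test_values(self, x, expected):
        assert round_half_up(x) == expected


class TestRates:
    def test_reference_matrix(self):
        rs = rates(ConfusionMatrix(16, 1, 8, 11))
        assert round_half_up(rs.tp) == 0.58
        assert round_half_up(rs.fn) == 0.42
        assert rs.tp == pytest.approx(11 / 19)
        assert rs.fn == pytest.approx(8 / 19)

    def test_perfect_classifier(self):
        rs = rates(ConfusionMatrix(10, 0, 0, 10))
        assert (rs.tp, rs.tn, rs.precision, rs.accuracy) == (1.0, 1.0, 1.0, 1.0)
        assert (rs.fp, rs.fn) == (0.0, 0.0)

    def test_complementary_pairs(self):
        rs = rates(ConfusionMatrix(7, 3, 2, 8))
        assert rs.tp + rs.fn == pytest.approx(1.0)
        assert rs.fp + rs.tn == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        rs = rates(ConfusionMatrix(5, 2, 0, 0))
        assert rs.tp is None and rs.fn is None
        assert rs.tn is not None

    def test_recomposition(self):
        cm = ConfusionMatrix(16, 1, 8, 11)
        rs = rates(cm)
        assert rs.tp * (cm.c + cm.d) == pytest.approx(cm.d)
        assert rs.fp * (cm.a + cm.b) == pytest.approx(cm.b)
        assert rs.fn * (cm.c + cm.d) == pytest.approx(cm.c)
        assert rs.tn * (cm.a + cm.b) == pytest.approx(cm.a)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(-1, 0, 0, 1)

    def test_empty_matrix(self):
        with pytest.raises(ValidationError, match="empty"):
            rates(ConfusionMatrix(0, 0, 0, 0))


class TestDbi:
    def test_zero_spread(self):
        assert dbi([[0.0, 0.0], [5.0, 5.0]]) == 0.0

    def test_hand_case(self):
        value = dbi([[0.0, 1.0, 2.0], [10.0, 12.0]])
        expected = np.std([1.0, 0.0, 1.0], ddof=1) / 10.0
        assert value == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance(self):
        a = [0.0, 1.0, 2.0]
        b = [10.0, 12.0]
        shifted = dbi([[v + 37.5 for v in a], [v + 37.5 for v in b]])
        assert shifted == pytest.approx(dbi([a, b]), abs=1e-12)

    def test_coincident_centroids(self):
        with pytest.raises(ValidationError, match="coincident"):
            dbi([[1.0, -1.0], [0.5, -0.5]])

    def test_requires_two_clusters(self):
        with pytest.raises(ValidationError):
            dbi([[1.0, 2.0]])
        with pytest.raises(ValidationError, match="two clusters"):
            dbi([[1.0], [2.0], [3.0]])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dim = rng.integers(1, 4)
            n_a = int(rng.integers(2, 50))
            n_b = int(rng.integers(2, 50))
            a = rng.normal(size=(n_a, dim))
            b = rng.normal(loc=3.0, size=(n_b, dim))
            assert dbi([a, b]) == pytest.approx(
                dbi_bruteforce(list(a), list(b)), abs=1e-12)

    def test_canonical_variant(self):
        rng = np.random.default_rng(1)
        tight = [rng.normal(0, 0.1, size=(30, 2)),
                 rng.normal(8, 0.1, size=(30, 2))]
        loose = [rng.normal(0, 3.0, size=(30, 2)),
                 rng.normal(8, 3.0, size=(30, 2))]
        assert dbi_canonical(tight) < dbi_canonical(loose)


class TestDbiWindowSweep:
    @pytest.fixture()
    def unified_and_labels(self):
        rng = np.random.default_rng(3)
        n = 40
        values = np.concatenate([rng.normal(0, 0.3, 20), rng.normal(0, 2.0, 20)])
        unified = FeatureSeries("spectro_1d", np.arange(n, dtype=float), values)
        labels = LabelSeries(labels=[NF] * 20 + [TF] * 20)
        return unified, labels

    def test_span_keys(self, unified_and_labels):
        unified, labels = unified_and_labels
        sweep = dbi_window_sweep(unified, labels, (NF, TF))
        assert set(sweep) == {1, 2, 3, 4, 5}

    def test_span_one_uses_raw_values(self, unified_and_labels):
        unified, labels = unified_and_labels
        sweep = dbi_window_sweep(unified, labels, (NF, TF), spans=(1,))
        direct = dbi([unified.values[:20], unified.values[20:]])
        assert sweep[1] == pytest.approx(direct, abs=1e-12)

    def test_missing_class_error(self, unified_and_labels):
        unified, _ = unified_and_labels
        labels = LabelSeries(labels=[NF] * 40)
        with pytest.raises(ValidationError, match="no seconds"):
            dbi_window_sweep(unified, labels, (NF, TF))


REFERENCE_NF_TF = {
    "spectro_std": [82.1, 86.27, 82.55, 75.69, 84, 86.84, 75.88, 80.71,
                    88.93, 72.86],
    "imdf_std3": [53.2, 50.32, 54.71, 49.79, 55.77, 51.52, 60.36, 51.4,
                  55.47, 55.71],
    "bandpower_std3": [73.31, 62.4, 59.49, 55.94, 67.53, 59.14, 57.67,
                       72.22, 64.88, 62.94],
    "fi2_std3": [62.95, 51.75, 55.55, 63.02, 53.35, 57.38, 63.11, 60.46,
                 65.09, 52.44],
    "wavelet_db3_std3": [74.43, 61.33, 62.61, 54.82, 75.93, 71.46, 74.39,
                         72.24, 61.36, 72.33],
}
REFERENCE_TF_F = {
    "spectro_std": [53.75, 80.86, 79.13, 35.62, 70.09, 57.88, 85.88, 69.89,
                    64.06, 68.75],
    "imdf_std3": [53.35, 57.5, 54.17, 59.8, 48.4, 56.94, 55.44, 51.24,
                  65.66, 58.33],
    "bandpower_std3": [54.01, 45.41, 54.56, 57.84, 59.29, 50.69, 60.55,
                       53.9, 61.74, 66.41],
    "fi2_std3": [58.53, 58.82, 54.37, 53.92, 64.15, 79.17, 68.77, 64.82,
                 60.63, 46.28],
    "wavelet_db3_std3": [58.33, 61.62, 73.25, 50.88, 67.19, 59.42, 68.08,
                         52.77, 57.16, 54.27],
}


class TestSummarize:
    def test_reference_nf_tf_column(self):
        rep = summarize(pd.DataFrame(REFERENCE_NF_TF))
        assert rep.rounded_mean("spectro_std") == 81.58
        assert rep.rounded_sd("spectro_std") == 5.32
        assert rep.rounded_mean("wavelet_db3_std3") == 68.09

    def test_reference_tf_f_column(self):
        rep = summarize(pd.DataFrame(REFERENCE_TF_F))
        assert rep.rounded_mean("spectro_std") == 66.59
        assert rep.rounded_sd("spectro_std") == 14.78
        assert rep.rounded_mean("fi2_std3") == 60.95

    def test_constant_column_sd_zero(self):
        rep = summarize(pd.DataFrame({"a": [50.0, 50.0, 50.0],
                                      "b": [1.0, 2.0, 3.0]}))
        assert rep.rounded_sd("a") == 0.0

    def test_display_rows(self):
        rep = summarize(pd.DataFrame(REFERENCE_NF_TF))
        assert list(rep.display.index[-2:]) == ["AVG", "STDEV"]

    def test_needs_two_subjects(self):
        with pytest.raises(ValidationError, match="two subjects"):
            summarize(pd.DataFrame({"a": [1.0]}))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.uniform(40, 95, size=(10, 4)),
                             columns=list("abcd"))
        rep = summarize(table)
        for col in table.columns:
            vals = table[col].to_numpy()
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            assert rep.means[col] == pytest.approx(mean, abs=1e-12)
            assert rep.sds[col] == pytest.approx(np.sqrt(var), abs=1e-12)


class TestImprovements:
    def test_reference_deltas(self):
        imp = improvements(summarize(pd.DataFrame(REFERENCE_NF_TF)))
        assert imp["wavelet_db3_std3"]["delta"] == 13.49
        assert imp["average_of_others"]["delta"] == 20.58
        imp5 = improvements(summarize(pd.DataFrame(REFERENCE_TF_F)))
        assert imp5["fi2_std3"]["delta"] == 5.64

    def test_significance_reported(self):
        imp = improvements(summarize(pd.DataFrame(REFERENCE_NF_TF)))
        assert imp["imdf_std3"]["p_value"] < 0.01
        assert "t-test" in imp["imdf_std3"]["test"]

    def test_identical_columns(self):
        table = pd.DataFrame({"spectro_std": [60.0, 70.0, 80.0],
                              "other": [60.0, 70.0, 80.0]})
        imp = improvements(summarize(table))
        assert imp["other"]["delta"] == 0.0
        assert np.isnan(imp["other"]["p_value"])

    def test_missing_reference(self):
        with pytest.raises(ValidationError, match="reference"):
            improvements(summarize(pd.DataFrame(REFERENCE_NF_TF)),
                         reference_feature="nope")
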