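"""AUC, bootstrap, IDI, BI-RADS binning and NRI."""

import numpy as np
import pytest

from threecb import (
    BiradsBins,
    RiskPair,
    assign_birads_category,
    binary_nri_at_threshold,
    bootstrap_auc_ci,
    categorical_nri,
    idi_components,
    roc_auc,
)
from threecb.exceptions import InputError, UndefinedMetricError

#: Representative probability for each BI-RADS category (mid-bin).
CAT_PROBS = {"3": 0.01, "4a": 0.05, "4b": 0.30, "4c&5": 0.70}


def pair_counting_auc(labels, scores):
    """Exhaustive pair-counting oracle: P(score_pos > score_neg) + ties/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def pair_from_tables(events_cells, nonevents_cells):
    """RiskPair realizing given (reference row x new column) count tables."""
    labels, p_ref, p_new = [], [], []
    cats = list(CAT_PROBS)
    for label, cells in ((1, events_cells), (0, nonevents_cells)):
        for i, row in enumerate(cells):
            for j, count in enumerate(row):
                labels += [label] * count
                p_ref += [CAT_PROBS[cats[i]]] * count
                p_new += [CAT_PROBS[cats[j]]] * count
    return RiskPair(np.array(labels), np.array(p_ref), np.array(p_new))


class TestRocAuc:
    def test_known_values(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc([0, 0, 1, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pair_counting_oracle_on_fuzzed_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid to force ties
            assert roc_auc(labels, scores) == pytest.approx(
                pair_counting_auc(labels, scores), abs=1e-12
            )


class TestBootstrap:
    def test_perfect_separation_collapses_interval(self):
        labels = np.r_[np.zeros(20), np.ones(20)]
        scores = np.r_[np.linspace(0, 0.4, 20), np.linspace(0.6, 1, 20)]
        mean, lo, hi = bootstrap_auc_ci(labels, scores, n_boot=50, seed=0)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert lo == pytest.approx(1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_single_resample_interval_collapses(self):
        labels = np.r_[np.zeros(10), np.ones(10)]
        rng = np.random.default_rng(0)
        scores = rng.random(20)
        mean, lo, hi = bootstrap_auc_ci(labels, scores, n_boot=1, seed=1)
        assert mean == lo == hi

    def test_patient_level_resampling_requires_ids(self):
        labels = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(InputError):
            bootstrap_auc_ci(labels, np.linspace(0, 1, 20), patient_level=True)


class TestIdi:
    def test_reported_decomposition_sums_exactly(self):
        """IS of -1.06 and IP of 13.17 combine to an IDI of 12.11 points."""
        pair = RiskPair(
            labels=np.array([1, 1, 0, 0]),
            p_ref=np.array([0.60, 0.80, 0.4000, 0.6000]),
            p_new=np.array([0.5894, 0.7894, 0.2683, 0.4683]),
        )
        is_, ip, idi = idi_components(pair)
        assert is_ == pytest.approx(-1.06, abs=1e-9)
        assert ip == pytest.approx(13.17, abs=1e-9)
        assert idi == pytest.approx(12.11, abs=1e-9)

    def test_identity_models_give_zero(self):
        p = np.array([0.1, 0.4, 0.6, 0.9])
        pair = RiskPair(np.array([0, 0, 1, 1]), p, p.copy())
        assert idi_components(pair) == (0.0, 0.0, 0.0)

    def test_direct_mean_arithmetic(self):
        pair = RiskPair(
            labels=np.array([1, 1, 0]),
            p_ref=np.array([0.6, 0.8, 0.4]),
            p_new=np.array([0.7, 0.9, 0.2]),
        )
        is_, ip, idi = idi_components(pair)
        assert (is_, ip, idi) == pytest.approx((10.0, 20.0, 30.0))

    def test_antisymmetry_under_model_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = 30
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            a, b = rng.random(n), rng.random(n)
            fwd = idi_components(RiskPair(labels, a, b))
            rev = idi_components(RiskPair(labels, b, a))
            assert fwd == pytest.approx(tuple(-x for x in rev), abs=1e-9)


class TestBiradsBinning:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, "3"), (0.02, "3"), (0.021, "4a"), (0.10, "4a"),
         (0.3, "4b"), (0.50, "4b"), (0.51, "4c&5"), (1.0, "4c&5")],
    )
    def test_upper_inclusive_bins(self, p, expected):
        assert assign_birads_category(p) == expected

    def test_bins_validate(self):
        with pytest.raises(InputError):
            BiradsBins(borders=(0.5, 0.1))


class TestCategoricalNri:
    # Events and non-events cross-tables of a reported diagnostic test set
    # (reference rows 3/4a/4b/4c&5 by new columns, same order).
    EVENTS = [[0, 0, 0, 1], [0, 0, 1, 0], [0, 0, 9, 8], [0, 0, 11, 20]]
    NONEVENTS = [[0, 0, 0, 0], [2, 2, 8, 3], [0, 6, 51, 9], [0, 5, 47, 13]]

    def test_reported_events_table_gives_minus_two_percent(self):
        """50 events with 10 upward and 11 downward moves: NRI_e = -0.02."""
        pair = pair_from_tables(self.EVENTS, self.NONEVENTS)
        report = categorical_nri(pair)
        assert report.events_table.to_numpy().tolist() == self.EVENTS
        assert report.nri_events == pytest.approx(-0.02, abs=1e-12)
        assert report.nri_nonevents == pytest.approx((60 - 20) / 146, abs=1e-12)
        assert report.nri_total == pytest.approx(
            report.nri_events + report.nri_nonevents, abs=1e-12
        )

    def test_table_margins_match_class_counts(self):
        pair = pair_from_tables(self.EVENTS, self.NONEVENTS)
        report = categorical_nri(pair)
        assert report.events_table.to_numpy().sum() == (pair.labels == 1).sum() == 50
        assert report.nonevents_table.to_numpy().sum() == (pair.labels == 0).sum() == 146

    def test_identity_models_concentrate_on_diagonal(self):
        rng = np.random.default_rng(2)
        p = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        report = categorical_nri(RiskPair(labels, p, p.copy()))
        for table in (report.events_table, report.nonevents_table):
            arr = table.to_numpy()
            assert arr.sum() == np.trace(arr)
        assert report.nri_events == report.nri_nonevents == 0.0

    def test_two_category_count_arithmetic(self):
        # 4 events: 3 move up across 0.5, 1 moves down
        labels = np.ones(4, int)
        p_ref = np.array([0.3, 0.3, 0.3, 0.7])
        p_new = np.array([0.7, 0.7, 0.7, 0.3])
        pair = RiskPair(np.r_[labels, [0]], np.r_[p_ref, [0.3]], np.r_[p_new, [0.3]])
        nri_e, _, _ = binary_nri_at_threshold(pair, 0.5)
        assert nri_e == pytest.approx(0.5)


class TestBinaryNri:
    def test_identity_gives_zero(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert binary_nri_at_threshold(RiskPair(labels, p, p.copy()), 0.1) == (0, 0, 0)

    def test_single_event_crossing_up_among_fifty(self):
        labels = np.r_[np.ones(50, int), np.zeros(10, int)]
        p_ref = np.full(60, 0.4)
        p_new = p_ref.copy()
        p_new[0] = 0.6
        nri_e, nri_n, total = binary_nri_at_threshold(
            RiskPair(labels, p_ref, p_new), 0.5
        )
        assert nri_e == pytest.approx(0.02)
        assert nri_n == 0.0 and total == pytest.approx(0.02)

    def test_degenerate_zero_threshold(self):
        labels = np.array([0, 1, 0, 1])
        p = np.array([0.2, 0.4, 0.6, 0.8])
        assert binary_nri_at_threshold(RiskPair(labels, p, p * 0.5), 0.0) == (0, 0, 0)

    def test_two_bin_categorical_equals_binary_at_shared_border(self):
        """Oracle equivalence on fuzzed inputs."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            t = float(rng.uniform(0.1, 0.9))
            pair = RiskPair(labels, rng.random(n), rng.random(n))
            bins = BiradsBins(upper_edges=(t, 1.0), labels=("lo", "hi"),
                              borders=(t,))
            report = categorical_nri(pair, bins)
            nri_e, nri_n, _ = binary_nri_at_threshold(pair, t)
            assert report.nri_events == pytest.approx(nri_e, abs=1e-12)
            assert report.nri_nonevents == pytest.approx(nri_n, abs=1e-12)

    def test_nri_components_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = 25
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            pair = RiskPair(labels, rng.random(n), rng.random(n))
            report = categorical_nri(pair)
            assert -1.0 <= report.nri_events <= 1.0
            assert -1.0 <= report.nri_nonevents <= 1.0
            assert -100.0 <= report.idi <= 100.0
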