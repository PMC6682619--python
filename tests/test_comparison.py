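"""Scaling, subtraction heatmaps, correlation and concordance statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thromboquant.comparison import (
    InvalidInputError,
    PairingError,
    PhenotypeAnnotation,
    ScaleAnchors,
    build_delta_matrix,
    compute_anchors,
    concordance_table,
    correlation_matrix,
    delta_heatmap_row,
    kendall_tau_b,
    rank_and_cluster,
    scale_univariate,
    wildtype_cv,
)
from thromboquant.parameters import StrainSummary


def brute_tau_b(x, y):
    """Independent tau-b oracle: explicit pair counting with tie terms."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom else float("nan")


def _summary(strain, db, genotype, mean, sd, n=4, surface="M1"):
    return StrainSummary(
        strain_id=strain, database_id=db, genotype_class=genotype,
        surface=surface, mean=dict(mean), sd=dict(sd),
        n={p: n for p in mean}, n_experiments=n,
    )


class TestScaling:
    def test_observed_max_maps_to_ten(self):
        scaled, anchors = scale_univariate([93.67, 40.0, 0.0])
        assert scaled[0] == 10.0
        assert scaled[2] == 0.0
        assert anchors == ScaleAnchors(0.0, 93.67)

    def test_linear_midpoint(self):
        scaled, _ = scale_univariate([2.0, 4.0, 8.0])
        assert scaled[1] == 5.0

    def test_negative_values_rejected(self):
        with pytest.raises(InvalidInputError):
            scale_univariate([-1.0, 2.0])

    def test_degenerate_all_zero_column_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            scaled, _ = scale_univariate([0.0, 0.0])
        assert np.all(scaled == 0.0)

    def test_idempotent_with_recorded_anchors(self):
        scaled, anchors = scale_univariate([2.0, 4.0, 8.0])
        again, _ = scale_univariate(scaled, anchors=ScaleAnchors(0.0, 10.0))
        assert np.allclose(again, scaled)

    @given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=12))
    @settings(derandomize=True, max_examples=80)
    def test_bounded_and_monotone(self, values):
        scaled, _ = scale_univariate(values)
        assert np.all((scaled >= 0) & (scaled <= 10))
        order = np.argsort(values)
        assert np.all(np.diff(scaled[order]) >= -1e-12)


class TestDeltaHeatmap:
    def test_strain_against_itself_is_null(self):
        wt = _summary("wt", "01", "wildtype", {"P1": 40.0}, {"P1": 3.0})
        mod = _summary("m", "01", "modified", {"P1": 40.0}, {"P1": 3.0})
        anchors = {("M1", "P1"): ScaleAnchors(0.0, 50.0)}
        d, c, r = delta_heatmap_row(mod, wt, anchors)
        assert d["P1"] == 0.0 and not r["P1"]

    def test_planted_effect_recovered_and_flagged(self):
        from thromboquant.comparison import ScaleAnchors
        from thromboquant.parameters import summarize_strain
        from thromboquant.simulate import generate_strain_table

        truth = generate_strain_table(
            n_wildtype_sets=1, n_modified=1,
            planted_effects={"mod01": {"P1": -4.0}}, group_sd=0.5,
            n_per_group=4, seed=33,
        )
        wt = summarize_strain(truth.wildtype_records())
        mod = summarize_strain(truth.modified_records())
        anchors = {k: ScaleAnchors(*v) for k, v in truth.anchors.items()}
        dm = build_delta_matrix([mod], [wt], anchors=anchors)
        delta = dm.delta.loc["mod01", "M1:P1"]
        assert delta == pytest.approx(-4.0, abs=0.5)
        assert bool(dm.relevant.loc["mod01", "M1:P1"])

    def test_false_flag_rate_of_relevance_filter_under_null(self):
        # Monte-Carlo estimate of how often |delta| > composite SD under a
        # planted null: with n=4 per group the rate stays well below 0.35
        rng = np.random.default_rng(99)
        flagged = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(5.0, 1.0, size=4)
            b = rng.normal(5.0, 1.0, size=4)
            delta = a.mean() - b.mean()
            comp = math.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2)
            if abs(delta) > comp:
                flagged += 1
        assert flagged / reps <= 0.35

    def test_unmatched_database_id_raises(self):
        wt = _summary("wt", "02", "wildtype", {"P1": 40.0}, {"P1": 3.0})
        mod = _summary("m", "01", "modified", {"P1": 30.0}, {"P1": 3.0})
        with pytest.raises(PairingError):
            delta_heatmap_row(mod, wt, {("M1", "P1"): ScaleAnchors(0.0, 50.0)})

    def test_max_sd_mode_is_more_conservative(self):
        wt = _summary("wt", "01", "wildtype", {"P1": 40.0}, {"P1": 2.0})
        mod = _summary("m", "01", "modified", {"P1": 25.0}, {"P1": 6.0})
        anchors = {("M1", "P1"): ScaleAnchors(0.0, 50.0)}
        _, c_rms, _ = delta_heatmap_row(mod, wt, anchors, sd_mode="rms")
        _, c_max, _ = delta_heatmap_row(mod, wt, anchors, sd_mode="max")
        assert c_max["P1"] >= c_rms["P1"]


class TestKendall:
    def test_perfect_concordance_and_reversal(self):
        assert kendall_tau_b([1, 2, 3, 4], [1, 2, 3, 4]).tau == 1.0
        assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]).tau == -1.0

    def test_known_pair_count(self):
        # 8 concordant and 2 discordant of the 10 pairs
        res = kendall_tau_b([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.tau == pytest.approx(0.6)

    def test_all_tied_vector_gives_undefined_marker(self):
        res = kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.tau)

    @given(st.lists(st.integers(0, 5), min_size=3, max_size=8),
           st.data())
    @settings(derandomize=True, max_examples=120)
    def test_matches_brute_force_enumeration(self, x, data):
        y = data.draw(st.lists(st.integers(0, 5), min_size=len(x),
                               max_size=len(x)))
        expected = brute_tau_b(x, y)
        if math.isnan(expected) or len(set(x)) == 1 or len(set(y)) == 1:
            return
        assert kendall_tau_b(x, y).tau == pytest.approx(expected)

    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=8, unique=True))
    @settings(derandomize=True, max_examples=60)
    def test_invariant_under_monotone_transform(self, x):
        y = list(reversed(sorted(x)))
        t0 = kendall_tau_b(x, y).tau
        t1 = kendall_tau_b([math.exp(v / 50) for v in x], y).tau
        assert t0 == pytest.approx(t1)


class TestCorrelationMatrix:
    def test_monotone_transform_gives_unit_tau(self):
        df = pd.DataFrame({
            "P1": [1.0, 3.0, 2.0, 5.0, 4.0],
            "P2": [2.0, 6.0, 4.0, 10.0, 8.0],
            "P3": [5.0, 1.0, 4.0, 2.0, 3.0],
            "P4": [1.0, 2.0, 3.0, 4.0, 5.0],
            "P5": [2.0, 3.0, 1.0, 5.0, 4.0],
        })
        tau, pval = correlation_matrix(df)
        assert tau.loc["P1", "P2"] == pytest.approx(1.0)
        assert np.allclose(tau.values, tau.values.T)
        assert np.all(np.diag(tau.values) == 1.0)

    def test_independent_columns_have_small_tau(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(60, 5)),
                          columns=["P1", "P2", "P3", "P4", "P5"])
        tau, _ = correlation_matrix(df)
        off = tau.values[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.3)

    def test_insufficient_rows_rejected(self):
        df = pd.DataFrame({"P1": [1.0, 2.0], "P2": [2.0, 1.0],
                           "P3": [1.0, 2.0], "P4": [1.0, 2.0],
                           "P5": [1.0, 2.0]})
        with pytest.raises(Exception):
            correlation_matrix(df)


class TestWildtypeCV:
    def test_identical_means_zero_cv(self):
        df = pd.DataFrame({"P1": [40.0, 40.0, 40.0]})
        assert wildtype_cv(df)["P1"] == 0.0

    def test_closed_form(self):
        df = pd.DataFrame({"P1": [10.0, 20.0, 30.0]})
        assert wildtype_cv(df)["P1"] == pytest.approx(50.0)

    def test_recovers_generated_dispersion(self):
        from thromboquant.parameters import summarize_strain
        from thromboquant.simulate import generate_strain_table

        truth = generate_strain_table(n_wildtype_sets=22, n_modified=0,
                                      wildtype_baseline_cv=20.0, seed=8)
        groups = {}
        for r in truth.wildtype_records():
            groups.setdefault(r.strain_id, []).append(r)
        means = pd.DataFrame({
            s: summarize_strain(rs).mean for s, rs in groups.items()
        }).T
        cv = wildtype_cv(means)
        assert cv["P1"] == pytest.approx(20.0, abs=6.0)


class TestRankAndCluster:
    def _matrix(self, rows):
        cols = ["M1:P1", "M1:P2", "M1:P3", "M1:P4", "M1:P5"]
        return pd.DataFrame(rows).T.set_axis(cols, axis=1)

    def test_signature_ranking_ascending(self):
        m = pd.DataFrame(
            {"M1:P2": [-2.0, 1.0], "M1:P3": [-1.0, 0.5],
             "M1:P4": [-1.0, 0.25], "M1:P5": [-1.0, 0.25]},
            index=["deep", "up"])
        assert rank_and_cluster(m, "signature") == ["deep", "up"]

    def test_tie_broken_alphabetically(self):
        m = pd.DataFrame({"M1:P2": [1.0, 1.0], "M1:P3": [0.0, 0.0],
                          "M1:P4": [0.0, 0.0], "M1:P5": [0.0, 0.0]},
                         index=["zeta", "alpha"])
        assert rank_and_cluster(m, "signature") == ["alpha", "zeta"]

    def test_identical_pair_adjacent_in_leaf_order(self):
        # brute-force check over all three dendrogram topologies: the two
        # identical rows must be merged first, hence adjacent leaves
        m = pd.DataFrame({"M1:P1": [0.0, 0.0, 9.0],
                          "M1:P2": [1.0, 1.0, -8.0]},
                         index=["a", "b", "far"])
        order = rank_and_cluster(m, "none")
        pos = {s: order.index(s) for s in m.index}
        assert abs(pos["a"] - pos["b"]) == 1

    def test_empty_matrix(self):
        assert rank_and_cluster(pd.DataFrame(), "signature") == []


class TestConcordance:
    def _dm(self, deltas, relevant):
        from thromboquant.comparison import DeltaMatrix

        cols = ["M1:P1", "M1:P2", "M1:P3", "M1:P4", "M1:P5"]
        d = pd.DataFrame(deltas, columns=cols)
        r = pd.DataFrame(relevant, columns=cols, index=d.index)
        sd = pd.DataFrame(1.0, columns=cols, index=d.index)
        return DeltaMatrix(delta=d, composite_sd=sd, relevant=r)

    def test_unchanged_strain_is_concordant(self):
        dm = self._dm(pd.DataFrame([[0.5, -0.5, 0.2, 0.0, 0.1]],
                                   index=["Gp6"]).values.tolist() and
                      {"M1:P1": [0.5], "M1:P2": [-0.5], "M1:P3": [0.2],
                       "M1:P4": [0.0], "M1:P5": [0.1]},
                      {"M1:P1": [False], "M1:P2": [False], "M1:P3": [False],
                       "M1:P4": [False], "M1:P5": [False]})
        dm.delta.index = dm.relevant.index = dm.composite_sd.index = ["x"]
        ann = [PhenotypeAnnotation("x", "unchanged", "unchanged")]
        table = concordance_table(dm, ann)
        assert table.in_vitro_class["x"] == "unchanged"
        assert table.thrombosis.loc["unchanged", "unchanged"] == 1

    def test_decreased_strain_classified_by_relevant_sum(self):
        dm = self._dm({"M1:P1": [-4.0], "M1:P2": [-3.0], "M1:P3": [0.1],
                       "M1:P4": [0.0], "M1:P5": [0.0]},
                      {"M1:P1": [True], "M1:P2": [True], "M1:P3": [False],
                       "M1:P4": [False], "M1:P5": [False]})
        dm.delta.index = dm.relevant.index = dm.composite_sd.index = ["k"]
        table = concordance_table(dm, [PhenotypeAnnotation("k", "decreased",
                                                           "prolonged")])
        assert table.in_vitro_class["k"] == "decreased"

    def test_empty_annotations_allowed(self):
        dm = self._dm({"M1:P1": [], "M1:P2": [], "M1:P3": [], "M1:P4": [],
                       "M1:P5": []}, {"M1:P1": [], "M1:P2": [], "M1:P3": [],
                                      "M1:P4": [], "M1:P5": []})
        table = concordance_table(dm, [])
        assert len(table.in_vitro_class) == 0

    def test_unknown_category_token_rejected(self):
        with pytest.raises(InvalidInputError):
            PhenotypeAnnotation("x", "bigger", "unchanged")
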