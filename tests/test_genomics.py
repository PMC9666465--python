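"""COG association statistics, FDR, pathway summaries, tree classifiers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from auxokit.genomics import (
    CogPresenceMatrix,
    benjamini_hochberg,
    cog_association,
    compare_usage,
    count_coenzyme_reactions,
    pathway_completeness,
    pathway_differential,
    predict_auxotrophy,
    random_feature_baseline,
    train_auxotrophy_classifier,
)
from auxokit.synthetic import GenomeSpec, simulate_cog_matrix


from oracles import bh_oracle, chi2_oracle


def table1_matrix(seed=0):
    """Exact Table-1-shaped fixture: marker in 0/18 auxotrophs, 13/17 prototrophs,
    over a random pathway-mapped background (synthetic stand-in for the real
    strain panel)."""
    rng = np.random.default_rng(seed)
    strains = [f"aux_{i}" for i in range(18)] + [f"proto_{i}" for i in range(17)]
    presence = pd.DataFrame(
        rng.random((35, 40)) < 0.6, index=strains,
        columns=[f"BG{i:02d}" for i in range(40)],
    )
    presence["BioD"] = [False] * 18 + [True] * 13 + [False] * 4
    pathway_map = {c: f"pw_{i % 8}" for i, c in enumerate(presence.columns)}
    pathway_map["BioD"] = "biotin_biosynthesis"
    labels = pd.DataFrame({"biotin": ["auxotroph"] * 18 + ["prototroph"] * 17},
                          index=strains)
    return CogPresenceMatrix(presence=presence, pathway_map=pathway_map, labels=labels)


class TestCogAssociation:
    def test_biod_row_matches_independent_chi2_oracle(self):
        m = table1_matrix()
        rec = {r.cog: r for r in cog_association(m, "biotin")}["BioD"]
        assert rec.counts == (0, 18, 13, 4)
        stat, p = chi2_oracle([[0, 18], [13, 4]])
        assert rec.chi2_stat == pytest.approx(stat, abs=1e-10)
        assert rec.p_value == pytest.approx(p, abs=1e-10)
        assert rec.direction == "more_in_prototrophs"
        assert rec.pct_present_aux == 0.0
        assert rec.pct_present_proto == pytest.approx(100 * 13 / 17)

    def test_identical_proportions_give_chi2_zero_p_one(self):
        strains = [f"s{i}" for i in range(20)]
        presence = pd.DataFrame({"G1": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5},
                                index=strains)
        labels = pd.DataFrame({"v": ["auxotroph"] * 10 + ["prototroph"] * 10},
                              index=strains)
        m = CogPresenceMatrix(presence=presence, pathway_map={"G1": "p"}, labels=labels)
        rec = cog_association(m, "v")[0]
        assert rec.chi2_stat == 0.0
        assert rec.p_value == 1.0

    def test_constant_cog_flagged_with_p_one(self):
        m = table1_matrix()
        m.presence["CONST"] = True
        m.pathway_map["CONST"] = "pw_0"
        rec = {r.cog: r for r in cog_association(m, "biotin")}["CONST"]
        assert rec.p_value == 1.0 and rec.flagged

    def test_label_swap_symmetry(self):
        m = table1_matrix()
        swapped = CogPresenceMatrix(
            presence=m.presence, pathway_map=m.pathway_map,
            labels=m.labels.replace({"auxotroph": "prototroph", "prototroph": "auxotroph"}),
        )
        a = {r.cog: r for r in cog_association(m, "biotin")}
        b = {r.cog: r for r in cog_association(swapped, "biotin")}
        flip = {"more_in_auxotrophs": "more_in_prototrophs",
                "more_in_prototrophs": "more_in_auxotrophs", "none": "none"}
        for cog in a:
            assert a[cog].p_value == pytest.approx(b[cog].p_value, abs=1e-12)
            assert flip[a[cog].direction] == b[cog].direction

    def test_empty_class_is_an_error(self):
        m = table1_matrix()
        labels = m.labels.copy()
        labels["biotin"] = "auxotroph"
        bad = CogPresenceMatrix(presence=m.presence, pathway_map=m.pathway_map, labels=labels)
        with pytest.raises(ValueError, match="non-empty"):
            cog_association(bad, "biotin")

    def test_label_shuffle_control_yields_no_hits(self):
        """Randomized labels on a background-only matrix: ~no q<0.05 records."""
        spec = GenomeSpec(n_auxotrophs=18, n_prototrophs=17, marker_cogs={},
                          background_cogs=80, background_presence_rate=0.6, seed=5)
        base = simulate_cog_matrix(spec)
        rng = np.random.default_rng(42)
        clean = 0
        status = np.array(["auxotroph"] * 18 + ["prototroph"] * 17)
        for _ in range(100):
            labels = pd.DataFrame({"none": rng.permutation(status)},
                                  index=base.presence.index)
            m = CogPresenceMatrix(presence=base.presence, pathway_map=base.pathway_map,
                                  labels=labels)
            records = cog_association(m, "none")
            if not any(r.q_value < 0.05 for r in records):
                clean += 1
        assert clean >= 95


class TestBenjaminiHochberg:
    def test_single_p_is_unchanged(self):
        assert benjamini_hochberg([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_monotone_when_sorted_by_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p) and np.all(q <= 1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestPathways:
    def test_completeness_extremes(self):
        presence = pd.DataFrame({"A": [True, False], "B": [True, False]},
                                index=["full", "none"])
        labels = pd.DataFrame({"v": ["auxotroph", "prototroph"]}, index=["full", "none"])
        m = CogPresenceMatrix(presence=presence, pathway_map={"A": "p", "B": "p"},
                              labels=labels)
        pc = pathway_completeness(m)
        assert pc.loc["full", "p"] == 1.0
        assert pc.loc["none", "p"] == 0.0

    def test_completeness_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        presence = pd.DataFrame(rng.random((20, 50)) < 0.5,
                                index=[f"s{i}" for i in range(20)],
                                columns=[f"c{i}" for i in range(50)])
        pathway_map = {f"c{i}": f"p{i % 7}" for i in range(50)}
        labels = pd.DataFrame({"v": ["auxotroph"] * 20}, index=presence.index)
        m = CogPresenceMatrix(presence=presence, pathway_map=pathway_map, labels=labels)
        pc = pathway_completeness(m)
        for pw in pc.columns:
            cogs = [c for c, p in pathway_map.items() if p == pw]
            for s in presence.index:
                assert pc.loc[s, pw] == sum(presence.loc[s, c] for c in cogs) / len(cogs)

    def test_completeness_invariant_to_column_permutation(self):
        rng = np.random.default_rng(3)
        presence = pd.DataFrame(rng.random((10, 12)) < 0.5,
                                index=[f"s{i}" for i in range(10)],
                                columns=[f"c{i}" for i in range(12)])
        pathway_map = {f"c{i}": "p0" for i in range(12)}
        labels = pd.DataFrame({"v": ["auxotroph"] * 10}, index=presence.index)
        m1 = CogPresenceMatrix(presence=presence, pathway_map=pathway_map, labels=labels)
        perm = presence[list(rng.permutation(presence.columns))]
        m2 = CogPresenceMatrix(presence=perm, pathway_map=pathway_map, labels=labels)
        assert pathway_completeness(m1).equals(pathway_completeness(m2))

    def test_differential_cutoff_is_strict(self):
        m = table1_matrix()
        records = cog_association(m, "biotin")

        def fake(rec, q):
            return type(rec)(cog=rec.cog, counts=rec.counts, chi2_stat=rec.chi2_stat,
                             p_value=rec.p_value, q_value=q, direction="more_in_prototrophs",
                             pct_present_aux=0, pct_present_proto=1, flagged=False)

        # pathway pw_0 has 5 tested genes (indices 0, 8, 16, 24, 32)
        pw0 = [r for r in records if m.pathway_map[r.cog] == "pw_0"]
        assert len(pw0) == 5
        others = [r for r in records if m.pathway_map[r.cog] != "pw_0"]
        neutral = [fake(r, 1.0) for r in others]
        one_sig = [fake(r, 0.01 if i < 1 else 1.0) for i, r in enumerate(pw0)]
        two_sig = [fake(r, 0.01 if i < 2 else 1.0) for i, r in enumerate(pw0)]
        # 1/5 = 0.2 is NOT strictly above the 0.2 cutoff; 2/5 = 0.4 is
        assert pathway_differential(neutral + one_sig, m) == []
        diffs = pathway_differential(neutral + two_sig, m)
        assert len(diffs) == 1
        assert diffs[0].pathway == "pw_0"
        assert diffs[0].fraction == pytest.approx(0.4)
        assert diffs[0].enriched_group == "more_in_prototrophs"

    def test_no_significant_records_gives_empty_list(self):
        m = table1_matrix()
        records = [r for r in cog_association(m, "biotin") if r.cog != "BioD"]
        assert pathway_differential(records, m, alpha=1e-9) == []

    def test_cutoff_bounds(self):
        m = table1_matrix()
        with pytest.raises(ValueError):
            pathway_differential([], m, cutoff=1.5)


class TestClassifier:
    def test_perfect_marker_gives_depth_one_exact_recovery(self):
        m = table1_matrix()
        m.presence["PERFECT"] = [False] * 18 + [True] * 17
        m.pathway_map["PERFECT"] = "pw_1"
        clf = train_auxotrophy_classifier(m, "biotin", ["PERFECT"], seed=0)
        assert clf.metrics["accuracy"] == 1.0
        assert clf.metrics["train_accuracy"] == 1.0
        assert clf.model.get_depth() == 1
        pred = predict_auxotrophy(clf, m)
        assert (pred == m.labels["biotin"]).all()

    def test_depth_is_bounded_by_three(self):
        m = table1_matrix()
        clf = train_auxotrophy_classifier(m, "biotin", list(m.presence.columns), seed=1)
        assert clf.model.get_depth() <= 3

    def test_predictions_are_deterministic(self):
        m = table1_matrix()
        clf = train_auxotrophy_classifier(m, "biotin", ["BioD"], seed=2)
        assert predict_auxotrophy(clf, m).equals(predict_auxotrophy(clf, m))

    def test_training_set_predictions_reproduce_reported_accuracy(self):
        m = table1_matrix()
        clf = train_auxotrophy_classifier(m, "biotin", ["BioD", "BG00"], seed=3)
        pred = predict_auxotrophy(clf, m)
        overall = (pred == m.labels["biotin"]).mean()
        # the full matrix is train + test, so overall accuracy lies between
        # the two reported values
        lo = min(clf.metrics["accuracy"], clf.metrics["train_accuracy"])
        hi = max(clf.metrics["accuracy"], clf.metrics["train_accuracy"])
        assert lo - 1e-12 <= overall <= hi + 1e-12

    def test_missing_feature_is_an_error(self):
        m = table1_matrix()
        clf = train_auxotrophy_classifier(m, "biotin", ["BioD"], seed=0)
        trimmed = CogPresenceMatrix(presence=m.presence.drop(columns=["BioD"]),
                                    pathway_map=m.pathway_map, labels=m.labels)
        with pytest.raises(KeyError, match="BioD"):
            predict_auxotrophy(clf, trimmed)

    def test_random_features_score_at_chance(self):
        m = table1_matrix(seed=8)
        base = random_feature_baseline(m, "biotin", 2, n_randomizations=200, seed=0)
        se = base.accuracy.std(ddof=1) / math.sqrt(len(base))
        assert abs(base.accuracy.mean() - 0.5) <= 3 * se + 0.02

    def test_accuracy_degrades_with_marker_noise(self):
        """Held-out accuracy is monotone non-increasing in marker noise."""
        rng = np.random.default_rng(0)
        grid = [0.0, 0.15, 0.3, 0.5]
        means = []
        for noise in grid:
            accs = []
            for _ in range(30):
                flip = rng.random(35) < noise
                marker = np.array([False] * 18 + [True] * 17) ^ flip
                presence = pd.DataFrame({"M": marker,
                                         "B": rng.random(35) < 0.5},
                                        index=[f"s{i}" for i in range(35)])
                labels = pd.DataFrame({"v": ["auxotroph"] * 18 + ["prototroph"] * 17},
                                      index=presence.index)
                m = CogPresenceMatrix(presence=presence,
                                      pathway_map={"M": "p", "B": "p"}, labels=labels)
                clf = train_auxotrophy_classifier(m, "v", ["M"],
                                                  seed=int(rng.integers(2**31)))
                accs.append(clf.metrics["accuracy"])
            means.append(np.mean(accs))
        assert all(a >= b - 0.05 for a, b in zip(means, means[1:]))
        assert means[0] == 1.0


class TestCoenzymeUsage:
    def test_empty_table_gives_all_zero_counts(self):
        usage = count_coenzyme_reactions(pd.DataFrame(), strains=["s1", "s2"])
        assert (usage == 0).all().all()
        assert list(usage.index) == ["s1", "s2"]

    def test_toy_table_matches_brute_force_tally(self):
        table = pd.DataFrame(
            {
                "strain": ["s1", "s1", "s1", "s2", "s2"],
                "reaction_id": ["r1", "r2", "r3", "r1", "r4"],
                "cofactors": ["NAD(H)", "NAD(H);FAD(H)", "biotin", "NAD(H)", "CoA;NAD(H)"],
            }
        )
        usage = count_coenzyme_reactions(table)
        assert usage.loc["s1", "NAD(H)"] == 2
        assert usage.loc["s1", "FAD(H)"] == 1
        assert usage.loc["s1", "biotin"] == 1
        assert usage.loc["s2", "NAD(H)"] == 2
        assert usage.loc["s2", "CoA"] == 1
        assert usage.loc["s2", "biotin"] == 0

    def test_unknown_cofactor_is_an_error(self):
        table = pd.DataFrame({"strain": ["s1"], "reaction_id": ["r1"],
                              "cofactors": ["mystery"]})
        with pytest.raises(ValueError, match="mystery"):
            count_coenzyme_reactions(table)

    def test_ten_percent_excess_is_recovered(self):
        """Usage tables built with a 10% auxotroph excess report ~+10%."""
        rng = np.random.default_rng(1)
        n = 40
        strains = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series(["auxotroph"] * n + ["prototroph"] * n, index=strains)
        base = 100
        counts = np.concatenate([
            rng.poisson(base * 1.1, size=n),  # auxotrophs
            rng.poisson(base, size=n),
        ])
        usage = pd.DataFrame({"NAD(H)": counts, "FAD(H)": rng.poisson(50, size=2 * n)},
                             index=strains)
        cmp = compare_usage(usage, labels)
        assert cmp.loc["NAD(H)", "pct_difference"] == pytest.approx(10.0, abs=3.0)
        assert cmp.loc["NAD(H)", "direction"] == "more_in_auxotrophs"
        assert cmp.loc["NAD(H)", "p_value"] < 0.05
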