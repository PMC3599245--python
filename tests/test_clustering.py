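"""Profile clustering under Pearson distance and the shift taxonomy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ripeshift.clustering import (
    ANTICIPATED,
    DELAYED,
    GROUP_COMMON,
    GROUP_DIFFERENT,
    GROUP_NONE,
    GROUP_PB,
    GROUP_V,
    NON_MODULATION,
    NOVEL,
    NO_EFFECT,
    OTHER,
    TemplateLabel,
    assign_templates,
    brute_force_best_partition,
    classify_shift,
    kmeans_pearson,
    pearson_distance,
    pooled_profiles,
    select_shift_candidates,
    stage_profiles,
    template_from_log2_profile,
)
from ripeshift.expression import fold_change


def profiles_df(rows, stages=("BV", "EV", "H")):
    idx = pd.MultiIndex.from_tuples(
        [(f"g{i}", "C") for i in range(len(rows))], names=["gene", "condition"]
    )
    return pd.DataFrame(np.asarray(rows, float), index=idx, columns=list(stages))


class TestPearsonDistance:
    def test_affine_copies_have_zero_distance(self):
        x = np.array([1.0, 3.0, 2.0])
        assert pearson_distance(x, 5 * x + 2) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        x = np.array([0.0, 1.0, 2.0])
        assert pearson_distance(x, -x) == pytest.approx(2.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=6),
           st.lists(st.floats(-100, 100), min_size=3, max_size=6))
    def test_bounds_and_self_distance(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        d = pearson_distance(x, y)
        assert -1e-9 <= d <= 2 + 1e-9
        assert pearson_distance(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            pearson_distance(np.ones(3), np.array([1.0, 2.0, 3.0]))


class TestKMeans:
    def test_matches_exhaustive_oracle_on_six_profiles(self):
        rows = [
            [0, -2.0, -2.1], [0, -1.9, -2.0], [0, -2.05, -1.95],  # down at EV
            [0, 0.1, 2.0], [0, -0.05, 1.9], [0, 0.0, 2.1],        # up at H
        ]
        prof = profiles_df(rows)
        model = kmeans_pearson(prof, k=2, n_init=10, seed=0)
        best_obj, best_labels = brute_force_best_partition(prof, k=2)
        assert model.objective == pytest.approx(best_obj, abs=1e-9)
        lab = model.assignments.to_numpy()
        same = lambda l: tuple(np.asarray(l) == l[0])
        assert same(lab) == same(best_labels)

    def test_determinism_and_restart_improvement(self):
        rng = np.random.default_rng(1)
        prof = profiles_df(rng.normal(size=(40, 3)))
        m1 = kmeans_pearson(prof, k=4, seed=5)
        m2 = kmeans_pearson(prof, k=4, seed=5)
        assert m1.assignments.equals(m2.assignments)
        single = kmeans_pearson(prof, k=4, n_init=1, seed=5)
        assert m1.objective <= single.objective + 1e-9

    def test_affine_copies_cluster_together(self):
        base = np.array([0.0, -2.0, -2.0])
        rows = [base, 3 * base + 1, [0, 0.1, 2.0], [0, -0.1, 1.9]]
        model = kmeans_pearson(profiles_df(rows), k=2, seed=0)
        lab = model.assignments.to_numpy()
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]

    def test_too_few_profiles_raises(self):
        with pytest.raises(ValueError):
            kmeans_pearson(profiles_df([[0, 1, 2], [0, 2, 1]]), k=8)


class TestStageProfiles:
    def test_consistency_with_fold_change(self, small_sim):
        matrix, _, _ = small_sim
        prof = stage_profiles(matrix, "C", stages=["BV", "EV", "H"])
        fc = fold_change(matrix, ("C", "BV"), ("C", "EV"))["fc"]
        # profile difference is a log2 FC of the geometric replicate mean;
        # agreement with the arithmetic-mean FC is checked on its sign
        delta = prof["EV"] - prof["BV"]
        strong = fc.abs() > 1.5
        assert (np.sign(delta[strong]) == np.sign(fc[strong])).all()

    def test_noise_free_planted_effect_exact(self, noise_free_sim):
        matrix, _, truth = noise_free_sim
        down = truth.index[truth["label"] == "program-down"]
        prof = stage_profiles(matrix, "C", list(down), stages=["BV", "EV", "H"])
        assert np.allclose(prof["EV"] - prof["BV"], -2.0)

    def test_constant_gene_flat_profile(self, noise_free_sim):
        matrix, _, truth = noise_free_sim
        flat = truth.index[truth["label"] == "flat"][:10]
        prof = stage_profiles(matrix, "PB", list(flat), stages=["BV", "EV", "H"])
        assert np.allclose(prof["EV"], prof["BV"]) and np.allclose(prof["H"], prof["BV"])


class TestTemplates:
    @pytest.mark.parametrize("centroid,dirs,cls,onset", [
        ((0, -1.5, -1.5), ("down", "down"), "down", "EV"),
        ((0, 0, 1.5), ("flat", "up"), "up", "H"),
        ((0, 0.2, -0.3), ("flat", "flat"), "flat", None),
        ((0, -1.5, 1.5), ("down", "up"), OTHER, "EV"),
    ])
    def test_threshold_labels(self, centroid, dirs, cls, onset):
        lab = template_from_log2_profile(np.array(centroid), ["BV", "EV", "H"], fc_threshold=2.0)
        assert lab.directions == dirs
        assert lab.cls == cls
        assert lab.onset == onset

    def test_planted_templates_recovered(self, noise_free_sim):
        matrix, _, truth = noise_free_sim
        interesting = truth.index[truth["label"].isin(
            ["program-down", "program-up", "delayed-in-PB", "delayed-in-V"])]
        prof = pooled_profiles(matrix, {c: set(interesting) for c in ("C", "PB", "V")},
                               stages=["BV", "EV", "H"])
        model = kmeans_pearson(prof, k=4, seed=3)
        templates = assign_templates(model)
        for (gene, cond), cid in model.assignments.items():
            lab = templates[cid]
            tag = truth.at[gene, f"template_{cond}"]
            want_cls, want_onset = tag.split("@")
            assert (lab.cls, lab.onset) == (want_cls, want_onset)


def L(ev, h):
    return template_from_log2_profile(
        np.array([0.0, {"down": -2, "flat": 0, "up": 2}[ev],
                  {"down": -2, "flat": 0, "up": 2}[h]]), ["BV", "EV", "H"]
    )


class TestClassifyShift:
    def test_no_effect_when_labels_match(self):
        lab = L("down", "down")
        rec = classify_shift("g", lab, lab, lab, {"C": True, "PB": True, "V": True})
        assert rec.shift_PB == NO_EFFECT and rec.shift_V == NO_EFFECT
        assert rec.effect_group == GROUP_NONE

    def test_pb_delayed_specific(self):
        rec = classify_shift(
            "g", L("down", "down"), L("flat", "down"), L("down", "down"),
            {"C": True, "PB": True, "V": True},
        )
        assert rec.shift_PB == DELAYED and rec.shift_V == NO_EFFECT
        assert rec.effect_group == GROUP_PB

    def test_anticipated_and_common(self):
        rec = classify_shift(
            "g", L("flat", "up"), L("up", "up"), L("up", "up"),
            {"C": True, "PB": True, "V": True},
        )
        assert rec.shift_PB == ANTICIPATED and rec.shift_V == ANTICIPATED
        assert rec.effect_group == GROUP_COMMON

    def test_novel_and_non_modulation(self):
        rec = classify_shift(
            "g", L("down", "down"), None, L("up", "up"),
            {"C": True, "PB": False, "V": True},
        )
        assert rec.shift_PB == NON_MODULATION
        assert rec.shift_V == OTHER  # modulated in both but class flips
        novel = classify_shift("g", None, L("up", "up"), None,
                               {"C": False, "PB": True, "V": False})
        assert novel.shift_PB == NOVEL and novel.shift_V == NO_EFFECT
        assert novel.effect_group == GROUP_PB

    def test_different_effect_group(self):
        rec = classify_shift(
            "g", L("down", "down"), L("flat", "down"), None,
            {"C": True, "PB": True, "V": False},
        )
        assert rec.shift_PB == DELAYED and rec.shift_V == NON_MODULATION
        assert rec.effect_group == GROUP_DIFFERENT

    def test_label_required_when_modulated(self):
        with pytest.raises(ValueError):
            classify_shift("g", None, L("up", "up"), None,
                           {"C": True, "PB": True, "V": False})



class TestSelectCandidates:
    def test_exclusion_and_fc_floor(self):
        prof = pd.DataFrame(
            [[10.0, 10.0, 8.0],    # |log2 FC| = 2 -> 4-fold, passes fc_min 3
             [10.0, 11.0, 10.0],   # 2-fold only
             [10.0, 13.0, 13.0]],  # 8-fold but directly DE
            index=pd.MultiIndex.from_tuples(
                [("a", "C"), ("b", "C"), ("c", "C")], names=["gene", "condition"]),
            columns=["BV", "EV", "H"],
        )
        out = select_shift_candidates(
            {"C": {"a", "b", "c"}}, prof, fc_min=3.0, exclude={"c"}
        )
        assert out == {"a"}

    def test_matches_enumeration_on_simulation(self, small_sim):
        matrix, _, truth = small_sim
        genes = list(truth.index[truth["label"] != "silent"])
        conds = ("C", "PB", "V")
        prof = pooled_profiles(matrix, {c: set(genes) for c in conds},
                               stages=["BV", "EV", "H"])
        modulated = {c: set(genes[: 100 + 20 * i]) for i, c in enumerate(conds)}
        exclude = set(genes[:30])
        got = select_shift_candidates(modulated, prof, fc_min=3.0, exclude=exclude)
        # independent enumeration
        expected = set()
        log_thr = np.log2(3.0)
        for g in set().union(*modulated.values()):
            ok = False
            for c in conds:
                row = prof.loc[(g, c)]
                if max(abs(row["EV"] - row["BV"]), abs(row["H"] - row["BV"])) >= log_thr:
                    ok = True
            if ok and g not in exclude:
                expected.add(g)
        assert got == expected
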