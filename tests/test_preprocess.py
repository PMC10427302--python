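import numpy as np
import pandas as pd
import pytest

import harshpref as hp
from harshpref.preprocess import (PreprocessError, apply_exclusions,
                                  code_side_contrast, cronbach_alpha,
                                  standardise_scales)


def study_fixture(recognition_counts=(), n_raters=289, n_targets=12,
                  n_nonhet=0, n_attention_fail=0):
    """289-rater style fixture with a prescribed recognition distribution.

    ``recognition_counts`` is a list of (n_raters, n_recognised) pairs;
    those raters recognise that many distinct targets.
    """
    per_cond = (102, 101, 86)
    conds = np.repeat(list(hp.CONDITIONS), per_cond)[:n_raters]
    raters = pd.DataFrame({
        "rater_id": [f"r{i}" for i in range(n_raters)],
        "condition": conds,
        "heterosexual": [0] * n_nonhet + [1] * (n_raters - n_nonhet),
        "attention_correct": ([0] * n_attention_fail
                              + [2] * (n_raters - n_attention_fail)),
        "masc_side": ["left", "right"] * (n_raters // 2)
                     + ["left"] * (n_raters % 2),
        "age": 21, "relationship_status": 0,
        "mate_value_face": 4, "mate_value_body": 4,
        "pp_score": np.linspace(1, 5, n_raters),
        "rs_score": np.linspace(2, 6, n_raters),
    })
    rec = {}
    i = 0
    for count, k in recognition_counts:
        for _ in range(count):
            rec[f"r{i}"] = k
            i += 1
    choices = pd.DataFrame([
        {"rater_id": f"r{i}", "target_id": t + 1,
         "chose_masculinised": (i + t) % 2,
         "recognised": int(t < rec.get(f"r{i}", 0))}
        for i in range(n_raters) for t in range(n_targets)])
    ratings = pd.DataFrame([
        {"rater_id": f"r{i}", "target_id": t + 1, "version": v,
         "dimension": dim, "score": 1 + (i + t + len(v)) % 7}
        for i in range(n_raters) for t in range(n_targets)
        for v in hp.VERSIONS for dim in hp.DIMENSIONS])
    return hp.StudyDataset(raters, choices, ratings)


class TestExclusionCascade:
    def test_printed_recognition_distribution_removes_110_points(self):
        """21x1 + 14x2 + 7x3 + 10x4 recognised faces = 110 data points."""
        ds = study_fixture(recognition_counts=[(21, 1), (14, 2), (7, 3),
                                               (10, 4)])
        out, rep = apply_exclusions(ds)
        assert rep.n_datapoints_removed_recognition == 110
        assert rep.n_raters_removed_recognition == 0

    def test_retained_datapoints_3358(self):
        ds = study_fixture(recognition_counts=[(21, 1), (14, 2), (7, 3),
                                               (10, 4)])
        out, rep = apply_exclusions(ds)
        assert rep.n_retained_raters == 289
        assert rep.n_retained_datapoints == 289 * 12 - 110 == 3358
        assert rep.per_condition_retained == {
            "control": 102, "pathogen_prevalence": 101,
            "resource_scarcity": 86}
        assert sum(rep.per_condition_retained.values()) == 289

    def test_rater_recognising_more_than_four_removed_entirely(self):
        ds = study_fixture(recognition_counts=[(9, 5), (3, 2)])
        out, rep = apply_exclusions(ds)
        assert rep.n_raters_removed_recognition == 9
        assert rep.n_retained_raters == 280
        # the 3 raters with 2 recognitions lose only those data points
        assert rep.n_datapoints_removed_recognition == 6

    def test_no_flags_identity(self):
        ds = study_fixture()
        out, rep = apply_exclusions(ds)
        assert out.equals(ds)
        assert rep.n_removed_nonheterosexual == 0
        assert rep.n_removed_attention == 0
        assert rep.n_datapoints_removed_recognition == 0

    def test_orientation_and_attention_filters(self):
        ds = study_fixture(n_nonhet=5, n_attention_fail=8)
        # overlap: the first 5 raters are non-het AND may fail attention
        out, rep = apply_exclusions(ds)
        assert rep.n_removed_nonheterosexual == 5
        assert rep.n_removed_attention == 3     # remaining failures
        assert rep.n_retained_raters == 281

    def test_manual_drop_list_runs_first(self):
        ds = study_fixture()
        out, rep = apply_exclusions(ds, drop_raters=["r0", "r1"])
        assert rep.n_removed_idiosyncratic == 2
        assert rep.n_retained_raters == 287

    def test_idempotence(self):
        ds = study_fixture(recognition_counts=[(10, 3), (2, 6)],
                           n_nonhet=4)
        once, rep1 = apply_exclusions(ds)
        twice, rep2 = apply_exclusions(once)
        assert once.equals(twice)
        assert rep2.n_removed_nonheterosexual == 0
        assert rep2.n_datapoints_removed_recognition == 0

    def test_variant_monotonicity(self):
        """Relaxing any variant flag never shrinks the retained counts."""
        ds = study_fixture(recognition_counts=[(15, 2), (4, 6)],
                           n_nonhet=10, n_attention_fail=12)
        _, base = apply_exclusions(ds, hp.ExclusionVariant())
        for flag in ("keep_recognised_points", "keep_attention_failures",
                     "keep_nonheterosexual"):
            _, relaxed = apply_exclusions(
                ds, hp.ExclusionVariant(**{flag: True}))
            assert relaxed.n_retained_raters >= base.n_retained_raters
            assert (relaxed.n_retained_datapoints
                    >= base.n_retained_datapoints)

    def test_count_conservation_per_stage(self):
        ds = study_fixture(recognition_counts=[(6, 2)], n_nonhet=3,
                           n_attention_fail=5)
        _, rep = apply_exclusions(ds)
        assert (rep.n_recruited - rep.n_removed_idiosyncratic
                - rep.n_removed_nonheterosexual - rep.n_removed_attention
                - rep.n_raters_removed_recognition == rep.n_retained_raters)
        assert (rep.n_retained_datapoints
                == 12 * rep.n_retained_raters
                - rep.n_datapoints_removed_recognition)

    def test_missing_recognition_flags_error(self):
        ds = study_fixture()
        ds.choices = ds.choices.drop(columns=["recognised"])
        with pytest.raises(PreprocessError, match="recognition"):
            apply_exclusions(ds)

    def test_attention_out_of_range_error(self):
        ds = study_fixture()
        ds.raters.loc[0, "attention_correct"] = 3
        with pytest.raises(PreprocessError, match="attention"):
            apply_exclusions(ds)


class TestScaleScoring:
    def test_alpha_perfect_consistency(self):
        """Identical items across raters (nonzero spread) give alpha = 1."""
        items = np.array([[1, 1, 1], [3, 3, 3], [5, 5, 5], [7, 7, 7]])
        assert cronbach_alpha(items) == pytest.approx(1.0)

    @pytest.mark.parametrize("items", [
        [[1, 2], [2, 3], [3, 4]],
        [[1, 4], [2, 2], [3, 3]],
    ])
    def test_alpha_matches_variance_formula(self, items):
        items = np.asarray(items, dtype=float)
        k = items.shape[1]
        expected = k / (k - 1) * (
            1 - items.var(axis=0, ddof=1).sum()
            / items.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(items) == pytest.approx(expected)

    def test_alpha_single_rater_undefined(self):
        with pytest.raises(PreprocessError):
            cronbach_alpha(np.array([[1, 2, 3]]))

    def test_alpha_zero_variance_flagged(self):
        with pytest.raises(PreprocessError, match="zero"):
            cronbach_alpha(np.array([[2, 2], [2, 2], [2, 2]]))

    def test_score_scales_on_backfilled_items(self):
        cfg = hp.default_sim_config(seed=4, backfill_items=True,
                                    recognition_rate=0.0)
        d = hp.simulate_study(cfg)
        raters, alphas = hp.score_scales(d.raters)
        # equal-loading item model tuned to the published reliabilities
        assert 0.70 < alphas["pp"] < 0.95
        assert 0.55 < alphas["rs"] < 0.85
        item_cols = [c for c in raters.columns if c.startswith("pp_item_")]
        assert np.allclose(raters["pp_score"],
                           raters[item_cols].mean(axis=1))


class TestStandardisation:
    def test_symmetric_triple(self):
        raters = pd.DataFrame({"pp_score": [1.0, 2.0, 3.0],
                               "rs_score": [1.0, 2.0, 3.0]})
        out = standardise_scales(raters)
        assert np.allclose(out["z_pp"], [-1, 0, 1])

    def test_mean_zero_sd_one(self, tiny_clean):
        z = tiny_clean.raters["z_pp"]
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_constant_scores_error(self):
        raters = pd.DataFrame({"pp_score": [2.0, 2.0], "rs_score": [1.0,
                                                                    3.0]})
        with pytest.raises(PreprocessError, match="variance"):
            standardise_scales(raters)


class TestSideContrast:
    def test_left_right_coding(self):
        raters = pd.DataFrame({"rater_id": ["a", "b"],
                               "masc_side": ["left", "right"]})
        choices = pd.DataFrame({"rater_id": ["a", "a", "b"],
                                "target_id": [1, 2, 1]})
        out = code_side_contrast(choices, raters)
        assert list(out["side_contrast"]) == [-0.5, -0.5, 0.5]

    def test_unknown_side_label_error(self):
        raters = pd.DataFrame({"rater_id": ["a"], "masc_side": ["centre"]})
        choices = pd.DataFrame({"rater_id": ["a"], "target_id": [1]})
        with pytest.raises(PreprocessError, match="centre"):
            code_side_contrast(choices, raters)

    def test_inconsistent_existing_contrast_error(self):
        raters = pd.DataFrame({"rater_id": ["a"], "masc_side": ["left"]})
        choices = pd.DataFrame({"rater_id": ["a", "a"], "target_id": [1, 2],
                                "side_contrast": [-0.5, 0.5]})
        with pytest.raises(PreprocessError, match="inconsistent"):
            code_side_contrast(choices, raters)
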