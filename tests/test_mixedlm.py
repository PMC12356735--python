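"""Design coding, mixed-model fitting through the lme4 bridge, stepwise
random-structure reduction, simple slopes, and influence screening."""

import numpy as np
import pandas as pd
import pytest

from rlerp.mixedlm import (
    CODING,
    MLMSpec,
    MODEL_TEMPLATES,
    _contrast_vector,
    code_predictors,
    fit_mlm,
    probe_simple_slopes,
    reduction_sequence,
    screen_influence,
)


def toy_table(n_participants=20, n_per_cell=6, planted=None, resid=3.0, ranef_sd=2.0, seed=0):
    """Balanced group x timing x valence design with planted coefficients
    (keys over coded predictors) and a participant random intercept."""
    planted = planted or {}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"p{i:02d}"
        grp = "patient" if i < n_participants // 2 else "control"
        u = rng.normal(0, ranef_sd)
        for session in ("immediate", "delayed"):
            for val in ("positive", "negative"):
                for k in range(n_per_cell):
                    upe = rng.uniform(-0.5, 0.5)
                    coded = {
                        "group": CODING["group"][grp],
                        "timing": CODING["timing"][session],
                        "valence": CODING["valence"][val],
                        "upe": upe,
                    }
                    y = u + rng.normal(0, resid)
                    for term, coef in planted.items():
                        prod = 1.0
                        for var in term.split(":"):
                            prod *= coded[var] if var != "1" else 1.0
                        y += coef * prod
                    rows.append(
                        dict(
                            participant=pid,
                            group=grp,
                            session=session,
                            feedback_valence=val,
                            upe=upe,
                            y=y,
                        )
                    )
    return pd.DataFrame(rows)


class TestCoding:
    def test_simple_coding_map(self):
        df = pd.DataFrame(
            {
                "participant": ["a", "b", "c", "d"],
                "group": ["patient", "control", "patient", "control"],
                "session": ["delayed", "immediate", "delayed", "immediate"],
                "feedback_valence": ["positive", "negative", "negative", "positive"],
                "learnability": ["learnable", "unlearnable", "learnable", "unlearnable"],
                "response_type": ["correct", "false", "correct", "false"],
            }
        )
        coded = code_predictors(df)
        assert list(coded["group"]) == [0.5, -0.5, 0.5, -0.5]
        assert list(coded["timing"]) == [0.5, -0.5, 0.5, -0.5]
        assert list(coded["valence"]) == [0.5, -0.5, -0.5, 0.5]
        assert list(coded["learnability"]) == [0.5, -0.5, 0.5, -0.5]
        assert list(coded["response_type"]) == [0.5, -0.5, 0.5, -0.5]

    def test_block_standardized_over_modeled_rows(self):
        df = pd.DataFrame(
            {
                "participant": ["a"] * 8,
                "group": ["control"] * 8,
                "block": range(1, 9),
            }
        )
        coded = code_predictors(df)
        assert coded["block_scaled"].mean() == pytest.approx(0.0, abs=1e-12)
        assert coded["block_scaled"].std(ddof=1) == pytest.approx(1.0)

    def test_unknown_level_raises(self):
        df = pd.DataFrame({"participant": ["a"], "group": ["martian"]})
        with pytest.raises(ValueError, match="martian"):
            code_predictors(df)


class TestReductionOrder:
    def test_interactions_removed_before_main_effects_last_listed_first(self):
        seq = reduction_sequence(("timing", "valence", "timing:valence", "valence:upe"))
        assert seq[0] == ["timing", "valence", "timing:valence", "valence:upe"]
        assert seq[1] == ["timing", "valence", "timing:valence"]  # last interaction first
        assert seq[2] == ["timing", "valence"]
        assert seq[3] == ["timing"]
        assert seq[4] == []

    def test_templates_mirror_printed_random_structures(self):
        assert MODEL_TEMPLATES["accuracy"].formula == (
            "accuracy ~ group*timing*block_scaled + "
            "(1 + timing + block_scaled + timing:block_scaled | participant)"
        )
        assert "valence:response_type" in MODEL_TEMPLATES["switching"].random_terms
        assert MODEL_TEMPLATES["p3b"].random_terms == (
            "timing",
            "valence",
            "upe",
            "timing:upe",
        )


@pytest.fixture(scope="module")
def planted_fit():
    planted = {
        "1": 3.0,
        "group": 1.5,
        "valence": 0.8,
        "upe": 0.245,
        "group:upe": -0.49,
        "valence:upe": 0.49,
        "group:valence:upe": -0.98,
    }
    table = toy_table(n_participants=24, n_per_cell=12, planted=planted, seed=3)
    design = code_predictors(table, carry=("y",))
    spec = MLMSpec(response="y", fixed="group*timing*upe*valence", random_terms=("timing",))
    return planted, fit_mlm(design, spec)


class TestFitting:
    def test_planted_fixed_effects_recovered_within_ci(self, planted_fit):
        planted, res = planted_fit
        for term in ("group", "valence"):
            est = res.coefficients.loc[term, "estimate"]
            se = res.coefficients.loc[term, "se"]
            assert abs(est - planted[term]) < 2.5 * se

    def test_satterthwaite_df_far_smaller_for_between_subject_effect(self, planted_fit):
        _, res = planted_fit
        df_group = res.coefficients.loc["group", "df"]
        df_upe = res.coefficients.loc["upe", "df"]
        assert df_group < 40  # ~ number of participants
        assert df_upe > 500  # within-subject, trial-level resolution

    def test_intercept_only_model_recovers_grand_mean(self):
        table = toy_table(n_participants=10, n_per_cell=4, planted={"1": 7.0}, seed=4)
        design = code_predictors(table, carry=("y",))
        spec = MLMSpec(response="y", fixed="1", random_terms=())
        res = fit_mlm(design, spec)
        grand = design["y"].mean()
        # REML intercept on balanced data equals the grand mean
        assert res.coefficients.loc["(Intercept)", "estimate"] == pytest.approx(grand, abs=1e-6)

    def test_reduction_reports_realized_structure(self):
        # data generated with intercept-only random effects: a maximal
        # slope structure must be reduced, never the fixed part
        table = toy_table(n_participants=12, n_per_cell=4, seed=6)
        design = code_predictors(table, carry=("y",))
        spec = MLMSpec(
            response="y",
            fixed="group*timing*valence",
            random_terms=("timing", "valence", "timing:valence"),
        )
        res = fit_mlm(design, spec)
        assert set(res.random_terms) <= {"timing", "valence", "timing:valence"}
        assert len(res.coefficients) == 8  # full factorial fixed part intact

    def test_balanced_main_effect_equals_difference_of_level_means(self):
        table = toy_table(n_participants=16, n_per_cell=8, planted={"valence": 2.0}, resid=0.0,
                          ranef_sd=0.0, seed=8)
        design = code_predictors(table, carry=("y",))
        spec = MLMSpec(response="y", fixed="group*timing*valence", random_terms=())
        res = fit_mlm(design, spec)
        means = table.groupby("feedback_valence")["y"].mean()
        diff = means["positive"] - means["negative"]
        assert res.coefficients.loc["valence", "estimate"] == pytest.approx(diff, abs=1e-8)


class TestSimpleSlopes:
    def test_contrast_vector_hand_oracle(self):
        names = ["(Intercept)", "group", "upe", "valence", "group:upe",
                 "group:valence", "upe:valence", "group:upe:valence"]
        c = _contrast_vector(names, "upe", {"group": -0.5, "valence": 0.5})
        # slope = b_upe + b_g:upe*(-0.5) + b_upe:v*(0.5) + b_g:upe:v*(-0.25)
        expected = [0, 0, 1.0, 0, -0.5, 0, 0.5, -0.25]
        np.testing.assert_allclose(c, expected)

    def test_planted_slope_pattern_recovered(self, planted_fit):
        _, res = planted_fit
        slopes = probe_simple_slopes(res, "upe", ["group", "valence"])
        cell = slopes.set_index(["group", "valence"])
        focal = cell.loc[("control", "positive")]
        assert abs(focal["estimate"] - 0.98) < 2.5 * focal["se"]
        for other in [("patient", "positive"), ("patient", "negative"), ("control", "negative")]:
            assert abs(cell.loc[other, "estimate"]) < 2.5 * cell.loc[other, "se"]

    def test_no_interaction_means_identical_slopes(self):
        table = toy_table(n_participants=12, n_per_cell=6, planted={"upe": 1.0},
                          resid=1.0, ranef_sd=1.0, seed=9)
        design = code_predictors(table, carry=("y",))
        # model without any upe interactions: slopes cannot vary by level
        spec = MLMSpec(response="y", fixed="group + valence + upe + group:valence",
                       random_terms=())
        res = fit_mlm(design, spec)
        with pytest.raises(ValueError, match="interaction"):
            probe_simple_slopes(res, "upe", ["group"])

    def test_unknown_moderator_rejected(self, planted_fit):
        _, res = planted_fit
        with pytest.raises(ValueError):
            probe_simple_slopes(res, "upe", ["learnability"])


class TestInfluence:
    def test_observation_distances_nonnegative(self):
        table = toy_table(n_participants=12, n_per_cell=4, planted={"1": 5.0}, seed=10)
        design = code_predictors(table, carry=("y",))
        res = fit_mlm(design, MLMSpec(response="y", fixed="group*timing", random_terms=()))
        infl = screen_influence(res)
        assert (infl["cooks_distance"] >= 0).all()
        assert len(infl) == res.nobs

    def test_shifted_participant_flagged_at_participant_level(self):
        table = toy_table(n_participants=16, n_per_cell=6, planted={"1": 5.0}, seed=10)
        shifted = table.copy()
        sd = shifted["y"].std()
        shifted.loc[shifted.participant == "p03", "y"] += 10 * sd
        design = code_predictors(shifted, carry=("y",))
        spec = MLMSpec(response="y", fixed="group*timing", random_terms=())
        res = fit_mlm(design, spec)
        infl = screen_influence(res, level="participant")
        top = infl.set_index("participant")["cooks_distance"]
        assert (top >= 0).all()
        assert top.idxmax() == "p03"
        assert infl.set_index("participant").loc["p03", "flagged"]
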