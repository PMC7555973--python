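"""Tests for the accuracy indices: cells, profiles, aggregation, subscores."""

import math

import numpy as np
import pandas as pd
import pytest

from persacc.data_model import CriterionMatrix, JudgeRecord, RatingScale, RatingsCube
from persacc.scoring import (
    CellCorrelations,
    cell_correlations,
    gender_pairing_accuracy,
    normative_profiles,
    profile_accuracy,
    score_study,
    trait_accuracy,
)
from persacc.simulate import SimulationConfig, simulate_study

from conftest import make_random_cube
from _oracles import bf_pearson, bf_profile_scores


def _cube_from_array(vals, modalities=None, genders=None):
    J, T, A = vals.shape
    targets = [f"t{i}" for i in range(T)]
    traits = [f"a{i}" for i in range(A)]
    cube = RatingsCube(
        [f"j{i}" for i in range(J)],
        targets,
        traits,
        np.asarray(vals, dtype=float),
        np.zeros((J, T), dtype=bool),
        RatingScale(1, 5, integer_grid=False),
    )
    idx = pd.Index(targets, name="target_id")
    rng = np.random.default_rng(0)
    crit = CriterionMatrix(
        pd.DataFrame(rng.uniform(1, 5, (T, A)), index=idx, columns=traits),
        pd.Series(modalities if modalities is not None else ["photo"] * T, index=idx),
        pd.Series(genders if genders is not None else ["female"] * T, index=idx),
    )
    return cube, crit


class TestCellCorrelations:
    def test_perfect_judge_gets_r_one(self, tiny_cube, tiny_criteria):
        tiny_cube.ratings[0] = tiny_criteria.values.to_numpy()
        cells = cell_correlations(tiny_cube, tiny_criteria)
        assert np.allclose(cells.r[0], 1.0)

    def test_constant_rating_vector_undefined(self, tiny_cube, tiny_criteria):
        tiny_cube.ratings[0, :, 0] = 3.0
        cells = cell_correlations(tiny_cube, tiny_criteria)
        assert math.isnan(cells.r[0, 0, 0])

    def test_hand_derived_three_target_cell(self, tiny_cube, tiny_criteria):
        tiny_cube.ratings[0, :, 0] = [1.0, 2.0, 4.0]
        crit = tiny_criteria.values.copy()
        crit["a"] = [2.0, 1.0, 5.0]
        tc = CriterionMatrix(crit, tiny_criteria.modality, tiny_criteria.gender)
        cells = cell_correlations(tiny_cube, tc)
        assert cells.r[0, 0, 0] == pytest.approx(48.0 / math.sqrt(42.0 * 78.0))

    def test_modality_with_too_few_targets_undefined(self):
        vals = np.random.default_rng(1).uniform(1, 5, (1, 4, 3))
        cube, crit = _cube_from_array(
            vals, modalities=["photo", "photo", "mute_video", "mute_video"]
        )
        cells = cell_correlations(cube, crit)
        assert np.isnan(cells.r).all()  # 2 targets per modality < 3


class TestTraitAccuracy:
    def _cells(self, r):
        J, A, M = r.shape
        return CellCorrelations(
            [f"j{i}" for i in range(J)],
            [f"a{i}" for i in range(A)],
            ["photo", "mute_video", "audio_video"][:M],
            r,
            np.full(r.shape, 10, dtype=int),
        )

    def test_constant_cells_aggregate_to_same_value(self):
        scores = trait_accuracy(self._cells(np.full((1, 8, 3), 0.3)))
        assert scores.total.iloc[0] == pytest.approx(0.3)
        assert np.allclose(scores.subscores.iloc[0], 0.3)

    def test_19_of_24_defined_total_missing(self):
        r = np.full((1, 8, 3), 0.3)
        r.ravel()[:5] = np.nan
        scores = trait_accuracy(self._cells(r))
        assert math.isnan(scores.total.iloc[0])

    def test_20_of_24_defined_total_present(self):
        r = np.full((1, 8, 3), 0.3)
        r.ravel()[:4] = np.nan
        scores = trait_accuracy(self._cells(r))
        assert scores.total.iloc[0] == pytest.approx(0.3)
        assert scores.n_available.iloc[0] == 20

    def test_subscore_availability_rule(self):
        r = np.full((1, 8, 3), 0.3)
        r[0, 0, 0] = np.nan  # trait a0 has 2/3 cells -> below 0.8
        scores = trait_accuracy(self._cells(r))
        assert math.isnan(scores.subscores.iloc[0]["trait:a0"])
        # modality photo has 7/8 -> 0.875 passes
        assert scores.subscores.iloc[0]["modality:photo"] == pytest.approx(0.3)


class TestNormativeProfiles:
    def test_grand_mean_rating(self):
        vals = np.array([[[1.0], [3.0]], [[2.0], [4.0]]])  # 2 judges x 2 targets
        cube, crit = _cube_from_array(vals)
        prof = normative_profiles(cube, crit)
        assert prof.normative_rating.iloc[0] == pytest.approx(2.5)
        assert prof.normative_criterion.iloc[0] == pytest.approx(
            crit.values.iloc[:, 0].mean()
        )

    def test_single_judge_single_target(self):
        vals = np.full((1, 1, 2), 4.0)
        cube, crit = _cube_from_array(vals)
        prof = normative_profiles(cube, crit)
        assert (prof.normative_rating == 4.0).all()

    def test_constant_criterion_gives_zero_distinctive_entries(self, tiny_cube, tiny_criteria):
        tiny_criteria.values["a"] = 3.0
        prof = normative_profiles(tiny_cube, tiny_criteria)
        assert (
            tiny_criteria.values["a"] - prof.normative_criterion["a"]
        ).abs().max() == 0.0


class TestProfileAccuracy:
    def test_perfect_judge_hits_clip_ceiling(self, tiny_cube, tiny_criteria):
        tiny_cube.ratings[0] = tiny_criteria.values.to_numpy()
        scores, prof = profile_accuracy(tiny_cube, tiny_criteria, "overall")
        assert np.allclose(prof.r[0], 1.0)
        assert scores.total.iloc[0] == pytest.approx(math.tanh(math.atanh(0.999)))

    def test_normative_rater_has_missing_distinctive(self):
        # both judges give the exact same profile to every target -> their
        # distinctive rating profiles are zero vectors -> all undefined
        base = np.array([2.0, 3.0, 4.0])
        vals = np.tile(base, (2, 3, 1))
        cube, crit = _cube_from_array(vals)
        scores, prof = profile_accuracy(cube, crit, "distinctive")
        assert np.isnan(prof.r).all()
        assert scores.total.isna().all()

    def test_two_trait_profiles_undefined(self):
        vals = np.random.default_rng(2).uniform(1, 5, (1, 3, 2))
        cube, crit = _cube_from_array(vals)
        scores, prof = profile_accuracy(cube, crit, "overall")
        assert np.isnan(prof.r).all()

    def test_unknown_mode_rejected(self, tiny_cube, tiny_criteria):
        with pytest.raises(ValueError):
            profile_accuracy(tiny_cube, tiny_criteria, "semi")


def test_profile_modes_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(40):
        cube, crit = make_random_cube(
            rng,
            n_judges=int(rng.integers(2, 5)),
            n_targets=int(rng.integers(4, 8)),
            n_traits=int(rng.integers(3, 6)),
            missing=0.15,
        )
        for mode in ("overall", "distinctive"):
            scores, _ = profile_accuracy(cube, crit, mode, min_prop=0.5)
            expected = bf_profile_scores(
                cube.values().tolist(), crit.values.to_numpy().tolist(), mode, 0.5
            )
            for j, exp in enumerate(expected):
                got = scores.total.iloc[j]
                if exp is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(exp, abs=1e-10)
                checked += 1
    assert checked >= 100


def test_cells_match_brute_force_oracle():
    rng = np.random.default_rng(43)
    for _ in range(20):
        cube, crit = make_random_cube(rng, 3, 9, 4, missing=0.1)
        cells = cell_correlations(cube, crit)
        vals = cube.values()
        mod = crit.modality.to_numpy()
        for j in range(3):
            for a in range(4):
                for mi, m in enumerate(cells.modalities):
                    sel = mod == m
                    exp = bf_pearson(
                        vals[j, sel, a].tolist(), crit.values.to_numpy()[sel, a].tolist()
                    )
                    got = cells.r[j, a, mi]
                    if exp is None:
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(exp, abs=1e-10)


def test_affine_invariance_of_trait_and_overall():
    """Rescaling one judge's entire rating set leaves trait and overall
    accuracy unchanged (Pearson affine invariance); distinctive is exempt."""
    rng = np.random.default_rng(7)
    cube, crit = make_random_cube(rng, 3, 9, 5, missing=0.0)
    base = score_study(cube, crit)
    cube2 = RatingsCube(
        cube.judges, cube.targets, cube.traits, cube.ratings.copy(), cube.known, cube.scale
    )
    cube2.ratings[1] = 0.5 * cube2.ratings[1] + 1.0
    moved = score_study(cube2, crit)
    for name in ("trait", "overall"):
        pd.testing.assert_series_equal(
            base.indices[name].total, moved.indices[name].total, atol=1e-12
        )


def test_distinctive_equals_overall_when_normative_profiles_flat():
    """With exactly constant normative rating and criterion profiles the
    normative subtraction is a constant shift, so the two modes coincide."""
    rng = np.random.default_rng(8)
    vals1 = rng.uniform(1.5, 4.5, (1, 6, 4))
    vals = np.concatenate([vals1, 6.0 - vals1], axis=0)  # trait means exactly 3
    cube, crit = _cube_from_array(vals)
    # force criterion columns to mean exactly 3 as well
    cvals = crit.values - crit.values.mean(axis=0) + 3.0
    crit = CriterionMatrix(cvals, crit.modality, crit.gender)
    ov, ov_p = profile_accuracy(cube, crit, "overall")
    di, di_p = profile_accuracy(cube, crit, "distinctive")
    np.testing.assert_allclose(ov_p.r, di_p.r, atol=1e-12)


def test_permutation_null_drives_indices_to_zero():
    """Shuffling target identities in the criteria destroys all signal.

    Uses a flat normative criterion profile so that no index retains a
    normative component the shuffle cannot touch.
    """
    cfg = SimulationConfig(seed=77, n_judges=150, normative_criterion=(3.0,) * 8)
    study = simulate_study(cfg)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(study.criteria.targets))
    shuffled = CriterionMatrix(
        pd.DataFrame(
            study.criteria.values.to_numpy()[perm],
            index=study.criteria.values.index,
            columns=study.criteria.values.columns,
        ),
        study.criteria.modality,
        study.criteria.gender,
    )
    res = score_study(study.cube, shuffled)
    for name in ("trait", "overall", "distinctive"):
        tot = res.indices[name].total.dropna()
        se = tot.std(ddof=1) / math.sqrt(len(tot))
        assert abs(tot.mean()) < 3 * se + 1e-9, name


class TestGenderPairing:
    def test_single_gender_equals_unrestricted(self):
        rng = np.random.default_rng(3)
        cube, crit = make_random_cube(rng, 4, 9, 4)
        crit = CriterionMatrix(
            crit.values, crit.modality, pd.Series("female", index=crit.values.index)
        )
        judges = [JudgeRecord(j, "male") for j in cube.judges]
        per_judge, summary = gender_pairing_accuracy(cube, crit, judges, min_prop=0.5)
        full = score_study(cube, crit, min_prop=0.5)
        for name in ("trait", "overall", "distinctive"):
            pd.testing.assert_series_equal(
                per_judge[f"{name}/targets_female"],
                full.indices[name].total,
                atol=1e-12,
                check_names=False,
            )

    def test_pairing_table_structure(self, default_study):
        res = score_study(
            default_study.cube, default_study.criteria, judges=default_study.judges
        )
        _, summary = gender_pairing_accuracy(
            default_study.cube, default_study.criteria, default_study.judges
        )
        assert set(summary["judge_gender"]) == {"male", "female"}
        assert set(summary["target_gender"]) == {"male", "female"}
        assert len(summary) == 12  # 2 x 2 pairings x 3 indices
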