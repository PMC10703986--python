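"""Morris screening: design structure, effects, summaries, classification.

Includes a deliberately independent pure-Python reference implementation
(loops, no shared code with the package) used to cross-validate the
elementary effects and their mu*/sigma summaries.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sctsa as S


# ---------------------------------------------------------------- reference

def reference_morris(matrix, outputs, k, reps):
    """Loop-based reference: find the moved factor of each consecutive row
    pair, accumulate effects, and summarise with plain Python arithmetic."""
    effects = {i: [] for i in range(k)}
    rows_per_traj = k + 1
    for r in range(reps):
        for s in range(k):
            a = matrix[r * rows_per_traj + s]
            b = matrix[r * rows_per_traj + s + 1]
            moved = [i for i in range(k) if a[i] != b[i]]
            assert len(moved) == 1
            i = moved[0]
            effects[i].append(
                (outputs[r * rows_per_traj + s + 1] - outputs[r * rows_per_traj + s])
                / (b[i] - a[i])
            )
    summary = {}
    for i in range(k):
        ee = effects[i]
        mu = sum(ee) / len(ee)
        mu_star = sum(abs(e) for e in ee) / len(ee)
        var = sum((e - mu) ** 2 for e in ee) / (len(ee) - 1)
        summary[i] = (mu, mu_star, math.sqrt(var))
    return summary


FACTORS3 = (
    S.FactorSpec("a", 0.0, 1.0),
    S.FactorSpec("b", 0.0, 1.0),
    S.FactorSpec("c", 0.0, 1.0),
)


# ------------------------------------------------------------------- design

class TestDesign:
    @pytest.mark.parametrize(
        "k,reps,expected", [(3, 50, 200), (5, 40, 240), (2, 10, 30)]
    )
    def test_row_count_arithmetic(self, k, reps, expected):
        factors = tuple(S.FactorSpec(f"f{i}", 0.0, 1.0) for i in range(k))
        design = S.build_design(factors, reps, seed=0)
        assert design.n_rows == reps * (k + 1) == expected

    @given(st.integers(1, 5), st.integers(2, 8), st.integers(0, 1000))
    def test_oat_trajectory_structure(self, k, reps, seed):
        """Consecutive rows differ in exactly one coordinate by |Delta|;
        every factor moves exactly once per trajectory; all coordinates sit
        on the level grid within [0, 1]."""
        factors = tuple(S.FactorSpec(f"f{i}", 0.0, 1.0) for i in range(k))
        design = S.build_design(factors, reps, levels=4, seed=seed)
        grid = np.arange(4) / 3.0
        assert np.all(
            np.min(np.abs(design.matrix[..., None] - grid), axis=-1) < 1e-12
        )
        for traj in design.trajectories():
            moved = []
            for s in range(k):
                diff = traj[s + 1] - traj[s]
                nz = np.flatnonzero(diff != 0)
                assert nz.size == 1
                assert np.isclose(abs(diff[nz[0]]), design.delta)
                moved.append(int(nz[0]))
            assert sorted(moved) == list(range(k))

    def test_same_seed_reproducible(self):
        a = S.build_design(FACTORS3, 10, seed=42)
        b = S.build_design(FACTORS3, 10, seed=42)
        assert np.array_equal(a.matrix, b.matrix)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            S.build_design(FACTORS3, 1)  # too few repetitions
        with pytest.raises(ValueError):
            S.build_design(FACTORS3, 10, levels=3)  # odd level count
        with pytest.raises(ValueError):
            S.build_design((), 10)


class TestDenormalise:
    def test_bounds_and_midpoint(self):
        factors = (S.FactorSpec("hu", -250.0, 250.0),)
        assert S.denormalise(np.array([[0.0]]), factors)[0, 0] == -250.0
        assert S.denormalise(np.array([[1.0]]), factors)[0, 0] == 250.0
        assert S.denormalise(np.array([[0.5]]), factors)[0, 0] == 0.0

    def test_round_trip_identity(self):
        factors = (
            S.FactorSpec("hu", -250.0, 250.0),
            S.FactorSpec("mm", 2.0, 50.0),
        )
        design = S.build_design(factors, 8, seed=3)
        back = S.normalise(S.denormalise(design.matrix, factors), factors)
        assert np.allclose(back, design.matrix, atol=1e-12)


# ------------------------------------------------------------------ effects

class TestElementaryEffects:
    def test_constant_model_gives_zero_effects(self):
        design = S.build_design(FACTORS3, 6, seed=1)
        ee = S.elementary_effects(design, np.full(design.n_rows, 7.0))
        assert np.allclose(ee.to_numpy(), 0.0)

    def test_linear_model_recovers_coefficients(self):
        a = np.array([3.0, -1.0, 0.0])
        design = S.build_design(FACTORS3, 20, seed=9)
        ee = S.elementary_effects(design, design.matrix @ a)
        assert np.allclose(ee["a"], 3.0, atol=1e-10)
        assert np.allclose(ee["b"], -1.0, atol=1e-10)
        assert np.allclose(ee["c"], 0.0, atol=1e-10)

    def test_interaction_model_matches_brute_force(self):
        """f = x1 * x2: effects equal the re-evaluated finite differences."""
        design = S.build_design(FACTORS3, 12, seed=4)
        outputs = design.matrix[:, 0] * design.matrix[:, 1]
        ee = S.elementary_effects(design, outputs)
        ref = reference_morris(
            design.matrix.tolist(), outputs.tolist(), k=3, reps=12
        )
        for i, name in enumerate(["a", "b", "c"]):
            mu, mu_star, sigma = ref[i]
            assert np.isclose(ee[name].mean(), mu, atol=1e-12)
            assert np.isclose(ee[name].abs().mean(), mu_star, atol=1e-12)

    def test_effect_count_per_factor(self):
        design = S.build_design(FACTORS3, 15, seed=2)
        ee = S.elementary_effects(design, np.arange(design.n_rows, dtype=float))
        assert ee.shape == (15, 3)
        assert not ee.isna().any().any()

    def test_non_finite_output_names_offending_row(self):
        design = S.build_design(FACTORS3, 4, seed=0)
        outputs = np.zeros(design.n_rows)
        outputs[5] = np.nan
        with pytest.raises(ValueError, match="row 5"):
            S.elementary_effects(design, outputs)

    def test_misaligned_outputs_rejected(self):
        design = S.build_design(FACTORS3, 4, seed=0)
        with pytest.raises(ValueError):
            S.elementary_effects(design, np.zeros(design.n_rows - 1))


# ---------------------------------------------------------------- summaries

class TestSummaries:
    def test_equal_effects(self):
        s = S.summarise(pd.DataFrame({"f": [2.0, 2.0, 2.0]}))
        assert s.loc["f", "mu"] == 2.0
        assert s.loc["f", "mu_star"] == 2.0
        assert s.loc["f", "sigma"] == 0.0
        assert s.loc["f", "distance"] == 2.0

    def test_opposite_signs_cancel_in_mu_but_not_mu_star(self):
        s = S.summarise(pd.DataFrame({"f": [-2.0, 2.0]}))
        assert s.loc["f", "mu"] == 0.0
        assert s.loc["f", "mu_star"] == 2.0

    def test_hand_arithmetic_example(self):
        s = S.summarise(pd.DataFrame({"f": [1.0, 3.0]}))
        assert s.loc["f", "mu"] == 2.0
        assert np.isclose(s.loc["f", "sigma"], np.sqrt(2.0))
        assert s.loc["f", "mu_star"] == 2.0
        assert np.isclose(s.loc["f", "distance"], np.sqrt(6.0))

    def test_linear_sum_model_summary(self):
        """f = sum a_i x_i: mu = a, mu* = |a|, sigma = 0 for any seed."""
        a = np.array([3.0, -1.0, 0.0])
        for seed in (0, 1, 123):
            design = S.build_design(FACTORS3, 10, seed=seed)
            s = S.summarise(S.elementary_effects(design, design.matrix @ a))
            assert np.allclose(s["mu"], a, atol=1e-10)
            assert np.allclose(s["mu_star"], np.abs(a), atol=1e-10)
            assert np.allclose(s["sigma"], 0.0, atol=1e-10)

    def test_agrees_with_independent_reference(self):
        """mu*/sigma match the loop-based reference on a shared design and
        a nonlinear output, to 1e-10."""
        k, reps = 4, 25
        factors = tuple(S.FactorSpec(f"f{i}", 0.0, 1.0) for i in range(k))
        design = S.build_design(factors, reps, seed=77)
        x = design.matrix
        outputs = np.sin(3 * x[:, 0]) + x[:, 1] * x[:, 2] ** 2 - 0.5 * x[:, 3]
        s = S.summarise(S.elementary_effects(design, outputs))
        ref = reference_morris(x.tolist(), outputs.tolist(), k, reps)
        for i in range(k):
            mu, mu_star, sigma = ref[i]
            assert abs(s.iloc[i]["mu_star"] - mu_star) < 1e-10
            assert abs(s.iloc[i]["sigma"] - sigma) < 1e-10

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30
        )
    )
    def test_summary_invariants(self, ee_values):
        """mu* >= |mu|, sigma >= 0 and D >= max(mu*, sigma) always hold."""
        s = S.summarise(pd.DataFrame({"f": ee_values}))
        row = s.loc["f"]
        assert row["mu_star"] >= abs(row["mu"]) - 1e-12
        assert row["sigma"] >= 0.0
        assert row["distance"] >= max(row["mu_star"], row["sigma"]) - 1e-12

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            S.summarise(pd.DataFrame({"f": [1.0]}))


class TestClassify:
    def _summary(self, rows):
        df = pd.DataFrame(rows, columns=["mu_star", "sigma"])
        df["mu"] = df["mu_star"]
        df["distance"] = np.sqrt(df["mu_star"] ** 2 + df["sigma"] ** 2)
        df.index.name = "factor"
        return df

    def test_zero_effect_factor_is_negligible(self):
        out = S.classify(self._summary([(0.0, 0.0), (10.0, 1.0)]))
        assert out.iloc[0]["label"] == "negligible"

    def test_dispersion_dominated_factor_flags_interaction(self):
        out = S.classify(self._summary([(5.0, 10.0)]))
        assert out.iloc[0]["label"] == "nonlinear-or-interacting"

    def test_mean_dominated_factor_is_linear(self):
        out = S.classify(self._summary([(10.0, 2.0)]))
        assert out.iloc[0]["label"] == "linear/additive"

    def test_ranking_descends_in_distance(self):
        df = self._summary([(3.0, 0.0), (5.0, 0.0), (1.0, 0.0)])
        out = S.classify(df)
        assert list(out["rank"]) == [2, 1, 3]

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            S.classify(self._summary([]).iloc[0:0])
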