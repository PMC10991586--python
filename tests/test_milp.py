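"""MASS MILP construction, solving and structural invariants."""

import numpy as np
import pytest

from mass_select import (
    MASSConfig,
    PhenotypeMatrix,
    build_absolute_loss_model,
    build_hinge_loss_model,
    encode_for_mass,
    enumerate_subsets,
    objective_decompose,
    solve,
)
from mass_select.milp import solve_fixed_z
from conftest import make_encoded, random_pm_one


def hinge_cfg(p, lam=0.0, **kw):
    return MASSConfig(p=p, sparsity_weight=lam, loss="hinge", **kw)


class TestTrivialOptima:
    def test_duplicate_column_zero_objective(self):
        rng = np.random.default_rng(0)
        v = rng.choice([-1.0, 1.0], size=10)
        X = make_encoded(np.column_stack([v, v, rng.choice([-1.0, 1.0], size=10)]))
        sol = solve(build_hinge_loss_model(X, hinge_cfg(1)))
        assert sol.objective == pytest.approx(0.0, abs=1e-8)
        assert sol.predictor_groups[0] in ("a0", "a1")

    def test_all_predictors_zero_loss(self):
        rng = np.random.default_rng(1)
        X = make_encoded(rng.choice([-1.0, 1.0], size=(8, 4)))
        sol = solve(build_hinge_loss_model(X, hinge_cfg(4)))
        assert sol.loss_term == pytest.approx(0.0, abs=1e-8)
        Xa = make_encoded(rng.normal(size=(8, 4)), domain="real")
        cfg = MASSConfig(p=4, sparsity_weight=0.0, loss="absolute")
        sol = solve(build_absolute_loss_model(Xa, cfg))
        assert sol.loss_term == pytest.approx(0.0, abs=1e-8)

    def test_budget_exceeds_units_errors(self):
        X = make_encoded(np.ones((3, 2)) * np.array([[1, -1]] * 3))
        with pytest.raises(ValueError, match="budget"):
            build_hinge_loss_model(X, hinge_cfg(3))


class TestGroupConstraint:
    def test_grouped_dummies_share_indicator(self):
        rng = np.random.default_rng(2)
        levels = ["negative", "weak", "positive"]
        vals = np.array(rng.choice(levels, size=(12, 3)), dtype=object)
        mat = PhenotypeMatrix(
            [f"s{i}" for i in range(12)], ["c1", "c2", "c3"], vals, level_set=levels
        )
        enc = encode_for_mass(mat, drop_level="negative")
        sol = solve(build_hinge_loss_model(enc, hinge_cfg(1, lam=1e-3)))
        fg = enc.feature_to_group()
        for g in range(len(enc.groups)):
            vals_g = sol.predictor_indicator[fg == g]
            assert vals_g.all() or (~vals_g).all()

    def test_per_group_budget_counts_attributes(self):
        rng = np.random.default_rng(3)
        levels = ["negative", "weak", "positive"]
        col = rng.choice(levels, size=10)
        vals = np.array(np.column_stack([col, col, col]), dtype=object)
        mat = PhenotypeMatrix(
            [f"s{i}" for i in range(10)], ["c1", "c2", "c3"], vals, level_set=levels
        )
        enc = encode_for_mass(mat, drop_level="negative")
        # p=1 selects one whole attribute (two dummy features)
        sol = solve(build_hinge_loss_model(enc, hinge_cfg(1, lam=1e-3)))
        assert sol.group_indicator.sum() == 1
        assert sol.predictor_indicator.sum() == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("lam", [0.0, 1e-3])
    def test_hinge_matches_enumeration(self, seed, lam):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(10, 25)), int(rng.integers(4, 7))
        X = random_pm_one(rng, n, m)
        cfg = hinge_cfg(int(rng.integers(1, 4)), lam=lam)
        sol = solve(build_hinge_loss_model(X, cfg))
        best, _ = enumerate_subsets(X, cfg)
        assert sol.objective == pytest.approx(best.objective, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_absolute_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = make_encoded(rng.normal(size=(10, 4)), domain="real")
        cfg = MASSConfig(p=2, sparsity_weight=0.0, loss="absolute")
        sol = solve(build_absolute_loss_model(X, cfg))
        best, _ = enumerate_subsets(X, cfg)
        assert sol.objective == pytest.approx(best.objective, abs=1e-6)


class TestSolutionInvariants:
    @pytest.fixture
    def solved(self):
        rng = np.random.default_rng(9)
        X = random_pm_one(rng, 20, 6)
        cfg = hinge_cfg(2, lam=1e-3)
        return X, cfg, solve(build_hinge_loss_model(X, cfg))

    def test_nonpredictor_coefficients_zero(self, solved):
        X, cfg, sol = solved
        non_pred = ~sol.predictor_indicator
        assert np.abs(sol.coefficients[non_pred, :]).max(initial=0.0) <= 1e-7 * cfg.big_m

    def test_budget_respected(self, solved):
        _, cfg, sol = solved
        assert sol.group_indicator.sum() <= cfg.p

    def test_decomposition_matches(self, solved):
        X, cfg, sol = solved
        loss, penalty, per_resp = objective_decompose(sol, X, cfg)
        assert loss + cfg.sparsity_weight * penalty == pytest.approx(
            sol.objective, abs=1e-6
        )
        assert sum(per_resp.values()) == pytest.approx(loss, abs=1e-12)
        assert set(per_resp) == {
            f for f, on in zip(X.feature_ids, sol.predictor_indicator) if not on
        }

    def test_decompose_shape_mismatch(self, solved):
        X, cfg, sol = solved
        bad = make_encoded(X.values[:, :3])
        with pytest.raises(ValueError):
            objective_decompose(sol, bad, cfg)

    def test_monotone_in_p(self):
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            X = random_pm_one(rng, 15, 5)
            objs = [
                solve(build_hinge_loss_model(X, hinge_cfg(p))).objective
                for p in range(1, 5)
            ]
            assert all(objs[i + 1] <= objs[i] + 1e-8 for i in range(len(objs) - 1))

    def test_deterministic_resolve(self):
        rng = np.random.default_rng(5)
        X = random_pm_one(rng, 15, 5)
        cfg = hinge_cfg(2, lam=1e-3)
        a = solve(build_hinge_loss_model(X, cfg))
        b = solve(build_hinge_loss_model(X, cfg))
        assert a.objective == b.objective


class TestWarmStartAndFailure:
    def test_warm_start_incumbent_property(self):
        rng = np.random.default_rng(6)
        X = random_pm_one(rng, 15, 5)
        cfg = hinge_cfg(2)
        warm = np.array([True, True, False, False, False])
        warm_obj = solve_fixed_z(build_hinge_loss_model(X, cfg), warm).objective
        sol = solve(build_hinge_loss_model(X, cfg), warm_start=warm)
        assert sol.objective <= warm_obj + 1e-8

    def test_infeasible_reported(self):
        rng = np.random.default_rng(7)
        X = random_pm_one(rng, 8, 3)
        model = build_hinge_loss_model(X, hinge_cfg(1))
        # contradictory support requirement: at least 2 predictors under p=1
        model.add_row([model.i_z(g) for g in range(3)], [1.0] * 3, 2.0, np.inf)
        sol = solve(model)
        assert sol.status == "infeasible"

    def test_wrong_domain_rejected(self):
        X = make_encoded(np.array([[0.5, 1.0], [1.0, -1.0]]), domain="real")
        with pytest.raises(ValueError):
            build_hinge_loss_model(X, hinge_cfg(1))
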