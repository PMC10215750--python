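"""AI-REML against closed-form, brute-force and calibration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import ssgblup as sg
from ssgblup.mixed_model import ModelSpec, VarianceComponents, build_design
from ssgblup.reml import ai_reml, derived_parameters, se_from_ai

def _single_trait_design(ph, ped):
    spec = ModelSpec(traits=("y",), factors=(), age_col=None, include_pe=False)
    return build_design(ph, ped, spec)


class TestOracles:
    def test_balanced_oneway_equals_anova_reml(self):
        """Balanced one-way layout with K=I: REML equals the between/within
        mean-square closed form."""
        rng = np.random.default_rng(0)
        c, m = 12, 5
        ped = sg.Pedigree.from_records([(f"C{i}", None, None) for i in range(c)])
        rows = []
        for cid in ped.ids:
            u = rng.normal(0, 2.0)
            for _ in range(m):
                rows.append({"cow_id": cid, "y": 3.0 + u + rng.normal(0, 1.5)})
        d = _single_trait_design(pd.DataFrame(rows), ped)
        res = ai_reml(d, tol=1e-10, compute_se=False)
        arr = (
            pd.DataFrame(rows)
            .groupby("cow_id")["y"]
            .apply(np.array)
            .to_numpy()
        )
        arr = np.stack(arr)
        msw = ((arr - arr.mean(1, keepdims=True)) ** 2).sum() / (c * (m - 1))
        msb = m * ((arr.mean(1) - arr.mean()) ** 2).sum() / (c - 1)
        assert res.vc.Ga[0, 0] == pytest.approx((msb - msw) / m, rel=1e-6)
        assert res.vc.Re[0, 0] == pytest.approx(msw, rel=1e-6)

    def test_tiny_instance_matches_numeric_maximum(self):
        """On <= 8 records the REML optimum equals direct numeric
        maximization of the restricted likelihood built from V."""
        rng = np.random.default_rng(1)
        ped = sg.Pedigree.from_records([(f"C{i}", None, None) for i in range(4)])
        rows = [
            {"cow_id": cid, "y": rng.normal(5, 2)}
            for cid in ped.ids
            for _ in range(2)
        ]
        d = _single_trait_design(pd.DataFrame(rows), ped)
        res = ai_reml(d, tol=1e-12, compute_se=False)
        X, y, Z = d.X0, d.y[:, 0], d.Z0.toarray()
        n = len(y)

        def m2ll(th):
            V = th[0] * (Z @ Z.T) + th[1] * np.eye(n)
            Vi = np.linalg.inv(V)
            XVX = X.T @ Vi @ X
            b = np.linalg.solve(XVX, X.T @ Vi @ y)
            return (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XVX)[1]
                + (y - X @ b) @ Vi @ y
            )

        opt = optimize.minimize(
            m2ll, [1.0, 1.0], bounds=[(1e-8, None)] * 2, tol=1e-14
        )
        assert res.vc.Ga[0, 0] == pytest.approx(opt.x[0], abs=1e-4)
        assert res.vc.Re[0, 0] == pytest.approx(opt.x[1], abs=1e-4)

    def test_score_near_zero_at_truth_on_large_balanced_data(self):
        """Starting at the simulation truth, the REML gradient is far
        smaller than at a doubled-variance point (score sanity)."""
        from ssgblup.mixed_model import MMESystem
        from ssgblup.reml import _REMLWork

        rng = np.random.default_rng(2)
        c, m = 400, 8
        ped = sg.Pedigree.from_records([(f"C{i}", None, None) for i in range(c)])
        va, ve = 4.0, 8.0
        rows = []
        for cid in ped.ids:
            u = rng.normal(0, np.sqrt(va))
            for _ in range(m):
                rows.append({"cow_id": cid, "y": 3.0 + u + rng.normal(0, np.sqrt(ve))})
        d = _single_trait_design(pd.DataFrame(rows), ped)
        sys = MMESystem(d)
        truth = VarianceComponents(Ga=va, Gpe=None, Re=ve)
        w = _REMLWork(sys, truth)
        s_truth, _ = w.score_and_ai(w.stats())
        off = VarianceComponents(Ga=2 * va, Gpe=None, Re=2 * ve)
        w2 = _REMLWork(sys, off)
        s_off, _ = w2.score_and_ai(w2.stats())
        assert np.linalg.norm(s_truth) < 0.2 * np.linalg.norm(s_off)


@pytest.fixture(scope="module")
def fitted():
    from ssgblup.simulate import SimSpec, simulate_dataset

    spec = SimSpec(n_cows=120, mean_flushes=8.0, n_markers=0, seed=77)
    data = simulate_dataset(spec, effect_matrix="A")
    d = build_design(data.phenotypes, data.pedigree)
    K_inv = sg.build_A_inverse(data.pedigree)
    _, ld = np.linalg.slogdet(data.K.values)
    res = ai_reml(d, K_inv=K_inv, logdet_K=ld, max_iter=60)
    return data, d, res


class TestTwoTraitBehaviour:
    def test_likelihood_never_decreases(self, fitted):
        _, _, res = fitted
        trace = np.array(res.loglik_trace)  # -2 logL per iteration
        assert (np.diff(trace) <= 1e-8).all()

    def test_estimates_in_plausible_range(self, fitted):
        data, _, res = fitted
        h2 = res.vc.heritability()
        assert (h2 > 0.02).all() and (h2 < 0.7).all()
        assert res.se is not None and all(v > 0 for v in res.se.values())

    def test_record_order_and_coding_invariance(self, fitted):
        data, d, res = fitted
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data.phenotypes))
        ph2 = data.phenotypes.iloc[perm].reset_index(drop=True)
        d2 = build_design(ph2, data.pedigree)
        K_inv = sg.build_A_inverse(data.pedigree)
        _, ld = np.linalg.slogdet(data.K.values)
        res2 = ai_reml(d2, K_inv=K_inv, logdet_K=ld, compute_se=False,
                       max_iter=60)
        assert np.allclose(res2.vc.Ga, res.vc.Ga, rtol=1e-4, atol=1e-6)
        assert np.allclose(res2.vc.Re, res.vc.Re, rtol=1e-4, atol=1e-6)


class TestDerivedParameters:
    def test_reference_component_arithmetic(self):
        """Published pedigree-matrix components for TNE (28.07 additive,
        10.87 permanent-environment, 68.15 residual) give h2 = 0.26 and
        repeatability = 0.36 to the printed rounding."""
        vc = VarianceComponents(
            Ga=np.array([[28.07, 8.2526], [8.2526, 5.57]]),
            Gpe=np.array([[10.87, 0.0], [0.0, 3.63]]),
            Re=np.array([[68.15, 0.0], [0.0, 26.32]]),
        )
        der = derived_parameters(vc)
        assert der["h2_tne"] == pytest.approx(0.26, abs=0.005)
        assert der["repeatability_tne"] == pytest.approx(0.36, abs=0.005)

    def test_zero_covariance_zero_correlation(self):
        vc = VarianceComponents(
            Ga=np.diag([4.0, 2.0]), Gpe=np.diag([1.0, 1.0]),
            Re=np.diag([5.0, 5.0]),
        )
        assert derived_parameters(vc)["genetic_correlation"] == 0.0

    def test_genetic_correlation_round_trip(self):
        cov = 0.66 * np.sqrt(28.07 * 5.57)
        vc = VarianceComponents(
            Ga=np.array([[28.07, cov], [cov, 5.57]]),
            Gpe=np.diag([10.87, 3.63]),
            Re=np.diag([68.15, 26.32]),
        )
        assert derived_parameters(vc)["genetic_correlation"] == pytest.approx(
            0.66
        )


class TestStandardErrors:
    def test_diagonal_information_toy(self):
        """With a diagonal information matrix, SE = 1/sqrt(information)."""
        vc = VarianceComponents(Ga=2.0, Gpe=None, Re=3.0)
        ai = np.diag([4.0, 25.0])
        se, derived, dse = se_from_ai(ai, vc, ["var_a_y", "var_e_y"], False)
        assert se["var_a_y"] == pytest.approx(0.5)
        assert se["var_e_y"] == pytest.approx(0.2)

    def test_delta_method_matches_analytic_ratio(self):
        """SE of h2 = va/(va+ve) from the delta method equals the analytic
        gradient-based value on a toy covariance."""
        va, ve = 2.0, 6.0
        vc = VarianceComponents(Ga=va, Gpe=None, Re=ve)
        cov = np.array([[0.09, 0.01], [0.01, 0.16]])
        ai = np.linalg.inv(cov)
        _, derived, dse = se_from_ai(ai, vc, ["var_a_y", "var_e_y"], False)
        tot = va + ve
        g = np.array([ve / tot**2, -va / tot**2])
        want = np.sqrt(g @ cov @ g)
        key = [k for k in dse if k.startswith("h2")][0]
        assert dse[key] == pytest.approx(want, rel=1e-4)

    def test_se_calibration_against_replicate_spread(self):
        """Mean reported SE of h2 within a factor of 1.5 of the empirical
        SD of estimates across simulation replicates."""
        from ssgblup.simulate import SimSpec, simulate_dataset

        ests, ses = [], []
        for s in range(15):
            spec = SimSpec(n_cows=150, mean_flushes=8.0, n_markers=0,
                           seed=4000 + s)
            data = simulate_dataset(spec, effect_matrix="A")
            d = build_design(data.phenotypes, data.pedigree)
            K_inv = sg.build_A_inverse(data.pedigree)
            _, ld = np.linalg.slogdet(data.K.values)
            res = ai_reml(d, K_inv=K_inv, logdet_K=ld, max_iter=50)
            ests.append(res.vc.heritability()[0])
            ses.append(res.derived_se["h2_tne"])
        ratio = np.mean(ses) / np.std(ests, ddof=1)
        assert 1 / 1.5 < ratio < 1.5
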