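"""Generator structure, Mendelian inheritance, and model-implied moments."""

import numpy as np
import pytest

import ssgblup as sg
from ssgblup.simulate import (
    SimSpec,
    donor_cow_components,
    gene_drop,
    simulate_dataset,
    simulate_effects,
    simulate_effects_from_markers,
    simulate_pedigree,
    simulate_records,
)


class TestComponents:
    def test_pedigree_mode_derived_values(self):
        vc = donor_cow_components("A")
        assert vc.heritability() == pytest.approx([0.262, 0.157], abs=0.001)
        assert vc.repeatability() == pytest.approx([0.364, 0.259], abs=0.001)
        assert vc.genetic_correlation() == pytest.approx(0.66)

    def test_single_step_mode_derived_values(self):
        vc = donor_cow_components("H")
        assert vc.heritability() == pytest.approx([0.183, 0.113], abs=0.001)
        assert vc.genetic_correlation() == pytest.approx(0.61)


class TestSimulatePedigree:
    def test_one_generation_founders_only(self):
        sim = simulate_pedigree(SimSpec(n_cows=30, n_generations=1, seed=0))
        assert sim.pedigree.n == len(sim.pedigree.founders)
        assert len(sim.cows) == 30

    def test_sires_come_from_prior_generations(self):
        spec = SimSpec(n_cows=90, n_generations=3, sires_per_generation=10,
                       introduced_fraction=0.0, seed=1)
        sim = simulate_pedigree(spec)
        ped = sim.pedigree
        for k, a in enumerate(ped.ids):
            if not a.startswith(("C0", "S0")):
                assert ped.sire[k] >= 0
                assert ped.ids[ped.sire[k]].startswith("S")

    def test_introduced_cows_have_hidden_parents(self):
        spec = SimSpec(n_cows=120, introduced_fraction=0.3, seed=2)
        sim = simulate_pedigree(spec)
        rec_founders = set(sim.pedigree.founders)
        introduced = [c for c in sim.cows if c in rec_founders]
        assert introduced, "expected some introduced cows"
        tp = sim.true_pedigree
        for c in introduced:
            k = tp.index_of([c])[0]
            assert tp.sire[k] >= 0  # truly sired by a pool sire

    def test_passes_reader_validation(self, tmp_path):
        import ssgblup.io as sio

        sim = simulate_pedigree(SimSpec(n_cows=60, seed=3))
        sio.write_pedigree(sim.pedigree, tmp_path / "p.csv")
        ped = sio.read_pedigree(tmp_path / "p.csv")
        assert ped.n == sim.pedigree.n


class TestGeneDrop:
    def test_fixed_allele_gives_dosage_two(self):
        sim = simulate_pedigree(SimSpec(n_cows=20, seed=4))
        spec = SimSpec(n_cows=20, n_markers=5, seed=4,
                       founder_freq_range=(0.999999, 0.999999))
        gm, p = gene_drop(sim.true_pedigree, spec)
        assert np.all(gm.dosages == 2.0)

    def test_opposite_homozygote_parents_give_heterozygote(self):
        ped = sg.Pedigree.from_records(
            [("S", None, None), ("D", None, None), ("O", "S", "D")]
        )
        for seed in range(30):
            spec = SimSpec(n_cows=2, n_markers=50, seed=seed)
            gm, _ = gene_drop(ped, spec)
            s, d, o = gm.dosages
            both_homo = (s == 2) & (d == 0) | (s == 0) & (d == 2)
            assert np.all(o[both_homo] == 1.0)

    def test_het_by_het_segregation_ratio(self):
        """Offspring of two heterozygotes: dosages 0/1/2 in 1:2:1."""
        ped = sg.Pedigree.from_records(
            [("S", None, None), ("D", None, None), ("O", "S", "D")]
        )
        counts = np.zeros(3)
        n = 0
        for seed in range(500):
            spec = SimSpec(n_cows=2, n_markers=20, seed=seed)
            gm, _ = gene_drop(ped, spec)
            s, d, o = gm.dosages
            het = (s == 1) & (d == 1)
            for dose in o[het]:
                counts[int(dose)] += 1
                n += 1
        freq = counts / n
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * 0.75 / n)
        assert np.all(np.abs(freq - [0.25, 0.5, 0.25]) < 4 * se)

    def test_missingness_rate_applied(self):
        sim = simulate_pedigree(SimSpec(n_cows=40, seed=5))
        spec = SimSpec(n_cows=40, n_markers=200, missing_rate=0.05, seed=5)
        gm, _ = gene_drop(sim.true_pedigree, spec)
        miss = np.isnan(gm.dosages).mean()
        assert 0.03 < miss < 0.07


class TestSimulateEffects:
    def test_zero_variance_gives_zero(self):
        ped = sg.Pedigree.from_records([("a", None, None), ("b", None, None)])
        A = sg.build_A(ped)
        a = simulate_effects(A, np.zeros((2, 2)), seed=0)
        assert np.all(a == 0.0)

    def test_identity_K_diagonal_Ga_moments(self):
        Ga = np.diag([4.0, 9.0])
        acc = np.zeros(2)
        cross = 0.0
        reps = 400
        for r in range(reps):
            a = simulate_effects(np.eye(50), Ga, seed=r)
            acc += (a**2).mean(axis=0)
            cross += (a[:, 0] * a[:, 1]).mean()
        var = acc / reps
        assert var == pytest.approx([4.0, 9.0], rel=0.1)
        assert abs(cross / reps) < 0.2

    def test_covariance_is_Ga_kron_A(self, trio_ped):
        A = sg.build_A(trio_ped)
        Ga = np.array([[4.0, 1.5], [1.5, 2.0]])
        acc = np.zeros((6, 6))
        reps = 1500
        for r in range(reps):
            a = simulate_effects(A, Ga, seed=r)
            v = a.T.ravel()
            acc += np.outer(v, v)
        want = np.kron(Ga, A.values)
        assert np.abs(acc / reps - want).max() < 0.05 * np.abs(want).max() + 0.15

    def test_marker_effects_scale_to_Ga(self):
        rng = np.random.default_rng(0)
        m = 3000
        p = rng.uniform(0.2, 0.8, m)
        dos = rng.binomial(2, p, size=(200, m)).astype(float)
        Ga = np.array([[28.07, 8.25], [8.25, 5.57]])
        a = simulate_effects_from_markers(dos, p, Ga, seed=1)
        emp = np.cov(a.T)
        assert np.allclose(np.diag(emp), np.diag(Ga), rtol=0.25)


class TestSimulateRecords:
    def test_zero_variances_give_fixed_means(self):
        vc = sg.VarianceComponents(
            Ga=np.zeros((2, 2)), Gpe=np.zeros((2, 2)), Re=np.zeros((2, 2))
        )
        # bypass the PD check through direct construction
        spec = SimSpec(n_cows=10, mean_flushes=3.0, n_markers=0, seed=6,
                       fixed_effect_sd=(0.0, 0.0), age_beta=(0.0, 0.0),
                       age_beta2=(0.0, 0.0))
        spec.vc = vc
        sim = simulate_pedigree(spec)
        a = np.zeros((sim.pedigree.n, 2))
        ph = simulate_records(sim, a, spec)
        assert np.allclose(ph["tne"], 16.3)
        assert np.allclose(ph["nge"], 6.7)

    def test_flush_count_mean(self):
        spec = SimSpec(n_cows=400, n_generations=1, mean_flushes=13.5,
                       n_markers=0, seed=7)
        sim = simulate_pedigree(spec)
        a = np.zeros((sim.pedigree.n, 2))
        ph = simulate_records(sim, a, spec)
        per_cow = ph.groupby("cow_id").size()
        se = per_cow.std() / np.sqrt(len(per_cow))
        assert abs(per_cow.mean() - 13.5) < 4 * se

    def test_phenotypic_variance_decomposition(self):
        """Record variance matches sigma2_a + sigma2_pe + sigma2_e plus the
        fixed-effect contribution at large n."""
        spec = SimSpec(n_cows=1000, n_generations=1, mean_flushes=6.0,
                       n_markers=0, seed=8, fixed_effect_sd=(0.0, 0.0),
                       age_beta=(0.0, 0.0), age_beta2=(0.0, 0.0))
        sim = simulate_pedigree(spec)
        A = sg.build_A(sim.pedigree)
        a = simulate_effects(A, spec.vc.Ga, seed=8)
        ph = simulate_records(sim, a, spec)
        want = np.diag(spec.vc.total())
        got = ph[["tne", "nge"]].var().to_numpy()
        assert np.allclose(got, want, rtol=0.05)

    def test_intraclass_correlation_matches_repeatability(self):
        """Within-cow correlation of repeated records equals the
        generative repeatability at study shape."""
        spec = SimSpec(n_cows=800, n_generations=1, mean_flushes=13.5,
                       n_markers=0, seed=9, fixed_effect_sd=(0.0, 0.0),
                       age_beta=(0.0, 0.0), age_beta2=(0.0, 0.0))
        sim = simulate_pedigree(spec)
        A = sg.build_A(sim.pedigree)
        a = simulate_effects(A, spec.vc.Ga, seed=9)
        ph = simulate_records(sim, a, spec)
        for col, want in zip(("tne", "nge"), spec.vc.repeatability()):
            g = ph.groupby("cow_id")[col]
            n_i = g.size().to_numpy()
            m_i = g.mean().to_numpy()
            grand = ph[col].mean()
            msw = ((ph[col] - g.transform("mean")) ** 2).sum() / (
                len(ph) - len(m_i)
            )
            n0 = (len(ph) - (n_i**2).sum() / len(ph)) / (len(m_i) - 1)
            msb = (n_i * (m_i - grand) ** 2).sum() / (len(m_i) - 1)
            vb = (msb - msw) / n0
            assert vb / (vb + msw) == pytest.approx(want, abs=0.02)

    def test_count_mode_respects_trait_definitions(self):
        spec = SimSpec(n_cows=50, mean_flushes=5.0, n_markers=0,
                       count_traits=True, seed=10)
        data = simulate_dataset(spec)
        ph = data.phenotypes
        assert (ph["tne"] >= 0).all() and (ph["nge"] >= 0).all()
        assert (ph["nge"] <= ph["tne"]).all()
        assert np.allclose(ph["tne"], np.round(ph["tne"]))


class TestSubstreams:
    def test_stages_reproducible_and_independent(self):
        s1 = simulate_pedigree(SimSpec(n_cows=40, seed=11))
        s2 = simulate_pedigree(SimSpec(n_cows=40, seed=11))
        assert s1.pedigree.ids == s2.pedigree.ids
        d1 = simulate_dataset(SimSpec(n_cows=40, n_markers=100, seed=11))
        d2 = simulate_dataset(SimSpec(n_cows=40, n_markers=100, seed=11))
        assert np.array_equal(d1.genotypes.dosages, d2.genotypes.dosages)
        assert np.allclose(d1.phenotypes["tne"], d2.phenotypes["tne"])
        d3 = simulate_dataset(SimSpec(n_cows=40, n_markers=100, seed=12))
        assert d1.phenotypes["tne"].sum() != d3.phenotypes["tne"].sum()
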