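"""Shared fixtures: small pedigrees, oracles, and one mid-size dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.simulate import SimSpec, simulate_dataset


@pytest.fixture
def trio_ped() -> sg.Pedigree:
    """Sire, dam, offspring."""
    return sg.Pedigree.from_records(
        [("S", None, None), ("D", None, None), ("O", "S", "D")]
    )


@pytest.fixture
def fullsib_mating_ped() -> sg.Pedigree:
    """Full sibs B1, B2 mated; X is inbred with F = 0.25."""
    return sg.Pedigree.from_records(
        [
            ("S", None, None),
            ("D", None, None),
            ("B1", "S", "D"),
            ("B2", "S", "D"),
            ("X", "B1", "B2"),
        ]
    )


def random_pedigree(n: int, seed: int, n_founders: int | None = None) -> sg.Pedigree:
    """Random valid pedigree with some unknown parents."""
    rng = np.random.default_rng(seed)
    nf = n_founders or max(2, n // 5)
    recs = [(f"A{i}", None, None) for i in range(nf)]
    for i in range(nf, n):
        s = f"A{rng.integers(i)}" if rng.random() < 0.9 else None
        d = f"A{rng.integers(i)}" if rng.random() < 0.9 else None
        if s == d:
            d = None
        recs.append((f"A{i}", s, d))
    return sg.Pedigree.from_records(recs)


def coancestry_oracle(ped: sg.Pedigree) -> np.ndarray:
    """2 x kinship by naive recursive coancestry; independent of build_A."""
    n = ped.n
    cache: dict[tuple[int, int], float] = {}

    def f(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a < b:
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        if a == b:
            val = 0.5 * (1.0 + f(ped.sire[a], ped.dam[a]))
        else:
            # a is the younger individual (larger index): recurse on its parents
            val = 0.5 * (f(ped.sire[a], b) + f(ped.dam[a], b))
        cache[key] = val
        return val

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * f(i, j)
    return A


@pytest.fixture(scope="session")
def small_sim() -> sg.SimulatedData:
    """One mid-size synthetic dataset reused across read-only tests."""
    spec = SimSpec(n_cows=200, mean_flushes=6.0, n_markers=1000, seed=42)
    return simulate_dataset(spec, effect_matrix="A")


@pytest.fixture(scope="session")
def small_matrices(small_sim):
    """A, A^-1, G, A22, G*, H, H^-1 for the session dataset."""
    import ssgblup.genotype as gq
    import ssgblup.hmatrix as hm

    ped = small_sim.pedigree
    A = sg.build_A(ped)
    A_inv = sg.build_A_inverse(ped)
    g1, _ = gq.qc_samples(small_sim.genotypes)
    g2, _ = gq.qc_markers(g1)
    fr = gq.allele_frequencies(g2)
    g3 = gq.impute_missing(g2, fr)
    G = gq.build_G(g3, fr)
    A22 = sg.extract_A22(A, G.ids)
    Gstar = hm.blend_G(G, A22)
    H = hm.build_H(A, Gstar)
    H_inv = hm.build_H_inverse(A_inv, Gstar, A22, A.index_of(G.ids))
    return {
        "A": A,
        "A_inv": A_inv,
        "G": G,
        "A22": A22,
        "Gstar": Gstar,
        "H": H,
        "H_inv": H_inv,
    }


def toy_phenotypes(ped: sg.Pedigree, cows, rng, n_rec=(1, 4)) -> pd.DataFrame:
    """Small random flush table for MME tests.

    Factor levels cycle deterministically so tiny instances never alias;
    trait values and ages are random.
    """
    rows = []
    i = 0
    for c in cows:
        for _ in range(rng.integers(*n_rec)):
            rows.append(
                {
                    "cow_id": c,
                    "tne": rng.normal(16, 5),
                    "nge": rng.normal(7, 3),
                    "year": str(2015 + i % 2),
                    "month": str(1 + i % 3),
                    "program": "P1",
                    "technician": "T1",
                    "age_months": rng.uniform(24, 70),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def gls_oracle(d, Kv, vc):
    """Dense generalized-least-squares solve of the stacked system."""
    t = d.n_traits
    X = np.kron(np.eye(t), d.X0)
    Z = np.kron(np.eye(t), d.Z0.toarray())
    y = d.y.T.ravel()
    V = Z @ np.kron(vc.Ga, Kv) @ Z.T + np.kron(
        vc.Re, np.eye(d.n_records)
    )
    if d.W0 is not None:
        W = np.kron(np.eye(t), d.W0.toarray())
        V += W @ np.kron(vc.Gpe, np.eye(d.c)) @ W.T
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = np.kron(vc.Ga, Kv) @ Z.T @ Vi @ (y - X @ b)
    return b, u
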