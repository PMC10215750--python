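"""Synthetic donor-herd data with the statistical structure the model assumes.

The generator emulates an embryo-transfer donor population of the kind
the pipeline targets: a multi-generation pedigree with a small number of
heavily used sires, donor cows partly introduced from outside with no
recorded parents, a genotyped subset of the phenotyped cows, unlinked
biallelic markers gene-dropped through the pedigree, and two correlated
superovulatory response traits (TNE: total embryos/oocytes per flush;
NGE: good embryos per flush) with repeated flush records generated under
the repeatability animal model

    y = X b + Z a + W pe + e,   var(a) = Ga (x) K,
    var(pe) = Gpe (x) I,        var(e) = Re (x) I.

Default trait means (16.3, 6.7), flush intensity (13.5 flushes per cow)
and (co)variance truth match the published estimates for Japanese Black
donor cows; the default additive truth can be generated from the
pedigree matrix A, the single-step matrix H, or marker effects.

All randomness flows from a single seed through named substreams
(pedigree / genotype / effects / records), so each stage is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .matrices import RelationshipMatrix
from .mixed_model import VarianceComponents
from .pedigree import UNKNOWN, Pedigree

_STREAMS = {"pedigree": 0, "genotype": 1, "effects": 2, "records": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


def donor_cow_components(matrix: str = "A") -> VarianceComponents:
    """Reference (co)variance components for TNE and NGE in donor cows.

    ``matrix`` selects the component set estimated with the pedigree
    relationship matrix ("A") or the single-step matrix ("H").  The
    additive covariance is set from the corresponding genetic
    correlation (0.66 for A, 0.61 for H).  Permanent-environment and
    residual cross-trait correlations are not published for these
    traits; 0.5 is used as a realistic default for a part-whole trait
    pair and does not affect heritability or repeatability.
    """
    if matrix == "A":
        va = np.array([28.07, 5.57])
        vpe = np.array([10.87, 3.63])
        ve = np.array([68.15, 26.32])
        rg = 0.66
    elif matrix == "H":
        va = np.array([19.19, 3.99])
        vpe = np.array([17.49, 4.93])
        ve = np.array([68.16, 26.32])
        rg = 0.61
    else:
        raise ValueError("matrix must be 'A' or 'H'")
    r_pe = r_e = 0.5

    def block(v, r):
        c = r * math.sqrt(v[0] * v[1])
        return np.array([[v[0], c], [c, v[1]]])

    return VarianceComponents(
        Ga=block(va, rg), Gpe=block(vpe, r_pe), Re=block(ve, r_e)
    )


@dataclass
class SimSpec:
    """Study-shaped simulation conditions.

    Defaults scale the real donor herd down to desk size while keeping
    its statistical shape: a few heavily used sires per generation, a
    fraction of donors introduced with unknown parents, ~40% of the
    phenotyped cows genotyped, 13.5 flushes per cow on average, trait
    means (16.3, 6.7) and the published component estimates as truth.
    """

    n_cows: int = 600
    n_generations: int = 3
    sires_per_generation: int = 8
    introduced_fraction: float = 0.15
    genotyped_fraction: float = 0.4
    n_markers: int = 2000
    founder_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.0
    mean_flushes: float = 13.5
    trait_means: tuple = (16.3, 6.7)
    vc: VarianceComponents = field(
        default_factory=lambda: donor_cow_components("A")
    )
    n_years: int = 10
    n_months: int = 12
    n_programs: int = 3
    n_technicians: int = 5
    fixed_effect_sd: tuple = (1.0, 0.5)
    age_start_range: tuple = (20.0, 60.0)
    age_step: float = 2.5
    age_beta: tuple = (0.05, 0.02)
    age_beta2: tuple = (-0.001, -0.0004)
    count_traits: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 1 or self.n_generations < 1 or self.n_markers < 0:
            raise ValueError("counts must be positive")
        if not (0.0 < self.genotyped_fraction <= 1.0):
            raise ValueError("genotyped fraction must be in (0, 1]")
        np.linalg.cholesky(self.vc.Ga)
        np.linalg.cholesky(self.vc.Re)
        if self.vc.Gpe is not None:
            np.linalg.cholesky(self.vc.Gpe)


@dataclass
class SimulatedPedigree:
    """Recorded pedigree plus the deeper true pedigree behind it.

    Introduced cows are recorded with unknown parents (``pedigree``) but
    actually descend from popular sires and outside dams
    (``true_pedigree``), mirroring donors bought on markets whose
    ancestry is real yet undocumented.  Genotypes are dropped through
    the true pedigree, so genomic relationships reveal ties the
    recorded pedigree misses -- the mechanism that lets single-step
    evaluation add information for shallow-pedigree animals.
    """

    pedigree: Pedigree
    true_pedigree: Pedigree
    cows: list[str]  # phenotyped donor cows, oldest first


def simulate_pedigree(spec: SimSpec) -> SimulatedPedigree:
    """Overlapping-sire, multi-generation pedigree of a donor herd.

    Generation 0 holds founders only.  Each later generation adds
    females whose sires are drawn from the previous generation's sire
    pool with geometrically decaying weights (a few sires dominate, as
    in intensively selected beef populations) and a fraction of
    introduced females whose true parents (a pool sire and an outside
    dam) are omitted from the recorded pedigree.  Phenotyped cows are
    all females of generations >= 1 (founders-only pedigrees phenotype
    the founder females).
    """
    rng = _rng(spec.seed, "pedigree")
    recorded: list[tuple[str, str | None, str | None]] = []
    true_recs: list[tuple[str, str | None, str | None]] = []
    gens = spec.n_generations
    if gens == 1:
        cows = [f"C0_{k:05d}" for k in range(spec.n_cows)]
        for c in cows:
            recorded.append((c, None, None))
        for k in range(spec.sires_per_generation):
            recorded.append((f"S0_{k:03d}", None, None))
        ped = Pedigree.from_records(recorded)
        return SimulatedPedigree(ped, ped, cows)

    per_gen = math.ceil(spec.n_cows / (gens - 1))
    females = [[f"C0_{k:05d}" for k in range(per_gen)]]
    sires = [[f"S0_{k:03d}" for k in range(spec.sires_per_generation)]]
    for a in females[0] + sires[0]:
        recorded.append((a, None, None))
        true_recs.append((a, None, None))
    cows: list[str] = []
    for g in range(1, gens):
        w = 0.5 ** np.arange(len(sires[g - 1]))
        w /= w.sum()

        def mate():
            s = sires[g - 1][rng.choice(len(sires[g - 1]), p=w)]
            d = females[g - 1][rng.integers(len(females[g - 1]))]
            return s, d

        new_f = []
        for k in range(per_gen):
            cid = f"C{g}_{k:05d}"
            if rng.random() < spec.introduced_fraction:
                # introduced: recorded as parent-unknown, truly sired by a
                # popular sire out of an outside (hidden) dam
                s = sires[g - 1][rng.choice(len(sires[g - 1]), p=w)]
                hd = f"HD{g}_{k:05d}"
                true_recs.append((hd, None, None))
                true_recs.append((cid, s, hd))
                recorded.append((cid, None, None))
            else:
                s, d = mate()
                recorded.append((cid, s, d))
                true_recs.append((cid, s, d))
            new_f.append(cid)
        new_s = []
        for k in range(spec.sires_per_generation):
            sid = f"S{g}_{k:03d}"
            s, d = mate()
            recorded.append((sid, s, d))
            true_recs.append((sid, s, d))
            new_s.append(sid)
        females.append(new_f)
        sires.append(new_s)
        cows.extend(new_f)
    ped = Pedigree.from_records(recorded)
    true_ped = Pedigree.from_records(true_recs)
    return SimulatedPedigree(ped, true_ped, cows[: spec.n_cows])


def gene_drop(
    ped: Pedigree, spec: SimSpec, ids=None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop unlinked biallelic markers through the pedigree.

    Founders (and unknown-parent sides) draw alleles from per-marker
    founder frequencies ~ Uniform(founder_freq_range); every descendant
    inherits one uniformly chosen allele per marker from each known
    parent (no linkage).  Returns the dosage matrix for ``ids`` (default
    all animals) plus the founder allele frequencies.
    """
    rng = _rng(spec.seed, "genotype")
    m = spec.n_markers
    lo, hi = spec.founder_freq_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("founder frequencies must lie in (0, 1)")
    p = rng.uniform(lo, hi, size=m)
    n = ped.n
    hap = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        for side, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent == UNKNOWN:
                hap[i, side] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, side] = hap[parent, pick, np.arange(m)]
    dos = hap.sum(axis=1).astype(float)
    if ids is not None:
        idx = ped.index_of(ids)
        dos = dos[idx]
        out_ids = [ped.ids[k] for k in idx]
    else:
        out_ids = list(ped.ids)
    if spec.missing_rate > 0:
        mask = rng.random(dos.shape) < spec.missing_rate
        dos[mask] = np.nan
    markers = [f"M{k:06d}" for k in range(m)]
    return GenotypeMatrix(out_ids, markers, dos), p


def _psd_factor(K: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(K)
        if w[0] < -1e-6 * max(w[-1], 1.0):
            raise ValueError("relationship matrix is not PSD") from None
        return V * np.sqrt(np.maximum(w, 0.0))


def simulate_effects(
    K: RelationshipMatrix | np.ndarray,
    Ga: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """True breeding values with covariance Ga (x) K; shape (n_animals, t)."""
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)
    Ga = np.atleast_2d(np.asarray(Ga, dtype=float))
    rng = _rng(seed, "effects")
    L = _psd_factor(Kv)
    C = _psd_factor(Ga)
    Z = rng.standard_normal((Kv.shape[0], Ga.shape[0]))
    return L @ Z @ C.T


def simulate_effects_from_markers(
    dosages: np.ndarray, p: np.ndarray, Ga: np.ndarray, seed: int = 0
) -> np.ndarray:
    """True breeding values from iid marker effects scaled to Ga.

    Per-marker effect vectors are N(0, Ga / (2 sum p(1-p))); the TBV is
    the frequency-centered dosage weighted sum, so genotyped animals'
    TBVs have covariance Ga (x) G under VanRaden scaling.
    """
    rng = _rng(seed, "effects")
    Ga = np.atleast_2d(np.asarray(Ga, dtype=float))
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    C = _psd_factor(Ga / denom)
    m = dosages.shape[1]
    eff = rng.standard_normal((m, Ga.shape[0])) @ C.T
    Z = dosages - 2.0 * p
    return Z @ eff


def simulate_records(
    sim: SimulatedPedigree,
    true_a: np.ndarray,
    spec: SimSpec,
) -> pd.DataFrame:
    """Repeated flush records under the repeatability model.

    Flush counts per cow are 1 + Poisson(mean_flushes - 1); each record
    draws year/month/program/technician levels whose effects were drawn
    once per level from N(0, sd^2); the cow's age advances by
    ``age_step`` months per flush and enters through linear and
    quadratic coefficients.  Permanent environmental effects are drawn
    once per cow (covariance Gpe), residuals per record (covariance Re).
    Default output is on the raw Gaussian scale of the fitted model;
    ``count_traits`` rounds to non-negative integers and clamps
    NGE <= TNE (NGE counts a subset of the flushed embryos).
    """
    rng = _rng(spec.seed, "records")
    ped = sim.pedigree
    cows = sim.cows
    t = spec.vc.n_traits
    a_idx = ped.index_of(cows)
    mu = np.asarray(spec.trait_means[:t], dtype=float)
    sd = np.asarray(spec.fixed_effect_sd[:t], dtype=float)

    factors = {
        "year": [f"Y{2008 + k}" for k in range(spec.n_years)],
        "month": [str(k + 1) for k in range(spec.n_months)],
        "program": [f"P{k + 1}" for k in range(spec.n_programs)],
        "technician": [f"T{k + 1}" for k in range(spec.n_technicians)],
    }
    effects = {
        f: rng.standard_normal((len(lv), t)) * sd
        for f, lv in factors.items()
    }
    Lpe = None if spec.vc.Gpe is None else _psd_factor(spec.vc.Gpe)
    Le = _psd_factor(spec.vc.Re)
    b1 = np.asarray(spec.age_beta[:t])
    b2 = np.asarray(spec.age_beta2[:t])

    rows = []
    for ci, cow in enumerate(cows):
        nfl = 1 + rng.poisson(max(spec.mean_flushes - 1.0, 0.0))
        pe = (
            np.zeros(t)
            if Lpe is None
            else Lpe @ rng.standard_normal(t)
        )
        age0 = rng.uniform(*spec.age_start_range)
        a = true_a[a_idx[ci]]
        for j in range(nfl):
            lev = {f: rng.integers(len(v)) for f, v in factors.items()}
            age = age0 + spec.age_step * j
            ac = age - 60.0
            e = Le @ rng.standard_normal(t)
            y = (
                mu
                + sum(effects[f][lev[f]] for f in factors)
                + b1 * ac
                + b2 * ac**2
                + a
                + pe
                + e
            )
            rows.append(
                {
                    "cow_id": cow,
                    "tne": y[0],
                    "nge": y[1] if t > 1 else np.nan,
                    **{f: factors[f][lev[f]] for f in factors},
                    "age_months": age,
                }
            )
    df = pd.DataFrame(rows)
    if spec.count_traits:
        for c in ("tne", "nge"):
            df[c] = np.maximum(np.round(df[c]), 0.0)
        df["nge"] = np.minimum(df["nge"], df["tne"])
    return df


@dataclass
class SimulatedData:
    """One synthetic dataset plus its generative truth."""

    spec: SimSpec
    pedigree: Pedigree
    cows: list[str]
    genotyped: list[str]
    genotypes: GenotypeMatrix | None
    phenotypes: pd.DataFrame
    true_values: np.ndarray  # (n_animals, t) true breeding values
    K: RelationshipMatrix  # matrix the TBVs were generated from
    founder_freqs: np.ndarray | None

    def truth(self) -> dict:
        vc = self.spec.vc
        return {
            "seed": self.spec.seed,
            "effect_matrix": self.K.kind,
            "flush_distribution": (
                f"1 + Poisson({self.spec.mean_flushes - 1:.1f})"
            ),
            "Ga": vc.Ga.tolist(),
            "Gpe": None if vc.Gpe is None else vc.Gpe.tolist(),
            "Re": vc.Re.tolist(),
            "heritability": vc.heritability().tolist(),
            "repeatability": vc.repeatability().tolist(),
            "genetic_correlation": (
                vc.genetic_correlation() if vc.n_traits > 1 else None
            ),
            "trait_means": list(self.spec.trait_means),
        }


def simulate_dataset(
    spec: SimSpec, effect_matrix: str = "A"
) -> SimulatedData:
    """Full generative pass: pedigree, genotypes, TBVs, flush records.

    ``effect_matrix`` chooses the covariance of the true breeding
    values: "A" (pedigree expectation), "H" (single-step matrix built
    from the gene-dropped genotypes with default QC and blending, so the
    generative truth matches the genomic model), or "markers" (TBVs from
    iid marker effects).
    """
    from . import genotype as gq
    from . import hmatrix as hm
    from . import pedigree as pedmod

    sim = simulate_pedigree(spec)
    ped = sim.pedigree
    geno = None
    geno_all = None
    freqs_true = None
    genotyped: list[str] = []
    if spec.n_markers > 0:
        rng = _rng(spec.seed, "pedigree")  # subset choice; gene_drop has its own stream
        n_g = max(2, int(round(spec.genotyped_fraction * len(sim.cows))))
        pick = sorted(rng.choice(len(sim.cows), size=n_g, replace=False))
        genotyped = [sim.cows[k] for k in pick]
        # markers descend through the *true* pedigree, so genotypes carry
        # the relationships the recorded pedigree omits
        geno_all, freqs_true = gene_drop(sim.true_pedigree, spec)
        idx = sim.true_pedigree.index_of(genotyped)
        geno = GenotypeMatrix(
            genotyped, geno_all.markers, geno_all.dosages[idx]
        )

    if effect_matrix == "A":
        K = pedmod.build_A(ped)
        true_a = simulate_effects(K, spec.vc.Ga, seed=spec.seed)
    elif effect_matrix == "H":
        if geno is None:
            raise ValueError("H-based truth needs markers in the spec")
        A = pedmod.build_A(ped)
        g1, _ = gq.qc_samples(geno)
        g2, _ = gq.qc_markers(g1)
        fr = gq.allele_frequencies(g2)
        g3 = gq.impute_missing(g2, fr)
        G = gq.build_G(g3, fr)
        A22 = pedmod.extract_A22(A, G.ids)
        Gstar = hm.blend_G(G, A22)
        K = hm.build_H(A, Gstar)
        true_a = simulate_effects(K, spec.vc.Ga, seed=spec.seed)
    elif effect_matrix == "markers":
        if geno_all is None:
            raise ValueError("marker-based truth needs markers in the spec")
        true_all = simulate_effects_from_markers(
            geno_all.dosages, freqs_true, spec.vc.Ga, seed=spec.seed
        )
        # reindex from the true pedigree to the recorded one
        true_a = true_all[sim.true_pedigree.index_of(ped.ids)]
        K = pedmod.build_A(ped)
    else:
        raise ValueError("effect_matrix must be 'A', 'H' or 'markers'")

    ph = simulate_records(sim, true_a, spec)
    return SimulatedData(
        spec=spec,
        pedigree=ped,
        cows=sim.cows,
        genotyped=genotyped,
        genotypes=geno,
        phenotypes=ph,
        true_values=true_a,
        K=K,
        founder_freqs=freqs_true,
    )
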