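"""SNP quality control, allele frequencies and the genomic relationship matrix.

QC follows the usual chip-data workflow for relationship-matrix builds:
samples are filtered on call rate first, then markers on minor allele
frequency, call rate and a Hardy-Weinberg equilibrium goodness-of-fit
test (all strict inequalities), then allele frequencies are computed on
the retained data, remaining missing dosages are filled in, and G is
built with VanRaden's first method,

    G = Z Z' / (2 * sum_k p_k (1 - p_k)),   Z_ik = x_ik - 2 p_k,

with x the counted-allele dosage in {0,1,2} and p_k the counted-allele
frequency estimated from the genotyped animals themselves.  The genomic
inbreeding coefficient is g_ii - 1 and, unlike its pedigree counterpart,
can be negative (an individual more heterozygous than expected under the
sample allele frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import RelationshipMatrix

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage table with an explicit missing mask.

    ``dosages`` is a float array; missing entries are ``nan``.  Non-missing
    entries are counts in {0, 1, 2} of the counted allele.
    """

    ids: list[str]
    markers: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.markers = [str(m) for m in self.markers]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError("dosage array shape does not match labels")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in genotype matrix")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids in genotype matrix")
        vals = self.dosages[~np.isnan(self.dosages)]
        bad = ~np.isin(vals, (0.0, 1.0, 2.0))
        if np.any(bad):
            i, j = [
                (r, c)
                for r, c in zip(*np.nonzero(~np.isnan(self.dosages)))
                if self.dosages[r, c] not in (0.0, 1.0, 2.0)
            ][0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]!r} for individual "
                f"{self.ids[i]!r}, marker {self.markers[j]!r} "
                "(expected 0, 1, 2 or missing)"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.dosages)


@dataclass
class MarkerQCReport:
    """Per-marker and per-sample QC metrics plus keep flags."""

    markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)


def qc_samples(G: GenotypeMatrix, min_call: float = 0.95) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop individuals whose genotype call rate is not strictly above min_call."""
    call = 1.0 - G.missing.mean(axis=1)
    keep = call > min_call
    report = pd.DataFrame({"id": G.ids, "call_rate": call, "kept": keep})
    if not keep.any():
        raise ValueError("sample QC removed every individual")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("sample QC: removed %d of %d individuals", n_drop, G.n)
    out = GenotypeMatrix(
        [a for a, k in zip(G.ids, keep) if k], G.markers, G.dosages[keep]
    )
    return out, report


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """Hardy-Weinberg 1-df chi-square goodness-of-fit p-value.

    Observed genotype counts (n0, n1, n2) of dosages 0/1/2 are compared
    to q^2, 2pq, p^2 expectations at the sample allele frequency
    p = (n1 + 2 n2) / 2n.  A monomorphic marker returns p-value 1 (no
    test possible; such markers are removed by the MAF filter anyway).
    No continuity correction is applied.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("HWE test needs at least one genotype")
    p = (n1 + 2 * n2) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    q = 1.0 - p
    exp = np.array([q * q, 2 * p * q, p * p]) * n
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def qc_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    call_min: float = 0.95,
    hwe_p_min: float = 0.001,
) -> tuple[GenotypeMatrix, MarkerQCReport]:
    """Keep markers with MAF > maf_min, call rate > call_min, HWE p > hwe_p_min.

    All three criteria are strict inequalities; the report carries every
    input marker with its metrics and keep flag.
    """
    miss = G.missing
    ncall = (~miss).sum(axis=0)
    call_rate = ncall / G.n
    d = np.where(miss, 0.0, G.dosages)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2.0 * ncall)
    p = np.where(ncall == 0, np.nan, p)
    maf = np.fmin(p, 1.0 - p)
    hwe_p = np.ones(G.m)
    for j in range(G.m):
        if ncall[j] == 0:
            continue
        col = G.dosages[~miss[:, j], j]
        n0 = int(np.sum(col == 0))
        n1 = int(np.sum(col == 1))
        n2 = int(np.sum(col == 2))
        hwe_p[j] = hwe_test(n0, n1, n2)
    keep = (
        (ncall > 0)
        & (np.nan_to_num(maf) > maf_min)
        & (call_rate > call_min)
        & (hwe_p > hwe_p_min)
    )
    report = MarkerQCReport(
        markers=pd.DataFrame(
            {
                "marker": G.markers,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "kept": keep,
            }
        )
    )
    if not keep.any():
        raise ValueError("marker QC removed every marker")
    log.info("marker QC: kept %d of %d markers", int(keep.sum()), G.m)
    out = GenotypeMatrix(
        G.ids,
        [m for m, k in zip(G.markers, keep) if k],
        G.dosages[:, keep],
    )
    return out, report


@dataclass
class AlleleFrequencies:
    markers: list[str]
    p: np.ndarray  # counted-allele frequency per marker


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Counted-allele frequency per marker from non-missing dosages."""
    miss = G.missing
    ncall = (~miss).sum(axis=0)
    if np.any(ncall == 0):
        j = int(np.argmin(ncall))
        raise ValueError(f"marker {G.markers[j]!r} has zero genotype calls")
    d = np.where(miss, 0.0, G.dosages)
    p = d.sum(axis=0) / (2.0 * ncall)
    return AlleleFrequencies(list(G.markers), p)


def impute_missing(
    G: GenotypeMatrix,
    freqs: AlleleFrequencies,
    mode: str = "expected",
    seed: int | None = None,
) -> GenotypeMatrix:
    """Fill missing dosages from per-marker allele frequencies.

    ``expected`` fills the mean dosage 2 p_k (fractional values are fine
    downstream, where only centered dosages enter G); ``sample`` draws a
    genotype from Binomial(2, p_k).  This is a frequency-based stand-in
    for haplotype-phasing imputation: it preserves first moments but
    ignores linkage information, which is second-order for G at the
    sub-percent missingness typical after QC.
    """
    if freqs.markers != G.markers:
        raise ValueError("allele frequencies do not match genotype markers")
    miss = G.missing
    if not miss.any():
        return G
    filled = G.dosages.copy()
    rows, cols = np.nonzero(miss)
    if mode == "expected":
        filled[rows, cols] = 2.0 * freqs.p[cols]
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        filled[rows, cols] = rng.binomial(2, freqs.p[cols]).astype(float)
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.ids = list(G.ids)
    out.markers = list(G.markers)
    out.dosages = filled  # may hold fractional values; skip {0,1,2} check
    return out


def build_G(G: GenotypeMatrix, freqs: AlleleFrequencies) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix."""
    if freqs.markers != G.markers:
        raise ValueError("allele frequencies do not match genotype markers")
    if np.isnan(G.dosages).any():
        raise ValueError("missing dosages remain; impute before building G")
    p = freqs.p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: sum 2p(1-p) is zero")
    Z = G.dosages - 2.0 * p
    vals = (Z @ Z.T) / denom
    vals = 0.5 * (vals + vals.T)
    return RelationshipMatrix(G.ids, vals, "G", meta={"denom": denom})


def genomic_inbreeding(Gmat: RelationshipMatrix) -> dict[str, float]:
    """F_i = g_ii - 1; negative values are expected and meaningful."""
    if Gmat.kind != "G":
        raise ValueError(f"genomic inbreeding needs kind='G', got {Gmat.kind!r}")
    return dict(zip(Gmat.ids, (Gmat.diagonal() - 1.0).tolist()))
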