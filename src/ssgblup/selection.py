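"""Top-n selection, cross-setting agreement, and mean-kinship null tests.

Reproduces the selection experiment logic: the n candidates with the
highest EBVs for a trait are selected; agreement between settings is the
concordance rate of the selected sets and the Pearson/Spearman
correlation of the EBV vectors; the genetic similarity of a selected
set is its mean pairwise kinship coefficient, judged against an
empirical null distribution built from random same-size subsets of the
candidates.  Elevated mean kinship among EBV-selected elites (small
upper-tail p-value) is the diversity warning the analysis is after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import RelationshipMatrix, kinship_matrix

log = logging.getLogger(__name__)


def select_top(ebv: pd.Series | dict, n: int) -> list[str]:
    """Ids of the n largest EBVs; ties at the cutoff break by id order."""
    s = pd.Series(ebv)
    s.index = s.index.astype(str)
    if n > len(s):
        raise ValueError(f"cannot select {n} from {len(s)} candidates")
    ordered = s.sort_index().sort_values(ascending=False, kind="stable")
    if len(s) > n and ordered.iloc[n - 1] == ordered.iloc[n]:
        log.warning("EBV tie at the selection cutoff; resolved by id order")
    return list(ordered.index[:n])


def concordance(setA, setB, n: int) -> float:
    """Percentage overlap 100 |A∩B| / n of two equally sized selections."""
    A, B = set(map(str, setA)), set(map(str, setB))
    if len(A) != n or len(B) != n:
        raise ValueError("selected sets must both have the stated size")
    return 100.0 * len(A & B) / n


def mean_kinship(ids, M: RelationshipMatrix) -> float:
    """Mean standardized kinship R_ij over unordered pairs (diagonal excluded)."""
    ids = list(map(str, ids))
    if len(ids) < 2:
        raise ValueError("mean kinship needs at least two individuals")
    R = kinship_matrix(M.submatrix(ids))
    iu = np.triu_indices(len(ids), k=1)
    return float(R[iu].mean())


@dataclass
class EmpiricalNull:
    """Sampled mean-kinship values under random selection."""

    draws: np.ndarray
    n: int
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.size

    def mc_se(self) -> float:
        return float(self.draws.std(ddof=1) / np.sqrt(self.n_draws))


def empirical_null(
    M: RelationshipMatrix,
    candidates,
    n: int,
    iters: int,
    seed: int,
) -> EmpiricalNull:
    """Mean kinship of ``iters`` random n-subsets of the candidates.

    Subsets are drawn uniformly without replacement; the draw stream is
    fully determined by ``seed``.
    """
    candidates = list(map(str, candidates))
    if n > len(candidates):
        raise ValueError("subset size exceeds number of candidates")
    R = kinship_matrix(M.submatrix(candidates))
    rng = np.random.default_rng(seed)
    m = len(candidates)
    npairs = n * (n - 1) / 2.0
    draws = np.empty(iters)
    iu = np.triu_indices(n, k=1)
    for it in range(iters):
        pick = rng.choice(m, size=n, replace=False)
        sub = R[np.ix_(pick, pick)]
        draws[it] = sub[iu].sum() / npairs
    return EmpiricalNull(draws=draws, n=n, seed=seed)


def empirical_p(
    null: EmpiricalNull, observed: float, plus_one: bool = False
) -> float:
    """Upper-tail proportion of null draws at or above the observed value.

    High mean kinship among selected elites is the anomaly of interest,
    so small p-values flag selections far more related than random sets.
    ``plus_one`` applies the (k+1)/(N+1) permutation-test correction.
    """
    if null.n_draws == 0:
        raise ValueError("empty empirical null")
    k = int(np.count_nonzero(null.draws >= observed))
    if plus_one:
        return (k + 1) / (null.n_draws + 1)
    return k / null.n_draws


def ebv_agreement(ebv_by_setting: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson (upper) and Spearman (lower) EBV correlations.

    ``ebv_by_setting`` maps setting tags to per-cow EBV series on a
    common candidate set.  Returns a square DataFrame with Pearson
    correlations above the diagonal and Spearman below.
    """
    tags = list(ebv_by_setting)
    base = None
    aligned = {}
    for tag, s in ebv_by_setting.items():
        s = pd.Series(s)
        s.index = s.index.astype(str)
        if base is None:
            base = sorted(s.index)
        elif sorted(s.index) != base:
            raise ValueError("settings do not share a common cow set")
        aligned[tag] = s.loc[base].to_numpy()
    out = pd.DataFrame(np.ones((len(tags), len(tags))), index=tags, columns=tags)
    for i, a in enumerate(tags):
        for j, b in enumerate(tags):
            if i < j:
                out.iloc[i, j] = stats.pearsonr(aligned[a], aligned[b])[0]
            elif i > j:
                out.iloc[i, j] = stats.spearmanr(aligned[a], aligned[b])[0]
    return out
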