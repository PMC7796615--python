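"""Association statistics linking rearrangements, distance and expression.

The headline analysis assembles one row per unordered species pair — the
ortholog expression correlation r_expr, the pairwise rearrangement count PR,
and the patristic genetic distance — and applies plain two-sided Pearson
tests across those S(S-1)/2 rows: PR against genetic distance (a phylogeny
control) and PR against r_expr (the rearrangement-expression association).
Pairwise rows are not independent observations, so a Mantel permutation
test over species labels is provided as a robustness companion; the plain
Pearson test is nevertheless the primary statistic reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "pearson",
    "pearson_pvalue",
    "patristic_distances",
    "build_pair_table",
    "headline_analysis",
    "mantel_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    exact_r: bool = False  # |r| == 1: p degenerates to 0

    def __str__(self) -> str:
        return f"r = {self.r:.3f}, n = {self.n}, P = {self.p:.3g}"


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient via the t transformation.

    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with ``n - 2`` degrees of
    freedom.  ``|r| = 1`` returns 0 (flagged via CorrelationResult).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_test(x, y) -> CorrelationResult:
    r = pearson(x, y)
    n = len(x)
    return CorrelationResult(r=r, n=n, p=pearson_pvalue(r, n), exact_r=abs(r) == 1.0)


def patristic_distances(tree, species: list[str] | None = None) -> pd.DataFrame:
    """Tip-to-tip path lengths (sum of branch lengths) as a symmetric matrix."""
    tips = {t.name: t for t in tree.get_terminals()}
    if species is None:
        species = sorted(tips)
    missing = [s for s in species if s not in tips]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    mat = np.zeros((len(species), len(species)))
    for i, j in combinations(range(len(species)), 2):
        d = tree.distance(tips[species[i]], tips[species[j]])
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=species, columns=species)


def build_pair_table(
    expr_corrs: Mapping[tuple[str, str], float],
    rearr_matrix: pd.DataFrame,
    dist_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """One row per unordered species pair: r_expr, PR, genetic distance."""
    species = list(rearr_matrix.index)
    if set(species) != set(dist_matrix.index):
        raise ValueError("species sets of the two matrices differ")
    corr = {frozenset(k): v for k, v in expr_corrs.items()}
    if any(frozenset(p) not in corr for p in combinations(species, 2)):
        raise ValueError("expression correlations missing for some species pair")
    rows = []
    for a, b in combinations(species, 2):
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "r_expr": corr[frozenset((a, b))],
                "pr": rearr_matrix.loc[a, b],
                "genetic_distance": dist_matrix.loc[a, b],
            }
        )
    return pd.DataFrame(rows)


def headline_analysis(pair_table: pd.DataFrame) -> dict[str, CorrelationResult]:
    """The two Pearson tests over the pair table.

    ``pr_vs_distance``: rearrangement count against genetic distance (the
    phylogeny control); ``pr_vs_expression``: rearrangement count against
    the ortholog expression correlation (the association of interest, where
    a negative coefficient means expression conservation decays with
    rearrangement).
    """
    if len(pair_table) < 3:
        raise ValueError("need >= 3 species pairs")
    return {
        "pr_vs_distance": correlation_test(
            pair_table["pr"].to_numpy(), pair_table["genetic_distance"].to_numpy()
        ),
        "pr_vs_expression": correlation_test(
            pair_table["pr"].to_numpy(), pair_table["r_expr"].to_numpy()
        ),
    }


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test between two symmetric species matrices.

    Pearson r over the upper off-diagonal entries; the permutation p-value
    counts label permutations with ``|r*| >= |r|`` using the add-one
    estimator ``(1 + hits) / (n_perm + 1)``.  With four or fewer species all
    label permutations are enumerated exactly.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if list(mat_a.index) != list(mat_b.index):
        mat_b = mat_b.loc[mat_a.index, mat_a.index]
    A = mat_a.to_numpy(dtype=float)
    B = mat_b.to_numpy(dtype=float)
    for M, name in ((A, "A"), (B, "B")):
        if not np.allclose(M, M.T):
            raise ValueError(f"matrix {name} is not symmetric")
    r_obs = pearson(_offdiag(A), _offdiag(B))
    n = A.shape[0]
    if n <= 4:
        perms = list(permutations(range(n)))[1:]
        hits = sum(
            abs(pearson(_offdiag(A), _offdiag(B[np.ix_(p, p)]))) >= abs(r_obs)
            for p in perms
        )
        return r_obs, (1 + hits) / (len(perms) + 1)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if abs(pearson(_offdiag(A), _offdiag(B[np.ix_(p, p)]))) >= abs(r_obs):
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)
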