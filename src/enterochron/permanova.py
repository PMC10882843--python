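"""Permutational multivariate ANOVA on a dissimilarity matrix.

Sequential (Type-I) decomposition via projection matrices on the
Gower-centered matrix, pseudo-F statistics, and a permutation null that can
be restricted to shuffle samples only within strata (here: the repeatedly
sampled animal), accounting for the non-independence of longitudinal
samples. When the permutation group is small enough it is enumerated
exhaustively and the p-value is exact; otherwise Monte Carlo sampling with
the +1 correction is used.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from enterochron.lmm import bh_adjust

__all__ = ["PermanovaResult", "permanova", "pairwise_permanova"]

_EPS = 1e-12


@dataclasses.dataclass
class PermanovaResult:
    """Per-term R^2, pseudo-F and permutation p, plus the residual row.

    ``table`` has rows for each term and a Residual/Total row; term R^2
    values and the residual R^2 sum to one (sequential decomposition).
    """

    table: pd.DataFrame
    n_permutations: int
    strata: str | None
    method: str  # "exact" or "monte_carlo"

    def __str__(self) -> str:  # pragma: no cover - display only
        head = f"PERMANOVA ({self.method}, {self.n_permutations} permutations"
        head += f", strata={self.strata})" if self.strata else ")"
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _design_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if col.dtype.kind in "fiu" and col.nunique() > 2:
        return col.to_numpy(dtype=float)[:, None]
    # categorical: dummy-code all levels but the first
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _permutation_space(
    n: int, strata_codes: np.ndarray | None
) -> tuple[float, list[list[np.ndarray]] | None]:
    """Total number of within-strata permutations; per-stratum index lists."""
    if strata_codes is None:
        return float(math.factorial(n)), None
    blocks = []
    total = 1.0
    for lev in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == lev)
        blocks.append(idx)
        total *= math.factorial(len(idx))
    return total, [blocks]


def _iter_exhaustive(n: int, strata_codes: np.ndarray | None):
    """Yield every distinct within-strata permutation as an index array."""
    if strata_codes is None:
        for perm in itertools.permutations(range(n)):
            yield np.array(perm)
        return
    blocks = [np.flatnonzero(strata_codes == lev) for lev in np.unique(strata_codes)]
    per_block = [list(itertools.permutations(b)) for b in blocks]
    for combo in itertools.product(*per_block):
        perm = np.arange(n)
        for block, order in zip(blocks, combo):
            perm[block] = order
        yield perm


def _random_perm(
    rng: np.random.Generator, n: int, strata_codes: np.ndarray | None
) -> np.ndarray:
    if strata_codes is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for lev in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == lev)
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def permanova(
    dist: pd.DataFrame,
    design: pd.DataFrame,
    terms: Sequence[str] | None = None,
    strata: str | None = None,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential PERMANOVA of a dissimilarity matrix on model terms.

    Parameters
    ----------
    dist
        Square symmetric dissimilarity matrix (samples on both axes).
    design
        Per-sample covariates, indexed like ``dist`` (or with a
        ``sample_id`` column). Numeric columns with more than two values
        enter as continuous; everything else is dummy-coded.
    terms
        Term order of the sequential decomposition; defaults to every
        design column except the strata column.
    strata
        Column name whose levels restrict permutations: labels are only
        shuffled within each level (e.g. within pig for repeated measures).
    """
    dist = dist.copy()
    if "sample_id" in design.columns:
        design = design.set_index("sample_id")
    design = design.loc[[str(i) for i in dist.index]]
    if terms is None:
        terms = [c for c in design.columns if c != strata]
    n = dist.shape[0]
    D = dist.to_numpy(dtype=float)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = (G + G.T) / 2
    ss_total = float(np.trace(G))

    strata_codes = None
    if strata is not None:
        strata_codes = pd.factorize(design[strata])[0]

    # cumulative hat matrices (intercept first)
    Xs = [np.ones((n, 1))]
    dfs: list[int] = []
    for t in terms:
        Xs.append(np.hstack([Xs[-1], _design_matrix(design, t)]))
        dfs.append(
            int(np.linalg.matrix_rank(Xs[-1]) - np.linalg.matrix_rank(Xs[-2]))
        )
    hats = [_hat(X) for X in Xs]
    deltas = [hats[j + 1] - hats[j] for j in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]
    df_resid = n - int(np.linalg.matrix_rank(Xs[-1]))
    if df_resid <= 0:
        raise ValueError("model has no residual degrees of freedom")

    def stats(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(dlt * Gp.T)) for dlt in deltas])
        ss_res = float(np.sum(resid_proj * Gp.T))
        return ss_terms, ss_res

    ss_terms, ss_res = stats(G)

    if abs(ss_total) < _EPS:  # all samples identical: nothing to explain
        rows = [
            {"term": t, "df": dfs[j], "sum_sq": 0.0, "R2": 0.0,
             "pseudo_F": 0.0, "p_value": 1.0}
            for j, t in enumerate(terms)
        ]
        rows.append({"term": "Residual", "df": df_resid, "sum_sq": 0.0,
                     "R2": 0.0, "pseudo_F": np.nan, "p_value": np.nan})
        rows.append({"term": "Total", "df": n - 1, "sum_sq": 0.0, "R2": 1.0,
                     "pseudo_F": np.nan, "p_value": np.nan})
        return PermanovaResult(pd.DataFrame(rows), 0, strata, "degenerate")

    denom = ss_res / df_resid
    F_obs = np.array(
        [
            (ss_terms[j] / dfs[j]) / denom if denom > _EPS else 0.0
            for j in range(len(terms))
        ]
    )

    total_perms, _ = _permutation_space(n, strata_codes)
    exhaustive = total_perms <= n_permutations
    geq = np.zeros(len(terms))
    n_done = 0
    if exhaustive:
        for perm in _iter_exhaustive(n, strata_codes):
            Gp = G[np.ix_(perm, perm)]
            ssp, ssr = stats(Gp)
            den = ssr / df_resid
            Fp = np.where(den > _EPS, (ssp / np.array(dfs)) / max(den, _EPS), 0.0)
            geq += Fp >= F_obs - _EPS
            n_done += 1
        p = geq / n_done
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            perm = _random_perm(rng, n, strata_codes)
            Gp = G[np.ix_(perm, perm)]
            ssp, ssr = stats(Gp)
            den = ssr / df_resid
            Fp = np.where(den > _EPS, (ssp / np.array(dfs)) / max(den, _EPS), 0.0)
            geq += Fp >= F_obs - _EPS
            n_done += 1
        p = (1.0 + geq) / (1.0 + n_done)
        method = "monte_carlo"

    rows = []
    for j, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": dfs[j],
                "sum_sq": ss_terms[j],
                "R2": ss_terms[j] / ss_total,
                "pseudo_F": F_obs[j],
                "p_value": p[j],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "sum_sq": ss_res,
            "R2": ss_res / ss_total,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": ss_total,
            "R2": 1.0,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return PermanovaResult(pd.DataFrame(rows), n_done, strata, method)


def pairwise_permanova(
    dist: pd.DataFrame,
    groups: Mapping[str, str],
    strata: Mapping[str, str] | None = None,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise two-group PERMANOVAs with BH-adjusted p-values.

    ``groups`` (and optional ``strata``) map sample id to label. Each pair
    is tested on the sub-matrix of its samples.
    """
    ids = [str(s) for s in dist.index]
    labels = sorted({groups[s] for s in ids})
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(labels, 2):
        keep = [s for s in ids if groups[s] in (a, b)]
        sub = dist.loc[keep, keep]
        design = pd.DataFrame({"group": [groups[s] for s in keep]}, index=keep)
        strata_col = None
        if strata is not None:
            design["stratum"] = [strata[s] for s in keep]
            strata_col = "stratum"
        res = permanova(
            sub,
            design,
            terms=["group"],
            strata=strata_col,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        term = res.table.iloc[0]
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "R2": term["R2"],
                "pseudo_F": term["pseudo_F"],
                "p_value": term["p_value"],
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
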