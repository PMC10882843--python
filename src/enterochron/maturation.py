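"""Microbiome maturation score from genus first-appearance concordance.

For each pig, every genus is ranked by the earliest age at which its
relative abundance exceeds a threshold (default 0.5%), with midranks for
ties. Agreement of these first-appearance rankings across pigs is
quantified by Kendall's coefficient of concordance W with a within-pig
permutation test, and the median rank across pigs defines one consensus
genus order. A sample's maturation score is then the mean consensus rank
of the genera present (above threshold) in it: communities dominated by
late-arriving genera score high, so the score tracks developmental age.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from enterochron.io import CountTable, SampleRecord

__all__ = [
    "ConsensusRanking",
    "first_appearance_ranks",
    "kendalls_w",
    "consensus_order",
    "maturation_scores",
]


def _metadata_frame(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        return metadata
    return pd.DataFrame(
        [
            {"sample_id": r.sample_id, "pig_id": r.pig_id, "age_weeks": r.age_weeks}
            for r in metadata
        ]
    )


def first_appearance_ranks(
    counts: CountTable,
    metadata: Sequence[SampleRecord] | pd.DataFrame,
    ra_threshold: float = 0.005,
) -> pd.DataFrame:
    """Pigs x genera matrix of within-pig first-appearance ranks.

    A genus "appears" for a pig at the earliest sampled age where its
    relative abundance exceeds ``ra_threshold``; appearance ages are ranked
    within the pig with midranks for ties. Genera never appearing for a
    pig are NaN; pigs with no qualifying genus are dropped with a warning.
    """
    meta = _metadata_frame(metadata).set_index("sample_id")
    ra = counts.relative_abundance()
    missing = [s for s in ra.index if s not in meta.index]
    if missing:
        raise ValueError(f"count sample(s) missing from metadata: {missing}")
    pigs = meta.loc[ra.index, "pig_id"]
    ages = meta.loc[ra.index, "age_weeks"].astype(float)
    rows = {}
    for pig, sample_idx in ra.groupby(pigs).groups.items():
        sub = ra.loc[sample_idx]
        sub_ages = ages.loc[sample_idx]
        if sub.shape[0] < 2:
            warnings.warn(f"pig {pig!r} has fewer than 2 age points; excluded")
            continue
        above = sub.gt(ra_threshold)
        first_age = np.full(sub.shape[1], np.nan)
        for j in range(sub.shape[1]):
            hit = sub_ages[above.iloc[:, j].to_numpy()]
            if len(hit):
                first_age[j] = hit.min()
        if np.all(np.isnan(first_age)):
            warnings.warn(f"pig {pig!r} has no genus above threshold; excluded")
            continue
        ranks = np.full_like(first_age, np.nan)
        obs = ~np.isnan(first_age)
        ranks[obs] = rankdata(first_age[obs], method="average")
        rows[pig] = ranks
    return pd.DataFrame.from_dict(rows, orient="index", columns=counts.taxon_ids)


def _w_statistic(R: np.ndarray) -> float:
    """Kendall's W with the standard tie correction.

    ``R`` is pigs x genera of within-pig ranks (complete, no NaN).
    """
    m, n = R.shape
    col_sums = R.sum(axis=0)
    S = float(((col_sums - col_sums.mean()) ** 2).sum())
    T = 0.0
    for i in range(m):
        _, counts = np.unique(R[i], return_counts=True)
        T += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        return 1.0  # every pig fully tied: trivially concordant
    return 12.0 * S / denom


def kendalls_w(
    rank_matrix: pd.DataFrame | np.ndarray,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Kendall's coefficient of concordance and a within-pig permutation p.

    Genera with a missing rank for any pig are excluded (complete-case
    submatrix). The null permutes each pig's ranks independently; when the
    full permutation group (n!)^m is enumerable within ``n_permutations``
    the p-value is exact.
    """
    R = (
        rank_matrix.to_numpy(dtype=float)
        if isinstance(rank_matrix, pd.DataFrame)
        else np.asarray(rank_matrix, dtype=float)
    )
    complete = ~np.isnan(R).any(axis=0)
    R = R[:, complete]
    m, n = R.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 pigs and 2 shared genera")
    # re-rank within each pig so rows are proper (midrank) rankings of the
    # n retained genera rather than of the original item set
    R = np.vstack([rankdata(row, method="average") for row in R])
    W = _w_statistic(R)
    total = math.factorial(n) ** m
    if total <= n_permutations:
        perms = list(itertools.permutations(range(n)))
        geq = 0
        for combo in itertools.product(perms, repeat=m):
            Rp = np.stack([R[i, list(combo[i])] for i in range(m)])
            if _w_statistic(Rp) >= W - 1e-12:
                geq += 1
        return W, geq / total
    rng = np.random.default_rng(seed)
    geq = 0
    Rp = R.copy()
    for _ in range(n_permutations):
        for i in range(m):
            Rp[i] = R[i, rng.permutation(n)]
        if _w_statistic(Rp) >= W - 1e-12:
            geq += 1
    return W, (1 + geq) / (1 + n_permutations)


@dataclasses.dataclass
class ConsensusRanking:
    """Cross-pig consensus genus order with its concordance statistics."""

    order: list[str]  # genera sorted by median rank (ties alphabetical)
    median_ranks: pd.Series  # per genus
    kendalls_w: float
    permutation_p: float
    n_permutations: int

    def rank_of(self, genus: str) -> float:
        return float(self.median_ranks[genus])


def consensus_order(
    rank_matrix: pd.DataFrame,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> ConsensusRanking:
    """Median first-appearance rank per genus (missing entries ignored),
    ordered ascending with alphabetical tie-break; Kendall's W attached."""
    present = rank_matrix.notna().any(axis=0)
    dropped = rank_matrix.columns[~present].tolist()
    if dropped:
        warnings.warn(
            f"genera absent from every pig excluded from consensus: {dropped}"
        )
    med = rank_matrix.loc[:, present].median(axis=0, skipna=True)
    order = sorted(med.index, key=lambda g: (med[g], g))
    W, p = kendalls_w(rank_matrix, n_permutations=n_permutations, seed=seed)
    return ConsensusRanking(
        order=order,
        median_ranks=med,
        kendalls_w=W,
        permutation_p=p,
        n_permutations=n_permutations,
    )


def maturation_scores(
    consensus: ConsensusRanking,
    counts: CountTable,
    metadata: Sequence[SampleRecord] | pd.DataFrame | None = None,
    ra_threshold: float = 0.005,
) -> pd.DataFrame:
    """Presence-weighted mean consensus rank per sample.

    presence(g) = 1 when the genus's relative abundance in the sample
    exceeds ``ra_threshold``; the score is the plain average of the
    consensus ranks of present genera. Samples with no present consensus
    genus get a missing score (flagged).
    """
    ra = counts.relative_abundance()
    genera = [g for g in consensus.median_ranks.index if g in ra.columns]
    ranks = consensus.median_ranks[genera].to_numpy(float)
    sub = ra[genera].to_numpy(float)
    present = sub > ra_threshold
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.where(
            n_present > 0, (present * ranks).sum(axis=1) / np.maximum(n_present, 1),
            np.nan,
        )
    out = pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "score": score,
            "n_present_genera": n_present,
        }
    )
    if metadata is not None:
        meta = _metadata_frame(metadata)
        out = out.merge(
            meta[["sample_id", "pig_id", "age_weeks"]], on="sample_id", how="left"
        )
    return out
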