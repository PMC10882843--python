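"""Normalization, diversity and community-structure summaries.

CSS (cumulative sum scaling) divides each sample's counts by the sum of its
counts at or below its own q-th count quantile, damping the influence of a
few dominant features on library-size correction. Alpha diversity is
richness and natural-log Shannon; beta diversity is Bray-Curtis, with
beta-dispersion computed as distance to the group centroid in the
principal-coordinates embedding.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from enterochron.io import CountTable

__all__ = [
    "NormalizedTable",
    "css_normalize",
    "alpha_diversity",
    "bray_curtis",
    "beta_dispersion",
    "shared_features",
]


@dataclasses.dataclass
class NormalizedTable:
    """CSS-normalized counts with the per-sample scaling factors.

    normalized value = raw count / scaling_factor * scale_constant.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    scaling_factors: np.ndarray
    scale_constant: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def relative_abundance(self) -> pd.DataFrame:
        tot = self.values.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            self.values / tot, index=self.sample_ids, columns=self.taxon_ids
        )


def css_normalize(
    counts: CountTable, quantile: float = 0.5, scale_constant: float = 1000.0
) -> NormalizedTable:
    """Cumulative sum scaling.

    The scaling factor of a sample is the sum of its counts that are less
    than or equal to its own ``quantile``-th count value (computed over all
    its counts, zeros included, with linear interpolation). Doubling every
    count of a sample doubles its factor and leaves normalized values
    unchanged.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    x = counts.counts.astype(float)
    factors = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        row = x[i]
        if row.sum() == 0:
            raise ValueError(
                f"sample {counts.sample_ids[i]!r} has no counts; "
                "CSS scaling is undefined"
            )
        qval = np.quantile(row, quantile)
        factors[i] = row[row <= qval].sum()
        if factors[i] == 0:
            # all counts above the quantile value cannot happen for q>0, but
            # guard against degenerate float behavior
            factors[i] = row.sum()
    values = x / factors[:, None] * scale_constant
    return NormalizedTable(
        sample_ids=list(counts.sample_ids),
        taxon_ids=list(counts.taxon_ids),
        values=values,
        scaling_factors=factors,
        scale_constant=float(scale_constant),
    )


def alpha_diversity(counts: CountTable) -> pd.DataFrame:
    """Richness and Shannon diversity (natural log) per sample.

    An all-zero sample gets richness 0 and Shannon 0 by convention.
    """
    x = counts.counts.astype(float)
    rich = (x > 0).sum(axis=1)
    tot = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, x / np.where(tot > 0, tot, 1.0), 0.0)
        logp = np.where(p > 0, np.log(p), 0.0)
    shannon = -(p * logp).sum(axis=1)
    return pd.DataFrame(
        {"sample_id": counts.sample_ids, "richness": rich, "shannon": shannon}
    )


def bray_curtis(table: CountTable | NormalizedTable | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix, d(a,b) = sum|a-b| / sum(a+b)."""
    if isinstance(table, (CountTable, NormalizedTable)):
        df = table.to_frame()
    else:
        df = table
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples for a dissimilarity matrix")
    x = df.to_numpy(dtype=float)
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [str(df.index[i]) for i in np.flatnonzero(zero)]
        raise ValueError(
            f"Bray-Curtis is undefined between all-zero samples: {', '.join(bad)}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def beta_dispersion(
    dist: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-sample distance to the group centroid in principal-coordinates
    space (the multivariate dispersion of each group).

    The distance matrix is embedded by eigendecomposition of the
    Gower-centered squared-distance matrix; axes with negative eigenvalues
    contribute *negatively* to squared distances (imaginary part), and the
    corrected squared distance is floored at zero before the square root.
    Samples that are alone in their group get dispersion 0.
    """
    ids = [str(s) for s in dist.index]
    missing = [s for s in ids if s not in groups]
    if missing:
        raise ValueError(f"unlabeled sample(s): {', '.join(missing)}")
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = (G + G.T) / 2
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = np.abs(eigval) > 1e-10 * max(np.abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    pos = eigval > 0
    coords_r = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_i = eigvec[:, ~pos] * np.sqrt(-eigval[~pos])
    labels = np.array([groups[s] for s in ids])
    disp = np.zeros(n)
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        if len(members) == 1:
            disp[members[0]] = 0.0
            continue
        cr = coords_r[members].mean(axis=0)
        ci = coords_i[members].mean(axis=0)
        d2 = ((coords_r[members] - cr) ** 2).sum(axis=1) - (
            (coords_i[members] - ci) ** 2
        ).sum(axis=1)
        disp[members] = np.sqrt(np.maximum(d2, 0.0))
    return pd.DataFrame(
        {"sample_id": ids, "group": labels, "distance_to_centroid": disp}
    )


def shared_features(
    counts: CountTable,
    groups: Mapping[str, str],
    min_samples: int = 1,
) -> pd.DataFrame:
    """UpSet-style shared/unique feature counts across sample groups.

    A feature is *present* in a group when it has a nonzero count in at
    least ``min_samples`` samples of that group. The result has one row per
    nonempty group combination (exclusive membership, as in an UpSet plot)
    plus a ``total`` row per group and an ``all_groups`` intersection row.
    """
    ids = counts.sample_ids
    missing = [s for s in ids if s not in groups]
    if missing:
        raise ValueError(f"unlabeled sample(s): {', '.join(missing)}")
    labels = np.array([groups[s] for s in ids])
    group_names = sorted(set(labels))
    presence = {}
    for g in group_names:
        rows = counts.counts[labels == g]
        presence[g] = (rows > 0).sum(axis=0) >= min_samples
    records = []
    # exclusive combination counts
    membership = np.stack([presence[g] for g in group_names])  # groups x taxa
    anywhere = membership.any(axis=0)
    for r in range(1, len(group_names) + 1):
        for combo in itertools.combinations(range(len(group_names)), r):
            in_combo = np.ones(counts.n_taxa, bool)
            for gi in range(len(group_names)):
                if gi in combo:
                    in_combo &= membership[gi]
                else:
                    in_combo &= ~membership[gi]
            cnt = int(in_combo.sum())
            if cnt > 0 or r == len(group_names):
                records.append(
                    {
                        "combination": "&".join(group_names[gi] for gi in combo),
                        "kind": "exclusive",
                        "n_features": cnt,
                    }
                )
    for g in group_names:
        records.append(
            {"combination": g, "kind": "total", "n_features": int(presence[g].sum())}
        )
    records.append(
        {
            "combination": "all_groups",
            "kind": "intersection",
            "n_features": int(membership.all(axis=0).sum()),
        }
    )
    records.append(
        {
            "combination": "any_group",
            "kind": "union",
            "n_features": int(anywhere.sum()),
        }
    )
    return pd.DataFrame.from_records(records)
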