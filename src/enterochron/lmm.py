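"""Random-intercept linear mixed models and the per-genus
differential-abundance scan.

The LMM is y = X beta + b_group + eps with one random intercept per group
(here: per pig, absorbing the repeated-measures correlation). The variance
ratio gamma = var(b)/var(eps) is profiled out of the REML criterion and
found by one-dimensional bounded optimization; fixed effects are then GLS
estimates at the optimum, with Wald tests against the normal reference.

The differential-abundance scan mirrors a Maaslin2-style workflow on
CSS-normalized values: prevalence/abundance filtering, log transform with a
per-genus half-minimum pseudo count, an LMM with age and cohort fixed
effects and a pig random intercept, Benjamini-Hochberg adjustment across
genera, and sign-based trend classification.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RandomInterceptLMM",
    "LMMResults",
    "fit_random_intercept_lmm",
    "bh_adjust",
    "differential_abundance_scan",
]


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class RandomInterceptLMM:
    """Linear mixed model with a single random intercept per group.

    Parameters
    ----------
    endog
        Outcome vector, length n.
    exog
        Fixed-effect design matrix (n x p). An intercept column is NOT
        added automatically.
    groups
        Grouping labels, length n (e.g. pig identifiers).
    exog_names
        Optional column names for reporting.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: Sequence,
        exog_names: Sequence[str] | None = None,
    ) -> None:
        self.y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        n, p = X.shape
        if len(self.y) != n or len(groups) != n:
            raise ValueError("endog, exog and groups must have equal length")
        if n <= p + 1:
            raise ValueError("need n_obs > n_fixed_effects + 1")
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(p)]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # name the columns past the numerical rank in a pivoted QR
            from scipy.linalg import qr

            _, _, piv = qr(X, mode="economic", pivoting=True)
            bad = sorted(self.exog_names[j] for j in piv[rank:])
            raise ValueError(f"singular fixed-effect design; collinear column(s): {', '.join(bad)}")
        codes, self.group_names = pd.factorize(np.asarray(groups))
        self.group_idx = [np.flatnonzero(codes == g) for g in range(len(self.group_names))]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        fixed: Sequence[str],
        group: str,
        add_intercept: bool = True,
    ) -> "RandomInterceptLMM":
        """Build the model from a tidy DataFrame; categorical fixed effects
        are dummy-coded (first level as reference)."""
        cols = []
        names = []
        if add_intercept:
            cols.append(np.ones(len(data)))
            names.append("Intercept")
        for f in fixed:
            col = data[f]
            if isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=f, drop_first=True)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy(dtype=float))
                    names.append(str(c))
                continue
            if col.dtype.kind in "fiu" and col.nunique() > 2:
                cols.append(col.to_numpy(dtype=float))
                names.append(f)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=f, drop_first=True)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy(dtype=float))
                    names.append(c)
        X = np.column_stack(cols)
        return cls(data[outcome].to_numpy(float), X, data[group].to_numpy(), names)

    # -- profiled REML machinery ------------------------------------------

    def _gls_pieces(self, gamma: float):
        """X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| for V = I + gamma*ZZ'."""
        p = self.X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        yty = 0.0
        logdetV = 0.0
        for idx in self.group_idx:
            Xi, yi = self.X[idx], self.y[idx]
            ni = len(idx)
            c = gamma / (1.0 + gamma * ni)
            sx, sy = Xi.sum(axis=0), yi.sum()
            XtVX += Xi.T @ Xi - c * np.outer(sx, sx)
            XtVy += Xi.T @ yi - c * sx * sy
            yty += yi @ yi - c * sy * sy
            logdetV += np.log1p(gamma * ni)
        return XtVX, XtVy, yty, logdetV

    def reml_criterion(self, gamma: float) -> float:
        """-2 x profile REML log-likelihood (up to an additive constant)."""
        n, p = self.X.shape
        XtVX, XtVy, yty, logdetV = self._gls_pieces(gamma)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yty - XtVy @ beta  # r' V^-1 r
        rss = max(rss, 1e-300)
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        return logdetV + logdetXtVX + (n - p) * np.log(rss / (n - p))

    def fit(self, method: str = "reml") -> "LMMResults":
        if method.lower() != "reml":
            raise ValueError("only REML fitting is implemented")
        # optimize over log(1+gamma) for a well-scaled 1-D search
        res = optimize.minimize_scalar(
            lambda t: self.reml_criterion(np.expm1(t)),
            bounds=(0.0, np.log1p(1e6)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = float(np.expm1(res.x))
        # snap to the boundary when gamma=0 does as well (within numerical
        # tolerance); with singleton groups the criterion is flat in gamma
        if self.reml_criterion(0.0) <= res.fun + 1e-8 * (abs(res.fun) + 1.0):
            gamma = 0.0
        n, p = self.X.shape
        XtVX, XtVy, yty, logdetV = self._gls_pieces(gamma)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yty - XtVy @ beta, 1e-300)
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(XtVX)
        bse = np.sqrt(np.diag(cov))
        z = beta / bse
        pvals = 2 * stats.norm.sf(np.abs(z))
        _, logdetXtVX = np.linalg.slogdet(XtVX)
        reml_ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2)
            + logdetV
            + logdetXtVX
            + (n - p)
        )
        return LMMResults(
            model=self,
            params=beta,
            bse=bse,
            pvalues=pvals,
            cov_params=cov,
            resid_var=float(sigma2),
            group_var=float(gamma * sigma2),
            variance_ratio=gamma,
            reml_loglik=float(reml_ll),
            boundary=gamma < 1e-6,
            n_obs=n,
            n_groups=len(self.group_idx),
        )


@dataclasses.dataclass
class LMMResults:
    """Fitted random-intercept LMM: estimates, Wald tests, variance
    components and the REML log-likelihood."""

    model: RandomInterceptLMM
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    cov_params: np.ndarray
    resid_var: float
    group_var: float
    variance_ratio: float
    reml_loglik: float
    boundary: bool
    n_obs: int
    n_groups: int

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def wald_contrast(self, L: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and two-sided normal p for a contrast L'beta."""
        L = np.asarray(L, float).ravel()
        est = float(L @ self.params)
        se = float(np.sqrt(L @ self.cov_params @ L))
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
        return est, se, p

    def pairwise_contrasts(self, names: Sequence[str]) -> pd.DataFrame:
        """All pairwise Wald contrasts among the listed coefficients (plus
        the implicit reference level at zero), BH-adjusted."""
        idx = {nm: self.exog_names.index(nm) for nm in names}
        levels = ["<reference>"] + list(names)
        rows = []
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                L = np.zeros(len(self.params))
                if a != "<reference>":
                    L[idx[a]] = 1.0
                L_b = np.zeros(len(self.params))
                L_b[idx[b]] = 1.0
                est, se, p = self.wald_contrast(L - L_b)
                rows.append({"a": a, "b": b, "estimate": est, "se": se, "p_value": p})
        out = pd.DataFrame(rows)
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        return out

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (REML)",
            f"  n_obs: {self.n_obs}   n_groups: {self.n_groups}",
            f"  group var: {self.group_var:.5g}   residual var: {self.resid_var:.5g}"
            + ("   [boundary: group var ~ 0]" if self.boundary else ""),
            f"  REML log-likelihood: {self.reml_loglik:.4f}",
            f"  {'term':<24}{'coef':>12}{'se':>12}{'z':>9}{'P>|z|':>10}",
        ]
        for nm, b, s, p in zip(self.exog_names, self.params, self.bse, self.pvalues):
            z = b / s if s > 0 else np.nan
            lines.append(f"  {nm:<24}{b:>12.5g}{s:>12.5g}{z:>9.3f}{p:>10.3g}")
        return "\n".join(lines)


def fit_random_intercept_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    method: str = "reml",
    exog_names: Sequence[str] | None = None,
) -> LMMResults:
    """Convenience wrapper: build and fit a :class:`RandomInterceptLMM`."""
    return RandomInterceptLMM(y, X, groups, exog_names).fit(method=method)


def differential_abundance_scan(
    norm_counts,
    metadata: pd.DataFrame,
    min_mean_ra: float = 0.0001,
    alpha_p: float = 0.05,
    alpha_q: float = 0.25,
) -> pd.DataFrame:
    """Per-genus longitudinal differential-abundance scan.

    Genera with mean relative abundance below ``min_mean_ra`` (default
    0.01%) are dropped; each remaining genus is log-transformed
    (normalized value + half its smallest nonzero normalized value) and
    fitted with fixed effects age (continuous weeks) + cohort and a pig
    random intercept. Age p-values are BH-adjusted across genera; a genus
    trends increased/decreased by the sign of its age coefficient when
    p < ``alpha_p`` and q < ``alpha_q``, else ns.

    ``metadata`` needs columns sample_id, pig_id, cohort, age_weeks.
    """
    values = norm_counts.to_frame() if hasattr(norm_counts, "to_frame") else norm_counts
    meta = metadata.set_index("sample_id").loc[values.index]
    ra = values.div(values.sum(axis=1), axis=0)
    keep = ra.mean(axis=0) >= min_mean_ra
    rows = []
    pvals = []
    kept = []
    for genus in values.columns[keep]:
        v = values[genus].to_numpy(float)
        nonzero = v[v > 0]
        if nonzero.size == 0:
            warnings.warn(f"genus {genus!r} is all-zero after filtering; skipped")
            continue
        y = np.log(v + nonzero.min() / 2.0)
        if np.allclose(y, y[0]):
            warnings.warn(f"genus {genus!r} constant after transform; skipped")
            continue
        df = pd.DataFrame(
            {
                "y": y,
                "age_weeks": meta["age_weeks"].to_numpy(float),
                "cohort": meta["cohort"].astype(str).to_numpy(),
                "pig_id": meta["pig_id"].to_numpy(),
            }
        )
        fit = RandomInterceptLMM.from_dataframe(
            df, "y", ["age_weeks", "cohort"], "pig_id"
        ).fit()
        j = fit.exog_names.index("age_weeks")
        rows.append(
            {
                "genus": genus,
                "age_coef": fit.params[j],
                "p_value": fit.pvalues[j],
                "prevalence": float((v > 0).mean()),
                "mean_relative_abundance": float(ra[genus].mean()),
            }
        )
        pvals.append(fit.pvalues[j])
        kept.append(genus)
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    out["q_value"] = bh_adjust(np.array(pvals))
    sig = (out["p_value"] < alpha_p) & (out["q_value"] < alpha_q)
    out["trend"] = np.where(
        sig, np.where(out["age_coef"] > 0, "increased", "decreased"), "ns"
    )
    return out[
        [
            "genus",
            "age_coef",
            "p_value",
            "q_value",
            "trend",
            "prevalence",
            "mean_relative_abundance",
        ]
    ]
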