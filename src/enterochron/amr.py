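"""Penalized-spline age trends with continuous-time AR(1) errors for
resistant-bacteria plate counts, and qPCR gene-copy standardization.

The trend model is y = B(age) beta + cohort gamma + e, with B a cubic
B-spline basis (knots at age quantiles), a curvature penalty (integrated
squared derivative of configurable order, smoothing parameter chosen by
GCV), and within-animal residual correlation corr(e_s, e_t) =
phi^|t - s| in weeks. Fitting alternates penalized GLS on the whitened
problem with maximum-likelihood estimation of phi from the residuals.
Change windows are the maximal age intervals where the pointwise 95%
confidence band of the fitted curve's first derivative excludes zero.

Plate counts of zero (no growth) are left-censored at the detection limit
and excluded from fitting by default; an alternative substitutes half the
detection limit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

from enterochron.lmm import RandomInterceptLMM, LMMResults

__all__ = [
    "SplineTrendAR1",
    "TrendFitResults",
    "DerivativeBand",
    "SignificanceWindow",
    "fit_penalized_spline_ar1",
    "derivative_band",
    "significance_windows",
    "standardize_gene_copies",
    "qpcr_age_models",
]


def _knot_vector(age: np.ndarray, n_knots: int, degree: int) -> np.ndarray:
    """Quantile-placed knots over the observed age range, deduplicated,
    with boundary knots repeated degree+1 times."""
    uniq = np.unique(age)
    inner = np.unique(np.quantile(uniq, np.linspace(0, 1, n_knots)))
    return np.concatenate(
        [np.repeat(inner[0], degree), inner, np.repeat(inner[-1], degree)]
    )


def _basis(t: np.ndarray, degree: int, x: np.ndarray, deriv: int = 0) -> np.ndarray:
    n_basis = len(t) - degree - 1
    spl = BSpline(t, np.eye(n_basis), degree, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(x)
    return np.nan_to_num(out)


def _derivative_penalty(t: np.ndarray, degree: int, order: int) -> np.ndarray:
    """Penalty matrix  P_jk = integral of B_j^(m) B_k^(m)  over the knot
    span (O'Sullivan penalty).

    Its null space is exactly the polynomials of degree ``order - 1``
    whatever the knot spacing, so lambda -> infinity shrinks the fit to the
    best such polynomial (a straight line for the default order 2).
    Computed exactly by Gauss-Legendre quadrature on each inter-knot
    interval (the integrand is piecewise polynomial of degree
    2*(degree - order)).
    """
    if order > degree:
        raise ValueError("penalty order cannot exceed the spline degree")
    n_basis = len(t) - degree - 1
    spl = BSpline(t, np.eye(n_basis), degree, extrapolate=False)
    dspl = spl.derivative(order)
    nodes, weights = np.polynomial.legendre.leggauss(degree - order + 1)
    P = np.zeros((n_basis, n_basis))
    breaks = np.unique(t)
    for a, b in zip(breaks[:-1], breaks[1:]):
        x = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        w = 0.5 * (b - a) * weights
        Dm = np.nan_to_num(dspl(x))
        P += (Dm * w[:, None]).T @ Dm
    return P


def _ar1_negloglik(phi: float, resid_by_group) -> float:
    """-2 profile log-likelihood of a stationary continuous-time AR(1)
    over grouped residual series (profiled innovation scale)."""
    q = 0.0
    logdet = 0.0
    n = 0
    for e, tt in resid_by_group:
        q += e[0] ** 2
        n += len(e)
        for i in range(1, len(e)):
            rho = phi ** (tt[i] - tt[i - 1])
            v = max(1.0 - rho**2, 1e-12)
            q += (e[i] - rho * e[i - 1]) ** 2 / v
            logdet += np.log(v)
    if q <= 0:
        return np.inf
    return n * np.log(q / n) + logdet


def _estimate_phi(resid: np.ndarray, groups: np.ndarray, age: np.ndarray) -> float:
    """Continuous-time AR(1) decay per week, restricted to [0, 1) - the
    only range for which phi^|dt| is a valid correlation function in
    continuous time (an Ornstein-Uhlenbeck decay)."""
    by_group = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        order = idx[np.argsort(age[idx])]
        if len(order) >= 2:
            by_group.append((resid[order], age[order]))
    if not by_group or np.var(resid) < 1e-12:
        return 0.0
    res = optimize.minimize_scalar(
        _ar1_negloglik, args=(by_group,), bounds=(0.0, 0.999), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(res.x)
    if _ar1_negloglik(0.0, by_group) <= res.fun:
        phi = 0.0
    if phi > 0.998:
        warnings.warn("AR(1) phi estimate at the stationarity boundary")
    return phi


def _whiten(y, X, groups, age, phi):
    """Per-group Cholesky whitening under corr = phi^|dt|."""
    if phi == 0.0:
        return y.copy(), X.copy()
    yw = y.copy()
    Xw = X.copy()
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        order = idx[np.argsort(age[idx])]
        tt = age[order]
        R = phi ** np.abs(tt[:, None] - tt[None, :])
        np.fill_diagonal(R, 1.0)
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            # repeated time points make R singular; a small ridge keeps the
            # whitening defined while leaving distinct-age correlation intact
            warnings.warn(
                "singular within-group correlation (repeated ages); "
                "ridge-regularized whitening applied"
            )
            L = np.linalg.cholesky(R + 1e-6 * np.eye(len(tt)))
        yw[order] = np.linalg.solve(L, y[order])
        Xw[order] = np.linalg.solve(L, X[order])
    return yw, Xw


@dataclasses.dataclass
class SignificanceWindow:
    """A maximal age interval of significant change in the fitted trend."""

    start: float
    end: float
    direction: str  # "increasing" or "decreasing"


@dataclasses.dataclass
class DerivativeBand:
    """Pointwise first-derivative estimate with its confidence bounds."""

    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


class SplineTrendAR1:
    """Penalized-spline trend over age with AR(1) within-animal errors.

    Parameters
    ----------
    y
        Outcome (log10 CFU/g). NaN entries (no growth) are dropped before
        fitting unless ``censor_substitute`` is set, in which case they
        are replaced by that value (e.g. half the detection limit).
    age, cohort, pig
        Aligned covariate vectors; cohort enters as a linear parametric
        term, pig defines the correlation groups.
    """

    def __init__(
        self,
        y: np.ndarray,
        age: np.ndarray,
        cohort: np.ndarray | None = None,
        pig: np.ndarray | None = None,
        n_knots: int = 9,
        degree: int = 3,
        penalty_order: int = 2,
        censor_substitute: float | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        age = np.asarray(age, dtype=float)
        if censor_substitute is not None:
            y = np.where(np.isnan(y), censor_substitute, y)
        keep = ~np.isnan(y)
        self.y = y[keep]
        self.age = age[keep]
        self.cohort = (
            np.asarray(cohort)[keep] if cohort is not None else None
        )
        self.pig = (
            np.asarray(pig)[keep]
            if pig is not None
            else np.arange(keep.sum())  # no grouping: every obs its own series
        )
        if len(np.unique(self.age)) < 2:
            raise ValueError("ages must span at least 2 distinct values")
        if len(self.y) < n_knots + degree + 2:
            raise ValueError(
                f"need at least n_knots + degree + 2 = {n_knots + degree + 2} "
                f"observations, got {len(self.y)}"
            )
        self.degree = degree
        self.knots = _knot_vector(self.age, n_knots, degree)
        self.n_basis = len(self.knots) - degree - 1
        B = _basis(self.knots, degree, self.age)
        if self.cohort is not None:
            levels = np.unique(self.cohort)
            extra = [
                (self.cohort == lev).astype(float) for lev in levels[1:]
            ]  # first level is reference, absorbed by the spline's constant
            self.X = np.column_stack([B] + extra)
            self.n_parametric = len(extra)
        else:
            self.X = B
            self.n_parametric = 0
        P = _derivative_penalty(self.knots, degree, penalty_order)
        self.P = np.zeros((self.X.shape[1], self.X.shape[1]))
        self.P[: self.n_basis, : self.n_basis] = P

    def _penalized_gls(self, lam: float, yw: np.ndarray, Xw: np.ndarray):
        M = Xw.T @ Xw + lam * self.P
        Minv = np.linalg.pinv(M)
        beta = Minv @ (Xw.T @ yw)
        fitted_w = Xw @ beta
        edf = float(np.trace(Minv @ (Xw.T @ Xw)))
        rss = float(((yw - fitted_w) ** 2).sum())
        return beta, Minv, edf, rss

    def _gcv_lambda(self, yw, Xw, grid: np.ndarray) -> float:
        n = len(yw)
        gcvs = np.empty(len(grid))
        for i, lam in enumerate(grid):
            _, _, edf, rss = self._penalized_gls(lam, yw, Xw)
            denom = max(n - edf, 1e-8)
            gcvs[i] = n * rss / denom**2
        best = gcvs.min()
        # near-ties go to the largest (smoothest) lambda: when the data are
        # fit equally well at every lambda (e.g. a noiseless polynomial in
        # the penalty null space) GCV carries no smoothness signal
        ok = gcvs <= best * (1.0 + 1e-8) + 1e-12
        return float(np.asarray(grid)[ok].max())

    def fit(
        self,
        lambda_: float | None = None,
        lambda_grid: np.ndarray | None = None,
        max_iter: int = 20,
        tol: float = 1e-4,
    ) -> "TrendFitResults":
        """Iterated GLS: penalized spline fit, AR(1) estimation from the
        residuals, refit on the whitened data; repeated until phi settles."""
        if lambda_grid is None:
            lambda_grid = np.logspace(-4, 6, 41)
        phi = 0.0
        converged = False
        yw, Xw = self.y, self.X
        beta = Minv = None
        lam = lambda_
        for _ in range(max_iter):
            lam_use = lambda_ if lambda_ is not None else self._gcv_lambda(
                yw, Xw, lambda_grid
            )
            beta, Minv, edf, rss = self._penalized_gls(lam_use, yw, Xw)
            resid = self.y - self.X @ beta
            phi_new = _estimate_phi(resid, self.pig, self.age)
            lam = lam_use
            if abs(phi_new - phi) < tol:
                phi = phi_new
                converged = True
                break
            phi = phi_new
            yw, Xw = _whiten(self.y, self.X, self.pig, self.age, phi)
        if not converged:
            warnings.warn("AR(1)/spline iteration did not converge")
        yw, Xw = _whiten(self.y, self.X, self.pig, self.age, phi)
        beta, Minv, edf, rss = self._penalized_gls(lam, yw, Xw)
        n = len(self.y)
        sigma2 = rss / max(n - edf, 1e-8)
        cov = sigma2 * (Minv @ (Xw.T @ Xw) @ Minv)
        cov = (cov + cov.T) / 2
        return TrendFitResults(
            model=self,
            coef=beta,
            cov=cov,
            lambda_=float(lam),
            phi=float(phi),
            sigma2=float(sigma2),
            edf=float(edf),
            fitted=self.X @ beta,
            converged=converged,
        )


@dataclasses.dataclass
class TrendFitResults:
    """Fitted penalized-spline AR(1) trend."""

    model: SplineTrendAR1
    coef: np.ndarray
    cov: np.ndarray
    lambda_: float
    phi: float
    sigma2: float
    edf: float
    fitted: np.ndarray
    converged: bool

    @property
    def cohort_effect(self) -> float | None:
        if self.model.n_parametric == 0:
            return None
        return float(self.coef[self.model.n_basis])

    def _check_grid(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.model.age.min(), self.model.age.max()
        if (grid < lo).any() or (grid > hi).any():
            raise ValueError(
                f"grid extends outside the fitted age range [{lo}, {hi}]"
            )
        return grid

    def predict(self, grid: np.ndarray, cohort_level: int = 0) -> np.ndarray:
        grid = self._check_grid(grid)
        B = _basis(self.model.knots, self.model.degree, grid)
        mu = B @ self.coef[: self.model.n_basis]
        if cohort_level and self.model.n_parametric:
            mu = mu + self.coef[self.model.n_basis + cohort_level - 1]
        return mu

    def derivative_band(self, grid: np.ndarray, level: float = 0.95) -> DerivativeBand:
        """Analytic first derivative of the spline with pointwise CI."""
        grid = self._check_grid(grid)
        dB = _basis(self.model.knots, self.model.degree, grid, deriv=1)
        rows = np.zeros((len(grid), len(self.coef)))
        rows[:, : self.model.n_basis] = dB
        est = rows @ self.coef
        var = np.einsum("ij,jk,ik->i", rows, self.cov, rows)
        se = np.sqrt(np.maximum(var, 0.0))
        z = stats.norm.ppf(0.5 + level / 2)
        return DerivativeBand(
            grid=grid, estimate=est, lower=est - z * se, upper=est + z * se,
            level=level,
        )

    def significance_windows(
        self, grid: np.ndarray | None = None, level: float = 0.95
    ) -> list[SignificanceWindow]:
        if grid is None:
            grid = np.linspace(self.model.age.min(), self.model.age.max(), 200)
        return significance_windows(self.derivative_band(grid, level))

    def summary(self) -> str:
        lines = [
            "Penalized-spline trend with continuous-time AR(1) errors",
            f"  n_obs: {len(self.model.y)}   basis: {self.model.n_basis} "
            f"(degree {self.model.degree})   edf: {self.edf:.2f}",
            f"  lambda: {self.lambda_:.4g}   phi (per week): {self.phi:.3f}"
            f"   sigma2: {self.sigma2:.4g}",
        ]
        if self.cohort_effect is not None:
            se = np.sqrt(self.cov[self.model.n_basis, self.model.n_basis])
            lines.append(f"  cohort effect: {self.cohort_effect:.4f} (se {se:.4f})")
        wins = self.significance_windows()
        if wins:
            for w in wins:
                lines.append(
                    f"  {w.direction} from {w.start:.1f} to {w.end:.1f} weeks"
                )
        else:
            lines.append("  no significant change windows")
        return "\n".join(lines)


def fit_penalized_spline_ar1(
    y: np.ndarray,
    age: np.ndarray,
    cohort: np.ndarray | None = None,
    pig: np.ndarray | None = None,
    n_knots: int = 9,
    degree: int = 3,
    penalty_order: int = 2,
    lambda_: float | None = None,
    censor_substitute: float | None = None,
) -> TrendFitResults:
    """Convenience wrapper over :class:`SplineTrendAR1`."""
    return SplineTrendAR1(
        y, age, cohort=cohort, pig=pig, n_knots=n_knots, degree=degree,
        penalty_order=penalty_order, censor_substitute=censor_substitute,
    ).fit(lambda_=lambda_)


def derivative_band(
    fit: TrendFitResults, grid: np.ndarray, level: float = 0.95
) -> DerivativeBand:
    return fit.derivative_band(grid, level)


def significance_windows(band: DerivativeBand) -> list[SignificanceWindow]:
    """Maximal intervals where the derivative CI is bounded away from zero.

    Window endpoints falling between grid points are located by linear
    interpolation of the relevant confidence bound's zero crossing.
    """

    def crossings(bound: np.ndarray, positive: bool) -> list[tuple[float, float]]:
        sig = bound > 0 if positive else bound < 0
        out = []
        g = band.grid
        i = 0
        while i < len(g):
            if not sig[i]:
                i += 1
                continue
            # start of a run: interpolate the entry point
            if i == 0:
                start = g[0]
            else:
                b0, b1 = bound[i - 1], bound[i]
                frac = abs(b0) / max(abs(b1 - b0), 1e-300)
                start = g[i - 1] + frac * (g[i] - g[i - 1])
            j = i
            while j + 1 < len(g) and sig[j + 1]:
                j += 1
            if j == len(g) - 1:
                end = g[-1]
            else:
                b0, b1 = bound[j], bound[j + 1]
                frac = abs(b0) / max(abs(b1 - b0), 1e-300)
                end = g[j] + frac * (g[j + 1] - g[j])
            out.append((float(start), float(end)))
            i = j + 1
        return out

    windows = [
        SignificanceWindow(s, e, "increasing")
        for s, e in crossings(band.lower, positive=True)
    ] + [
        SignificanceWindow(s, e, "decreasing")
        for s, e in crossings(band.upper, positive=False)
    ]
    return sorted(windows, key=lambda w: w.start)


def standardize_gene_copies(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample log10 absolute and 16S-standardized gene copies.

    standardized = log10(gene copies) - log10(16S copies). Samples with a
    missing or zero 16S record keep their absolute value but get a missing
    standardized value and a flag.
    """
    ref = (
        qpcr[qpcr["gene"] == "16S"]
        .set_index("sample_id")["copies_per_g"]
        .to_dict()
    )
    rows = []
    for _, r in qpcr[qpcr["gene"] != "16S"].iterrows():
        sid = r["sample_id"]
        if r["copies_per_g"] <= 0:
            warnings.warn(f"non-positive copy number for {r['gene']} in {sid!r}")
            continue
        log_abs = float(np.log10(r["copies_per_g"]))
        ref_val = ref.get(sid, 0.0)
        if ref_val and ref_val > 0:
            rows.append(
                {
                    "sample_id": sid,
                    "gene": r["gene"],
                    "log10_copies_per_g": log_abs,
                    "log10_standardized": log_abs - float(np.log10(ref_val)),
                    "missing_16s": False,
                }
            )
        else:
            rows.append(
                {
                    "sample_id": sid,
                    "gene": r["gene"],
                    "log10_copies_per_g": log_abs,
                    "log10_standardized": np.nan,
                    "missing_16s": True,
                }
            )
    if any(r["missing_16s"] for r in rows):
        warnings.warn("samples without a positive 16S record were flagged")
    return pd.DataFrame(rows)


def qpcr_age_models(
    qpcr: pd.DataFrame, metadata: pd.DataFrame
) -> dict[tuple[str, str], LMMResults]:
    """Random-intercept LMMs of qPCR outcomes on categorical age + cohort.

    Returns a fit per (gene, outcome) with outcome "absolute" or
    "standardized"; flagged (missing-16S) records are excluded from the
    standardized models.
    """
    std = standardize_gene_copies(qpcr)
    meta = metadata.set_index("sample_id")
    fits: dict[tuple[str, str], LMMResults] = {}
    for gene in std["gene"].unique():
        sub = std[std["gene"] == gene].set_index("sample_id")
        for outcome, col in (("absolute", "log10_copies_per_g"),
                             ("standardized", "log10_standardized")):
            y = sub[col].dropna()
            df = pd.DataFrame(
                {
                    "y": y.to_numpy(float),
                    "age": meta.loc[y.index, "age_weeks"].astype(float).astype(int).astype(str).to_numpy(),
                    "cohort": meta.loc[y.index, "cohort"].astype(str).to_numpy(),
                    "pig_id": meta.loc[y.index, "pig_id"].to_numpy(),
                }
            )
            # order age levels numerically so contrasts are readable
            df["age"] = pd.Categorical(
                df["age"], categories=sorted(df["age"].unique(), key=float)
            )
            fits[(gene, outcome)] = RandomInterceptLMM.from_dataframe(
                df, "y", ["age", "cohort"], "pig_id"
            ).fit()
    return fits
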