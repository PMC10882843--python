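"""Dirichlet-multinomial mixture (DMM) enterotyping.

A sample's taxon count vector x (total n) under one component with
concentration vector alpha (total A) has log-density

    log Gamma(A) - log Gamma(n + A) + log Gamma(n + 1)
    + sum_j [ log Gamma(x_j + a_j) - log Gamma(a_j) - log Gamma(x_j + 1) ],

an overdispersed multinomial that captures the large sample-to-sample
variability of community profiles. A K-component mixture of these
densities is fitted by EM: responsibilities with log-sum-exp in the
E-step, and in the M-step each component's responsibility-weighted
log-likelihood is increased over log(alpha) by a warm-started bounded
quasi-Newton step (a generalized EM, which preserves the monotone
ascent). Following standard practice for community typing, the fit is a
MAP estimate under a weak Gamma(0.1, 0.1) prior on every concentration
parameter: with ~100 taxa and a few dozen samples many concentrations are
only weakly identified, and the prior both regularizes the optimum and
keeps the model-evidence integral proper. The number of community types
is chosen by the lowest Laplace approximation to the negative log model
evidence,

    -[ log L(theta_hat) + log p(theta_hat) + d/2 log 2 pi
       - 1/2 log det H ],

with d = K*S + (K-1) free parameters and H the analytic Hessian of the
negative penalized objective at the optimum in the unconstrained
parameterization (log concentrations, weight logits), assembled from the
responsibility-weighted per-component blocks plus the mixture-weight
block. Samples are assigned to the component with maximum posterior
probability.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster.vq import kmeans2
from scipy.special import gammaln, logsumexp, polygamma, psi

from enterochron.io import CountTable, SampleRecord

__all__ = [
    "DirichletMultinomialMixture",
    "DMMResults",
    "TrajectorySummary",
    "dm_log_likelihood",
    "fit_mixture",
    "laplace_score",
    "select_k",
    "assign_enterotypes",
    "trajectories",
]

_LOG_ALPHA_BOUNDS = (-12.0, 12.0)

# Gamma(shape, rate) prior on each concentration parameter; in the
# log-alpha parameterization (Jacobian absorbed) the log-density is
# shape*lambda - rate*exp(lambda) up to a constant.
PRIOR_SHAPE = 0.1
PRIOR_RATE = 0.1


def _log_prior(log_alphas: np.ndarray) -> float:
    """Log prior density of the concentration parameters (log-alpha space),
    including the Gamma normalizing constant."""
    la = np.asarray(log_alphas)
    const = PRIOR_SHAPE * np.log(PRIOR_RATE) - gammaln(PRIOR_SHAPE)
    return float(
        np.sum(PRIOR_SHAPE * la - PRIOR_RATE * np.exp(la)) + const * la.size
    )


def dm_log_likelihood(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log-probability of one count vector under a Dirichlet-multinomial.

    Computed entirely with log-gamma; includes the multinomial
    coefficient, so probabilities over all compositions of a fixed total
    sum to one.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("all concentration parameters must be positive")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    n, A = x.sum(), alpha.sum()
    return float(
        gammaln(A)
        - gammaln(n + A)
        + gammaln(n + 1)
        + np.sum(gammaln(x + alpha) - gammaln(alpha) - gammaln(x + 1))
    )


def _component_loglik(X: np.ndarray, totals: np.ndarray, const: np.ndarray,
                      alpha: np.ndarray) -> np.ndarray:
    """Vectorized DM log-likelihood of every sample row under one alpha."""
    A = alpha.sum()
    return (
        gammaln(A)
        - gammaln(totals + A)
        + const
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _weighted_neg_objective(log_alpha: np.ndarray, X: np.ndarray, totals: np.ndarray,
                            r: np.ndarray) -> tuple[float, np.ndarray]:
    """Responsibility-weighted negative penalized DM log-likelihood (MAP
    objective) and its gradient in log(alpha); the multinomial-coefficient
    and prior-normalization constants are omitted."""
    alpha = np.exp(log_alpha)
    A = alpha.sum()
    ll = r @ (
        gammaln(A) - gammaln(totals + A)
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )
    ll += np.sum(PRIOR_SHAPE * log_alpha - PRIOR_RATE * alpha)
    R = r.sum()
    grad_alpha = (
        R * psi(A)
        - r @ psi(totals + A)
        + r @ (psi(X + alpha) - psi(alpha))
    )
    grad_log = alpha * grad_alpha + (PRIOR_SHAPE - PRIOR_RATE * alpha)
    return -float(ll), -grad_log


@dataclasses.dataclass
class TrajectorySummary:
    """Per-pig enterotype sequences and cohort-level transition structure."""

    per_pig: pd.DataFrame  # columns: pig_id, age_weeks, enterotype
    age_proportions: pd.DataFrame  # ages x enterotypes, rows sum to 1
    transitions: pd.DataFrame  # K x K counts over consecutive-age pairs


class DirichletMultinomialMixture:
    """DMM model bound to a genus/ASV count table.

    The likelihood models raw counts (library size enters through the
    multinomial total), so the input is the unnormalized count table.
    """

    def __init__(self, counts: CountTable | np.ndarray, K: int) -> None:
        if isinstance(counts, CountTable):
            self.sample_ids = list(counts.sample_ids)
            self.taxon_ids = list(counts.taxon_ids)
            X = counts.counts.astype(float)
        else:
            X = np.asarray(counts, dtype=float)
            self.sample_ids = [f"S{i}" for i in range(X.shape[0])]
            self.taxon_ids = [f"T{j}" for j in range(X.shape[1])]
        if K < 1:
            raise ValueError("K must be >= 1")
        if X.shape[0] < K:
            raise ValueError(f"need at least K={K} samples, got {X.shape[0]}")
        self.X = X
        self.K = K
        self.totals = X.sum(axis=1)
        self.const = gammaln(self.totals + 1) - gammaln(X + 1).sum(axis=1)

    # -- initialization ----------------------------------------------------

    def _initial_alphas(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Seeded k-means on proportion profiles; moment-style concentration."""
        n, S = self.X.shape
        props = self.X / np.maximum(self.totals[:, None], 1.0)
        jitter = 1e-6 * rng.standard_normal(props.shape)
        if self.K == 1:
            labels = np.zeros(n, int)
        else:
            _, labels = kmeans2(
                props + jitter, self.K, minit="++", seed=rng, missing="warn"
            )
        alphas = np.empty((self.K, S))
        weights = np.empty(self.K)
        for k in range(self.K):
            members = props[labels == k]
            if len(members) == 0:  # re-seed an empty cluster from one sample
                members = props[rng.integers(n)][None, :]
            mean_p = members.mean(axis=0)
            alphas[k] = np.maximum(mean_p, 1e-6) * 50.0
            weights[k] = max(len(members), 1)
        weights /= weights.sum()
        return np.log(alphas), weights

    # -- EM ---------------------------------------------------------------

    def _e_step(self, log_alphas: np.ndarray, weights: np.ndarray):
        K = log_alphas.shape[0]
        logp = np.empty((self.X.shape[0], K))
        for k in range(K):
            logp[:, k] = _component_loglik(
                self.X, self.totals, self.const, np.exp(log_alphas[k])
            )
        joint = logp + np.log(weights)
        norm = logsumexp(joint, axis=1)
        return np.exp(joint - norm[:, None]), float(norm.sum())

    def fit(
        self,
        n_restarts: int = 5,
        max_iter: int = 200,
        tol: float = 1e-6,
        seed: int | None = None,
        inner_maxiter: int = 15,
    ) -> "DMMResults":
        """Best-of-restarts generalized EM fit.

        ``tol`` is on the relative log-likelihood change between EM sweeps;
        ``inner_maxiter`` caps the quasi-Newton steps of each M-step (warm
        started, so the overall ascent remains monotone).
        """
        master = np.random.default_rng(seed)
        best: DMMResults | None = None
        for _ in range(max(n_restarts, 1)):
            rng = np.random.default_rng(master.integers(2**31 - 1))
            res = self._fit_once(rng, max_iter, tol, inner_maxiter)
            if best is None or res.log_likelihood > best.log_likelihood:
                best = res
        return best

    def _fit_once(self, rng, max_iter: int, tol: float,
                  inner_maxiter: int) -> "DMMResults":
        log_alphas, weights = self._initial_alphas(rng)
        trace: list[float] = []
        prev = -np.inf
        converged = False
        r, ll = self._e_step(log_alphas, weights)
        for it in range(max_iter):
            # M-step: weights exactly, concentrations by warm-started ascent
            weights = np.maximum(r.mean(axis=0), 1e-12)
            weights /= weights.sum()
            for k in range(self.K):
                if r[:, k].sum() < 1e-10:
                    continue
                f0, _ = _weighted_neg_objective(
                    log_alphas[k], self.X, self.totals, r[:, k]
                )
                opt = optimize.minimize(
                    _weighted_neg_objective,
                    log_alphas[k],
                    args=(self.X, self.totals, r[:, k]),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[_LOG_ALPHA_BOUNDS] * self.X.shape[1],
                    options={"maxiter": inner_maxiter},
                )
                if opt.fun <= f0:  # keep only improving updates (GEM)
                    log_alphas[k] = opt.x
            r, ll = self._e_step(log_alphas, weights)
            objective = ll + _log_prior(log_alphas)
            trace.append(objective)
            if np.isfinite(prev) and abs(objective - prev) <= tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = objective
        if not converged:
            warnings.warn(
                f"DMM EM did not converge in {max_iter} iterations (K={self.K})"
            )
        # prune empty components
        alive = weights > 1e-6
        if not alive.all():
            warnings.warn(
                f"pruned {int((~alive).sum())} empty DMM component(s) (K={self.K})"
            )
            log_alphas = log_alphas[alive]
            weights = weights[alive] / weights[alive].sum()
            r, ll = self._e_step(log_alphas, weights)
        return DMMResults(
            model=self,
            K=int(alive.sum()) if not alive.all() else self.K,
            weights=weights,
            alphas=np.exp(log_alphas),
            log_likelihood=ll,
            loglik_trace=np.array(trace),
            n_em_iterations=len(trace),
            converged=converged,
        )


@dataclasses.dataclass
class DMMResults:
    """A fitted DMM: component weights/concentrations, log-likelihood
    trace, and the Laplace model-evidence score."""

    model: DirichletMultinomialMixture
    K: int
    weights: np.ndarray
    alphas: np.ndarray
    log_likelihood: float
    loglik_trace: np.ndarray
    n_em_iterations: int
    converged: bool
    _laplace: float | None = dataclasses.field(default=None, repr=False)

    @property
    def n_free_parameters(self) -> int:
        return self.K * self.alphas.shape[1] + (self.K - 1)

    def component_means(self) -> np.ndarray:
        """Expected taxon proportions of each component."""
        return self.alphas / self.alphas.sum(axis=1, keepdims=True)

    def top_taxa(self, k: int, n: int = 10) -> pd.Series:
        means = self.component_means()[k]
        order = np.argsort(means)[::-1][:n]
        return pd.Series(means[order], index=[self.model.taxon_ids[j] for j in order])

    def laplace(self) -> float:
        if self._laplace is None:
            self._laplace = laplace_score(self)
        return self._laplace

    def posterior(self, counts: CountTable | np.ndarray | None = None) -> pd.DataFrame:
        """Posterior component probabilities per sample (log-sum-exp)."""
        if counts is None:
            X, ids = self.model.X, self.model.sample_ids
        elif isinstance(counts, CountTable):
            X, ids = counts.counts.astype(float), list(counts.sample_ids)
        else:
            X = np.asarray(counts, float)
            ids = [f"S{i}" for i in range(X.shape[0])]
        if X.shape[1] != self.alphas.shape[1]:
            raise ValueError(
                f"sample dimension {X.shape[1]} does not match model "
                f"({self.alphas.shape[1]} taxa)"
            )
        totals = X.sum(axis=1)
        const = gammaln(totals + 1) - gammaln(X + 1).sum(axis=1)
        logp = np.empty((X.shape[0], self.K))
        for k in range(self.K):
            logp[:, k] = _component_loglik(X, totals, const, self.alphas[k])
        joint = logp + np.log(self.weights)
        post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
        return pd.DataFrame(
            post, index=ids, columns=[f"E{k + 1}" for k in range(self.K)]
        )

    def summary(self) -> str:
        lines = [
            f"Dirichlet-multinomial mixture, K={self.K}",
            f"  log-likelihood: {self.log_likelihood:.3f}"
            f"   Laplace(-log evidence): {self.laplace():.3f}",
            f"  EM iterations: {self.n_em_iterations}"
            f"   converged: {self.converged}",
        ]
        for k in range(self.K):
            tops = self.top_taxa(k, 3)
            top_str = ", ".join(f"{t} ({v:.2f})" for t, v in tops.items())
            lines.append(
                f"  E{k + 1}: weight={self.weights[k]:.3f}  "
                f"A={self.alphas[k].sum():.1f}  top: {top_str}"
            )
        return "\n".join(lines)


def _dm_grad_hess_logalpha(X, totals, alpha):
    """Per-sample gradient (n,S) and the pieces of the Hessian of the DM
    log-likelihood with respect to log(alpha)."""
    A = alpha.sum()
    g_alpha = (psi(A) - psi(totals + A))[:, None] + psi(X + alpha) - psi(alpha)
    grad = alpha * g_alpha  # chain rule to log-alpha
    # Hessian wrt alpha: c_i * 11' + diag(psi1(x+a) - psi1(a)); convert below
    c = polygamma(1, A) - polygamma(1, totals + A)  # (n,)
    diag_term = polygamma(1, X + alpha) - polygamma(1, alpha)  # (n,S)
    return grad, g_alpha, c, diag_term


def component_hessian_logalpha(X: np.ndarray, totals: np.ndarray,
                               alpha: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Hessian of the responsibility-weighted negative penalized DM
    objective with respect to log(alpha) for one mixture component."""
    grad, g_alpha, c, diag_term = _dm_grad_hess_logalpha(X, totals, alpha)
    Hk = (r @ c) * np.outer(alpha, alpha)
    Hk += np.diag(alpha**2 * (r @ diag_term) + alpha * (r @ g_alpha))
    Hk = -Hk  # negative objective
    Hk += np.diag(PRIOR_RATE * alpha)  # prior curvature
    return Hk


def laplace_score(result: DMMResults, counts=None) -> float:
    """Negative log model evidence via the Laplace approximation.

    The Hessian of the negative penalized objective is assembled from the
    responsibility-weighted per-component blocks over log(alpha) plus the
    mixture-weight logit block, and the evidence includes the prior density
    at the mode. A non-positive-definite block falls back to its diagonal
    with a warning.
    """
    model = result.model
    X, totals = model.X, model.totals
    K, S = result.K, result.alphas.shape[1]
    n = X.shape[0]
    logp = np.empty((n, K))
    for k in range(K):
        logp[:, k] = _component_loglik(X, totals, model.const, result.alphas[k])
    joint = logp + np.log(result.weights)
    norm = logsumexp(joint, axis=1)
    r = np.exp(joint - norm[:, None])  # (n,K)

    d = K * S + (K - 1)
    logdet = 0.0
    for k in range(K):
        Hk = component_hessian_logalpha(X, totals, result.alphas[k], r[:, k])
        sign, ld = np.linalg.slogdet(Hk)
        ok = sign > 0
        if ok:
            try:
                np.linalg.cholesky(Hk + 1e-10 * np.eye(S))
            except np.linalg.LinAlgError:
                ok = False
        if not ok:
            warnings.warn(
                "component Hessian not positive definite at the DMM optimum; "
                "using its diagonal for the Laplace score"
            )
            ld = float(np.sum(np.log(np.maximum(np.abs(np.diag(Hk)), 1e-12))))
        logdet += ld
    if K > 1:
        # weight-logit block of the observed-data negative log-likelihood
        pi = result.weights
        Heta = np.zeros((K - 1, K - 1))
        for m in range(K - 1):
            for p_ in range(K - 1):
                Heta[m, p_] = np.sum(
                    r[:, m] * ((m == p_) - r[:, p_])
                ) - n * pi[m] * ((m == p_) - pi[p_])
        Hneg = -Heta
        sign, ld = np.linalg.slogdet(Hneg)
        if sign <= 0:
            ld = float(
                np.sum(np.log(np.maximum(np.abs(np.diag(Hneg)), 1e-12)))
            )
        logdet += ld
    log_post = result.log_likelihood + _log_prior(np.log(result.alphas))
    return float(-(log_post + d / 2.0 * np.log(2 * np.pi) - 0.5 * logdet))


# -- functional wrappers ---------------------------------------------------


def fit_mixture(
    counts: CountTable | np.ndarray,
    K: int,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
) -> DMMResults:
    """Fit a K-component DMM (best of ``n_restarts`` seeded EM runs)."""
    return DirichletMultinomialMixture(counts, K).fit(
        n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed
    )


def select_k(
    counts: CountTable | np.ndarray,
    k_range: Sequence[int] = range(1, 8),
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[dict[int, DMMResults], int]:
    """Fit each K and choose the one with the lowest Laplace score
    (ties broken toward smaller K)."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    rng = np.random.default_rng(seed)
    fits: dict[int, DMMResults] = {}
    for K in k_range:
        fits[K] = fit_mixture(
            counts, K, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=int(rng.integers(2**31 - 1)),
        )
        fits[K].laplace()
    best = min(sorted(fits), key=lambda K: (fits[K].laplace(), K))
    return fits, best


def assign_enterotypes(
    result: DMMResults, counts: CountTable | np.ndarray | None = None
) -> pd.DataFrame:
    """MAP enterotype per sample with the full posterior attached."""
    post = result.posterior(counts)
    out = post.copy()
    out.insert(0, "map_label", post.to_numpy().argmax(axis=1) + 1)
    out.index.name = "sample_id"
    return out.reset_index()


def trajectories(
    assignments: pd.DataFrame, metadata: Sequence[SampleRecord] | pd.DataFrame
) -> TrajectorySummary:
    """Per-pig age-ordered enterotype sequences, per-age enterotype
    proportions, and the consecutive-age transition count matrix."""
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame(
            [
                {"sample_id": r.sample_id, "pig_id": r.pig_id, "age_weeks": r.age_weeks}
                for r in metadata
            ]
        )
    merged = assignments.merge(
        metadata[["sample_id", "pig_id", "age_weeks"]], on="sample_id", how="left"
    )
    if merged["pig_id"].isna().any():
        bad = merged.loc[merged["pig_id"].isna(), "sample_id"].tolist()
        raise ValueError(f"assignment sample(s) missing from metadata: {bad}")
    merged = merged.sort_values(["pig_id", "age_weeks"])
    per_pig = merged[["pig_id", "age_weeks", "map_label"]].rename(
        columns={"map_label": "enterotype"}
    )
    labels = sorted(merged["map_label"].unique())
    prop = (
        merged.groupby("age_weeks")["map_label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=labels, fill_value=0.0)
    )
    prop.columns = [f"E{k}" for k in prop.columns]
    trans = np.zeros((len(labels), len(labels)), dtype=int)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    for _, grp in merged.groupby("pig_id"):
        seq = grp["map_label"].tolist()
        for a, b in zip(seq[:-1], seq[1:]):
            trans[lab_idx[a], lab_idx[b]] += 1
    trans_df = pd.DataFrame(
        trans,
        index=[f"E{k}" for k in labels],
        columns=[f"E{k}" for k in labels],
    )
    return TrajectorySummary(
        per_pig=per_pig.reset_index(drop=True),
        age_proportions=prop,
        transitions=trans_df,
    )
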