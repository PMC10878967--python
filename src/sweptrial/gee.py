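"""Modified-Poisson GEE with small-sample-corrected sandwich variance.

This is the package's inferential engine for cluster-randomized data.
"Modified Poisson" regression estimates relative risks for a *binary*
outcome by fitting a log-link model with the Poisson variance function
and basing inference on a robust (sandwich) covariance; the working
model is deliberately misspecified for the Bernoulli outcome, which is
exactly why the sandwich is mandatory.  Estimation is by generalized
estimating equations (GEE): the population-average score

    sum_i D_i' V_i^{-1} (y_i - mu_i) = 0,

iterated to convergence, where for cluster ``i`` ``D_i = d mu_i / d
beta``, ``V_i = phi A_i^{1/2} R(alpha) A_i^{1/2}`` with ``A_i =
diag(v(mu_i))`` and ``R(alpha)`` the exchangeable working correlation
(every within-cluster pair shares correlation ``alpha``).  ``alpha``
is updated each iteration by the moment estimator: the average of
standardized Pearson-residual cross-products over all within-cluster
pairs, divided by the scale ``phi`` (the mean squared Pearson
residual).

With very few clusters the ordinary sandwich ``A^{-1} M A^{-1}`` with
``M = sum_i q_i q_i'``, ``q_i = D_i' V_i^{-1} e_i``, is biased
downward.  The Mancl-DeRouen correction inflates each cluster residual
by the inverse of (identity minus the cluster leverage ``H_i = D_i
A^{-1} D_i' V_i^{-1}``) inside the meat.  Algebraically the corrected
cluster score collapses to a p-dimensional solve,

    q_i^MD = (I_p - G_i A^{-1})^{-1} q_i,   G_i = D_i' V_i^{-1} D_i,

which this module uses so the correction costs O(p^3) per cluster even
for clusters with thousands of observations.  Confidence intervals
pair the corrected sandwich with a t reference on N - 2 degrees of
freedom (N = number of clusters), the conservative convention for
trials with a handful of clusters.

The same machinery with an identity link and Gaussian variance
function backs the duration (mean-difference) analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    AliasingError,
    InferenceInfeasibleError,
    NumericalSingularityError,
    ValidationError,
)

logger = logging.getLogger(__name__)

VARIANCE_KINDS = ("model_based", "sandwich", "mancl_derouen")
_PHI_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Column names tying a trial dataset to the effect model.

    The linear predictor contains exactly an intercept, the binary
    treatment indicator and period-indicator contrasts.
    """

    outcome: str
    treatment: str = "treatment"
    period: str = "period"
    cluster: str = "cluster"


class EffectEstimate(NamedTuple):
    """Relative risk with t-based CI from a fitted log-link GEE."""

    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int
    se_log_rr: float


class ICCEstimate(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float
    n_boot: int


class MeanDifference(NamedTuple):
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int


class ModifiedPoissonGEE(BaseEstimator):
    """GEE estimator for clustered binary (or continuous) outcomes.

    Parameters
    ----------
    family : {"poisson", "gaussian"}
        ``"poisson"`` is the modified-Poisson relative-risk model (log
        link, variance v(mu) = mu) for binary outcomes; ``"gaussian"``
        (identity link, v = 1) backs mean-difference analyses.
    correlation : {"exchangeable", "independence"}
        Working correlation structure.
    tol : float
        Convergence tolerance on the maximum absolute coefficient
        change.
    max_iter : int
        Iteration cap; a fit that reaches it is returned with
        ``converged_ = False``, never silently as converged.
    add_intercept : bool
        Prepend an intercept column to the design matrix.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) coefficient vector (log scale for the Poisson family)
    alpha_ : exchangeable working-correlation parameter
    scale_ : dispersion (mean squared Pearson residual)
    converged_, n_iter_ : convergence flag and iteration count
    cluster_labels_, cluster_sizes_ : per-cluster bookkeeping
    n_pred_gt1_ : number of fitted probabilities above 1 (diagnostic;
        fitted values are never clamped)
    """

    def __init__(
        self,
        family: str = "poisson",
        correlation: str = "exchangeable",
        tol: float = 1e-8,
        max_iter: int = 100,
        add_intercept: bool = True,
    ):
        self.family = family
        self.correlation = correlation
        self.tol = tol
        self.max_iter = max_iter
        self.add_intercept = add_intercept

    # -- fitting ------------------------------------------------------

    def fit(self, X, y, clusters) -> "ModifiedPoissonGEE":
        if self.family not in ("poisson", "gaussian"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.correlation not in ("exchangeable", "independence"):
            raise ValidationError(
                f"unknown correlation {self.correlation!r}"
            )
        X, names = self._as_matrix(X)
        y = np.asarray(y, dtype=float)
        clusters = np.asarray(clusters)
        if y.ndim != 1 or len(y) != X.shape[0] or len(clusters) != len(y):
            raise ValidationError("X, y and clusters must align row-wise")
        if np.isnan(y).any():
            raise ValidationError("outcome contains missing values")
        if self.family == "poisson" and not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError(
                "modified-Poisson family expects a binary outcome"
            )

        labels, inverse = np.unique(clusters, return_inverse=True)
        if len(labels) < 2:
            raise ValidationError("need at least 2 clusters")
        order = np.argsort(inverse, kind="stable")
        X, y, inverse = X[order], y[order], inverse[order]
        bounds = np.searchsorted(inverse, np.arange(len(labels) + 1))
        sizes = np.diff(bounds)

        self._check_rank(X, names)
        n, p = X.shape

        beta = self._initial_beta(X, y)
        alpha = 0.0
        phi = 1.0
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            mu, dmu, v = self._mean_and_variance(X, beta)
            resid_p = (y - mu) / np.sqrt(v)
            phi = float(np.mean(resid_p**2))
            alpha = self._update_alpha(resid_p, bounds, sizes, phi)
            A = np.zeros((p, p))
            score = np.zeros(p)
            for i in range(len(labels)):
                G_i, q_i = self._cluster_blocks(
                    X, y, mu, dmu, v, bounds[i], bounds[i + 1], alpha, phi
                )
                A += G_i
                score += q_i
            try:
                delta = linalg.solve(A, score, assume_a="sym")
            except linalg.LinAlgError as exc:
                raise NumericalSingularityError(
                    "singular GEE information matrix"
                ) from exc
            beta = beta + delta
            if not np.all(np.isfinite(beta)):
                break
            if np.max(np.abs(delta)) < self.tol:
                converged = True
                break

        self.coef_ = beta
        self.term_names_ = names
        self.converged_ = bool(converged and np.all(np.isfinite(beta)))
        self.n_iter_ = n_iter
        self.cluster_labels_ = labels
        self.cluster_sizes_ = sizes
        self.n_clusters_ = len(labels)
        self.n_obs_ = n

        # final-state quantities retained for variance computation
        mu, dmu, v = self._mean_and_variance(X, beta)
        resid_p = (y - mu) / np.sqrt(v)
        phi = float(np.mean(resid_p**2))
        alpha = self._update_alpha(resid_p, bounds, sizes, phi)
        self.scale_ = phi
        self.alpha_ = alpha
        self.n_pred_gt1_ = (
            int(np.sum(mu > 1.0)) if self.family == "poisson" else 0
        )
        if self.n_pred_gt1_:
            logger.warning(
                "%d fitted probabilities exceed 1 (not clamped)",
                self.n_pred_gt1_,
            )
        G_blocks, q_blocks = [], []
        A = np.zeros((p, p))
        for i in range(len(labels)):
            G_i, q_i = self._cluster_blocks(
                X, y, mu, dmu, v, bounds[i], bounds[i + 1], alpha, phi
            )
            G_blocks.append(G_i)
            q_blocks.append(q_i)
            A += G_i
        self._G_blocks = G_blocks
        self._q_blocks = q_blocks
        self._A = A
        return self

    # -- variance -----------------------------------------------------

    def robust_covariance(
        self, kind: str = "mancl_derouen", allow_unconverged: bool = False
    ) -> np.ndarray:
        """Covariance of ``coef_``.

        ``model_based`` is the inverse working information; ``sandwich``
        the ordinary robust estimator; ``mancl_derouen`` the
        leverage-corrected sandwich.  The result is symmetrized and, by
        construction (sum of outer products conjugated by the bread),
        positive semidefinite.
        """
        self._check_fitted()
        if kind not in VARIANCE_KINDS:
            raise ValidationError(
                f"kind must be one of {VARIANCE_KINDS}, got {kind!r}"
            )
        if not self.converged_ and not allow_unconverged:
            raise ValidationError(
                "fit did not converge; pass allow_unconverged=True to "
                "compute a variance for the last iterate"
            )
        try:
            Ainv = linalg.inv(self._A)
        except linalg.LinAlgError as exc:
            raise NumericalSingularityError(
                "singular GEE information matrix"
            ) from exc
        if kind == "model_based":
            cov = Ainv
        elif self.scale_ < _PHI_FLOOR:
            # perfect fit: all residuals vanish, so does the meat
            cov = np.zeros((len(self.coef_), len(self.coef_)))
        else:
            p = len(self.coef_)
            M = np.zeros((p, p))
            for label, G_i, q_i in zip(
                self.cluster_labels_, self._G_blocks, self._q_blocks
            ):
                if kind == "mancl_derouen":
                    # (I - H_i)^{-1} folded into the cluster score:
                    # q_i^MD = (I_p - G_i A^{-1})^{-1} q_i
                    try:
                        g = linalg.solve(
                            np.eye(p) - G_i @ Ainv, q_i
                        )
                    except linalg.LinAlgError as exc:
                        raise NumericalSingularityError(
                            f"singular leverage correction for cluster "
                            f"{label!r}"
                        ) from exc
                else:
                    g = q_i
                M += np.outer(g, g)
            cov = Ainv @ M @ Ainv
        cov = 0.5 * (cov + cov.T)
        return cov

    # -- internals ----------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise ValidationError("estimator is not fitted")

    def _as_matrix(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = [f"x{j}" for j in range(X.shape[1])]
        if self.add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["intercept"] + names
        return X, names

    def _check_rank(self, X, names) -> None:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        if d.size == 0 or d[0] == 0.0:
            raise AliasingError(names)
        bad = d < d[0] * 1e-10
        if bad.any():
            raise AliasingError([names[j] for j in piv[bad]])

    def _initial_beta(self, X, y):
        p = X.shape[1]
        beta = np.zeros(p)
        if self.family == "poisson":
            ybar = float(np.clip(np.mean(y), 1e-8, None))
            if self.add_intercept or np.all(X[:, 0] == 1.0):
                beta[0] = np.log(ybar)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    def _mean_and_variance(self, X, beta):
        eta = X @ beta
        if self.family == "poisson":
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            return mu, mu, mu
        return eta, np.ones_like(eta), np.ones_like(eta)

    def _update_alpha(self, resid_p, bounds, sizes, phi):
        if self.correlation == "independence":
            return 0.0
        n_pairs = np.sum(sizes * (sizes - 1))
        if n_pairs == 0 or phi < _PHI_FLOOR:
            return 0.0
        num = 0.0
        for i in range(len(sizes)):
            r = resid_p[bounds[i]: bounds[i + 1]]
            num += r.sum() ** 2 - (r**2).sum()
        alpha = num / (phi * n_pairs)
        # keep R(alpha) well inside positive definiteness for every
        # cluster size (the boundary -1/(n_max - 1) makes R singular)
        lo = -0.95 / (np.max(sizes) - 1.0) if np.max(sizes) > 1 else 0.0
        return float(np.clip(alpha, lo, 1.0 - 1e-10))

    def _cluster_blocks(self, X, y, mu, dmu, v, lo, hi, alpha, phi):
        """G_i = D'V^{-1}D and q_i = D'V^{-1}e via the closed-form
        inverse of the exchangeable correlation matrix,
        R^{-1} = c1 I + c2 J."""
        n_i = hi - lo
        sv = np.sqrt(v[lo:hi])
        W = X[lo:hi] * (dmu[lo:hi] / sv)[:, None]
        s = (y[lo:hi] - mu[lo:hi]) / sv
        phi_eff = max(phi, _PHI_FLOOR)
        c1 = 1.0 / (1.0 - alpha)
        c2 = -alpha / ((1.0 - alpha) * (1.0 + (n_i - 1) * alpha))
        w = W.sum(axis=0)
        G = (c1 * (W.T @ W) + c2 * np.outer(w, w)) / phi_eff
        q = (c1 * (W.T @ s) + c2 * w * s.sum()) / phi_eff
        return G, q


# ---------------------------------------------------------------------
# trial-level conveniences


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec, with_treatment: bool = True
) -> pd.DataFrame:
    """Intercept-free frame of treatment + period contrasts.

    The period factor is reference-coded against the first (smallest)
    period present; empty period levels are dropped.  The treatment
    indicator comes from ``spec.treatment`` if that column exists, else
    from a ``condition`` column (``intervention`` -> 1).
    """
    cols = {}
    if with_treatment:
        if spec.treatment in data.columns:
            cols["treatment"] = data[spec.treatment].astype(float)
        elif "condition" in data.columns:
            cols["treatment"] = (
                data["condition"] == "intervention"
            ).astype(float)
        else:
            raise ValidationError(
                f"no treatment column {spec.treatment!r} or 'condition'"
            )
    periods = np.sort(data[spec.period].unique())
    for level in periods[1:]:
        cols[f"period_{level}"] = (
            data[spec.period] == level
        ).astype(float)
    return pd.DataFrame(cols, index=data.index)


def fit_trial_gee(
    data: pd.DataFrame,
    outcome: str,
    *,
    spec: ModelSpec | None = None,
    family: str = "poisson",
    correlation: str = "exchangeable",
    with_treatment: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ModifiedPoissonGEE:
    """Fit the trial effect model: outcome ~ treatment + period factor."""
    spec = spec or ModelSpec(outcome=outcome)
    X = build_design_matrix(data, spec, with_treatment=with_treatment)
    est = ModifiedPoissonGEE(
        family=family,
        correlation=correlation,
        tol=tol,
        max_iter=max_iter,
        add_intercept=True,
    )
    return est.fit(X, data[outcome].to_numpy(dtype=float),
                   data[spec.cluster].to_numpy())


def effect_estimate(
    fit: ModifiedPoissonGEE,
    kind: str = "mancl_derouen",
    df: int | None = None,
    term: str = "treatment",
    level: float = 0.95,
    allow_unconverged: bool = False,
) -> EffectEstimate:
    """Relative risk with t(df) CI; df defaults to N_clusters - 2."""
    if df is None:
        df = fit.n_clusters_ - 2
    if df < 1:
        raise InferenceInfeasibleError(
            f"t inference needs df >= 1, got {df} "
            f"({fit.n_clusters_} clusters)"
        )
    j = fit.term_names_.index(term)
    cov = fit.robust_covariance(kind, allow_unconverged=allow_unconverged)
    beta = float(fit.coef_[j])
    se = float(np.sqrt(cov[j, j]))
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    tstat = beta / se if se > 0 else np.inf * np.sign(beta or 1.0)
    p_value = float(2.0 * stats.t.sf(abs(tstat), df)) if se > 0 else 0.0
    return EffectEstimate(
        rr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - tq * se)),
        ci_high=float(np.exp(beta + tq * se)),
        p_value=p_value,
        df=int(df),
        se_log_rr=se,
    )


def estimate_icc(
    data: pd.DataFrame,
    outcome: str,
    *,
    spec: ModelSpec | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> ICCEstimate:
    """ICC of a binary outcome from control-period data.

    The point estimate is the fitted exchangeable working-correlation
    parameter of a GEE with period fixed effects and no treatment term
    (the caller supplies the control-period subset).  The CI resamples
    clusters with replacement (cluster bootstrap, percentile interval,
    lower bound truncated at 0).
    """
    spec = spec or ModelSpec(outcome=outcome)
    labels = data[spec.cluster].unique()
    if len(labels) < 3:
        raise InferenceInfeasibleError(
            "cluster bootstrap needs at least 3 clusters"
        )
    sizes = data.groupby(spec.cluster).size()
    if (sizes <= 1).all():
        raise InferenceInfeasibleError(
            "icc undefined: every cluster has a single member"
        )

    def _alpha(frame: pd.DataFrame) -> float:
        fit = fit_trial_gee(
            frame, outcome, spec=spec, with_treatment=False
        )
        return float(fit.alpha_)

    icc = _alpha(data)
    rng = np.random.default_rng(seed)
    groups = {c: g for c, g in data.groupby(spec.cluster)}
    draws = []
    for _ in range(n_boot):
        chosen = rng.choice(labels, size=len(labels), replace=True)
        parts = []
        for k, c in enumerate(chosen):
            g = groups[c].copy()
            g[spec.cluster] = f"b{k}"
            parts.append(g)
        boot = pd.concat(parts, ignore_index=True)
        try:
            draws.append(_alpha(boot))
        except Exception:
            continue
    if not draws:
        raise InferenceInfeasibleError("all bootstrap refits failed")
    lo, hi = np.quantile(draws, [(1 - level) / 2, 0.5 + level / 2])
    return ICCEstimate(
        icc=icc,
        ci_low=float(max(lo, 0.0)),
        ci_high=float(hi),
        n_boot=len(draws),
    )


def mean_difference(
    data: pd.DataFrame,
    outcome: str,
    *,
    spec: ModelSpec | None = None,
    kind: str = "mancl_derouen",
    level: float = 0.95,
) -> MeanDifference:
    """Intervention-minus-control mean difference for a duration (days).

    The point estimate is the raw difference of arm means; the CI and p
    value come from the treatment coefficient of an identity-link
    Gaussian GEE (exchangeable working correlation) with the
    Mancl-DeRouen sandwich and t(N-2) reference.
    """
    spec = spec or ModelSpec(outcome=outcome)
    keep = data[outcome].notna()
    if not keep.any():
        raise ValidationError(f"outcome {outcome!r} has no observed values")
    sub = data.loc[keep]
    if (sub[outcome] < 0).any():
        raise ValidationError("durations must be non-negative")
    X = build_design_matrix(sub, spec)
    trt = X["treatment"].to_numpy() == 1.0
    diff = float(
        sub.loc[trt, outcome].mean() - sub.loc[~trt, outcome].mean()
    )
    fit = fit_trial_gee(sub, outcome, spec=spec, family="gaussian")
    df = fit.n_clusters_ - 2
    if df < 1:
        raise InferenceInfeasibleError("t inference needs df >= 1")
    j = fit.term_names_.index("treatment")
    cov = fit.robust_covariance(kind, allow_unconverged=True)
    beta = float(fit.coef_[j])
    se = float(np.sqrt(cov[j, j]))
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    p = float(2.0 * stats.t.sf(abs(beta / se), df)) if se > 0 else 0.0
    return MeanDifference(
        difference=diff,
        ci_low=beta - tq * se,
        ci_high=beta + tq * se,
        p_value=p,
        df=df,
    )
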