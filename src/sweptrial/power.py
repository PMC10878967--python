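"""Power for a cross-sectional stepped-wedge trial with a binary outcome.

The closed form follows the classical generalized-least-squares route on
cluster-period means.  Cluster ``i`` contributes a ``T x T`` covariance
block for its vector of period means: the diagonal is
``sigma^2 * (1 + (m_eff - 1) * rho) / m_eff`` and every off-diagonal
entry is ``sigma^2 * rho * r``, where ``rho`` is the within-period
intraclass correlation, ``r`` the cluster autocorrelation (so
``rho * r`` is the between-period within-cluster correlation),
``sigma^2 = pbar * (1 - pbar)`` the Bernoulli variance at the midpoint
of the two proportions, and ``m_eff`` the effective cluster-period
size.  Unequal cluster-period sizes with coefficient of variation CV
degrade information by the standard relative-efficiency factor,
``m_eff = m / (1 + CV^2)``; partial periods (a truncated final period,
the transition window carved out after crossover) scale ``m_eff`` by
the fraction of analysis days they retain.

GLS with intercept, period fixed effects and the treatment indicator
yields ``Var(effect)``; power uses the two-sided normal approximation
``Phi(|p0 - p1| / SE - z_{1-alpha/2})``.

A simulation arm (:func:`power_by_simulation`) generates whole trials
from the synthetic-data generator and analyses each with the package's
own modified-Poisson GEE under Mancl-DeRouen + t(N-2) inference, so the
closed form can be validated against the inference actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy import stats

from .design import SWDesign, default_design
from .exceptions import DesignInfeasibleError, ValidationError


@dataclass(frozen=True)
class PowerInputs:
    """Design assumptions feeding the power computation.

    ``icc`` is the within-period intraclass correlation rho; ``cac`` is
    the cluster autocorrelation r, the ratio of between-period to
    within-period within-cluster correlation, so rho * r <= rho always.
    ``mean_cluster_period_size`` is the expected number of analysis
    women per cluster per full period, and ``cv_cluster_size`` their
    coefficient of variation across cluster-periods.
    """

    p_control: float
    p_intervention: float
    icc: float = 0.02
    cac: float = 0.90
    mean_cluster_period_size: float = 300.0
    cv_cluster_size: float = 0.60
    alpha: float = 0.05
    design: SWDesign = field(default_factory=default_design)

    def __post_init__(self) -> None:
        for name in ("p_control", "p_intervention"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValidationError(f"{name} must lie strictly in (0, 1)")
        if not 0.0 <= self.icc < 1.0:
            raise ValidationError("icc must lie in [0, 1)")
        if not 0.0 <= self.cac <= 1.0:
            raise ValidationError("cac must lie in [0, 1]")
        if self.icc * self.cac > self.icc:
            raise ValidationError(
                "between-period correlation icc*cac cannot exceed icc"
            )
        if self.mean_cluster_period_size <= 0:
            raise ValidationError("mean_cluster_period_size must be > 0")
        if self.cv_cluster_size < 0:
            raise ValidationError("cv_cluster_size must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")


SCALES = ("risk_difference", "log_rr")


def treatment_se_gls(
    inputs: PowerInputs, scale: str = "risk_difference"
) -> float:
    """Standard error of the treatment effect by generalized least
    squares on the cluster-period mean layout (intercept, period fixed
    effects with the first period as reference, and the planned 0/1
    treatment staircase).

    ``scale="risk_difference"`` uses a common variance
    ``sigma^2 = pbar(1 - pbar)`` at the midpoint of the two
    proportions — the classical sample-size convention.
    ``scale="log_rr"`` propagates arm-specific Bernoulli variances
    through the log transform (delta method per cluster-period), which
    matches the Wald test on the log relative risk that the GEE
    analysis actually performs.
    """
    if scale not in SCALES:
        raise ValidationError(f"scale must be one of {SCALES}")
    design = inputs.design
    T = design.n_periods
    p0, p1 = inputs.p_control, inputs.p_intervention
    pbar = 0.5 * (p0 + p1)
    rho, r = inputs.icc, inputs.cac
    meff_base = inputs.mean_cluster_period_size / (
        1.0 + inputs.cv_cluster_size**2
    )

    p = 1 + (T - 1) + 1  # intercept + period contrasts + treatment
    A = np.zeros((p, p))
    for cluster in design.clusters:
        x = np.array(
            [design.treatment_indicator(cluster, t) for t in range(1, T + 1)],
            dtype=float,
        )
        if scale == "risk_difference":
            sd = np.full(T, np.sqrt(pbar * (1.0 - pbar)))
            grad = np.ones(T)
        else:
            pv = np.where(x == 1.0, p1, p0)
            sd = np.sqrt(pv * (1.0 - pv))
            grad = 1.0 / pv  # d log(p) / d p
        V = np.outer(sd * grad, sd * grad) * rho * r
        for t in range(1, T + 1):
            frac = design.analysis_fraction(cluster, t)
            meff = max(meff_base * frac, 1e-9)
            V[t - 1, t - 1] = (
                sd[t - 1] ** 2
                * (1.0 + (meff - 1.0) * rho)
                / meff
                * grad[t - 1] ** 2
            )
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise DesignInfeasibleError(
                f"singular cluster covariance for {cluster}"
            ) from exc
        Z = np.zeros((T, p))
        Z[:, 0] = 1.0
        for t in range(1, T):
            Z[t, t] = 1.0
        Z[:, -1] = x
        A += Z.T @ Vinv @ Z

    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DesignInfeasibleError(
            "degenerate design: GLS information matrix is singular"
        ) from exc
    var = cov[-1, -1]
    if var <= 0:  # pragma: no cover - defensive
        raise DesignInfeasibleError("non-positive treatment-effect variance")
    return float(np.sqrt(var))


def power_closed_form(
    inputs: PowerInputs, scale: str = "risk_difference"
) -> float:
    """Two-sided power for the treatment effect.

    Normal approximation ``Phi(|effect| / SE - z_{1 - alpha/2})``,
    where the effect is ``p_intervention - p_control`` on the
    risk-difference scale (default, the sample-size convention) or
    ``log(p_intervention / p_control)`` with ``scale="log_rr"``, the
    analogue of the analysis model's Wald test.  Under a null effect
    this returns ``alpha / 2`` (the rejection probability on the
    favorable side).
    """
    se = treatment_se_gls(inputs, scale=scale)
    if scale == "risk_difference":
        effect = abs(inputs.p_control - inputs.p_intervention)
    else:
        effect = abs(np.log(inputs.p_intervention / inputs.p_control))
    z = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    return float(stats.norm.cdf(effect / se - z))


@dataclass
class PowerSimResult:
    """Rejection fraction over simulated trials with its binomial CI.

    ``power_known_variance`` re-tests every replicate's estimated log
    relative risk against the *ensemble* standard deviation of those
    estimates with a normal quantile.  It is the simulation analogue
    of the closed form's known-variance z test — the right quantity
    for validating the GLS variance model — whereas ``power`` uses the
    per-trial inference rule and also carries its estimation noise.
    """

    power: float
    ci: Tuple[float, float]
    n_sims: int
    n_rejected: int
    n_failed: int
    warnings: list
    power_known_variance: float
    se_log_rr_empirical: float

    def __iter__(self):  # (power, ci) unpacking convenience
        return iter((self.power, self.ci))


INFERENCE_RULES = ("t_mancl_derouen", "z_sandwich", "z_model")


def power_by_simulation(
    inputs: PowerInputs,
    n_sims: int = 1000,
    seed: int = 0,
    inference: str = "t_mancl_derouen",
) -> PowerSimResult:
    """Estimate power by simulating and analysing whole trials.

    Each replicate draws a full individual-level trial from the
    synthetic-data generator with a homogeneous analysis cohort at the
    control proportion ``p_control`` and relative risk
    ``p_intervention / p_control``, fits the modified-Poisson GEE
    (exchangeable working correlation) and tests the treatment effect
    at level ``alpha``.  ``inference`` selects the rejection rule:

    - ``"t_mancl_derouen"`` (default): the trial's actual small-sample
      inference — Mancl-DeRouen sandwich with a t reference on N-2
      degrees of freedom.  With a handful of clusters this is far more
      conservative than the closed form's known-variance z test, and
      the gap it surfaces is real.
    - ``"z_sandwich"``: uncorrected sandwich + normal quantile.
    - ``"z_model"``: model-based (working) covariance + normal
      quantile — the simulation analogue of the closed form, used to
      validate it.

    Replicates whose fit does not converge are counted as failures and
    excluded from the rejection fraction; if more than 10% fail a
    warning is attached to the result.
    """
    from .gee import effect_estimate, fit_trial_gee
    from .simulate import GeneratorConfig, generate_trial

    if n_sims < 100:
        raise ValidationError("n_sims must be at least 100")
    if inference not in INFERENCE_RULES:
        raise ValidationError(
            f"inference must be one of {INFERENCE_RULES}"
        )

    rr = inputs.p_intervention / inputs.p_control
    config = GeneratorConfig.uniform_cohort(
        design=inputs.design,
        baseline_p=inputs.p_control,
        intervention_rr=rr,
        icc=inputs.icc,
        cac=inputs.cac,
        cluster_size_mean_per_period=inputs.mean_cluster_period_size,
        cluster_size_cv=inputs.cv_cluster_size,
        seed=0,
    )

    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_sims)
    n_rejected = 0
    n_failed = 0
    betas = []
    for s in seeds:
        data = generate_trial(replace(config, seed=int(s)))
        data = data[data["condition"] != "transition"]
        try:
            fit = fit_trial_gee(data, outcome="cesarean")
        except Exception:
            n_failed += 1
            continue
        if not fit.converged_:
            n_failed += 1
            continue
        betas.append(fit.coef_[fit.term_names_.index("treatment")])
        if inference == "t_mancl_derouen":
            est = effect_estimate(fit, kind="mancl_derouen")
            reject = est.p_value < inputs.alpha
        else:
            kind = "sandwich" if inference == "z_sandwich" else "model_based"
            j = fit.term_names_.index("treatment")
            se = float(np.sqrt(fit.robust_covariance(kind)[j, j]))
            z = abs(fit.coef_[j]) / se if se > 0 else np.inf
            reject = z > stats.norm.ppf(1.0 - inputs.alpha / 2.0)
        if reject:
            n_rejected += 1

    n_ok = n_sims - n_failed
    if n_ok == 0:
        raise DesignInfeasibleError("all simulated fits failed")
    test = stats.binomtest(n_rejected, n_ok)
    ci = test.proportion_ci(confidence_level=0.95, method="wilson")
    warnings = []
    if n_failed > 0.10 * n_sims:
        warnings.append(
            f"{n_failed}/{n_sims} simulated fits failed to converge"
        )
    betas = np.asarray(betas)
    sd = float(betas.std(ddof=1))
    z = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    pw_known = float(np.mean(np.abs(betas) / sd > z)) if sd > 0 else 1.0
    return PowerSimResult(
        power=n_rejected / n_ok,
        ci=(float(ci.low), float(ci.high)),
        n_sims=n_sims,
        n_rejected=n_rejected,
        n_failed=n_failed,
        warnings=warnings,
        power_known_variance=pw_known,
        se_log_rr_empirical=sd,
    )
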