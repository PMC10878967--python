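"""Synthetic stepped-wedge trial data with controlled correlation.

Generates individual-level birth records that mimic a four-hospital
stepped-wedge trial: log-normally sized cluster-periods, a realistic
obstetric covariate mix (parity, previous cesarean, onset,
presentation, plurality, gestational age) calibrated so roughly 30% of
women fall in Robson Group 1, group-specific baseline cesarean
probabilities, an intervention relative risk applied to the laboring
low-risk groups, and secondary process-of-care, health and survey
outcomes that respect the analysis denominators (augmentation and
artificial rupture of membranes only for women in spontaneous labor;
episiotomy and operative vaginal birth only for vaginal births;
stillbirth and neonatal death counted per baby; the experience-of-care
survey restricted to Robson Group 1 or 3 women with a liveborn baby
delivering in the last days of each period).

Within-cluster correlation is induced on a latent logistic scale with
nested random effects: a cluster effect ``u ~ N(0, cluster_sd^2)``
shared by all of a hospital's births and a cluster-period effect
``v ~ N(0, cluster_period_sd^2)`` shared within one hospital-period.
The targets, however, are stated on the outcome (proportion) scale —
the intraclass correlation rho between two women of the same
cluster-period and the cluster autocorrelation r (between-period
correlation rho * r) — matching the conventions of the power
calculation.  :func:`solve_variance_components` bridges the scales by
Gauss-Hermite quadrature, and per-probability offsets keep every
marginal outcome probability exactly at its configured value despite
the nonlinear link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special

from .design import SWDesign, default_design
from .exceptions import InfeasibleCorrelationError, SchemaError, ValidationError
from .robson import classify_frame

_GH_NODES = 41


# ---------------------------------------------------------------------
# latent-scale variance components


@lru_cache(maxsize=1)
def _gh() -> Tuple[np.ndarray, np.ndarray]:
    # nodes/weights for E[f(Z)], Z ~ N(0,1)
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


def _moments(eta0: float, sc: float, scp: float):
    """(marginal p, E[p^2] same cluster-period, E[(E_v p)^2] same cluster)."""
    z, w = _gh()
    u = sc * z
    v = scp * z
    p = special.expit(eta0 + u[:, None] + v[None, :])
    g = p @ w           # E over v given u
    pi = float(g @ w)
    ep2 = float(w @ (p**2) @ w)
    eg2 = float((g**2) @ w)
    return pi, ep2, eg2


def _solve_offset(p_target: float, sc: float, scp: float) -> float:
    """eta0 such that the marginal probability equals ``p_target``."""
    if sc == 0.0 and scp == 0.0:
        return float(special.logit(p_target))
    return float(
        optimize.brentq(
            lambda e: _moments(e, sc, scp)[0] - p_target, -35.0, 35.0,
            xtol=1e-12,
        )
    )


@lru_cache(maxsize=64)
def solve_variance_components(
    icc: float, cac: float, baseline_p: float
) -> Tuple[float, float]:
    """Latent logit-normal SDs hitting outcome-scale ICC/CAC targets.

    Returns ``(cluster_sd, cluster_period_sd)`` such that at marginal
    probability ``baseline_p`` the induced correlation between two
    outcomes of the same cluster-period equals ``icc`` and the
    between-period within-cluster correlation equals ``icc * cac``
    (so the cluster effect carries the fraction ``cac`` of the
    within-period correlation).  Deterministic; quadrature-based.
    """
    if not 0.0 <= icc < 1.0:
        raise ValidationError("icc must lie in [0, 1)")
    if not 0.0 <= cac <= 1.0:
        raise ValidationError("cac must lie in [0, 1]")
    if not 0.0 < baseline_p < 1.0:
        raise ValidationError("baseline_p must lie strictly in (0, 1)")
    if icc == 0.0:
        return 0.0, 0.0

    bern = baseline_p * (1.0 - baseline_p)

    def induced(sc: float, scp: float) -> Tuple[float, float]:
        eta0 = _solve_offset(baseline_p, sc, scp)
        pi, ep2, eg2 = _moments(eta0, sc, scp)
        return (ep2 - pi**2) / bern, (eg2 - pi**2) / bern

    # small-sigma linearization for the starting point:
    # Var(p) ~ (p(1-p))^2 * sigma_total^2
    s_tot = np.sqrt(icc / bern)
    x0 = np.array([s_tot * np.sqrt(cac), s_tot * np.sqrt(1.0 - cac)])

    def resid(x):
        iw, ib = induced(abs(x[0]), abs(x[1]))
        return [iw - icc, ib - icc * cac]

    if cac == 1.0:
        sc = optimize.brentq(
            lambda s: induced(s, 0.0)[0] - icc, 1e-12, 50.0, xtol=1e-12
        )
        return float(sc), 0.0
    if cac == 0.0:
        scp = optimize.brentq(
            lambda s: induced(0.0, s)[0] - icc, 1e-12, 50.0, xtol=1e-12
        )
        return 0.0, float(scp)

    sol = optimize.least_squares(
        resid, x0, bounds=([0.0, 0.0], [50.0, 50.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    iw, ib = induced(sol.x[0], sol.x[1])
    if abs(iw - icc) > 1e-6 or abs(ib - icc * cac) > 1e-6:
        max_iw, _ = induced(50.0, 50.0)
        raise InfeasibleCorrelationError(
            f"cannot induce icc={icc}, cac={cac} at p={baseline_p}; "
            f"attainable icc at this baseline is at most ~{max_iw:.3f}"
        )
    return float(sol.x[0]), float(sol.x[1])


@lru_cache(maxsize=4096)
def _offset(p: float, sc: float, scp: float) -> float:
    return _solve_offset(p, sc, scp)


# ---------------------------------------------------------------------
# configuration


def _probs(pairs) -> Tuple[Tuple, np.ndarray]:
    keys = tuple(k for k, _ in pairs)
    p = np.array([v for _, v in pairs], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities must be >= 0 and sum to 1: {pairs}")
    return keys, p


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything :func:`generate_trial` needs, with trial-like defaults.

    Covariate defaults reproduce the study population's headline mix:
    ~47% nulliparous; ~45% of multiparous women with a previous
    cesarean; gestational age mean ~38.3 (SD ~2.5) weeks from a
    preterm/term mixture with ~12% preterm; ~1.3% multiple pregnancies
    and ~4.5% non-cephalic presentations, which together put ~30% of
    women in Robson Group 1.  Group-specific baseline cesarean
    probabilities apply to laboring women (a prelabor cesarean is, by
    definition, delivered by cesarean) and average to an overall
    cesarean rate near 50%.  Secondary-outcome baselines are
    (control, intervention) pairs of crude proportions; durations are
    (mean, SD) pairs in days, drawn log-normally.
    """

    design: SWDesign = field(default_factory=default_design)
    seed: int = 0
    cluster_size_mean_per_period: float = 1100.0
    cluster_size_cv: float = 0.60

    # covariate model
    p_nulliparous: float = 0.47
    parity_probs_multiparous: Tuple = (
        (1, 0.60), (2, 0.28), (3, 0.10), (4, 0.015), (5, 0.005),
    )
    p_previous_cs_given_multiparous: float = 0.45
    p_two_plus_prev_cs_given_any: float = 0.196
    onset_probs_nulliparous: Tuple = (
        ("spontaneous", 0.78), ("induced", 0.135),
        ("prelabor_cesarean", 0.085),
    )
    onset_probs_multiparous: Tuple = (
        ("spontaneous", 0.72), ("induced", 0.14),
        ("prelabor_cesarean", 0.14),
    )
    p_multiple: float = 0.013
    presentation_probs: Tuple = (
        ("cephalic", 0.955), ("breech", 0.035),
        ("transverse_oblique", 0.010),
    )
    p_preterm: float = 0.12
    ga_term_mean: float = 39.0
    ga_term_sd: float = 1.1
    ga_preterm_mean: float = 33.5
    ga_preterm_sd: float = 3.0

    # outcome model
    group_cs_baseline: Tuple = (
        (1, 0.452), (2, 0.45), (3, 0.18), (4, 0.30), (5, 0.85),
        (6, 0.95), (7, 0.92), (8, 0.75), (9, 0.99), (10, 0.45),
    )
    intervention_rr: float = 0.85
    rr_groups: Tuple = (1, 2, 3, 4, 10)
    icc: float = 0.02
    cac: float = 0.90

    augmentation_p: Tuple = (0.273, 0.093)
    arm_rupture_p: Tuple = (0.067, 0.057)
    episiotomy_p: Tuple = (0.550, 0.659)
    operative_vaginal_p: Tuple = (0.0196, 0.0263)
    stillbirth_p: Tuple = (0.0316, 0.0300)
    neonatal_death_p: Tuple = (0.0174, 0.0138)
    labor_companion_p: Tuple = (0.839, 0.769)
    admission_to_birth_days: Tuple = ((0.30, 0.68), (0.34, 0.73))
    birth_to_discharge_days: Tuple = ((3.52, 1.88), (3.29, 1.75))
    survey_window_days: int = 15

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in (
            "p_nulliparous", "p_previous_cs_given_multiparous",
            "p_two_plus_prev_cs_given_any", "p_multiple", "p_preterm",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.cluster_size_mean_per_period <= 0:
            raise ValidationError("cluster_size_mean_per_period must be > 0")
        if self.cluster_size_cv < 0:
            raise ValidationError("cluster_size_cv must be >= 0")
        if self.intervention_rr < 0:
            raise ValidationError("intervention_rr must be >= 0")
        _probs(self.onset_probs_nulliparous)
        _probs(self.onset_probs_multiparous)
        _probs(self.presentation_probs)
        _probs(self.parity_probs_multiparous)
        for g, p in self.group_cs_baseline:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"group {g} baseline outside [0, 1]")

    @property
    def reference_p(self) -> float:
        """Baseline at which the correlation targets are anchored
        (the Robson Group 1 control cesarean probability)."""
        return dict(self.group_cs_baseline)[1]

    @classmethod
    def uniform_cohort(
        cls,
        design: SWDesign,
        baseline_p: float,
        intervention_rr: float,
        icc: float,
        cac: float,
        cluster_size_mean_per_period: float,
        cluster_size_cv: float,
        seed: int,
    ) -> "GeneratorConfig":
        """A homogeneous analysis cohort: every woman is a Robson
        Group 1 candidate (nulliparous, singleton, term, cephalic,
        spontaneous labor) with cesarean probability ``baseline_p``.
        Used by the simulation arm of the power calculation, where the
        cluster-period size is the analysis denominator itself."""
        return cls(
            design=design,
            seed=seed,
            cluster_size_mean_per_period=cluster_size_mean_per_period,
            cluster_size_cv=cluster_size_cv,
            p_nulliparous=1.0,
            onset_probs_nulliparous=(
                ("spontaneous", 1.0), ("induced", 0.0),
                ("prelabor_cesarean", 0.0),
            ),
            p_multiple=0.0,
            presentation_probs=(
                ("cephalic", 1.0), ("breech", 0.0),
                ("transverse_oblique", 0.0),
            ),
            p_preterm=0.0,
            group_cs_baseline=tuple(
                (g, baseline_p if g == 1 else p)
                for g, p in cls.group_cs_baseline
            ),
            intervention_rr=intervention_rr,
            rr_groups=(1,),
            icc=icc,
            cac=cac,
        )


# ---------------------------------------------------------------------
# generation


COLUMNS: Tuple[str, ...] = (
    "woman_id", "cluster", "birth_date", "period", "condition",
    "parity", "previous_cesareans", "labor_onset", "presentation",
    "n_fetuses", "gestational_age_weeks", "robson_group", "cesarean",
    "augmentation", "arm_rupture", "episiotomy", "operative_vaginal",
    "admission_to_birth_days", "birth_to_discharge_days",
    "n_stillbirths", "n_neonatal_deaths", "survey_eligible",
    "labor_companion",
)

DATA_DICTIONARY: Dict[str, str] = {
    "woman_id": "unique identifier, one row per woman",
    "cluster": "hospital (cluster) identifier",
    "birth_date": "calendar date of birth (ISO 8601)",
    "period": "1-based analysis period containing birth_date",
    "condition": "planned exposure: control / transition / intervention",
    "parity": "previous births before this pregnancy",
    "previous_cesareans": "previous cesarean sections (<= parity)",
    "labor_onset": "spontaneous / induced / prelabor_cesarean",
    "presentation": "cephalic / breech / transverse_oblique",
    "n_fetuses": "number of fetuses in this pregnancy",
    "gestational_age_weeks": "gestational age at birth, weeks (>= 20)",
    "robson_group": "Robson ten-group class (1-10)",
    "cesarean": "1 if delivered by cesarean section",
    "augmentation": "oxytocin augmentation; defined only for spontaneous labor",
    "arm_rupture": "artificial rupture of membranes; spontaneous labor only",
    "episiotomy": "episiotomy; vaginal births only",
    "operative_vaginal": "operative vaginal birth; vaginal births only",
    "admission_to_birth_days": "days from admission to childbirth",
    "birth_to_discharge_days": "days from childbirth to discharge",
    "n_stillbirths": "stillborn babies among n_fetuses",
    "n_neonatal_deaths": "neonatal deaths among liveborn babies",
    "survey_eligible": "1 if in the postpartum experience-survey sample",
    "labor_companion": "survey: labor companion present; survey sample only",
}


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    if mean <= 0:
        raise ValidationError("log-normal mean must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def generate_trial(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one complete synthetic trial as a records DataFrame.

    Fully reproducible from ``config.seed``.  The frame carries
    ``attrs['n_clamped']``, the number of outcome probabilities that
    had to be clamped to 1 after relative-risk scaling.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    if config.icc > 0:
        sc, scp = solve_variance_components(
            config.icc, config.cac, config.reference_p
        )
    else:
        sc, scp = 0.0, 0.0

    # cluster and cluster-period latent effects (fixed draw order)
    clusters = design.clusters
    u = {c: rng.normal(0.0, sc) if sc > 0 else 0.0 for c in clusters}
    v = {
        (c, t): rng.normal(0.0, scp) if scp > 0 else 0.0
        for c in clusters
        for t in range(1, design.n_periods + 1)
    }

    # cluster-period sizes, birth dates and per-chunk latent effects
    chunks = {
        "cluster": [], "period": [], "date": [], "latent": [],
        "days_since_cross": [], "days_to_period_end": [],
    }
    for c in clusters:
        cross_off = (design.crossover_date(c) - design.start_date).days
        for t in range(1, design.n_periods + 1):
            mean_size = (
                config.cluster_size_mean_per_period
                * design.period_fraction(t)
            )
            if config.cluster_size_cv == 0:
                size = int(round(mean_size))
            else:
                m_log, s_log = _lognormal_params(
                    mean_size, config.cluster_size_cv * mean_size
                )
                size = int(round(rng.lognormal(m_log, s_log)))
            if size <= 0:
                continue
            days = design.period_days(t)
            offsets = rng.integers(0, days, size=size)
            start = design.period_start(t)
            start_off = (start - design.start_date).days
            chunks["cluster"].append(np.full(size, c, dtype=object))
            chunks["period"].append(np.full(size, t))
            chunks["date"].append(
                np.datetime64(start) + offsets.astype("timedelta64[D]")
            )
            chunks["latent"].append(np.full(size, u[c] + v[(c, t)]))
            chunks["days_since_cross"].append(
                start_off + offsets - cross_off
            )
            chunks["days_to_period_end"].append(days - 1 - offsets)
    cluster_arr = np.concatenate(chunks["cluster"])
    period_arr = np.concatenate(chunks["period"])
    date_arr = np.array(
        np.concatenate(chunks["date"]).astype("datetime64[D]").tolist(),
        dtype=object,
    )
    latent = np.concatenate(chunks["latent"])
    days_since = np.concatenate(chunks["days_since_cross"])
    days_to_end = np.concatenate(chunks["days_to_period_end"])
    n = len(cluster_arr)

    # covariates
    nullip = rng.random(n) < config.p_nulliparous
    parity = np.zeros(n, dtype=np.int64)
    keys, pvec = _probs(config.parity_probs_multiparous)
    n_multi = int((~nullip).sum())
    parity[~nullip] = rng.choice(np.array(keys), size=n_multi, p=pvec)
    prev_any = np.zeros(n, dtype=bool)
    prev_any[~nullip] = (
        rng.random(n_multi) < config.p_previous_cs_given_multiparous
    )
    prev_cs = np.zeros(n, dtype=np.int64)
    two_plus = rng.random(n) < config.p_two_plus_prev_cs_given_any
    prev_cs[prev_any] = np.where(two_plus[prev_any], 2, 1)
    prev_cs = np.minimum(prev_cs, parity)

    onset = np.empty(n, dtype=object)
    k0, p0 = _probs(config.onset_probs_nulliparous)
    k1, p1 = _probs(config.onset_probs_multiparous)
    onset[nullip] = rng.choice(np.array(k0), size=int(nullip.sum()), p=p0)
    onset[~nullip] = rng.choice(np.array(k1), size=n_multi, p=p1)

    kp, pp = _probs(config.presentation_probs)
    presentation = rng.choice(np.array(kp), size=n, p=pp)
    n_fetuses = np.where(rng.random(n) < config.p_multiple, 2, 1)

    preterm = rng.random(n) < config.p_preterm
    ga = np.where(
        preterm,
        np.clip(
            rng.normal(config.ga_preterm_mean, config.ga_preterm_sd, n),
            20.0, 36.9,
        ),
        np.clip(
            rng.normal(config.ga_term_mean, config.ga_term_sd, n),
            37.0, 43.0,
        ),
    )
    ga = np.round(ga, 1)

    frame = pd.DataFrame(
        {
            "cluster": cluster_arr,
            "period": period_arr,
            "parity": parity,
            "previous_cesareans": prev_cs,
            "labor_onset": onset,
            "presentation": presentation,
            "n_fetuses": n_fetuses,
            "gestational_age_weeks": ga,
        }
    )
    group = classify_frame(frame)

    # planned exposure from the design schedule
    condition = np.where(
        days_since < 0,
        "control",
        np.where(days_since < design.transition_days, "transition",
                 "intervention"),
    )
    exposed = days_since >= 0  # transition births follow post-crossover care

    n_clamped = 0

    def bernoulli(p_by_arm, mask=None, latent_effects=True):
        """Draw a flag whose marginal probability is p_by_arm[exposed],
        optionally only where ``mask`` (NaN elsewhere)."""
        nonlocal n_clamped
        pc, pi_ = p_by_arm
        target = np.where(exposed, pi_, pc).astype(float)
        over = target > 1.0
        if over.any():
            n_clamped += int(over.sum())
            target = np.minimum(target, 1.0)
        if latent_effects and (sc > 0 or scp > 0):
            prob = np.empty(n)
            for val in np.unique(target):
                sel = target == val
                if val <= 0.0 or val >= 1.0:
                    prob[sel] = val
                else:
                    eta0 = _offset(float(val), sc, scp)
                    prob[sel] = special.expit(eta0 + latent[sel])
        else:
            prob = target
        draw = (rng.random(n) < prob).astype(float)
        if mask is not None:
            draw = np.where(mask, draw, np.nan)
        return draw

    # cesarean: group-specific baselines for laboring women, RR applied
    # to the configured groups when exposed; prelabor cesarean is a
    # cesarean by definition
    base = dict(config.group_cs_baseline)
    p_cs = np.array([base[g] for g in group])
    in_rr = np.isin(group, config.rr_groups)
    p_cs = np.where(exposed & in_rr, p_cs * config.intervention_rr, p_cs)
    over = p_cs > 1.0
    if over.any():
        n_clamped += int(over.sum())
        p_cs = np.minimum(p_cs, 1.0)
    if sc > 0 or scp > 0:
        prob_cs = np.empty(n)
        for val in np.unique(p_cs):
            sel = p_cs == val
            if val <= 0.0 or val >= 1.0:
                prob_cs[sel] = val
            else:
                prob_cs[sel] = special.expit(
                    _offset(float(val), sc, scp) + latent[sel]
                )
    else:
        prob_cs = p_cs
    cesarean = (rng.random(n) < prob_cs).astype(np.int64)
    cesarean[onset == "prelabor_cesarean"] = 1

    spont = onset == "spontaneous"
    vaginal = cesarean == 0
    augmentation = bernoulli(config.augmentation_p, mask=spont)
    arm_rupture = bernoulli(config.arm_rupture_p, mask=spont)
    episiotomy = bernoulli(config.episiotomy_p, mask=vaginal)
    operative_vaginal = bernoulli(
        config.operative_vaginal_p, mask=vaginal
    )

    p_sb = np.where(exposed, config.stillbirth_p[1], config.stillbirth_p[0])
    n_still = rng.binomial(n_fetuses, p_sb)
    p_nd = np.where(
        exposed, config.neonatal_death_p[1], config.neonatal_death_p[0]
    )
    n_neo = rng.binomial(n_fetuses - n_still, p_nd)

    durations = {}
    for name, pairs in (
        ("admission_to_birth_days", config.admission_to_birth_days),
        ("birth_to_discharge_days", config.birth_to_discharge_days),
    ):
        (mc, sdc), (mi, sdi) = pairs
        mlc, slc = _lognormal_params(mc, sdc)
        mli, sli = _lognormal_params(mi, sdi)
        z = rng.standard_normal(n)
        durations[name] = np.round(
            np.where(
                exposed, np.exp(mli + sli * z), np.exp(mlc + slc * z)
            ),
            3,
        )

    # survey subsample: Robson 1 or 3, liveborn baby, birth in the last
    # `survey_window_days` of the period
    survey = (
        np.isin(group, (1, 3))
        & (n_still < n_fetuses)
        & (days_to_end < config.survey_window_days)
    )
    labor_companion = bernoulli(config.labor_companion_p, mask=survey)

    out = pd.DataFrame(
        {
            "woman_id": [
                f"{c}-{i:06d}" for i, c in enumerate(cluster_arr)
            ],
            "cluster": cluster_arr,
            "birth_date": date_arr,
            "period": period_arr,
            "condition": condition,
            "parity": parity,
            "previous_cesareans": prev_cs,
            "labor_onset": onset,
            "presentation": presentation,
            "n_fetuses": n_fetuses,
            "gestational_age_weeks": ga,
            "robson_group": group,
            "cesarean": cesarean,
            "augmentation": augmentation,
            "arm_rupture": arm_rupture,
            "episiotomy": episiotomy,
            "operative_vaginal": operative_vaginal,
            "admission_to_birth_days": durations["admission_to_birth_days"],
            "birth_to_discharge_days": durations["birth_to_discharge_days"],
            "n_stillbirths": n_still,
            "n_neonatal_deaths": n_neo,
            "survey_eligible": survey.astype(np.int64),
            "labor_companion": labor_companion,
        }
    )
    out.attrs["n_clamped"] = n_clamped
    return out


def babies_table(records: pd.DataFrame) -> pd.DataFrame:
    """Expand the per-woman frame to one row per baby.

    Carries ``stillbirth`` and ``neonatal_death`` flags (deaths are
    assigned to the lowest baby indices; the flags are exchangeable
    within a pregnancy).
    """
    reps = records["n_fetuses"].to_numpy()
    idx = np.repeat(records.index.to_numpy(), reps)
    babies = records.loc[
        idx, ["woman_id", "cluster", "birth_date", "period", "condition"]
    ].reset_index(drop=True)
    baby_no = np.concatenate([np.arange(k) for k in reps])
    babies["baby_no"] = baby_no + 1
    n_still = np.repeat(records["n_stillbirths"].to_numpy(), reps)
    babies["stillbirth"] = (baby_no < n_still).astype(np.int64)
    n_neo = np.repeat(records["n_neonatal_deaths"].to_numpy(), reps)
    babies["neonatal_death"] = (
        (baby_no >= n_still) & (baby_no < n_still + n_neo)
    ).astype(np.int64)
    return babies


# ---------------------------------------------------------------------
# CSV round trip


_DTYPES = {
    "woman_id": str, "cluster": str, "condition": str,
    "labor_onset": str, "presentation": str,
    "period": np.int64, "parity": np.int64,
    "previous_cesareans": np.int64, "n_fetuses": np.int64,
    "robson_group": np.int64, "cesarean": np.int64,
    "n_stillbirths": np.int64, "n_neonatal_deaths": np.int64,
    "survey_eligible": np.int64,
    "gestational_age_weeks": float, "augmentation": float,
    "arm_rupture": float, "episiotomy": float,
    "operative_vaginal": float, "admission_to_birth_days": float,
    "birth_to_discharge_days": float, "labor_companion": float,
}


def write_dataset(records: pd.DataFrame, path) -> None:
    """Write records CSV plus a JSON data dictionary alongside."""
    path = Path(path)
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"records missing columns: {missing}")
    records.loc[:, list(COLUMNS)].to_csv(path, index=False)
    dict_path = path.with_suffix(".dict.json")
    dict_path.write_text(json.dumps(DATA_DICTIONARY, indent=2) + "\n")


def read_dataset(path) -> pd.DataFrame:
    """Read a records CSV written by :func:`write_dataset`.

    Unknown or missing columns raise :class:`SchemaError` listing the
    offending headers; the round trip is lossless.
    """
    path = Path(path)
    head = pd.read_csv(path, nrows=0)
    unknown = [c for c in head.columns if c not in COLUMNS]
    missing = [c for c in COLUMNS if c not in head.columns]
    if unknown or missing:
        raise SchemaError(
            f"schema mismatch: unknown columns {unknown}, "
            f"missing columns {missing}"
        )
    df = pd.read_csv(path, dtype=_DTYPES, parse_dates=["birth_date"])
    df["birth_date"] = df["birth_date"].dt.date
    return df.loc[:, list(COLUMNS)]


def validate_dataset(records: pd.DataFrame) -> None:
    """Schema and invariant checks on a records frame."""
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"records missing columns: {missing}")
    classify_frame(records)  # re-validates the obstetric profile columns
    if not records["robson_group"].isin(range(1, 11)).all():
        raise SchemaError("robson_group outside 1..10")
    if not records["cesarean"].isin((0, 1)).all():
        raise SchemaError("cesarean must be 0/1")
    both = (records["cesarean"] == 1) & (records["operative_vaginal"] == 1)
    if both.any():
        raise SchemaError(
            "cesarean and operative_vaginal flags must be exclusive"
        )
    if (records["n_stillbirths"] > records["n_fetuses"]).any():
        raise SchemaError("n_stillbirths cannot exceed n_fetuses")
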