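"""Robson ten-group classification of births and audit tables.

The Robson system sorts every birth into exactly one of ten mutually
exclusive, all-inclusive groups using six obstetric characteristics:
parity, previous cesarean section, onset of labor, fetal presentation
and lie, number of fetuses, and gestational age (term vs preterm).  It
is the WHO-recommended framework for auditing cesarean section use; a
facility's monthly Robson table shows which groups drive its cesarean
rate.

Classification hierarchy (applied top-down; the first matching rule
wins):

1.  multiple pregnancy                          -> Group 8
2.  singleton transverse or oblique lie         -> Group 9
3.  singleton breech, nulliparous               -> Group 6
4.  singleton breech, multiparous               -> Group 7
5.  singleton cephalic preterm (< 37 weeks)     -> Group 10
6.  singleton cephalic term, previous cesarean  -> Group 5
7.  nulliparous, spontaneous labor              -> Group 1
8.  nulliparous, induced or prelabor cesarean   -> Group 2
9.  multiparous, spontaneous labor              -> Group 3
10. multiparous, induced or prelabor cesarean   -> Group 4

Groups 6, 7, 9 and 10 absorb women with a previous cesarean; Groups 2
and 4 pool induced labor with prelabor cesarean (the undivided
ten-group version, without the 2a/2b or 5.1/5.2 subdivisions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ValidationError

LABOR_ONSETS = ("spontaneous", "induced", "prelabor_cesarean")
PRESENTATIONS = ("cephalic", "breech", "transverse_oblique")

DEFAULT_TERM_THRESHOLD_WEEKS = 37.0
MIN_GESTATIONAL_AGE_WEEKS = 20.0


@dataclass(frozen=True)
class ObstetricProfile:
    """The six characteristics that determine a woman's Robson group."""

    parity: int
    previous_cesareans: int
    labor_onset: str
    presentation: str
    n_fetuses: int
    gestational_age_weeks: float

    def __post_init__(self) -> None:
        if self.parity < 0:
            raise ValidationError("parity must be a non-negative count")
        if self.previous_cesareans < 0:
            raise ValidationError(
                "previous_cesareans must be a non-negative count"
            )
        if self.previous_cesareans > self.parity:
            raise ValidationError(
                "previous_cesareans cannot exceed parity "
                f"({self.previous_cesareans} > {self.parity})"
            )
        if self.labor_onset not in LABOR_ONSETS:
            raise ValidationError(
                f"labor_onset must be one of {LABOR_ONSETS}, "
                f"got {self.labor_onset!r}"
            )
        if self.presentation not in PRESENTATIONS:
            raise ValidationError(
                f"presentation must be one of {PRESENTATIONS}, "
                f"got {self.presentation!r}"
            )
        if self.n_fetuses < 1:
            raise ValidationError("n_fetuses must be a positive count")
        if self.gestational_age_weeks < MIN_GESTATIONAL_AGE_WEEKS:
            raise ValidationError(
                "gestational_age_weeks must be >= "
                f"{MIN_GESTATIONAL_AGE_WEEKS}"
            )


def classify(
    profile: ObstetricProfile,
    term_threshold_weeks: float = DEFAULT_TERM_THRESHOLD_WEEKS,
) -> int:
    """Robson group (1-10) of a single valid profile."""
    if profile.n_fetuses >= 2:
        return 8
    if profile.presentation == "transverse_oblique":
        return 9
    if profile.presentation == "breech":
        return 6 if profile.parity == 0 else 7
    if profile.gestational_age_weeks < term_threshold_weeks:
        return 10
    if profile.previous_cesareans >= 1:
        return 5
    if profile.parity == 0:
        return 1 if profile.labor_onset == "spontaneous" else 2
    return 3 if profile.labor_onset == "spontaneous" else 4


def classify_frame(
    df: pd.DataFrame,
    term_threshold_weeks: float = DEFAULT_TERM_THRESHOLD_WEEKS,
) -> np.ndarray:
    """Vectorized :func:`classify` over a records frame.

    Expects columns ``parity``, ``previous_cesareans``, ``labor_onset``,
    ``presentation``, ``n_fetuses``, ``gestational_age_weeks``.
    Validates the same invariants as :class:`ObstetricProfile` and
    raises on the first violated one, naming the offending column.
    """
    _validate_columns(df)
    parity = df["parity"].to_numpy()
    prev_cs = df["previous_cesareans"].to_numpy()
    onset = df["labor_onset"].to_numpy()
    pres = df["presentation"].to_numpy()
    nfet = df["n_fetuses"].to_numpy()
    ga = df["gestational_age_weeks"].to_numpy(dtype=float)

    group = np.zeros(len(df), dtype=np.int64)
    multiple = nfet >= 2
    group[multiple] = 8
    todo = ~multiple
    transverse = todo & (pres == "transverse_oblique")
    group[transverse] = 9
    todo &= ~transverse
    breech = todo & (pres == "breech")
    group[breech & (parity == 0)] = 6
    group[breech & (parity > 0)] = 7
    todo &= ~breech
    preterm = todo & (ga < term_threshold_weeks)
    group[preterm] = 10
    todo &= ~preterm
    prev = todo & (prev_cs >= 1)
    group[prev] = 5
    todo &= ~prev
    spont = onset == "spontaneous"
    group[todo & (parity == 0) & spont] = 1
    group[todo & (parity == 0) & ~spont] = 2
    group[todo & (parity > 0) & spont] = 3
    group[todo & (parity > 0) & ~spont] = 4
    return group


def _validate_columns(df: pd.DataFrame) -> None:
    required = (
        "parity", "previous_cesareans", "labor_onset", "presentation",
        "n_fetuses", "gestational_age_weeks",
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    if (df["parity"] < 0).any():
        raise ValidationError("parity must be a non-negative count")
    if (df["previous_cesareans"] < 0).any():
        raise ValidationError("previous_cesareans must be non-negative")
    if (df["previous_cesareans"] > df["parity"]).any():
        raise ValidationError("previous_cesareans cannot exceed parity")
    bad_onset = set(df["labor_onset"].unique()) - set(LABOR_ONSETS)
    if bad_onset:
        raise ValidationError(f"unknown labor_onset values: {bad_onset}")
    bad_pres = set(df["presentation"].unique()) - set(PRESENTATIONS)
    if bad_pres:
        raise ValidationError(f"unknown presentation values: {bad_pres}")
    if (df["n_fetuses"] < 1).any():
        raise ValidationError("n_fetuses must be a positive count")
    if (df["gestational_age_weeks"] < MIN_GESTATIONAL_AGE_WEEKS).any():
        raise ValidationError(
            f"gestational_age_weeks must be >= {MIN_GESTATIONAL_AGE_WEEKS}"
        )


class RobsonClassifier(BaseEstimator):
    """Deterministic Robson ten-group classifier, estimator-style.

    Stateless apart from its parameters; ``fit`` only validates and
    records the input schema so the class composes with scikit-learn
    pipelines and ``get_params``/``set_params`` tooling.

    Parameters
    ----------
    term_threshold_weeks : float, default 37.0
        Completed weeks of gestation at and above which a pregnancy
        counts as term.
    """

    def __init__(self, term_threshold_weeks: float = DEFAULT_TERM_THRESHOLD_WEEKS):
        self.term_threshold_weeks = term_threshold_weeks

    def fit(self, X: pd.DataFrame, y=None) -> "RobsonClassifier":
        _validate_columns(X)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.arange(1, 11)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return classify_frame(X, self.term_threshold_weeks)

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


# ---------------------------------------------------------------------
# audit tables


TABLE_COLUMNS = (
    "n_women",
    "n_cesarean",
    "group_size_pct",
    "group_cs_rate_pct",
    "absolute_contribution_pct",
    "relative_contribution_pct",
)


def tabulate(records: pd.DataFrame) -> pd.DataFrame:
    """WHO-style Robson audit table.

    ``records`` needs columns ``robson_group`` (1-10) and ``cesarean``
    (0/1); each row is one woman (multiple births count once).  Returns
    a frame indexed by group 1-10 plus a ``total`` row, with group
    sizes, cesarean counts and rates, and each group's absolute
    contribution (cesareans in the group as % of all women) and
    relative contribution (as % of all cesareans).  Identities: sizes
    sum to N, absolute contributions sum to the overall cesarean rate,
    relative contributions sum to 100%.
    """
    if len(records) == 0:
        raise ValidationError("cannot tabulate an empty record list")
    groups = records["robson_group"]
    if not groups.isin(range(1, 11)).all():
        raise ValidationError("robson_group values must lie in 1..10")
    n_total = len(records)
    cs_total = int(records["cesarean"].sum())

    idx = pd.RangeIndex(1, 11, name="robson_group")
    n_women = groups.value_counts().reindex(idx, fill_value=0)
    n_cs = (
        records.loc[records["cesarean"] == 1, "robson_group"]
        .value_counts()
        .reindex(idx, fill_value=0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        cs_rate = np.where(n_women > 0, 100.0 * n_cs / n_women, 0.0)
        rel = (
            np.where(cs_total > 0, 100.0 * n_cs / cs_total, 0.0)
            if cs_total
            else np.zeros(10)
        )
    table = pd.DataFrame(
        {
            "n_women": n_women.to_numpy(),
            "n_cesarean": n_cs.to_numpy(),
            "group_size_pct": 100.0 * n_women.to_numpy() / n_total,
            "group_cs_rate_pct": cs_rate,
            "absolute_contribution_pct": 100.0 * n_cs.to_numpy() / n_total,
            "relative_contribution_pct": rel,
        },
        index=idx,
    )
    total = pd.DataFrame(
        {
            "n_women": [n_total],
            "n_cesarean": [cs_total],
            "group_size_pct": [100.0],
            "group_cs_rate_pct": [100.0 * cs_total / n_total],
            "absolute_contribution_pct": [100.0 * cs_total / n_total],
            "relative_contribution_pct": [100.0 if cs_total else 0.0],
        },
        index=pd.Index(["total"], name="robson_group"),
    )
    return pd.concat([table, total])


def monthly_feedback_report(
    records: pd.DataFrame,
    calendar_month: str,
    *,
    as_csv: bool = False,
) -> str:
    """Monthly Robson audit-and-feedback report.

    Renders the Robson table for ``calendar_month`` (``"YYYY-MM"``)
    plus the trailing trend of overall and Group-1 cesarean rates over
    every month up to and including it.  A month with no births yields
    an explicit "no births" report rather than an error.  ``records``
    needs a ``birth_date`` column in addition to the tabulate columns.
    """
    if "birth_date" not in records.columns:
        raise ValidationError("records must carry a birth_date column")
    period = pd.Period(calendar_month, freq="M")
    dates = pd.PeriodIndex(
        pd.to_datetime(records["birth_date"]), freq="M"
    )
    month_slice = records.loc[dates == period]

    lines = [f"Robson classification report - {period}"]
    if len(month_slice) == 0:
        lines.append("no births recorded this month")
        return "\n".join(lines)

    table = tabulate(month_slice)
    lines.append(
        table.round(1).to_csv() if as_csv
        else table.round(1).to_string()
    )

    trend_rows = []
    for m in sorted({p for p in dates if p <= period}):
        chunk = records.loc[dates == m]
        g1 = chunk[chunk["robson_group"] == 1]
        trend_rows.append(
            {
                "month": str(m),
                "n_births": len(chunk),
                "overall_cs_rate_pct": 100.0 * chunk["cesarean"].mean(),
                "group1_cs_rate_pct": (
                    100.0 * g1["cesarean"].mean() if len(g1) else np.nan
                ),
            }
        )
    trend = pd.DataFrame(trend_rows)
    lines.append("trend of cesarean rates:")
    lines.append(
        trend.round(1).to_csv(index=False) if as_csv
        else trend.round(1).to_string(index=False)
    )
    return "\n".join(lines)
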