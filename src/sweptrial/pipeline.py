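"""End-to-end trial analysis: filter, classify, estimate, report.

Orchestrates the intention-to-treat analysis of a stepped-wedge birth
cohort: planned exposure is derived from the randomization schedule
and the birth date (never from a recorded condition column, which is
only cross-checked), transition-window births are excluded, every
outcome is evaluated on its own denominator (all women, a Robson
subset, women in spontaneous labor, vaginal births, babies, or the
postpartum-survey subsample), crude rates and crude absolute
differences are reported alongside model-based effect estimates
(relative risks from the modified-Poisson GEE with the Mancl-DeRouen
sandwich and t(N-2) inference, or mean differences for durations), and
the whole bundle serializes to JSON and plain-text tables.  A model
that fails to converge yields a row with crude statistics and an
explicit "no estimate" marker instead of aborting the run.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import SWDesign
from .exceptions import ValidationError
from .gee import (
    effect_estimate,
    estimate_icc,
    fit_trial_gee,
    mean_difference,
)
from .simulate import babies_table, validate_dataset

logger = logging.getLogger(__name__)

DENOMINATORS = (
    "all_women", "robson", "spontaneous", "vaginal", "babies", "survey",
)


def crude_rate(numerator: int, denominator: int) -> float:
    """Percentage ``100 * num / den`` rounded half-up to 1 decimal."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must lie in [0, denominator]")
    x = Decimal(100 * numerator) / Decimal(denominator)
    return float(x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def crude_absolute_difference(
    rate_intervention: float, rate_control: float
) -> float:
    """Intervention minus control, in percentage points, 1 decimal."""
    for r in (rate_intervention, rate_control):
        if not 0.0 <= r <= 100.0:
            raise ValidationError("rates must lie in [0, 100]")
    x = Decimal(str(rate_intervention)) - Decimal(str(rate_control))
    return float(x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OutcomeSpec:
    """One analysable outcome: numerator, denominator rule, estimand.

    ``denominator`` is one of ``all_women`` (every analysis woman),
    ``robson`` (women in ``robson_groups``), ``spontaneous`` (women in
    spontaneous labor), ``vaginal`` (vaginal births), ``babies`` (one
    unit per baby) or ``survey`` (the postpartum survey subsample).
    ``estimand`` is ``rr`` or ``mean_difference``.
    """

    name: str
    column: str
    denominator: str = "all_women"
    robson_groups: Tuple[int, ...] = ()
    estimand: str = "rr"

    def __post_init__(self):
        if self.denominator not in DENOMINATORS:
            raise ValidationError(
                f"denominator must be one of {DENOMINATORS}"
            )
        if self.estimand not in ("rr", "mean_difference"):
            raise ValidationError("estimand must be rr or mean_difference")
        if self.denominator == "robson" and not self.robson_groups:
            raise ValidationError("robson denominator needs robson_groups")

    def select(self, women: pd.DataFrame) -> pd.DataFrame:
        """Rows of the denominator population (women-level frames;
        ``babies`` is expanded by the caller)."""
        if self.denominator in ("all_women", "babies"):
            return women
        if self.denominator == "robson":
            return women[women["robson_group"].isin(self.robson_groups)]
        if self.denominator == "spontaneous":
            return women[women["labor_onset"] == "spontaneous"]
        if self.denominator == "vaginal":
            return women[women["cesarean"] == 0]
        return women[women["survey_eligible"] == 1]


def default_outcomes() -> List[OutcomeSpec]:
    """The trial's primary and headline secondary outcomes."""
    return [
        OutcomeSpec("cesarean_robson_1", "cesarean", "robson", (1,)),
        OutcomeSpec("cesarean_robson_1_3", "cesarean", "robson", (1, 3)),
        OutcomeSpec(
            "cesarean_robson_1_to_5", "cesarean", "robson", (1, 2, 3, 4, 5)
        ),
        OutcomeSpec("cesarean_all", "cesarean", "all_women"),
        OutcomeSpec("augmentation", "augmentation", "spontaneous"),
        OutcomeSpec("arm_rupture", "arm_rupture", "spontaneous"),
        OutcomeSpec("episiotomy", "episiotomy", "vaginal"),
        OutcomeSpec("operative_vaginal", "operative_vaginal", "vaginal"),
        OutcomeSpec(
            "admission_to_birth_days", "admission_to_birth_days",
            "all_women", estimand="mean_difference",
        ),
        OutcomeSpec(
            "birth_to_discharge_days", "birth_to_discharge_days",
            "all_women", estimand="mean_difference",
        ),
        OutcomeSpec("stillbirth", "stillbirth", "babies"),
        OutcomeSpec("labor_companion", "labor_companion", "survey"),
    ]


@dataclass
class OutcomeRow:
    name: str
    estimand: str
    n_intervention: int
    N_intervention: int
    n_control: int
    N_control: int
    rate_intervention: Optional[float]
    rate_control: Optional[float]
    crude_difference: Optional[float]
    estimate: Optional[float]  # RR or mean difference
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    df: Optional[int]
    estimated: bool
    note: str = ""


@dataclass
class ResultsBundle:
    """Everything one analysis run produced."""

    outcomes: List[OutcomeRow]
    flow: Dict
    icc: Optional[Dict]
    exclusions: Dict[str, int]

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "outcomes": [asdict(r) for r in self.outcomes],
            "flow": self.flow,
            "icc": self.icc,
            "exclusions": self.exclusions,
        }
        return json.dumps(payload, indent=indent, default=_json_default)

    def to_text(self) -> str:
        rows = []
        for r in self.outcomes:
            est = (
                f"{r.estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                if r.estimated
                else "not estimated"
            )
            rows.append(
                {
                    "outcome": r.name,
                    "intervention": f"{r.n_intervention}/{r.N_intervention}"
                    + (
                        f" ({r.rate_intervention})"
                        if r.rate_intervention is not None
                        else ""
                    ),
                    "control": f"{r.n_control}/{r.N_control}"
                    + (
                        f" ({r.rate_control})"
                        if r.rate_control is not None
                        else ""
                    ),
                    "crude_diff": r.crude_difference,
                    f"effect ({'RR' if r.estimand == 'rr' else 'MD'})": est,
                }
            )
        text = pd.DataFrame(rows).to_string(index=False)
        if self.icc is not None:
            text += (
                f"\n\nICC (control period): {self.icc['icc']:.3f} "
                f"(95% CI {self.icc['ci_low']:.3f}; "
                f"{self.icc['ci_high']:.3f})"
            )
        text += f"\n\nexclusions: {self.exclusions}"
        return text


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (dt.date, dt.datetime)):
        return o.isoformat()
    raise TypeError(f"not JSON serializable: {type(o)}")


def assign_condition(
    records: pd.DataFrame, design: SWDesign
) -> pd.Series:
    """Planned exposure from the schedule and the birth date.

    If the frame carries a recorded ``condition`` column it is only
    compared against the planned one; mismatches are logged, never
    used.
    """
    dates = records["birth_date"]
    if not isinstance(dates.iloc[0], dt.date):
        dates = pd.to_datetime(dates).dt.date
    planned = pd.Series(
        [
            design.condition(c, d)
            for c, d in zip(records["cluster"], dates)
        ],
        index=records.index,
        name="condition",
    )
    if "condition" in records.columns:
        mismatch = int((records["condition"] != planned).sum())
        if mismatch:
            logger.warning(
                "recorded condition disagrees with planned exposure for "
                "%d records; planned exposure used",
                mismatch,
            )
    return planned


def flow_counts(records: pd.DataFrame, design: SWDesign) -> Dict:
    """Women and babies per cluster and condition, plus totals.

    Counts partition the dataset; the analysis N is the control plus
    intervention total.
    """
    cond = assign_condition(records, design)
    women = (
        records.assign(condition=cond)
        .groupby(["cluster", "condition"], observed=True)
        .agg(women=("cluster", "size"), babies=("n_fetuses", "sum"))
        .reset_index()
    )
    totals = (
        women.groupby("condition", observed=True)[["women", "babies"]]
        .sum()
        .to_dict(orient="index")
    )
    for d in totals.values():
        d["women"], d["babies"] = int(d["women"]), int(d["babies"])
    analysis_women = sum(
        totals.get(k, {"women": 0})["women"]
        for k in ("control", "intervention")
    )
    return {
        "per_cluster": women.to_dict(orient="records"),
        "totals": totals,
        "analysis_women": int(analysis_women),
        "all_women": int(len(records)),
        "all_babies": int(records["n_fetuses"].sum()),
    }


def run_trial_analysis(
    records: pd.DataFrame,
    design: SWDesign,
    outcomes: Optional[Sequence[OutcomeSpec]] = None,
    *,
    icc_outcome: Optional[OutcomeSpec] = None,
    icc_n_boot: int = 200,
    seed: int = 0,
) -> ResultsBundle:
    """Intention-to-treat analysis of a full trial dataset.

    ``icc_outcome`` (default: the first outcome) names the binary
    outcome whose control-period ICC is reported with a cluster-
    bootstrap CI.
    """
    validate_dataset(records)
    outcomes = list(outcomes) if outcomes is not None else default_outcomes()

    cond = assign_condition(records, design)
    records = records.assign(condition=cond.to_numpy())
    flow = flow_counts(records, design)
    n_transition = int((cond == "transition").sum())
    analysis = records.loc[cond != "transition"].copy()
    analysis["treatment"] = (
        analysis["condition"] == "intervention"
    ).astype(np.int64)
    exclusions = {"transition_window": n_transition}
    logger.info("excluded %d transition-window records", n_transition)

    babies = babies_table(analysis)
    babies["treatment"] = (
        babies["condition"] == "intervention"
    ).astype(np.int64)

    rows = []
    for spec_ in outcomes:
        frame = (
            babies if spec_.denominator == "babies"
            else spec_.select(analysis)
        )
        rows.append(_analyse_outcome(spec_, frame))

    icc_report = None
    icc_spec = icc_outcome or (outcomes[0] if outcomes else None)
    if icc_spec is not None and icc_spec.estimand == "rr":
        control = icc_spec.select(
            analysis[analysis["condition"] == "control"]
        )
        try:
            icc_est = estimate_icc(
                control, icc_spec.column, n_boot=icc_n_boot, seed=seed
            )
            icc_report = {
                "outcome": icc_spec.name,
                "icc": icc_est.icc,
                "ci_low": icc_est.ci_low,
                "ci_high": icc_est.ci_high,
                "n_boot": icc_est.n_boot,
            }
        except Exception as exc:  # report the failure, keep the run
            icc_report = {"outcome": icc_spec.name, "error": str(exc)}

    return ResultsBundle(
        outcomes=rows, flow=flow, icc=icc_report, exclusions=exclusions
    )


def _analyse_outcome(spec_: OutcomeSpec, frame: pd.DataFrame) -> OutcomeRow:
    col = spec_.column
    observed = frame[frame[col].notna()]
    arm = observed["treatment"] == 1
    Ni, Nc = int(arm.sum()), int((~arm).sum())

    if spec_.estimand == "mean_difference":
        row = OutcomeRow(
            name=spec_.name, estimand=spec_.estimand,
            n_intervention=Ni, N_intervention=Ni,
            n_control=Nc, N_control=Nc,
            rate_intervention=(
                round(float(observed.loc[arm, col].mean()), 2) if Ni else None
            ),
            rate_control=(
                round(float(observed.loc[~arm, col].mean()), 2) if Nc else None
            ),
            crude_difference=None, estimate=None, ci_low=None,
            ci_high=None, p_value=None, df=None, estimated=False,
        )
        try:
            md = mean_difference(observed, col)
            row.estimate, row.ci_low, row.ci_high = (
                round(md.difference, 4), md.ci_low, md.ci_high
            )
            row.p_value, row.df, row.estimated = md.p_value, md.df, True
        except Exception as exc:
            row.note = f"no estimate: {exc}"
        return row

    ni = int(observed.loc[arm, col].sum())
    nc = int(observed.loc[~arm, col].sum())
    ri = crude_rate(ni, Ni) if Ni else None
    rc = crude_rate(nc, Nc) if Nc else None
    row = OutcomeRow(
        name=spec_.name, estimand="rr",
        n_intervention=ni, N_intervention=Ni,
        n_control=nc, N_control=Nc,
        rate_intervention=ri, rate_control=rc,
        crude_difference=(
            crude_absolute_difference(ri, rc)
            if ri is not None and rc is not None
            else None
        ),
        estimate=None, ci_low=None, ci_high=None,
        p_value=None, df=None, estimated=False,
    )
    try:
        fit = fit_trial_gee(observed, col)
        if not fit.converged_:
            row.note = "no estimate: model did not converge"
            return row
        est = effect_estimate(fit)
        row.estimate, row.ci_low, row.ci_high = est.rr, est.ci_low, est.ci_high
        row.p_value, row.df, row.estimated = est.p_value, est.df, True
    except Exception as exc:
        row.note = f"no estimate: {exc}"
    return row
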