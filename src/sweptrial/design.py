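"""Stepped-wedge design geometry.

A stepped-wedge cluster-randomized design enrolls every cluster in the
control condition, then crosses clusters over to the intervention at
staggered, randomly assigned calendar times ("steps"); by the final
period every cluster delivers the intervention.  :class:`SWDesign`
encodes that geometry — the calendar grid of analysis periods, the
per-cluster crossover step, and the post-crossover transition window
that is excluded from analysis while the intervention beds in — and
answers the one question the analysis pipeline needs: *which condition
was this cluster in on this date?*

The default geometry mirrors a four-hospital trial running just over a
year: seven analysis periods of two months (the last truncated at the
trial end date), one hospital crossing over every two months, and a
two-week transition window after each crossover.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np

from .exceptions import DesignInfeasibleError, ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
TRANSITION = "transition"
INTERVENTION = "intervention"
EXCLUDED = "excluded"

_DEFAULT_START = dt.date(2021, 7, 1)
_DEFAULT_END = dt.date(2022, 7, 15)


@dataclass(frozen=True)
class SWDesign:
    """Cluster-by-period exposure layout of a stepped-wedge trial.

    Parameters
    ----------
    sequence_of_cluster
        Maps each cluster id to its *step*: the number of whole periods
        the cluster spends in the control condition.  A cluster at step
        ``k`` is control during periods ``1..k`` and intervention from
        period ``k + 1`` on.  Exactly one cluster crosses over per step.
    n_periods
        Number of analysis periods.  Periods are indexed from 1.
    period_length_days
        Nominal period length; the final period may be shorter if
        ``end_date`` truncates it.
    transition_days
        Length of the transition window that opens at each cluster's
        crossover date.  Births in the window belong to neither arm.
    start_date, end_date
        Calendar range covered by the trial.  ``end_date`` defaults to
        the end of the last nominal period.
    """

    sequence_of_cluster: Mapping[str, int]
    n_periods: int = 7
    period_length_days: int = 61
    transition_days: int = 14
    start_date: dt.date = _DEFAULT_START
    end_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.n_periods < 2:
            raise DesignInfeasibleError("a wedge needs at least 2 periods")
        if self.period_length_days < 1:
            raise ValidationError("period_length_days must be positive")
        if self.transition_days < 0:
            raise ValidationError("transition_days must be non-negative")
        if self.transition_days > self.period_length_days:
            raise ValidationError(
                "transition window cannot exceed one period"
            )
        steps = sorted(self.sequence_of_cluster.values())
        n = len(self.sequence_of_cluster)
        if n < 2:
            raise DesignInfeasibleError("a wedge needs at least 2 clusters")
        if steps != list(range(1, n + 1)):
            raise ValidationError(
                "steps must be a permutation of 1..n_clusters "
                f"(exactly one cluster crosses per step); got {steps}"
            )
        if steps[-1] >= self.n_periods:
            raise DesignInfeasibleError(
                "last cluster must reach the intervention before the final "
                f"period: max step {steps[-1]} with {self.n_periods} periods"
            )
        nominal_end = self.start_date + dt.timedelta(
            days=self.n_periods * self.period_length_days - 1
        )
        if self.end_date is None:
            object.__setattr__(self, "end_date", nominal_end)
        else:
            min_end = self.period_start(self.n_periods)
            if not (min_end <= self.end_date <= nominal_end):
                raise ValidationError(
                    "end_date must fall inside the final period"
                )

    # -- geometry -----------------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(self.sequence_of_cluster)

    @property
    def clusters(self) -> Tuple[str, ...]:
        return tuple(sorted(self.sequence_of_cluster))

    def period_start(self, period: int) -> dt.date:
        self._check_period(period)
        return self.start_date + dt.timedelta(
            days=(period - 1) * self.period_length_days
        )

    def period_end(self, period: int) -> dt.date:
        """Last calendar day of ``period`` (inclusive)."""
        self._check_period(period)
        nominal = self.start_date + dt.timedelta(
            days=period * self.period_length_days - 1
        )
        return min(nominal, self.end_date)

    def period_days(self, period: int) -> int:
        return (self.period_end(period) - self.period_start(period)).days + 1

    def period_fraction(self, period: int) -> float:
        """Length of ``period`` as a fraction of the nominal length."""
        return self.period_days(period) / self.period_length_days

    def period_of(self, date: dt.date) -> int:
        """1-based analysis period containing ``date``."""
        self._check_date(date)
        return (date - self.start_date).days // self.period_length_days + 1

    def crossover_date(self, cluster: str) -> dt.date:
        """First day of the cluster's first intervention period."""
        step = self._step(cluster)
        return self.period_start(step + 1)

    def condition(self, cluster: str, date: dt.date) -> str:
        """Planned exposure of ``cluster`` on ``date``.

        ``transition`` covers the ``transition_days`` immediately
        following the crossover date.
        """
        cross = self.crossover_date(cluster)
        self._check_date(date)
        if date < cross:
            return CONTROL
        if (date - cross).days < self.transition_days:
            return TRANSITION
        return INTERVENTION

    def treatment_indicator(self, cluster: str, period: int) -> int:
        """Planned 0/1 exposure of the cluster-period (transition ignored)."""
        self._check_period(period)
        return int(period > self._step(cluster))

    def analysis_fraction(self, cluster: str, period: int) -> float:
        """Fraction of a nominal period that is analysis time.

        Accounts for final-period truncation and for the transition
        window carved out of the cluster's first intervention period.
        """
        frac = self.period_fraction(period)
        if self.transition_days and period == self._step(cluster) + 1:
            frac -= min(self.transition_days, self.period_days(period)) / (
                self.period_length_days
            )
        return max(frac, 0.0)

    # -- helpers ------------------------------------------------------

    def _step(self, cluster: str) -> int:
        try:
            return self.sequence_of_cluster[cluster]
        except KeyError:
            raise ValidationError(f"unknown cluster id {cluster!r}") from None

    def _check_period(self, period: int) -> None:
        if not 1 <= period <= self.n_periods:
            raise ValidationError(
                f"period {period} outside 1..{self.n_periods}"
            )

    def _check_date(self, date: dt.date) -> None:
        if not self.start_date <= date <= self.end_date:
            raise ValidationError(
                f"date {date} outside trial range "
                f"[{self.start_date}, {self.end_date}]"
            )


def default_design() -> SWDesign:
    """The package's reference four-cluster, seven-period wedge.

    Hospitals H1..H4 cross over after periods 1..4; two-month (61-day)
    periods from 1 Jul 2021; trial ends 15 Jul 2022, truncating the
    seventh period to 14 days; two-week transition windows.
    """
    return SWDesign(
        sequence_of_cluster={"H1": 1, "H2": 2, "H3": 3, "H4": 4},
        n_periods=7,
        period_length_days=61,
        transition_days=14,
        start_date=_DEFAULT_START,
        end_date=_DEFAULT_END,
    )


def randomize_sequences(
    n_clusters: int,
    seed: int,
    *,
    n_periods: int | None = None,
    period_length_days: int = 61,
    transition_days: int = 14,
    start_date: dt.date = _DEFAULT_START,
    end_date: dt.date | None = None,
) -> SWDesign:
    """Randomly assign clusters to crossover steps.

    Draws a uniformly random permutation of the clusters onto steps
    ``1..n_clusters``; identical seeds reproduce identical assignments.
    The assignment is written to the package audit log.

    ``n_periods`` defaults to ``n_clusters + 3`` so the wedge keeps a
    leading all-control period and trailing all-intervention periods,
    mirroring the reference geometry.
    """
    if n_clusters < 2:
        raise DesignInfeasibleError(
            "randomization needs at least 2 clusters"
        )
    if n_periods is None:
        n_periods = n_clusters + 3
    rng = np.random.default_rng(seed)
    clusters = [f"H{i + 1}" for i in range(n_clusters)]
    steps = rng.permutation(n_clusters) + 1
    sequence = {c: int(s) for c, s in zip(clusters, steps)}
    logger.info(
        "audit: randomized %d clusters onto steps with seed %d: %s",
        n_clusters, seed, sequence,
    )
    return SWDesign(
        sequence_of_cluster=sequence,
        n_periods=n_periods,
        period_length_days=period_length_days,
        transition_days=transition_days,
        start_date=start_date,
        end_date=end_date,
    )


def exposure_matrix(design: SWDesign) -> "np.ndarray":
    """Cluster-by-period plan as a matrix of ``0 / 1 / 'excluded'``.

    Entries are 0 for control periods and 1 for intervention periods;
    the cluster-period that contains the transition window (the first
    post-crossover period, when ``transition_days > 0``) is marked
    ``'excluded'`` because it mixes transition and intervention time.

    Returns an object array of shape ``(n_clusters, n_periods)`` with
    rows ordered by :attr:`SWDesign.clusters`.
    """
    mat = np.empty((design.n_clusters, design.n_periods), dtype=object)
    for i, cluster in enumerate(design.clusters):
        step = design.sequence_of_cluster[cluster]
        for t in range(1, design.n_periods + 1):
            if t <= step:
                mat[i, t - 1] = 0
            elif t == step + 1 and design.transition_days > 0:
                mat[i, t - 1] = EXCLUDED
            else:
                mat[i, t - 1] = 1
    return mat


def design_from_dict(cfg: Dict) -> SWDesign:
    """Build a design from a plain (YAML/JSON-friendly) mapping."""
    kwargs = dict(cfg)
    for key in ("start_date", "end_date"):
        if isinstance(kwargs.get(key), str):
            kwargs[key] = dt.date.fromisoformat(kwargs[key])
    return SWDesign(**kwargs)
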