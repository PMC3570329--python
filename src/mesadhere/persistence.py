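"""Treatment persistence: episode construction, Kaplan–Meier, log-rank.

A member is persistent while the index 5-ASA treatment is not definitively
ceased.  Cessation (GAP_DISCONTINUATION) is declared at the first supply
runout followed by a grace period (>=60 days, twice the usual refill time)
with no 5-ASA fill; a fill of a *different* 5-ASA product is a SWITCH and
ends persistence at that fill's date.  Members with neither event inside
the 365-day window are CENSORED at day 365.

Event-time conventions (documented because claims papers rarely state
them): a gap discontinuation is timed at runout + 1 days from index (the
first unmedicated day, counting the index day as day 1); a switch is timed
at the switch fill's day offset from index.  Early refills are banked
(carry-forward stockpiling) so they never create artificial gaps.  A gap
counts only when the full grace period elapses inside the window: a runout
later than day 365 - grace leaves the silence unobservable by the end of
follow-up, so the episode is censored, not discontinued (right-edge rule;
a patient refilling steadily until late in the year is persistent).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from ._rounding import pct
from .adherence import PartitionError
from .claims_model import DrugClass, Product
from .cohort import WINDOW_DAYS, CohortMember
from .config import DEFAULT_GRACE_DAYS

__all__ = [
    "EventType",
    "TreatmentEpisode",
    "SurvivalCurve",
    "build_episode",
    "build_episodes",
    "km_estimate",
    "logrank_compare",
    "permutation_logrank",
    "persistence_summary",
    "episodes_to_frame",
]


class EventType(str, enum.Enum):
    GAP_DISCONTINUATION = "GAP_DISCONTINUATION"
    SWITCH = "SWITCH"
    CENSORED = "CENSORED"


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    index_product: Product
    runout_dates: tuple[int, ...]  # day offsets from index where each fill's supply ends
    event_type: EventType
    event_time_days: int  # in [1, 365]

    @property
    def persistent_at_365(self) -> bool:
        return self.event_type is EventType.CENSORED


def build_episode(
    member: CohortMember,
    fills: pd.DataFrame,
    grace_days: int = DEFAULT_GRACE_DAYS,
    any_asa_closes_gap: bool = True,
    require_abandonment: bool = False,
) -> TreatmentEpisode:
    """Classify one member's episode as gap discontinuation, switch, or censored.

    ``any_asa_closes_gap`` (default) reads the >=60-day rule as "no 5-ASA
    treatment of any product"; the strict alternative requires an
    index-product fill to close a gap.  ``require_abandonment`` only counts
    a different-product fill as a switch when no index-product fill follows
    it.
    """
    horizon = WINDOW_DAYS - 1  # analysis is confined to the 365-day window

    idx_fills: list[tuple[int, int]] = []
    other_ts: list[int] = []
    for row in fills.itertuples(index=False):
        if row.drug_class != DrugClass.FIVE_ASA.value:
            continue
        t = (row.dispense_date - member.index_date).days
        if t < 0 or t > horizon:
            continue
        if row.product == member.index_product.value:
            idx_fills.append((t, int(row.days_supply)))
        else:
            other_ts.append(t)
    idx_fills.sort()
    other_ts.sort()
    if not idx_fills or idx_fills[0][0] != 0:
        raise ValueError(
            f"patient {member.patient_id!r}: no index-product fill at the index date"
        )

    switch_t: int | None = None
    for t in other_ts:
        if require_abandonment and any(ft > t for ft, _ in idx_fills):
            continue
        switch_t = t
        break

    def gap_qualifies(runout: int) -> bool:
        if runout + grace_days > horizon:
            return False  # grace period does not elapse inside the window
        silent = range(runout + 1, runout + grace_days + 1)
        if any(ft in silent for ft, _ in idx_fills):
            return False
        if any_asa_closes_gap and any(ot in silent for ot in other_ts):
            return False
        return True

    runouts: list[int] = []
    prev_runout: int | None = None
    gap_event: int | None = None
    for t, s in idx_fills:
        if prev_runout is not None and t > prev_runout + grace_days and gap_event is None:
            if gap_qualifies(prev_runout):
                gap_event = prev_runout + 1
        start = t if prev_runout is None else max(t, prev_runout + 1)
        prev_runout = start + s - 1
        runouts.append(prev_runout)
    if gap_event is None and prev_runout is not None and gap_qualifies(prev_runout):
        gap_event = prev_runout + 1

    if switch_t is not None and (gap_event is None or switch_t < gap_event):
        event, time = EventType.SWITCH, max(1, switch_t)
    elif gap_event is not None:
        event, time = EventType.GAP_DISCONTINUATION, gap_event
    else:
        event, time = EventType.CENSORED, WINDOW_DAYS
    return TreatmentEpisode(
        patient_id=member.patient_id,
        index_product=member.index_product,
        runout_dates=tuple(runouts),
        event_type=event,
        event_time_days=time,
    )


def build_episodes(
    members: Sequence[CohortMember],
    dispensing: pd.DataFrame,
    grace_days: int = DEFAULT_GRACE_DAYS,
    any_asa_closes_gap: bool = True,
    require_abandonment: bool = False,
) -> list[TreatmentEpisode]:
    by_patient = dict(tuple(dispensing.groupby("patient_id", sort=False)))
    empty = dispensing.iloc[0:0]
    return [
        build_episode(
            m, by_patient.get(m.patient_id, empty), grace_days,
            any_asa_closes_gap, require_abandonment,
        )
        for m in members
    ]


def episodes_to_frame(episodes: Iterable[TreatmentEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.patient_id, e.index_product.value, e.event_type.value,
             e.event_time_days, e.persistent_at_365)
            for e in episodes
        ],
        columns=["patient_id", "index_product", "event_type", "event_time_days",
                 "persistent_at_365"],
    )


# ---------------------------------------------------------------------------
# Survival estimation


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: stepwise survival over event times."""

    event_times: tuple[int, ...]
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    survival: tuple[float, ...]

    def at(self, t: float) -> float:
        """S(t): survival just after time t (right-continuous step function)."""
        s = 1.0
        for time, surv in zip(self.event_times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_at_risk,
                "n_event": self.n_events,
                "survival": self.survival,
            }
        )


def _durations_events(episodes: Sequence[TreatmentEpisode]) -> tuple[np.ndarray, np.ndarray]:
    durations = np.array([e.event_time_days for e in episodes], dtype=float)
    observed = np.array([e.event_type is not EventType.CENSORED for e in episodes], dtype=bool)
    return durations, observed


def km_estimate(episodes: Sequence[TreatmentEpisode]) -> SurvivalCurve:
    """Kaplan–Meier time-to-discontinuation for one group of episodes."""
    if not episodes:
        raise ValueError("km_estimate requires at least one episode")
    durations, observed = _durations_events(episodes)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = tuple(int(t) for t in event_rows.index)
    survival = tuple(float(kmf.survival_function_at_times(t).iloc[0]) for t in times)
    return SurvivalCurve(
        event_times=times,
        n_at_risk=tuple(int(v) for v in event_rows["at_risk"]),
        n_events=tuple(int(v) for v in event_rows["observed"]),
        survival=survival,
    )


def _logrank_arrays(groups: Mapping[Hashable, Sequence[TreatmentEpisode]]):
    labels, durations, observed = [], [], []
    for name, eps in groups.items():
        if len(eps) == 0:
            raise ValueError(f"log-rank group {name!r} has zero episodes")
        d, o = _durations_events(eps)
        durations.append(d)
        observed.append(o)
        labels.extend([name] * len(eps))
    return np.concatenate(durations), np.concatenate(observed), np.asarray(labels, dtype=object)


def logrank_compare(groups: Mapping[Hashable, Sequence[TreatmentEpisode]]) -> tuple[float, float]:
    """Log-rank chi-square statistic and asymptotic p across >=2 groups."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, observed, labels = _logrank_arrays(groups)
    res = multivariate_logrank_test(durations, labels, observed)
    return float(res.test_statistic), float(res.p_value)


def permutation_logrank(
    groups: Mapping[Hashable, Sequence[TreatmentEpisode]],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for the log-rank statistic (labels reshuffled).

    Serves as a small-sample check on the chi-square asymptotic; p uses the
    add-one estimator (1 + #{perm >= observed}) / (n + 1).
    """
    durations, observed, labels = _logrank_arrays(groups)
    stat = float(multivariate_logrank_test(durations, labels, observed).test_statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        perm_stat = float(multivariate_logrank_test(durations, perm, observed).test_statistic)
        if perm_stat >= stat - 1e-12:
            hits += 1
    return stat, (1 + hits) / (n_permutations + 1)


def persistence_summary(
    episodes: Sequence[TreatmentEpisode],
    grouping: Mapping[Hashable, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-group persistent-at-365 counts and round-half-up percentages."""
    frame = episodes_to_frame(episodes)
    if grouping is None:
        grouping = {"overall": list(frame["patient_id"])}
    groups = {label: [str(i) for i in ids] for label, ids in grouping.items()}
    seen: set[str] = set()
    for label, ids in groups.items():
        id_set = set(ids)
        if seen & id_set:
            raise PartitionError("overlapping persistence groups")
        seen |= id_set
    if set(frame["patient_id"].astype(str)) - seen:
        raise PartitionError("patients missing from persistence grouping")
    indexed = frame.set_index(frame["patient_id"].astype(str))
    rows = []
    for label, ids in groups.items():
        sub = indexed.loc[ids] if ids else indexed.iloc[0:0]
        n = len(sub)
        n_pers = int(sub["persistent_at_365"].sum())
        rows.append((label, n, n_pers, pct(n_pers, n) if n else float("nan")))
    return pd.DataFrame(rows, columns=["group", "n", "n_persistent_365", "pct_persistent"])
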