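"""Actuarial mortality rates for cohorts with time-varying status.

The observation window (default ages 1.5–11.5 years) is subdivided into
fixed intervals (default 6 months).  Within each interval and status,
the annual mortality rate is the number of deaths of individuals
holding that status divided by the summed person-years those
individuals spent at risk in the interval: an individual alive through
a whole 6-month interval contributes 0.5 years, one dying or censored
mid-interval contributes the time up to the event.  An individual that
switches status inside an interval has its exposure split exactly at
the transition age, which conserves total person-time.

Rates per status are reported only for intervals containing at least a
minimum number of individuals of that status (default 10), and two
statuses are compared by a paired t-test across their common retained
intervals (with a Shapiro–Wilk normality diagnostic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "PairedComparison",
    "read_cohort_table",
    "write_cohort_table",
    "status_exposure",
    "mortality_rates",
]

_EVENTS = ("death", "censored")


@dataclass
class CohortTable:
    """Per-individual status episodes plus the terminal event.

    `episodes`: DataFrame with columns id, status, start, end (ages in
    years); `events`: DataFrame with columns id, event ("death" or
    "censored"), event_age.  Episodes of one individual must be
    ordered, non-overlapping and contiguous, and must cover the ages up
    to the terminal event.
    """

    episodes: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        ep, ev = self.episodes, self.events
        for col in ("id", "status", "start", "end"):
            if col not in ep.columns:
                raise ValueError(f"episodes missing column {col!r}")
        for col in ("id", "event", "event_age"):
            if col not in ev.columns:
                raise ValueError(f"events missing column {col!r}")
        if not set(ev["event"]).issubset(_EVENTS):
            raise ValueError(f"event must be one of {_EVENTS}")
        if ev["id"].duplicated().any():
            raise ValueError("one terminal event per individual")
        if (ep[["start", "end"]] < 0).any().any() or (ev["event_age"] < 0).any():
            raise ValueError("ages must be nonnegative")
        if set(ep["id"]) != set(ev["id"]):
            raise ValueError("episodes and events must cover the same individuals")
        event_age = ev.set_index("id")["event_age"]
        for ind, sub in ep.groupby("id"):
            sub = sub.sort_values("start")
            if (sub["end"] < sub["start"]).any():
                raise ValueError(f"individual {ind!r}: episode with end < start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1] - 1e-9):
                raise ValueError(f"individual {ind!r}: overlapping episodes")
            if np.any(np.abs(starts[1:] - ends[:-1]) > 1e-9):
                raise ValueError(f"individual {ind!r}: non-contiguous episodes")
            if ends[-1] < event_age.loc[ind] - 1e-9:
                raise ValueError(
                    f"individual {ind!r}: episodes end before the terminal event"
                )

    @property
    def individuals(self) -> list:
        return list(self.events["id"])


@dataclass
class PairedComparison:
    """Paired t-test of two statuses across common retained intervals."""

    status_a: str
    status_b: str
    n_intervals: int
    mean_rate_a: float
    mean_rate_b: float
    t_stat: float
    p: float
    shapiro_p: float
    defined: bool


def read_cohort_table(path) -> CohortTable:
    """Read the episode-per-row cohort TSV
    (``id birth_age_origin episode_status episode_start episode_end event event_age``).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    episodes = df.rename(columns={
        "episode_status": "status", "episode_start": "start", "episode_end": "end",
    })[["id", "status", "start", "end"]]
    events = df[["id", "event", "event_age"]].drop_duplicates()
    return CohortTable(episodes=episodes, events=events)


def write_cohort_table(cohort: CohortTable, path, provenance: str | None = None) -> None:
    ev = cohort.events.set_index("id")
    df = cohort.episodes.copy()
    df["birth_age_origin"] = 0.0
    df["event"] = ev.loc[df["id"], "event"].to_numpy()
    df["event_age"] = ev.loc[df["id"], "event_age"].to_numpy()
    df = df.rename(columns={"status": "episode_status", "start": "episode_start",
                            "end": "episode_end"})
    cols = ["id", "birth_age_origin", "episode_status", "episode_start",
            "episode_end", "event", "event_age"]
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def status_exposure(
    cohort: CohortTable,
    interval_length: float = 0.5,
    observation_window: tuple[float, float] = (1.5, 11.5),
) -> pd.DataFrame:
    """Per (interval, status) deaths, person-years and annual rates.

    Returns the unfiltered mortality table: one row per (interval,
    status) with columns interval_index, start, end, status, deaths,
    person_years, annual_rate, n_individuals.
    """
    w_start, w_end = observation_window
    if not (w_end > w_start >= 0) or interval_length <= 0:
        raise ValueError("invalid observation window or interval length")
    n_intervals = int(np.ceil((w_end - w_start) / interval_length - 1e-9))
    edges = w_start + interval_length * np.arange(n_intervals + 1)
    edges[-1] = min(edges[-1], w_end)

    event = cohort.events.set_index("id")
    statuses = sorted(cohort.episodes["status"].unique())
    s_pos = {s: i for i, s in enumerate(statuses)}
    person_years = np.zeros((n_intervals, len(statuses)))
    deaths = np.zeros((n_intervals, len(statuses)), dtype=int)
    contributors: dict[tuple[int, int], set] = {}

    for ind, sub in cohort.episodes.groupby("id"):
        t_event = float(event.loc[ind, "event_age"])
        is_death = event.loc[ind, "event"] == "death"
        sub = sub.sort_values("start")
        death_status = None
        for status, ep_start, ep_end in sub[["status", "start", "end"]].itertuples(index=False):
            a = max(ep_start, w_start)
            b = min(ep_end, t_event, w_end)
            j = s_pos[status]
            # The status held at the moment of death: last episode whose
            # span reaches the event age (boundary deaths credit the
            # episode being left, not double-credit both).
            if is_death and ep_start <= t_event <= ep_end + 1e-9 and death_status is None:
                death_status = j
            if b <= a:
                continue
            first = int(np.floor((a - w_start) / interval_length))
            last = int(np.ceil((b - w_start) / interval_length)) - 1
            last = min(last, n_intervals - 1)
            for i in range(first, last + 1):
                lo = max(a, edges[i])
                hi = min(b, edges[i + 1])
                if hi <= lo:
                    continue
                person_years[i, j] += hi - lo
                contributors.setdefault((i, j), set()).add(ind)
        if is_death and death_status is not None and w_start <= t_event < w_end:
            i_death = min(int(np.floor((t_event - w_start) / interval_length)),
                          n_intervals - 1)
            deaths[i_death, death_status] += 1

    rows = []
    for i in range(n_intervals):
        for s, j in s_pos.items():
            py = person_years[i, j]
            rows.append({
                "interval_index": i,
                "start": edges[i],
                "end": edges[i + 1],
                "status": s,
                "deaths": int(deaths[i, j]),
                "person_years": py,
                "annual_rate": deaths[i, j] / py if py > 0 else np.nan,
                "n_individuals": len(contributors.get((i, j), ())),
            })
    return pd.DataFrame(rows)


def mortality_rates(
    table: pd.DataFrame,
    min_individuals: int = 10,
    compare: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, PairedComparison | None]:
    """Filter the mortality table and optionally compare two statuses.

    Rows with fewer than `min_individuals` of the status in the
    interval are dropped.  If `compare` names two statuses, a paired
    t-test runs across their common retained intervals with defined
    rates; fewer than 2 common intervals leaves the comparison
    undefined (flagged).
    """
    filtered = table[table["n_individuals"] >= min_individuals].reset_index(drop=True)
    if compare is None:
        return filtered, None
    status_a, status_b = compare
    a = filtered[filtered["status"] == status_a].set_index("interval_index")["annual_rate"]
    b = filtered[filtered["status"] == status_b].set_index("interval_index")["annual_rate"]
    common = a.index.intersection(b.index)
    ra, rb = a.loc[common], b.loc[common]
    ok = ra.notna() & rb.notna()
    ra, rb = ra[ok], rb[ok]
    if len(ra) < 2:
        logger.warning("mortality comparison %s vs %s: fewer than 2 common intervals",
                       status_a, status_b)
        return filtered, PairedComparison(
            status_a=status_a, status_b=status_b, n_intervals=len(ra),
            mean_rate_a=float("nan"), mean_rate_b=float("nan"),
            t_stat=float("nan"), p=float("nan"), shapiro_p=float("nan"),
            defined=False,
        )
    diff = ra.to_numpy() - rb.to_numpy()
    t_stat, p = stats.ttest_rel(ra, rb)
    if np.allclose(diff, diff[0]):
        shapiro_p = float("nan")  # constant differences: normality check degenerate
    else:
        shapiro_p = float(stats.shapiro(diff).pvalue)
    return filtered, PairedComparison(
        status_a=status_a, status_b=status_b, n_intervals=int(len(ra)),
        mean_rate_a=float(ra.mean()), mean_rate_b=float(rb.mean()),
        t_stat=float(t_stat), p=float(p), shapiro_p=shapiro_p, defined=True,
    )
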