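"""Formation / elimination / turnover statistics for tracked boutons.

Definitions (per axon or field, per inter-session interval):

* formation rate  f = newly formed boutons / bouton count in the previous
  session;
* elimination rate e = eliminated boutons / bouton count in the previous
  session;
* turnover rate   t = (f + e) / 2;
* period-averaged rates: the unweighted mean of the per-interval rates
  (intervals are treated as units even though they span unequal numbers
  of days);
* survival fraction S(day): the fraction of the initial (day 0,
  analysis-included) bouton population still identifiable at the given
  day — a bouton that disappeared and reappeared by that day counts as
  surviving (identical-bouton rule);
* linear bouton density rho = bouton count / traced axon length;
* relative count and relative size: per-unit counts and per-bouton sizes
  normalized to their day-0 values;
* tercile survival: day-0 sizes ranked, lower/upper thirds defined as
  small/large boutons, day-7 survival computed per class.

Group summaries are reported as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import BoutonTrack, tracks_to_events

INTERVALS = ((0, 2), (2, 4), (4, 7))


class UnitExcludedError(ValueError):
    """Raised when a unit cannot contribute (zero denominator, too few boutons)."""


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

def formation_rate(n_new: int, n_prev: int) -> float:
    """Newly formed boutons divided by the previous session's count."""
    if n_prev <= 0:
        raise UnitExcludedError("formation rate undefined for n_prev = 0")
    return n_new / n_prev


def elimination_rate(n_elim: int, n_prev: int) -> float:
    """Eliminated boutons divided by the previous session's count."""
    if n_prev <= 0:
        raise UnitExcludedError("elimination rate undefined for n_prev = 0")
    return n_elim / n_prev


def turnover_rate(f: float, e: float) -> float:
    """Average of the formation and elimination rates."""
    if f < 0 or e < 0:
        raise ValueError("rates must be nonnegative")
    return 0.5 * (f + e)


def period_averaged_rates(per_interval_rates) -> float:
    """Unweighted mean of the per-interval rates of one unit.

    Raises :class:`UnitExcludedError` if any interval is missing (NaN).
    """
    rates = np.asarray(list(per_interval_rates), dtype=float)
    if rates.size == 0 or np.any(~np.isfinite(rates)):
        raise UnitExcludedError("missing interval rate; unit excluded")
    return float(rates.mean())


def bouton_density(n_boutons: int, traced_length_um: float) -> float:
    """Linear bouton density (um^-1) along the traced axon."""
    if traced_length_um <= 0:
        raise ValueError("traced length must be positive")
    return n_boutons / traced_length_um


# ---------------------------------------------------------------------------
# track-level statistics
# ---------------------------------------------------------------------------

def survival_fraction(
    tracks: list[BoutonTrack],
    day: int,
    count_reappeared: bool = True,
) -> float:
    """Fraction of initial (pre-existing, analysis-included) boutons
    surviving at ``day``.

    A bouton whose track shows status ``present`` or (with the
    identical-bouton rule, the default) ``reappeared`` at the day counts
    as surviving.
    """
    initial = [t for t in tracks if t.preexisting and t.included_in_analysis]
    if not initial:
        raise UnitExcludedError("empty initial bouton set")
    ok = ("present", "reappeared") if count_reappeared else ("present",)
    surviving = sum(t.status_by_session.get(day) in ok for t in initial)
    return surviving / len(initial)


def relative_count(n_by_day: dict[int, int] | pd.Series) -> pd.Series:
    """Bouton counts normalized to the day-0 count."""
    series = pd.Series(dict(n_by_day)).sort_index()
    n0 = series.iloc[0]
    if n0 <= 0:
        raise UnitExcludedError("zero day-0 count; unit excluded")
    return series / n0


def relative_size(
    sizes_by_day: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bouton sizes normalized to day 0, plus the mean +/- SEM summary.

    ``sizes_by_day`` has one row per bouton and one column per session
    day (NaN = absent). Boutons absent on day 0 are excluded.
    """
    df = sizes_by_day.copy()
    df.columns = [int(c) for c in df.columns]
    df = df[sorted(df.columns)]
    day0 = df.columns[0]
    valid = df[day0] > 0
    df = df.loc[valid]
    if df.empty:
        raise UnitExcludedError("no boutons present on day 0")
    rel = df.div(df[day0], axis=0)
    summary = pd.DataFrame({
        "mean": rel.mean(axis=0),
        "sem": rel.sem(axis=0),
        "n": rel.notna().sum(axis=0),
    })
    return rel, summary


def tracks_relative_size(tracks: list[BoutonTrack], session_days) -> tuple:
    """:func:`relative_size` over the pre-existing, included tracks."""
    rows = {
        t.track_id: {d: t.size_at(d) for d in session_days}
        for t in tracks if t.preexisting and t.included_in_analysis
    }
    if not rows:
        raise UnitExcludedError("no pre-existing included tracks")
    return relative_size(pd.DataFrame.from_dict(rows, orient="index"))


def tercile_survival(
    tracks: list[BoutonTrack],
    day: int = 7,
) -> dict[str, float]:
    """Day-``day`` survival of small vs large pre-existing boutons.

    Pre-existing (day-0) boutons are ranked by day-0 size, ties broken by
    position along the axon; the lower and upper thirds (floor(n/3) each)
    are the small and large classes. Requires at least 3 pre-existing
    boutons.
    """
    pre = [t for t in tracks if t.preexisting and t.included_in_analysis]
    if len(pre) < 3:
        raise UnitExcludedError("fewer than 3 pre-existing boutons")
    day0 = min(t for tr in pre for t in tr.observations)
    ranked = sorted(
        pre, key=lambda t: (t.size_at(day0), t.observations[day0][0])
    )
    n_tail = len(ranked) // 3
    small = ranked[:n_tail]
    large = ranked[-n_tail:]

    def _surv(group):
        return float(np.mean([t.present_at(day) for t in group]))

    return {
        "small_survival": _surv(small),
        "large_survival": _surv(large),
        "n_per_class": n_tail,
    }


# ---------------------------------------------------------------------------
# per-unit summaries
# ---------------------------------------------------------------------------

@dataclass
class DynamicsSummary:
    """Per-unit (field or animal) summary of bouton dynamics."""

    unit_id: str
    per_interval: pd.DataFrame      # day_start, day_end, f, e, turnover
    period_averaged: dict[str, float]
    survival: dict[int, float]      # day -> S(day)
    density_by_day: dict[int, float]
    relative_count: pd.Series
    group: str | None = None        # e.g. trained / control
    projection: str | None = None   # e.g. M2 / thalamic


def summarize_tracks(
    tracks: list[BoutonTrack],
    session_days,
    traced_length_um: float,
    unit_id: str = "field",
    group: str | None = None,
    projection: str | None = None,
) -> DynamicsSummary:
    """Compute the full dynamics summary for one field's tracks."""
    session_days = sorted(session_days)
    events = tracks_to_events(tracks, session_days)
    agg = events.groupby(["day_start", "day_end"], as_index=False).sum(
        numeric_only=True
    )
    rows = []
    for _, r in agg.iterrows():
        f = formation_rate(r["n_formed"], r["n_prev"])
        e = elimination_rate(r["n_eliminated"], r["n_prev"])
        rows.append({
            "day_start": r["day_start"], "day_end": r["day_end"],
            "formation_rate": f, "elimination_rate": e,
            "turnover_rate": turnover_rate(f, e),
        })
    per_interval = pd.DataFrame(rows)
    period = {
        "formation_rate": period_averaged_rates(per_interval["formation_rate"]),
        "elimination_rate": period_averaged_rates(
            per_interval["elimination_rate"]),
        "turnover_rate": period_averaged_rates(per_interval["turnover_rate"]),
    }
    included = [t for t in tracks if t.included_in_analysis]
    survival = {d: survival_fraction(tracks, d) for d in session_days}
    counts = {
        d: sum(t.present_at(d) for t in included) for d in session_days
    }
    density = {d: bouton_density(n, traced_length_um)
               for d, n in counts.items()}
    return DynamicsSummary(
        unit_id=unit_id,
        per_interval=per_interval,
        period_averaged=period,
        survival=survival,
        density_by_day=density,
        relative_count=relative_count(counts),
        group=group,
        projection=projection,
    )


def summary_frame(summaries: list[DynamicsSummary]) -> pd.DataFrame:
    """Tidy table over units: one row per unit x statistic x interval/day."""
    rows = []
    for s in summaries:
        base = {"unit_id": s.unit_id, "group": s.group,
                "projection": s.projection}
        for _, r in s.per_interval.iterrows():
            for stat in ("formation_rate", "elimination_rate",
                         "turnover_rate"):
                rows.append(base | {
                    "statistic": stat, "day_start": r["day_start"],
                    "day_end": r["day_end"], "value": r[stat]})
        for stat, v in s.period_averaged.items():
            rows.append(base | {"statistic": f"period_{stat}", "value": v})
        for d, v in s.survival.items():
            rows.append(base | {"statistic": "survival", "day_end": d,
                                "value": v})
        for d, v in s.density_by_day.items():
            rows.append(base | {"statistic": "density", "day_end": d,
                                "value": v})
        for d, v in s.relative_count.items():
            rows.append(base | {"statistic": "relative_count", "day_end": d,
                                "value": v})
    return pd.DataFrame(rows)


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean, as reported throughout."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return np.nan, np.nan
    sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else np.nan
    return float(arr.mean()), float(sem)
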