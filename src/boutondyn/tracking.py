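"""Cross-session bouton identity tracking along traced axons.

Sessions of the same axon are aligned by landmark boutons — large, stable
swellings used as positional anchors — and boutons are considered
identical between two sessions when their landmark-relative arc-length
positions differ by less than 0.7 um. Identity chains across the ordered
sessions form tracks; each track's per-session status records presence,
elimination (weight fallen below 1.3 or no detection at the expected
position) and reappearance (a later detection within 0.7 um of the
landmark-corrected last known position re-joins the same track). A new
track is opened for an unmatched detection with weight above the
putative threshold appearing after day 0 (newly formed bouton, defined
relative to the immediately preceding session only).

All discrepancies are one-dimensional arc-length distances: positions
are bound to the axon, and the identity rule is phrased as distance to
an adjacent landmark along the axon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import (
    BoutonObservation,
    DetectionThresholds,
    analysis_inclusion,
)

IDENTITY_TOL_UM = 0.7  # cross-session identity tolerance (um)

PRESENT_STATUSES = ("present", "reappeared")


class ScheduleError(ValueError):
    """Raised when observations disagree about the session schedule."""


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landmark:
    """A bouton present in both sessions of a pair, anchoring the offset."""

    s_a: float
    s_b: float
    size: float  # min of the two session sizes

    @property
    def offset(self) -> float:
        return self.s_b - self.s_a


@dataclass
class LandmarkSet:
    """Arc-length alignment between two sessions of one axon.

    ``fallback`` is set when landmark coverage is insufficient (fewer
    than one landmark per 50 um of axon, or none at all); offsets then
    fall back to 0.
    """

    day_a: int
    day_b: int
    landmarks: list[Landmark] = field(default_factory=list)
    fallback: bool = False

    def offset_at(self, s) -> np.ndarray | float:
        """Local arc-length offset (session a -> b frame) near coordinate s.

        Linear interpolation between landmark offsets, constant beyond
        the outermost landmarks; 0 everywhere in fallback mode.
        """
        s = np.asarray(s, dtype=float)
        if self.fallback or not self.landmarks:
            out = np.zeros_like(s)
            return float(out) if out.ndim == 0 else out
        sa = np.array([lm.s_a for lm in self.landmarks])
        off = np.array([lm.offset for lm in self.landmarks])
        order = np.argsort(sa)
        out = np.interp(s, sa[order], off[order])
        return float(out) if out.ndim == 0 else out


def select_landmarks(
    obs_a: list[BoutonObservation],
    obs_b: list[BoutonObservation],
    min_size: float = 3.0,
    max_gap_um: float = 2.0,
    axon_length: float | None = None,
    coverage_um: float = 50.0,
) -> LandmarkSet:
    """Choose landmark boutons for a session pair.

    Landmarks are large boutons (size >= ``min_size``) that are mutually
    nearest between the two sessions with position difference at most
    ``max_gap_um``, accepted greedily by descending size. The manual
    "visually identified adjacent landmark" step of interactive analysis
    is automated by this surrogate; its parameters are explicit here.
    """
    day_a = obs_a[0].session_day if obs_a else 0
    day_b = obs_b[0].session_day if obs_b else 0
    big_a = [o for o in obs_a if o.size >= min_size]
    big_b = [o for o in obs_b if o.size >= min_size]
    lset = LandmarkSet(day_a=day_a, day_b=day_b)
    if not big_a or not big_b:
        lset.fallback = True
        return lset

    sa = np.array([o.position_s for o in big_a])
    sb = np.array([o.position_s for o in big_b])
    nearest_in_b = np.array([np.argmin(np.abs(sb - s)) for s in sa])
    nearest_in_a = np.array([np.argmin(np.abs(sa - s)) for s in sb])
    pairs = []
    for i, j in enumerate(nearest_in_b):
        if nearest_in_a[j] == i and abs(sb[j] - sa[i]) <= max_gap_um:
            pairs.append((min(big_a[i].size, big_b[j].size), i, j))
    pairs.sort(key=lambda t: (-t[0], sa[t[1]]))
    used_a, used_b = set(), set()
    for size, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        lset.landmarks.append(Landmark(s_a=float(sa[i]), s_b=float(sb[j]),
                                       size=float(size)))
    lset.landmarks.sort(key=lambda lm: lm.s_a)

    if axon_length is None and lset.landmarks:
        axon_length = max(
            max(o.position_s for o in obs_a),
            max(o.position_s for o in obs_b),
        )
    required = max(1, int(np.floor((axon_length or 0.0) / coverage_um)))
    if len(lset.landmarks) < required or not lset.landmarks:
        lset.fallback = True
    return lset


# ---------------------------------------------------------------------------
# pairwise matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (index in a, index in b, discrepancy)
    unmatched_a: list[int]
    unmatched_b: list[int]


def match_pair(
    obs_a: list[BoutonObservation],
    obs_b: list[BoutonObservation],
    landmarks: LandmarkSet | None = None,
    tol_um: float = IDENTITY_TOL_UM,
) -> MatchResult:
    """Match boutons one-to-one between two sessions of the same axon.

    Each bouton in session a is carried to session b's frame by the local
    landmark offset; candidate pairs with landmark-relative position
    discrepancy strictly below ``tol_um`` are accepted greedily by
    ascending discrepancy (ties broken by ascending position), giving a
    deterministic one-to-one assignment.
    """
    landmarks = landmarks or LandmarkSet(day_a=0, day_b=0, fallback=True)
    sa = np.array([o.position_s for o in obs_a], dtype=float)
    sb = np.array([o.position_s for o in obs_b], dtype=float)
    corrected = sa + (landmarks.offset_at(sa) if sa.size else 0.0)

    candidates = []
    for i in range(sa.size):
        disc = np.abs(sb - corrected[i])
        for j in np.nonzero(disc < tol_um)[0]:
            candidates.append((float(disc[j]), float(sa[i]), float(sb[j]),
                               i, int(j)))
    candidates.sort()
    used_a, used_b = set(), set()
    pairs = []
    for disc, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, disc))
    return MatchResult(
        pairs=pairs,
        unmatched_a=[i for i in range(sa.size) if i not in used_a],
        unmatched_b=[j for j in range(sb.size) if j not in used_b],
    )


# ---------------------------------------------------------------------------
# track building
# ---------------------------------------------------------------------------

@dataclass
class BoutonTrack:
    """One physical bouton's identity across the imaging sessions."""

    track_id: int
    axon_id: str
    observations: dict[int, tuple[float, float]]  # day -> (position_s, size)
    status_by_session: dict[int, str]             # day -> status
    preexisting: bool
    formed_day: int | None
    included_in_analysis: bool

    def size_at(self, day: int) -> float | None:
        obs = self.observations.get(day)
        return obs[1] if obs is not None else None

    def present_at(self, day: int) -> bool:
        return self.status_by_session.get(day, "absent") in PRESENT_STATUSES

    @property
    def ever_eliminated(self) -> bool:
        return "eliminated" in self.status_by_session.values()


class _TrackState:
    __slots__ = ("observations", "status", "expected_s", "gone", "formed_day")

    def __init__(self, day, s, size, formed_day):
        self.observations = {day: (s, size)}
        self.status = {day: "present"}
        self.expected_s = s
        self.gone = False
        self.formed_day = formed_day


def build_tracks(
    obs_by_day: dict[int, list[BoutonObservation]],
    thresholds: DetectionThresholds | None = None,
    landmark_sets: dict[tuple[int, int], LandmarkSet] | None = None,
    axon_id: str | None = None,
    axon_length: float | None = None,
    tol_um: float = IDENTITY_TOL_UM,
    birth_min: float | None = None,
    landmark_min_size: float = 3.0,
    landmark_max_gap_um: float = 2.0,
) -> list[BoutonTrack]:
    """Chain per-session detections into bouton identity tracks.

    Tracks are seeded from day-0 detections above the birth threshold
    (default: the putative threshold, >2) and extended session by session
    by greedy landmark-corrected matching. A matched detection with size
    >= 1.3 continues (or, after a gap, re-joins) the track; a matched
    detection below 1.3, or no detection within 0.7 um of the expected
    position, marks the bouton eliminated. Unmatched detections above the
    birth threshold after day 0 open new tracks (newly formed boutons).
    Expected positions of unmatched tracks are carried through the chain
    of consecutive landmark offsets so reappearance is judged at the
    landmark-corrected last known position.
    """
    thresholds = thresholds or DetectionThresholds()
    if birth_min is None:
        birth_min = thresholds.putative_min
    days = sorted(obs_by_day)
    if not days:
        return []
    for day, obs in obs_by_day.items():
        for o in obs:
            if o.session_day != day:
                raise ScheduleError(
                    f"observation day {o.session_day} filed under day {day}"
                )
    if axon_id is None:
        first = next((o for obs in obs_by_day.values() for o in obs), None)
        axon_id = first.axon_id if first else "axon"

    states: list[_TrackState] = []
    day0 = days[0]
    for o in sorted(obs_by_day[day0], key=lambda o: o.position_s):
        if o.size > birth_min:
            states.append(_TrackState(day0, o.position_s, o.size, None))

    for d_prev, d in zip(days, days[1:]):
        if landmark_sets is not None and (d_prev, d) in landmark_sets:
            lset = landmark_sets[(d_prev, d)]
        else:
            lset = select_landmarks(
                obs_by_day[d_prev], obs_by_day[d],
                min_size=landmark_min_size, max_gap_um=landmark_max_gap_um,
                axon_length=axon_length,
            )
        obs = sorted(obs_by_day[d], key=lambda o: o.position_s)
        # advance all expected positions into session d's frame
        for tr in states:
            tr.expected_s = float(tr.expected_s + lset.offset_at(tr.expected_s))

        candidates = []
        for ti, tr in enumerate(states):
            for oi, o in enumerate(obs):
                disc = abs(o.position_s - tr.expected_s)
                if disc < tol_um:
                    candidates.append((disc, tr.expected_s, o.position_s,
                                       ti, oi))
        candidates.sort()
        used_t, used_o = set(), set()
        for disc, _, _, ti, oi in candidates:
            if ti in used_t or oi in used_o:
                continue
            used_t.add(ti)
            used_o.add(oi)
            tr, o = states[ti], obs[oi]
            tr.observations[d] = (o.position_s, o.size)
            if o.size >= thresholds.elimination_below:
                tr.status[d] = "reappeared" if tr.gone else "present"
                tr.gone = False
                tr.expected_s = o.position_s
            else:
                # detected but fallen below the elimination threshold
                tr.status[d] = "eliminated"
                tr.gone = True
        for ti, tr in enumerate(states):
            if ti not in used_t:
                tr.status[d] = "eliminated"
                tr.gone = True
        for oi, o in enumerate(obs):
            if oi not in used_o and o.size > birth_min:
                states.append(_TrackState(d, o.position_s, o.size, d))

    tracks = []
    for tid, tr in enumerate(states):
        status = {}
        for d in days:
            if d in tr.status:
                status[d] = tr.status[d]
            else:
                status[d] = "absent"  # before the track's first appearance
        sizes = [tr.observations.get(d, (None, None))[1] for d in days]
        tracks.append(BoutonTrack(
            track_id=tid,
            axon_id=axon_id,
            observations=dict(tr.observations),
            status_by_session=status,
            preexisting=tr.formed_day is None,
            formed_day=tr.formed_day,
            included_in_analysis=analysis_inclusion(sizes, thresholds),
        ))
    return tracks


def tracks_frame(tracks: list[BoutonTrack], session_days=None) -> pd.DataFrame:
    """Tracks as a tidy table: one row per track per session."""
    if session_days is None:
        session_days = sorted({d for t in tracks for d in t.status_by_session})
    rows = []
    for t in tracks:
        for d in session_days:
            obs = t.observations.get(d)
            rows.append({
                "track_id": t.track_id, "axon_id": t.axon_id,
                "session_day": d,
                "position_s": obs[0] if obs else np.nan,
                "size": obs[1] if obs else np.nan,
                "status": t.status_by_session.get(d, "absent"),
                "preexisting": t.preexisting,
                "included": t.included_in_analysis,
            })
    return pd.DataFrame(rows)


def tracks_to_events(
    tracks: list[BoutonTrack],
    session_days=None,
) -> pd.DataFrame:
    """Per-interval event counts over analysis-included tracks.

    One row per axon per interval with the bouton count in the earlier
    session (``n_prev``), counts newly formed / eliminated / reappeared in
    the interval, and the count in the later session (``n_next``). With no
    reappearances ``n_next = n_prev + n_formed - n_eliminated`` exactly.
    """
    if session_days is None:
        session_days = sorted({d for t in tracks for d in t.status_by_session})
    session_days = sorted(session_days)
    axons = sorted({t.axon_id for t in tracks}) or ["axon"]
    rows = []
    for axon in axons:
        sel = [t for t in tracks
               if t.axon_id == axon and t.included_in_analysis]
        for d_prev, d in zip(session_days, session_days[1:]):
            n_prev = sum(t.present_at(d_prev) for t in sel)
            n_next = sum(t.present_at(d) for t in sel)
            n_formed = sum(t.formed_day == d for t in sel)
            n_elim = sum(
                t.present_at(d_prev)
                and t.status_by_session.get(d) == "eliminated"
                for t in sel
            )
            n_reapp = sum(
                t.status_by_session.get(d) == "reappeared" for t in sel
            )
            rows.append({
                "axon_id": axon, "day_start": d_prev, "day_end": d,
                "n_prev": n_prev, "n_formed": n_formed,
                "n_eliminated": n_elim, "n_reappeared": n_reapp,
                "n_next": n_next,
            })
    cols = ["axon_id", "day_start", "day_end", "n_prev", "n_formed",
            "n_eliminated", "n_reappeared", "n_next"]
    return pd.DataFrame(rows, columns=cols)
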