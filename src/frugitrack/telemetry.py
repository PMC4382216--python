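"""Biangulation of paired radio-telemetry bearings into fix tracks.

Two coordinated observers take simultaneous compass bearings on a tagged
animal every two minutes.  Each bearing pair is converted to a planar
position by intersecting the two bearing rays ("biangulation").  Pairs are
filtered on bearing separation (too-acute or too-obtuse intersections are
geometrically unreliable), on physical plausibility (the intersection must
lie forward of both observers), and on transmitter range.  Consecutive fixes
at the same place are collapsed to one point to reduce spatial
autocorrelation, and tracks are partitioned into nightly observation
sessions.

All coordinates are planar meters in a user-declared projected system; the
package never reprojects.  Azimuths are degrees clockwise from grid north.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BearingRecord",
    "Fix",
    "Rejection",
    "Track",
    "bearing_separation",
    "triangulate_pair",
    "triangulate",
    "deduplicate_stationary",
    "assign_sessions",
    "select_sessions",
]

#: nominal fix schedule: one bearing pair every two minutes
FIX_INTERVAL_S = 120.0
#: nominal session length: one six-hour nightly observation window
SESSION_LENGTH_S = 6 * 3600.0


class InvalidInputError(ValueError):
    """Raised for non-finite, out-of-domain or structurally invalid input."""


@dataclass(frozen=True)
class BearingRecord:
    """One simultaneous two-observer bearing observation.

    Azimuths are degrees clockwise from grid north and are normalised to
    [0, 360) on construction.  The two observer positions must be distinct.
    """

    timestamp: float
    bat_id: str
    observer_pos_1: tuple[float, float]
    observer_pos_2: tuple[float, float]
    azimuth_1: float
    azimuth_2: float
    activity: str = "unknown"

    def __post_init__(self):
        for v in (*self.observer_pos_1, *self.observer_pos_2,
                  self.azimuth_1, self.azimuth_2):
            if not math.isfinite(v):
                raise InvalidInputError("non-finite bearing record field")
        object.__setattr__(self, "azimuth_1", self.azimuth_1 % 360.0)
        object.__setattr__(self, "azimuth_2", self.azimuth_2 % 360.0)


@dataclass(frozen=True)
class Fix:
    """A planar animal position, either triangulated or simulated truth."""

    timestamp: float
    bat_id: str
    position: tuple[float, float]
    session_id: int = 0
    provenance: str = "triangulated"

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.position):
            raise InvalidInputError("non-finite fix position")
        if self.session_id < 0:
            raise InvalidInputError("session_id must be >= 0")


@dataclass(frozen=True)
class Rejection:
    """A bearing pair that failed a filter, tagged with the first failing rule."""

    timestamp: float
    bat_id: str
    reason: str  # separation | behind-observer | out-of-range


@dataclass
class Track:
    """Time-ordered fixes of one bat, partitioned into observation sessions."""

    bat_id: str
    fixes: list[Fix]
    sessions: list[tuple[float, float]] = field(default_factory=list)
    roosts: list[tuple[float, float]] = field(default_factory=list)
    flagged: bool = False

    def __post_init__(self):
        ts = [f.timestamp for f in self.fixes]
        if ts != sorted(ts):
            raise InvalidInputError("track fixes must be time-ordered")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def observation_hours(self) -> float:
        return sum(e - s for s, e in self.sessions) / 3600.0

    @property
    def observation_days(self) -> int:
        return len(self.sessions)

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.fixes], dtype=float).reshape(-1, 2)

    def session_fixes(self, session_id: int) -> list[Fix]:
        return [f for f in self.fixes if f.session_id == session_id]


def bearing_separation(azimuth_1: float, azimuth_2: float) -> float:
    """Angular separation of two azimuths, in degrees within [0, 180].

    Wraps around north, so (10, 350) -> 20.  Symmetric in its arguments.
    """
    if not (math.isfinite(azimuth_1) and math.isfinite(azimuth_2)):
        raise InvalidInputError("non-finite azimuth")
    return abs((azimuth_1 - azimuth_2 + 180.0) % 360.0 - 180.0)


def _ray_direction(azimuth_deg: float) -> np.ndarray:
    # grid-north azimuth convention: 0 deg = +y, 90 deg = +x
    a = math.radians(azimuth_deg)
    return np.array([math.sin(a), math.cos(a)])


def triangulate_pair(
    record: BearingRecord,
    max_range: float = 400.0,
    sep_bounds: tuple[float, float] = (15.0, 165.0),
    declination: float = 0.0,
) -> Fix | Rejection:
    """Intersect the two bearing rays of one record into a single fix.

    The pair is accepted only if (checked in this order)

    1. the bearing separation lies within ``sep_bounds`` (default 15-165
       degrees; outside this band the intersection geometry is unreliable),
    2. the ray intersection lies forward of both observers, and
    3. the intersection is within ``max_range`` meters of *each* observer
       (beyond transmitter range the signal is not credible).

    ``declination`` is added to both azimuths before intersecting (magnetic
    to grid correction; default 0).

    Returns a :class:`Fix` on acceptance, else a :class:`Rejection` tagged
    with the first failing rule.
    """
    o1 = np.asarray(record.observer_pos_1, dtype=float)
    o2 = np.asarray(record.observer_pos_2, dtype=float)
    if np.allclose(o1, o2):
        raise InvalidInputError("coincident observer positions")

    az1 = (record.azimuth_1 + declination) % 360.0
    az2 = (record.azimuth_2 + declination) % 360.0

    sep = bearing_separation(az1, az2)
    lo, hi = sep_bounds
    if not (lo <= sep <= hi):
        return Rejection(record.timestamp, record.bat_id, "separation")

    d1 = _ray_direction(az1)
    d2 = _ray_direction(az2)
    # solve o1 + t1*d1 = o2 + t2*d2
    a = np.column_stack([d1, -d2])
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < 1e-12:
        # parallel rays inside the separation band cannot occur except at
        # 180 deg, which the band excludes; treat defensively
        return Rejection(record.timestamp, record.bat_id, "behind-observer")
    t1, t2 = np.linalg.solve(a, o2 - o1)
    if t1 < 0 or t2 < 0:
        return Rejection(record.timestamp, record.bat_id, "behind-observer")

    p = o1 + t1 * d1
    if t1 > max_range or t2 > max_range:
        return Rejection(record.timestamp, record.bat_id, "out-of-range")

    return Fix(record.timestamp, record.bat_id, (float(p[0]), float(p[1])))


def triangulate(
    records: list[BearingRecord],
    max_range: float = 400.0,
    sep_bounds: tuple[float, float] = (15.0, 165.0),
    declination: float = 0.0,
) -> tuple[list[Fix], list[Rejection]]:
    """Triangulate a batch of bearing records into accepted fixes + a rejection log."""
    fixes: list[Fix] = []
    rejections: list[Rejection] = []
    for rec in records:
        out = triangulate_pair(rec, max_range=max_range,
                               sep_bounds=sep_bounds, declination=declination)
        (fixes if isinstance(out, Fix) else rejections).append(out)
    return fixes, rejections


def deduplicate_stationary(fixes: list[Fix], stationary_radius: float = 50.0) -> list[Fix]:
    """Collapse consecutive same-place fixes to a single point.

    Each maximal run of consecutive fixes all lying within
    ``stationary_radius`` meters of the run's *first* fix is replaced by that
    first fix.  The output is a subsequence of the input, so the operation is
    idempotent.  The default radius of 50 m is on the order of typical
    biangulation error.
    """
    if stationary_radius < 0:
        raise InvalidInputError("stationary_radius must be >= 0")
    out: list[Fix] = []
    anchor: Fix | None = None
    for f in fixes:
        if anchor is None or math.dist(f.position, anchor.position) > stationary_radius:
            out.append(f)
            anchor = f
    return out


def assign_sessions(fixes: list[Fix], sessions: list[tuple[float, float]]) -> list[Fix]:
    """Stamp each fix with the index of the session window containing it.

    Fixes outside every window are dropped.  Windows are half-open
    [start, end) except the last, which is closed.
    """
    out = []
    for f in fixes:
        for sid, (s, e) in enumerate(sessions):
            if s <= f.timestamp < e or (sid == len(sessions) - 1 and f.timestamp == e):
                out.append(replace(f, session_id=sid))
                break
    return out


def infer_sessions(fixes: list[Fix], gap_s: float = 2 * 3600.0) -> list[tuple[float, float]]:
    """Infer session windows from gaps longer than ``gap_s`` between fixes."""
    if not fixes:
        return []
    windows = []
    start = prev = fixes[0].timestamp
    for f in fixes[1:]:
        if f.timestamp - prev > gap_s:
            windows.append((start, prev + FIX_INTERVAL_S))
            start = f.timestamp
        prev = f.timestamp
    windows.append((start, prev + FIX_INTERVAL_S))
    return windows


def select_sessions(
    track: Track,
    min_contact_fraction: float = 0.85,
    n_sessions: int = 3,
) -> Track:
    """Keep the sessions with the highest contact time.

    The contact fraction of a session is its achieved fix count divided by
    its scheduled fix count (session length / fix interval).  The
    ``n_sessions`` sessions with the highest fractions among those reaching
    ``min_contact_fraction`` are retained; ties are broken in favour of the
    earlier session.  If fewer than ``n_sessions`` qualify, all qualifying
    sessions are returned and the track is flagged (some animals yield only
    two usable nights).
    """
    if not track.sessions:
        raise InvalidInputError("track has no sessions")
    fracs = []
    for sid, (s, e) in enumerate(track.sessions):
        scheduled = max(1, round((e - s) / FIX_INTERVAL_S))
        achieved = sum(1 for f in track.fixes if f.session_id == sid)
        fracs.append((sid, achieved / scheduled))
    eligible = [(sid, fr) for sid, fr in fracs if fr >= min_contact_fraction]
    # highest fraction first; earlier session wins ties
    eligible.sort(key=lambda t: (-t[1], t[0]))
    chosen = sorted(sid for sid, _ in eligible[:n_sessions])
    flagged = len(chosen) < n_sessions

    keep = {sid: new for new, sid in enumerate(chosen)}
    fixes = [replace(f, session_id=keep[f.session_id])
             for f in track.fixes if f.session_id in keep]
    sessions = [track.sessions[sid] for sid in chosen]
    return Track(track.bat_id, fixes, sessions, list(track.roosts), flagged=flagged)
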