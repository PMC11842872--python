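"""Illumination schemes, localizations, and nearest-neighbor track linking.

An illumination scheme is an ordered cycle of camera events, each consisting
of an exposure, a camera readout, and an optional dark time without laser
excitation.  The scheme fixes the timestamp of every recorded frame and, for
interlaced schemes, the dark-time classes used to sort tracks into binding
classes.  Tracks are built from localization tables by greedy
nearest-neighbor linking in the style of single-particle trackers such as
TrackIt: each localization in a frame is linked to the nearest unclaimed
track head within a search radius, optionally bridging a limited number of
missed frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemeEvent",
    "IlluminationScheme",
    "Localization",
    "Track",
    "build_scheme",
    "continuous_scheme",
    "time_lapse_scheme",
    "itm_scheme",
    "taco_scheme",
    "link_tracks",
    "jump_distances",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
]

_TIME_DECIMALS = 9  # round timestamps to ns to make float comparisons exact


@dataclass(frozen=True)
class SchemeEvent:
    """One camera event: exposure, readout, then an optional dark period (s)."""

    exposure: float
    readout: float = 0.0
    dark: float = 0.0

    def __post_init__(self) -> None:
        for name in ("exposure", "readout", "dark"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} duration must be >= 0, got {getattr(self, name)}")

    @property
    def frame_cycle(self) -> float:
        """Frame cycle time: exposure plus camera readout (s)."""
        return self.exposure + self.readout

    @property
    def period(self) -> float:
        """Total duration of the event including the trailing dark time (s)."""
        return self.exposure + self.readout + self.dark


@dataclass(frozen=True)
class IlluminationScheme:
    """A repeated cycle of :class:`SchemeEvent`, one recorded frame per event."""

    name: str
    cycle: tuple[SchemeEvent, ...]
    repeats: int = 1

    def __post_init__(self) -> None:
        if len(self.cycle) == 0:
            raise ValueError("scheme cycle must contain at least one event")
        if not any(ev.exposure > 0 for ev in self.cycle):
            raise ValueError("scheme must contain at least one event with exposure > 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        object.__setattr__(self, "cycle", tuple(self.cycle))

    @property
    def n_frames(self) -> int:
        return self.repeats * len(self.cycle)

    @property
    def cycle_duration(self) -> float:
        return sum(ev.period for ev in self.cycle)

    @property
    def duration(self) -> float:
        return self.repeats * self.cycle_duration

    def event_for_frame(self, frame: int) -> SchemeEvent:
        if not 0 <= frame < self.n_frames:
            raise IndexError(f"frame {frame} outside scheme with {self.n_frames} frames")
        return self.cycle[frame % len(self.cycle)]

    def dark_after(self, frame: int) -> float:
        """Dark time following frame `frame` (s)."""
        return self.event_for_frame(frame).dark

    def frame_times(self) -> np.ndarray:
        """Start-of-exposure timestamp of every frame (s), strictly increasing."""
        periods = np.array([ev.period for ev in self.cycle], dtype=float)
        starts_one = np.concatenate(([0.0], np.cumsum(periods)[:-1]))
        offsets = np.arange(self.repeats)[:, None] * self.cycle_duration
        times = (offsets + starts_one[None, :]).ravel()
        return np.round(times, _TIME_DECIMALS)

    def dark_classes(self) -> np.ndarray:
        """Sorted unique positive dark durations in the cycle (s)."""
        darks = sorted({round(ev.dark, _TIME_DECIMALS) for ev in self.cycle if ev.dark > 0})
        return np.asarray(darks, dtype=float)

    def tile(self, duration: float) -> "IlluminationScheme":
        """Return a copy with enough repeats to cover at least `duration` s."""
        repeats = max(1, int(np.ceil(duration / self.cycle_duration)))
        return IlluminationScheme(self.name, self.cycle, repeats)


def build_scheme(
    name: str,
    events: Sequence[tuple[float, float, float]],
    repeats: int = 1,
) -> IlluminationScheme:
    """Build a scheme from (exposure, readout, dark) triples in seconds.

    Raises ``ValueError`` on negative durations or an all-dark cycle.
    """
    return IlluminationScheme(name, tuple(SchemeEvent(*ev) for ev in events), repeats)


def continuous_scheme(
    exposure: float = 0.010, readout: float = 0.0017, n_frames: int = 100
) -> IlluminationScheme:
    """Continuous illumination; defaults give the 11.7 ms frame cycle."""
    return build_scheme("continuous", [(exposure, readout, 0.0)], repeats=n_frames)


def time_lapse_scheme(
    frame_cycle: float = 0.5017, dark: float = 4.0136, repeats: int = 100
) -> IlluminationScheme:
    """Time-lapse: one long excitation frame followed by a dark time.

    The exposure and readout are lumped into `frame_cycle` because only the
    total frame cycle enters survival-time bookkeeping.
    """
    name = f"time-lapse-{frame_cycle + dark:g}s"
    return build_scheme(name, [(frame_cycle, 0.0, dark)], repeats=repeats)


def itm_scheme(
    exposure: float = 0.010,
    readout: float = 0.0017,
    short_dark: float = 0.2,
    long_dark: float = 4.0,
    repeats: int = 50,
) -> IlluminationScheme:
    """Interlaced time-lapse: frames alternating short and long dark times."""
    return build_scheme(
        "itm",
        [(exposure, readout, short_dark), (exposure, readout, long_dark)],
        repeats=repeats,
    )


def taco_scheme(
    variant: str = "long",
    exposure: float = 0.010,
    readout: float = 0.0017,
    short_dark: float = 0.2,
    long_dark: float = 4.0,
    n_continuous: int = 10,
    repeats: int = 20,
) -> IlluminationScheme:
    """Time-lapse alternated with continuous intervals.

    The ``long`` variant filters for long-bound molecules: two detection
    frames separated by long dark times precede an analysis period of
    `n_continuous` continuously illuminated frames.  The ``short`` variant
    places the analysis period right after a single short dark time, so a
    short-bound molecule is tracked through the burst and then vanishes
    before the following long dark time.
    """
    burst = [(exposure, readout, 0.0)] * (n_continuous - 1) + [(exposure, readout, long_dark)]
    if variant == "long":
        det = [(exposure, readout, long_dark), (exposure, readout, long_dark)]
    elif variant == "short":
        det = [(exposure, readout, short_dark)]
    else:
        raise ValueError("variant must be 'long' or 'short'")
    return build_scheme(f"taco-{variant}", det + burst, repeats=repeats)


@dataclass(frozen=True)
class Localization:
    """A single detection: frame index, timestamp (s), position (µm)."""

    frame: int
    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")


@dataclass
class Track:
    """Time-ordered localizations of one molecule."""

    id: int
    localizations: list[Localization] = field(default_factory=list)
    survived_dark_times: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = [loc.frame for loc in self.localizations]
        if len(frames) == 0:
            raise ValueError("a track needs at least one localization")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.localizations)

    @property
    def frames(self) -> np.ndarray:
        return np.array([loc.frame for loc in self.localizations], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        return np.array([[loc.x, loc.y] for loc in self.localizations], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.array([loc.t for loc in self.localizations], dtype=float)


def link_tracks(
    locs: Iterable[Localization],
    radius: float,
    max_gap_frames: int = 0,
    min_length: int = 1,
) -> list[Track]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Candidate (localization, track-head) pairs within `radius` are claimed in
    order of increasing distance; ties are broken deterministically by the
    lowest localization index, then the lowest track id.  Unlinked
    localizations seed new tracks.  A track head stays eligible while at most
    `max_gap_frames` frames have been missed since its last detection.
    Tracks with fewer than `min_length` localizations are discarded.
    """
    if radius <= 0:
        raise ValueError("search radius must be > 0")
    locs = list(locs)
    if not locs:
        return []

    by_frame: dict[int, list[tuple[int, Localization]]] = {}
    for idx, loc in enumerate(locs):
        by_frame.setdefault(loc.frame, []).append((idx, loc))

    tracks: list[Track] = []
    # active heads: (track_index, last_frame, x, y)
    active: list[int] = []

    for frame in sorted(by_frame):
        frame_locs = by_frame[frame]
        active = [
            ti
            for ti in active
            if 1 <= frame - tracks[ti].localizations[-1].frame <= max_gap_frames + 1
        ]
        candidates = []
        for order, (idx, loc) in enumerate(frame_locs):
            for ti in active:
                head = tracks[ti].localizations[-1]
                d = float(np.hypot(loc.x - head.x, loc.y - head.y))
                if d <= radius:
                    candidates.append((d, idx, tracks[ti].id, order, ti))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        claimed_locs: set[int] = set()
        claimed_tracks: set[int] = set()
        for d, idx, _tid, order, ti in candidates:
            if idx in claimed_locs or ti in claimed_tracks:
                continue
            tracks[ti].localizations.append(frame_locs[order][1])
            claimed_locs.add(idx)
            claimed_tracks.add(ti)
        for idx, loc in frame_locs:
            if idx not in claimed_locs:
                tracks.append(Track(id=len(tracks), localizations=[loc]))
        active = [ti for ti in range(len(tracks)) if tracks[ti].localizations[-1].frame >= frame - max_gap_frames]

    kept = [t for t in tracks if len(t) >= min_length]
    for new_id, t in enumerate(kept):
        t.id = new_id
    return kept


def jump_distances(
    track: Track, cap: int | None = 10, exclude_gap_jumps: bool = True
) -> np.ndarray:
    """Euclidean displacements (µm) between consecutive detections.

    Jumps spanning missed frames are removed when `exclude_gap_jumps` is set,
    and at most the first `cap` jumps are returned (``None`` disables the
    cap).  The default cap of 10 prevents long-lived bound molecules from
    dominating pooled jump-distance distributions.
    """
    if len(track) < 2:
        return np.empty(0, dtype=float)
    xy = track.xy
    frames = track.frames
    jumps = np.hypot(*(xy[1:] - xy[:-1]).T)
    if exclude_gap_jumps:
        jumps = jumps[np.diff(frames) == 1]
    if cap is not None:
        jumps = jumps[:cap]
    return jumps


def tracks_to_dataframe(tracks: Sequence[Track]) -> pd.DataFrame:
    """Flatten tracks into a (track_id, frame, t_s, x_um, y_um) table."""
    rows = [
        (t.id, loc.frame, loc.t, loc.x, loc.y)
        for t in tracks
        for loc in t.localizations
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_um", "y_um"])


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        locs = [
            Localization(int(r.frame), float(r.t_s), float(r.x_um), float(r.y_um))
            for r in grp.itertuples()
        ]
        tracks.append(Track(id=int(tid), localizations=locs))
    return tracks
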