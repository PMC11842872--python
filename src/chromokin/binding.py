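"""Binding-time classification from interlaced time-lapse (ITM/TACO) movies.

ITM movies interlace short (0.2 s) and long (4 s) dark times between
detection frames.  A track *survives* a dark time when detections flank it
while staying confined within a small radius.  Tracks are sorted into
disjoint classes:

* ``long``  — survived at least two long dark times (> 8.2 s of binding,
  emergent from the frame pattern, not a free parameter),
* ``short`` — survived at least one short dark time but no long one,
* ``spot``  — a single detection,
* ``excluded`` — survived exactly one long dark time (the "grey" tracks);
  these enter the denominator of the class fractions but neither numerator.

With this counting, the long- and short-bound fractions

    long fraction  = N_long  / (N_long + N_short + N_spot + N_excluded)
    short fraction = N_short / (N_long + N_short + N_spot + N_excluded)

agree with both published definitions of the denominator (the grey tracks
being folded into "one long or no long dark time" for the long fraction and
into "passed at least one long dark time" for the short fraction), so no
convention switch is needed.

TACO movies append 10-frame continuous bursts to the classification
pattern; per qualifying track the mean jump distance over its first
complete, gap-free burst measures the mobility of that binding class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .schemes import IlluminationScheme, Track

__all__ = [
    "BindingClassCounts",
    "ClassFractions",
    "TacoClassMobility",
    "classify_track",
    "classify_itm",
    "class_fractions",
    "taco_mobility",
]

SPOT, SHORT, LONG, EXCLUDED = "spot", "short", "long", "excluded"


class SchemeError(ValueError):
    """Raised when a scheme lacks the dark-time structure an analysis needs."""


@dataclass(frozen=True)
class BindingClassCounts:
    n_long: int = 0
    n_short: int = 0
    n_spot: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.n_long, self.n_short, self.n_spot, self.n_excluded) < 0:
            raise ValueError("class counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_long + self.n_short + self.n_spot + self.n_excluded


@dataclass(frozen=True)
class ClassFractions:
    long_fraction: float
    short_fraction: float
    per_movie: tuple[tuple[float, float], ...] = ()
    long_sd: float = float("nan")
    short_sd: float = float("nan")


@dataclass(frozen=True)
class TacoClassMobility:
    binding_class: str
    per_track_mean_jump: np.ndarray  # µm
    mean: float
    sd: float
    n_tracks: int


def _dark_classes(scheme: IlluminationScheme) -> tuple[float, float]:
    classes = scheme.dark_classes()
    if len(classes) < 2:
        raise SchemeError(
            "ITM/TACO classification needs a scheme with two dark-time classes, "
            f"found {len(classes)}"
        )
    return float(classes[0]), float(classes[-1])


def _survived_darks(
    track: Track, scheme: IlluminationScheme, confinement_radius: float
) -> list[float]:
    """Chronological list of dark durations the track survived while confined.

    A dark time between scheme frames a..b is survived when the track has
    detections at frames a and b (gaps allowed in between are treated as
    surviving the intervening darks) and the displacement between the
    flanking detections stays within the confinement radius.
    """
    survived: list[float] = []
    frames = track.frames
    xy = track.xy
    for i in range(len(frames) - 1):
        d = float(np.hypot(*(xy[i + 1] - xy[i])))
        if d > confinement_radius:
            continue
        for f in range(frames[i], frames[i + 1]):
            dark = scheme.dark_after(f)
            if dark > 0:
                survived.append(round(dark, 9))
    return survived


def classify_track(
    track: Track, scheme: IlluminationScheme, confinement_radius: float
) -> str:
    """Assign one track to exactly one of spot/short/long/excluded."""
    if len(track) == 1:
        return SPOT
    short_dark, long_dark = _dark_classes(scheme)
    survived = _survived_darks(track, scheme, confinement_radius)
    n_long = sum(1 for d in survived if np.isclose(d, long_dark))
    n_short = sum(1 for d in survived if np.isclose(d, short_dark))
    if n_long >= 2:
        return LONG
    if n_long == 1:
        return EXCLUDED
    if n_short >= 1:
        return SHORT
    return SPOT


def classify_itm(
    tracks: Sequence[Track], scheme: IlluminationScheme, confinement_radius: float
) -> BindingClassCounts:
    """Count spot/short/long/excluded tracks of one ITM movie."""
    counts = {SPOT: 0, SHORT: 0, LONG: 0, EXCLUDED: 0}
    for track in tracks:
        counts[classify_track(track, scheme, confinement_radius)] += 1
    return BindingClassCounts(
        n_long=counts[LONG],
        n_short=counts[SHORT],
        n_spot=counts[SPOT],
        n_excluded=counts[EXCLUDED],
    )


def class_fractions(
    counts: BindingClassCounts | Sequence[BindingClassCounts],
) -> ClassFractions:
    """Long/short bound fractions; movie-wise aggregation as mean ± s.d."""
    if isinstance(counts, BindingClassCounts):
        counts = [counts]
    per_movie = []
    for c in counts:
        if c.total == 0:
            raise ZeroDivisionError("class fractions undefined for an empty movie")
        per_movie.append((c.n_long / c.total, c.n_short / c.total))
    longs = np.array([p[0] for p in per_movie])
    shorts = np.array([p[1] for p in per_movie])
    return ClassFractions(
        long_fraction=float(longs.mean()),
        short_fraction=float(shorts.mean()),
        per_movie=tuple(per_movie),
        long_sd=float(longs.std(ddof=1)) if len(per_movie) > 1 else float("nan"),
        short_sd=float(shorts.std(ddof=1)) if len(per_movie) > 1 else float("nan"),
    )


def _continuous_bursts(scheme: IlluminationScheme) -> list[np.ndarray]:
    """Maximal runs of >= 2 frames separated by zero dark time."""
    bursts = []
    run = [0]
    for f in range(scheme.n_frames - 1):
        if scheme.dark_after(f) == 0:
            run.append(f + 1)
        else:
            if len(run) >= 2:
                bursts.append(np.array(run))
            run = [f + 1]
    if len(run) >= 2:
        bursts.append(np.array(run))
    return bursts


def _taco_qualifies(
    track: Track, scheme: IlluminationScheme, cls: str, confinement_radius: float
) -> bool:
    # the long TACO variant has only long dark times in its cycle, the
    # short variant both classes; qualify against whatever classes exist
    classes = scheme.dark_classes()
    if len(classes) == 0:
        raise SchemeError("TACO classification needs dark times in the scheme")
    long_dark = float(classes[-1])
    short_dark = float(classes[0]) if len(classes) > 1 else None
    survived = _survived_darks(track, scheme, confinement_radius)
    n_long = sum(1 for d in survived if np.isclose(d, long_dark))
    if cls == LONG:
        return n_long >= 2
    if cls == SHORT:
        if short_dark is None:
            return False
        n_short = sum(1 for d in survived if np.isclose(d, short_dark))
        return n_short == 1 and n_long == 0
    raise ValueError(f"unknown TACO class {cls!r}")


def taco_mobility(
    tracks: Sequence[Track],
    scheme: IlluminationScheme,
    binding_class: Literal["short", "long"],
    confinement_radius: float = 0.8,
) -> TacoClassMobility:
    """Per-class mobility from the continuous analysis periods of TACO movies.

    Tracks are filtered by the class rule (long: survived >= 2 long dark
    times; short: survived exactly one short dark time and no long one).
    Each qualifying track contributes the mean jump distance over its first
    complete, gap-free continuous burst; later bursts are discarded to avoid
    overrepresenting long-lived molecules.
    """
    bursts = _continuous_bursts(scheme)
    if not bursts:
        raise SchemeError("TACO analysis needs continuous bursts in the scheme")
    means = []
    for track in tracks:
        if len(track) < 2:
            continue
        if not _taco_qualifies(track, scheme, binding_class, confinement_radius):
            continue
        frame_set = set(int(f) for f in track.frames)
        xy_by_frame = {int(f): p for f, p in zip(track.frames, track.xy)}
        for burst in bursts:
            if all(int(f) in frame_set for f in burst):
                pts = np.array([xy_by_frame[int(f)] for f in burst])
                jumps = np.hypot(*(pts[1:] - pts[:-1]).T)
                means.append(float(jumps.mean()))
                break
    arr = np.asarray(means, dtype=float)
    return TacoClassMobility(
        binding_class=binding_class,
        per_track_mean_jump=arr,
        mean=float(arr.mean()) if arr.size else float("nan"),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        n_tracks=int(arr.size),
    )
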