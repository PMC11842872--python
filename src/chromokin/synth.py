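"""Ground-truth-labeled synthetic single-molecule movies.

Generates localization streams under any illumination scheme so that every
downstream analysis (diffusion fitting, binding-class classification,
survival-spectrum inversion, radial analysis) has a parameter-recovery test
without microscopy data.  Molecules switch between a free state and short-
or long-bound states by a continuous-time Markov chain with exponential
waiting times; free molecules undergo 2D Brownian motion drawn from a
mixture of diffusion components, bound molecules move with the slowest
(apparent) component, emulating localization error and slow chromatin
motion.  Photobleaching and tracking loss are merged into a single
per-detection Bernoulli loss: the detection is recorded and the molecule is
then lost with probability ``per_frame_loss_prob``, which reproduces the
survival attenuation (1 - p)^(t / cycle) used by the spectrum inversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .schemes import IlluminationScheme

__all__ = [
    "GroundTruth",
    "SimulatedMovie",
    "simulate_movie",
    "simulate_binding_tracks",
    "radial_place",
    "sample_jumps",
    "sample_dwell_times",
    "brownian_mixture_cdf",
]

FREE, BOUND_SHORT, BOUND_LONG = "free", "short-bound", "long-bound"


@dataclass
class GroundTruth:
    """True kinetic and imaging parameters of a simulated experiment.

    diffusion_components : sequence of (fraction, D [µm²/s]) for free motion;
        fractions must sum to 1.  The slowest component doubles as the
        apparent mobility of bound molecules.
    k_on_u, k_on_s : pseudo-first-order association rates (1/s) into the
        unspecific (short-lived) and specific (long-lived) bound states.
    k_off_u, k_off_s : dissociation rates (1/s) of the two bound states.
    dissociation_spectrum : optional list of (rate [1/s], event weight); when
        given it replaces the two-class dissociation model: each binding
        event draws its off-rate from this mixture and is labeled long-bound
        when the rate is < 0.1 1/s.
    bound_diffusion : apparent diffusion coefficient of bound molecules
        (µm²/s); defaults to the slowest free component, which emulates the
        localization-precision/chromatin-motion floor of continuous imaging.
    loc_error_sigma : isotropic Gaussian localization error (µm).
    per_frame_loss_prob : combined photobleach/mislink loss per detection.
    nucleus_radius : radius of the reflecting nuclear disk (µm).
    radial_bias : optional map CBD in [0, 1] -> relative binding density.
    """

    diffusion_components: Sequence[tuple[float, float]] = ((0.3, 0.01), (0.3, 0.3), (0.4, 2.5))
    k_on_u: float = 0.1
    k_on_s: float = 0.02
    k_off_u: float = 1.0
    k_off_s: float = 0.01
    dissociation_spectrum: Sequence[tuple[float, float]] | None = None
    bound_diffusion: float | None = None
    loc_error_sigma: float = 0.03
    per_frame_loss_prob: float = 0.0025
    nucleus_radius: float = 5.0
    radial_bias: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        fracs = np.array([f for f, _ in self.diffusion_components], dtype=float)
        if not math.isclose(fracs.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("diffusion component fractions must sum to 1")
        if min(self.k_on_u, self.k_on_s, self.k_off_u, self.k_off_s) <= 0:
            raise ValueError("all kinetic rates must be > 0")
        if not 0 <= self.per_frame_loss_prob < 1:
            raise ValueError("per_frame_loss_prob must be in [0, 1)")
        if self.dissociation_spectrum is not None:
            rates = np.array([r for r, _ in self.dissociation_spectrum])
            if np.any(rates <= 0):
                raise ValueError("spectrum rates must be > 0")

    @property
    def slow_diffusion(self) -> float:
        """Apparent mobility of bound molecules (µm²/s)."""
        if self.bound_diffusion is not None:
            return self.bound_diffusion
        return min(d for _, d in self.diffusion_components)

    def stationary_fractions(self) -> tuple[float, float, float]:
        """(p_free, p_bound_short, p_bound_long) of the three-state chain."""
        w_free = 1.0
        w_u = self.k_on_u / self.k_off_u
        w_s = self.k_on_s / self.k_off_s
        z = w_free + w_u + w_s
        return w_free / z, w_u / z, w_s / z


@dataclass
class SimulatedMovie:
    """Detections with ground-truth labels plus the generating context."""

    localizations: pd.DataFrame  # molecule, frame, t_s, x_um, y_um, state
    scheme: IlluminationScheme
    truth: GroundTruth
    seed: int
    bleach_frames: dict[int, int] = field(default_factory=dict)


def _draw_state(truth: GroundTruth, rng: np.random.Generator) -> str:
    p = truth.stationary_fractions()
    return [FREE, BOUND_SHORT, BOUND_LONG][rng.choice(3, p=p)]


def _reflect_disk(pos: np.ndarray, radius: float) -> np.ndarray:
    r = float(np.hypot(*pos))
    if r > radius and r > 0:
        pos = pos * ((2 * radius - r) / r)
        # repeated folding for pathological steps
        r = float(np.hypot(*pos))
        if r > radius:
            pos = pos * (radius / r)
    return pos


def simulate_movie(
    truth: GroundTruth,
    scheme: IlluminationScheme,
    n_molecules: int,
    duration: float | None = None,
    seed: int = 0,
) -> SimulatedMovie:
    """Simulate one movie of `n_molecules` under `scheme`.

    State switching is a continuous-time Markov chain (free <-> short-bound,
    free <-> long-bound).  Between consecutive frames, the displacement
    variance integrates 2*D*dt over the state segments spanning the
    interval.  Detections occur at every exposure while the molecule is
    alive; each recorded detection is followed by a Bernoulli loss with
    ``per_frame_loss_prob`` that permanently removes the molecule.
    """
    if duration is None:
        duration = scheme.duration
    if duration < 2 * scheme.cycle_duration:
        raise ValueError("duration must cover at least two scheme cycles")
    scheme = scheme.tile(duration)
    frame_times = scheme.frame_times()
    frame_times = frame_times[frame_times <= duration]

    max_rate = max(truth.k_on_u + truth.k_on_s, truth.k_off_u, truth.k_off_s)
    min_exposure = min(ev.exposure for ev in scheme.cycle if ev.exposure > 0)
    if max_rate * min_exposure > 1.0:
        warnings.warn(
            "kinetic rates imply >1 expected transition per exposure; "
            "state labels at frame times are poorly defined",
            RuntimeWarning,
        )

    rng = np.random.default_rng(seed)
    d_slow = truth.slow_diffusion
    comp_fracs = np.array([f for f, _ in truth.diffusion_components])
    comp_ds = np.array([d for _, d in truth.diffusion_components])

    spectrum = truth.dissociation_spectrum
    if spectrum is not None:
        spec_rates = np.array([r for r, _ in spectrum], dtype=float)
        spec_w = np.array([w for _, w in spectrum], dtype=float)
        spec_w = spec_w / spec_w.sum()

    rows = []
    bleach_frames: dict[int, int] = {}
    for mol in range(n_molecules):
        d_free = float(comp_ds[rng.choice(len(comp_ds), p=comp_fracs)])
        if truth.radial_bias is not None:
            placed = radial_place(truth, 1, seed=int(rng.integers(2**31)))
            pos = np.array(placed[0][:2])
        else:
            c = math.sqrt(rng.random()) * truth.nucleus_radius
            theta = rng.random() * 2 * math.pi
            pos = np.array([c * math.cos(theta), c * math.sin(theta)])

        # --- build the CTMC state path over [0, duration]
        state = _draw_state(truth, rng)
        k_off_current = None
        if state != FREE and spectrum is not None:
            k = float(rng.choice(spec_rates, p=spec_w))
            k_off_current = k
            state = BOUND_LONG if k < 0.1 else BOUND_SHORT
        segments = []  # (t_start, t_end, state)
        t = 0.0
        while t < duration:
            if state == FREE:
                rate = truth.k_on_u + truth.k_on_s
            elif spectrum is not None:
                rate = k_off_current
            else:
                rate = truth.k_off_u if state == BOUND_SHORT else truth.k_off_s
            dwell = rng.exponential(1.0 / rate)
            segments.append((t, min(t + dwell, duration), state))
            t += dwell
            if state == FREE:
                if spectrum is not None:
                    k_off_current = float(rng.choice(spec_rates, p=spec_w))
                    state = BOUND_LONG if k_off_current < 0.1 else BOUND_SHORT
                else:
                    p_s = truth.k_on_s / (truth.k_on_u + truth.k_on_s)
                    state = BOUND_LONG if rng.random() < p_s else BOUND_SHORT
            else:
                state = FREE

        seg_starts = np.array([s[0] for s in segments])
        seg_ends = np.array([s[1] for s in segments])
        seg_d = np.array([d_free if s[2] == FREE else d_slow for s in segments])

        def variance_between(t0: float, t1: float) -> float:
            """Per-axis displacement variance accumulated over [t0, t1]."""
            overlap = np.clip(np.minimum(seg_ends, t1) - np.maximum(seg_starts, t0), 0, None)
            return float(2.0 * np.sum(seg_d * overlap))

        def state_at(tq: float) -> str:
            i = int(np.searchsorted(seg_ends, tq, side="right"))
            i = min(i, len(segments) - 1)
            return segments[i][2]

        alive = True
        prev_t = 0.0
        for frame, tf in enumerate(frame_times):
            if not alive:
                break
            var = variance_between(prev_t, tf)
            if var > 0:
                pos = pos + rng.normal(0.0, math.sqrt(var), size=2)
                pos = _reflect_disk(pos, truth.nucleus_radius)
            prev_t = tf
            obs = pos + rng.normal(0.0, truth.loc_error_sigma, size=2)
            rows.append((mol, frame, tf, obs[0], obs[1], state_at(tf)))
            if rng.random() < truth.per_frame_loss_prob:
                alive = False
                bleach_frames[mol] = frame

    df = pd.DataFrame(rows, columns=["molecule", "frame", "t_s", "x_um", "y_um", "state"])
    return SimulatedMovie(df, scheme, truth, seed, bleach_frames)


def radial_place(
    truth: GroundTruth, n: int, seed: int = 0, grid_size: int = 2048
) -> np.ndarray:
    """Place `n` binding events with radial density proportional to the bias.

    The probability density over the center-border distance c is
    bias(c) * c (the ring-area measure in a disk), sampled by numerical
    inverse-CDF on a fine grid.  Returns an (n, 3) array of (x, y, CBD).
    """
    rng = np.random.default_rng(seed)
    bias = truth.radial_bias if truth.radial_bias is not None else (lambda c: np.ones_like(c))
    c_grid = np.linspace(0.0, 1.0, grid_size)
    density = np.asarray(bias(c_grid), dtype=float) * c_grid
    if np.any(density < 0) or not np.all(np.isfinite(density)):
        raise ValueError("radial bias must be nonnegative and finite on [0, 1]")
    cdf = np.cumsum((density[1:] + density[:-1]) / 2 * np.diff(c_grid))
    if cdf[-1] <= 0:
        raise ValueError("radial bias integrates to zero")
    cdf = np.concatenate(([0.0], cdf / cdf[-1]))
    c = np.interp(rng.random(n), cdf, c_grid)
    theta = rng.random(n) * 2 * math.pi
    r = c * truth.nucleus_radius
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), c])


def simulate_binding_tracks(
    scheme: IlluminationScheme,
    n_events: int,
    class_probs: dict[str, float],
    seed: int = 0,
    dwell_means: dict[str, float] | None = None,
    bound_diffusion: float = 0.005,
    loc_error_sigma: float = 0.03,
    nucleus_radius: float = 5.0,
    max_start_frame: int | None = None,
) -> tuple[list, list[str]]:
    """One track per binding event, for classifier parameter-recovery tests.

    Each event draws a class from ``class_probs`` (keys ``long``, ``short``,
    ``spot``), binds at a uniformly chosen scheme frame, and is detected at
    every frame until its dwell time ends (``spot`` events are single
    detections by construction).  ``dwell_means`` overrides the per-class
    mean dwell (s); ``long`` defaults to infinity, ``short`` to 0.3 s.
    Bound motion is Brownian with ``bound_diffusion`` plus localization
    noise; set both to zero for noise-free tracks.  ``max_start_frame``
    restricts binding starts (e.g. so that long events always have enough
    movie left to demonstrate two long dark times).  Returns (tracks,
    true class labels).
    """
    from .schemes import Localization, Track

    rng = np.random.default_rng(seed)
    labels_pool = list(class_probs)
    probs = np.array([class_probs[k] for k in labels_pool], dtype=float)
    probs = probs / probs.sum()
    dwell_means = dict(dwell_means or {})
    dwell_means.setdefault("long", math.inf)
    dwell_means.setdefault("short", 0.3)
    frame_times = scheme.frame_times()
    tracks: list[Track] = []
    labels: list[str] = []
    for i in range(n_events):
        label = labels_pool[rng.choice(len(labels_pool), p=probs)]
        start_hi = scheme.n_frames - 1 if max_start_frame is None else max_start_frame + 1
        start = int(rng.integers(0, max(1, start_hi)))
        if label == "spot":
            end_t = frame_times[start]
        else:
            mean = dwell_means[label]
            dwell = math.inf if math.isinf(mean) else rng.exponential(mean)
            end_t = frame_times[start] + dwell
        c = math.sqrt(rng.random()) * nucleus_radius
        theta = rng.random() * 2 * math.pi
        pos = np.array([c * math.cos(theta), c * math.sin(theta)])
        locs = []
        prev_t = frame_times[start]
        for frame in range(start, scheme.n_frames):
            tf = frame_times[frame]
            if tf > end_t:
                break
            if bound_diffusion > 0 and tf > prev_t:
                pos = pos + rng.normal(0.0, math.sqrt(2 * bound_diffusion * (tf - prev_t)), 2)
            prev_t = tf
            obs = pos + rng.normal(0.0, loc_error_sigma, 2) if loc_error_sigma > 0 else pos
            locs.append(Localization(frame, float(tf), float(obs[0]), float(obs[1])))
        tracks.append(Track(id=i, localizations=locs))
        labels.append(label)
    return tracks, labels


def sample_jumps(
    components: Sequence[tuple[float, float]],
    dt: float,
    n: int,
    seed: int = 0,
    loc_error_sigma: float = 0.0,
) -> np.ndarray:
    """Draw `n` 2D jump distances from a Brownian mixture.

    Each jump picks a component by its fraction; the per-axis variance is
    2*D*dt plus 2*sigma² for the two localization errors, so the jump
    distance is Rayleigh with scale sqrt(2*D*dt + 2*sigma²).
    """
    rng = np.random.default_rng(seed)
    fracs = np.array([f for f, _ in components], dtype=float)
    ds = np.array([d for _, d in components], dtype=float)
    if not math.isclose(fracs.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("component fractions must sum to 1")
    comp = rng.choice(len(ds), size=n, p=fracs)
    scale = np.sqrt(2 * ds[comp] * dt + 2 * loc_error_sigma**2)
    return rng.rayleigh(scale)


def brownian_mixture_cdf(
    r: np.ndarray, components: Sequence[tuple[float, float]], dt: float
) -> np.ndarray:
    """Closed-form CDF of jump distances for a Brownian mixture."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for frac, d in components:
        out = out + frac * (1.0 - np.exp(-(r**2) / (4.0 * d * dt)))
    return out


def sample_dwell_times(
    spectrum: Sequence[tuple[float, float]], n: int, seed: int = 0
) -> np.ndarray:
    """Draw `n` binding-event dwell times from an exponential mixture.

    `spectrum` lists (dissociation rate [1/s], event weight).
    """
    rng = np.random.default_rng(seed)
    rates = np.array([r for r, _ in spectrum], dtype=float)
    weights = np.array([w for _, w in spectrum], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(rates), size=n, p=weights)
    return rng.exponential(1.0 / rates[comp])
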