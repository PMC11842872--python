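"""Brownian-mixture fitting of cumulative jump-distance distributions.

The empirical cumulative distribution of single-molecule jump distances is
binned (1 nm bins, 747 bins by default) and fitted with a 2- or 3-component
Brownian mixture

    CDF(r) = sum_i A_i * (1 - exp(-r² / (4 D_i dt))),   sum_i A_i = 1.

The amplitude of the slowest component is the overall bound fraction f_b.
Model selection between the 2- and 3-component fits uses the AIC difference

    dAIC = (2 k_2 + n ln RSS_2) - (2 k_3 + n ln RSS_3)

with free-parameter counts k_2 = 3 and k_3 = 5 after the sum-to-one
constraint; a positive dAIC prefers the 3-component model.  Parameter
uncertainties come from refitting random resamples of the jump distances
(500 subsets of 80% by default).

No separate localization-error term appears in the CDF: localization noise
is absorbed into the slowest component's apparent coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "JumpDistribution",
    "DiffusionFitResult",
    "ModelComparison",
    "binned_cdf",
    "mixture_cdf",
    "fit_mixture",
    "compare_models",
    "resample_errors",
]

DEFAULT_BIN_WIDTH = 0.001  # µm (1 nm)
DEFAULT_N_BINS = 747

K_PARAMS = {2: 3, 3: 5}  # free parameters after the sum-to-one constraint


class FitError(RuntimeError):
    """Raised when the mixture fit cannot be performed."""


@dataclass(frozen=True)
class JumpDistribution:
    """Binned empirical cumulative jump-distance distribution."""

    bin_edges: np.ndarray  # right edges, µm
    cdf: np.ndarray  # fraction of jumps <= edge
    frame_interval: float  # s
    n_jumps: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges)


@dataclass
class DiffusionFitResult:
    n_components: int
    amplitudes: np.ndarray  # sorted by ascending D, sum to 1
    coefficients: np.ndarray  # µm²/s, ascending
    rss: float
    n_bins: int
    frame_interval: float
    n_jumps: int
    sd_amplitudes: np.ndarray | None = None
    sd_coefficients: np.ndarray | None = None

    @property
    def bound_fraction(self) -> float:
        """Amplitude of the slowest component (apparent bound fraction f_b)."""
        return float(self.amplitudes[0])


@dataclass(frozen=True)
class ModelComparison:
    k_2rate: int
    k_3rate: int
    n: int
    rss_2rate: float
    rss_3rate: float
    delta_aic: float

    @property
    def prefers_three_components(self) -> bool:
        return self.delta_aic > 0


def binned_cdf(
    jumps: np.ndarray,
    dt: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> JumpDistribution:
    """Bin jump distances into a cumulative distribution on fixed edges."""
    jumps = np.asarray(jumps, dtype=float)
    if jumps.size == 0:
        raise FitError("no jump distances supplied")
    edges = bin_width * np.arange(1, n_bins + 1)
    counts, _ = np.histogram(jumps, bins=np.concatenate(([0.0], edges)))
    cdf = np.cumsum(counts) / jumps.size
    return JumpDistribution(edges, cdf, dt, int(jumps.size))


def mixture_cdf(r: np.ndarray, amplitudes: np.ndarray, coefficients: np.ndarray, dt: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for a, d in zip(amplitudes, coefficients):
        out = out + a * (1.0 - np.exp(-(r**2) / (4.0 * d * dt)))
    return out


def _unpack(theta: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(theta[: m - 1])
    amplitudes = np.concatenate([a, [1.0 - a.sum()]])
    coefficients = 10.0 ** np.asarray(theta[m - 1 :])
    return amplitudes, coefficients


def _initializations(m: int) -> list[np.ndarray]:
    """Deterministic multistart points spanning the plausible D range."""
    inits = []
    if m == 2:
        d_sets = [(-2.0, 0.0), (-1.5, 0.5), (-2.5, -0.5), (-1.0, 0.0), (-2.0, 0.7)]
        a_sets = [[0.3], [0.1], [0.5], [0.2], [0.4]]
    else:
        d_sets = [
            (-2.0, -0.5, 0.4),
            (-2.5, -1.0, 0.0),
            (-1.5, -0.3, 0.7),
            (-2.0, 0.0, 0.7),
            (-3.0, -0.5, 0.5),
        ]
        a_sets = [[0.2, 0.3], [0.1, 0.4], [0.3, 0.3], [0.05, 0.35], [0.4, 0.3]]
    for a, d in zip(a_sets, d_sets):
        inits.append(np.array(a + list(d)))
    return inits


def _fit_binned(
    dist: JumpDistribution, n_components: int, x0_list: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, float]:
    m = n_components
    r = dist.bin_edges
    target = dist.cdf

    def residuals(theta: np.ndarray) -> np.ndarray:
        amplitudes, coefficients = _unpack(theta, m)
        res = mixture_cdf(r, amplitudes, coefficients, dist.frame_interval) - target
        tail = amplitudes[-1]
        if tail < 0:  # soft barrier for the sum-to-one parameterization
            res = res + 10.0 * abs(tail)
        return res

    lb = np.concatenate([np.zeros(m - 1), np.full(m, -5.0)])
    ub = np.concatenate([np.ones(m - 1), np.full(m, 2.0)])
    best = None
    for x0 in x0_list:
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    theta, rss = best
    amplitudes, coefficients = _unpack(theta, m)
    amplitudes = np.clip(amplitudes, 0.0, 1.0)
    amplitudes = amplitudes / amplitudes.sum()
    order = np.argsort(coefficients)
    return amplitudes[order], coefficients[order], rss


def fit_mixture(
    jumps: np.ndarray,
    dt: float,
    n_components: int = 3,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> DiffusionFitResult:
    """Least-squares fit of the binned empirical CDF with a Brownian mixture.

    Runs five deterministic initializations and keeps the best RSS.  Raises
    :class:`FitError` for degenerate input (all jumps identical).
    """
    if n_components not in K_PARAMS:
        raise ValueError("n_components must be 2 or 3")
    if dt <= 0:
        raise ValueError("frame interval dt must be > 0")
    jumps = np.asarray(jumps, dtype=float)
    if jumps.size and np.ptp(jumps) == 0.0:
        raise FitError("degenerate jump data: all jump distances identical")
    dist = binned_cdf(jumps, dt, bin_width, n_bins)
    amplitudes, coefficients, rss = _fit_binned(dist, n_components, _initializations(n_components))
    return DiffusionFitResult(
        n_components=n_components,
        amplitudes=amplitudes,
        coefficients=coefficients,
        rss=rss,
        n_bins=dist.n_bins,
        frame_interval=dt,
        n_jumps=dist.n_jumps,
    )


def compare_models(
    fit2: DiffusionFitResult, fit3: DiffusionFitResult, n: int | None = None
) -> ModelComparison:
    """AIC difference between the 2- and 3-component fits on the same bins."""
    if fit2.n_components != 2 or fit3.n_components != 3:
        raise ValueError("compare_models expects a 2-component and a 3-component fit")
    if n is None:
        if fit2.n_bins != fit3.n_bins:
            raise ValueError("fits were computed on different binnings")
        n = fit2.n_bins
    if fit2.rss <= 0 or fit3.rss <= 0:
        raise ValueError("RSS must be > 0 to compare models")
    k2, k3 = K_PARAMS[2], K_PARAMS[3]
    delta = (2 * k2 + n * np.log(fit2.rss)) - (2 * k3 + n * np.log(fit3.rss))
    return ModelComparison(k2, k3, n, fit2.rss, fit3.rss, float(delta))


def resample_errors(
    jumps: np.ndarray,
    dt: float,
    n_components: int = 3,
    n_resamples: int = 500,
    frac: float = 0.8,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter s.d. from refits on random subsets of the jumps.

    Returns (sd of amplitudes, sd of coefficients), each ordered by
    ascending D.  Each resample is refit from the full-data solution, which
    is adequate because subsets of the same data land in the same basin.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    jumps = np.asarray(jumps, dtype=float)
    rng = np.random.default_rng(seed)
    full = fit_mixture(jumps, dt, n_components, bin_width, n_bins)
    x0 = np.concatenate([full.amplitudes[:-1], np.log10(full.coefficients)])
    size = max(2, int(round(frac * jumps.size)))
    size = min(size, jumps.size)
    amps, ds = [], []
    for _ in range(n_resamples):
        sub = jumps[rng.choice(jumps.size, size=size, replace=False)]
        dist = binned_cdf(sub, dt, bin_width, n_bins)
        a, d, _rss = _fit_binned(dist, n_components, [x0])
        amps.append(a)
        ds.append(d)
    return np.std(np.array(amps), axis=0), np.std(np.array(ds), axis=0)
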