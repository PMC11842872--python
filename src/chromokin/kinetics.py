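"""Equilibrium two-class binding model: on-rates, search times, bound fractions.

A DNA-binding protein partitions between a free state (fraction p_f) and
two bound states, unspecific (p_b,u, dissociation rate k_off,u) and
specific (p_b,s, rate k_off,s).  At equilibrium the law of mass action
relates the pseudo-first-order association rate of either class to
measured fractions:

    k*_on,i = k_off,i * p_b,i / p_f                       (i = u, s)

Site concentrations and dissociation constants are never materialized: the
detailed-balance relation above eliminates them in favor of the measured
fractions, and k*_on,i absorbs the accessible-site concentration.

The facilitated-diffusion target-search time counts unspecific detours:

    N_trials = 1 / A^e_s
    tau_search = N_trials / k*_on,u + (N_trials - 1) / k_off,u

where A^e_s is the specific (long-binding) fraction of the event spectrum.
When the search mechanism is unknown (cohesin), the direct route inverts
the specific pseudo-on-rate: tau_search = 1 / k*_on,s = p_f / (k_off,s p_b,s).

The effective search time of *any* molecule scales the single-molecule
search time by nuclear volume over molecule count, tau_eff = tau V / N,
reported relative to a reference stage; V and N enter only as relative
quantities.  The predicted overall long-bound fraction from rates is

    p_b,s = (k*_s/k_s) / (k*_s/k_s + k*_u/k_u + 1)

which coincides with p_b,s = f_b * A^s_s when the rates derive from the
same fractions.  Uncertainties propagate to first order (delta method)
with numerical partial derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "KineticSummary",
    "NuclearContext",
    "pseudo_on_rate",
    "search_time_facilitated",
    "search_time_direct",
    "effective_search_time",
    "nuclear_volume_from_cross_section",
    "predict_bound_fraction",
    "bound_fraction_from_fractions",
    "fractions_from_rates",
    "propagate_gaussian",
]


@dataclass
class KineticSummary:
    """Per-stage fractions and rates feeding the search-time calculations.

    p_f + p_b_u + p_b_s must sum to 1 (within tolerance); event_fraction_s
    is A^e_s, the long-binding share of the event spectrum.
    """

    p_f: float
    p_b_u: float
    p_b_s: float
    k_off_u: float
    k_off_s: float
    event_fraction_s: float
    label: str = ""

    def __post_init__(self) -> None:
        total = self.p_f + self.p_b_u + self.p_b_s
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"fractions must sum to 1, got {total}")
        if self.k_off_u <= 0 or self.k_off_s <= 0:
            raise ValueError("dissociation rates must be > 0")

    @property
    def k_on_u_star(self) -> float:
        return pseudo_on_rate(self.k_off_u, self.p_b_u, self.p_f)

    @property
    def k_on_s_star(self) -> float:
        return pseudo_on_rate(self.k_off_s, self.p_b_s, self.p_f)

    @property
    def n_trials(self) -> float:
        if self.event_fraction_s <= 0:
            raise ValueError("event fraction of specific binding must be > 0")
        return 1.0 / self.event_fraction_s


@dataclass(frozen=True)
class NuclearContext:
    """Relative nuclear volume and molecule count of one stage."""

    v_nuc: float  # µm³ (or any consistent relative unit)
    n_mol: float  # relative molecule count

    def __post_init__(self) -> None:
        if self.v_nuc <= 0 or self.n_mol <= 0:
            raise ValueError("nuclear volume and molecule count must be > 0")


def pseudo_on_rate(k_off: float, p_b: float, p_f: float) -> float:
    """k*_on = k_off * p_b / p_f (detailed balance on measured fractions)."""
    if p_f <= 0:
        raise ZeroDivisionError("free fraction must be > 0")
    return k_off * p_b / p_f


def search_time_facilitated(summary: KineticSummary) -> float:
    """Facilitated-diffusion search time with unspecific detours (s)."""
    if not 0 < summary.event_fraction_s <= 1:
        if summary.event_fraction_s == 0:
            return math.inf
        raise ValueError("event_fraction_s must lie in (0, 1]")
    n = summary.n_trials
    return n / summary.k_on_u_star + (n - 1.0) / summary.k_off_u


def search_time_direct(k_off_s: float, p_b_s: float, p_f: float) -> float:
    """Direct search time 1 / k*_on,s = p_f / (k_off,s * p_b,s) (s)."""
    if p_b_s <= 0:
        return math.inf
    return p_f / (k_off_s * p_b_s)


def effective_search_time(
    tau_search: float,
    ctx: NuclearContext,
    reference_tau: float | None = None,
    reference: NuclearContext | None = None,
) -> float:
    """tau_eff = tau_search * V_nuc / N_mol, optionally relative to a reference.

    With `reference_tau` and `reference` given, returns the ratio of the
    stage's effective search time to the reference stage's (dimensionless);
    otherwise returns the absolute (relative-unit) effective search time.
    """
    tau_eff = tau_search * ctx.v_nuc / ctx.n_mol
    if reference is None and reference_tau is None:
        return tau_eff
    if reference is None or reference_tau is None:
        raise ValueError("both reference_tau and reference are needed for a ratio")
    ref_eff = reference_tau * reference.v_nuc / reference.n_mol
    return tau_eff / ref_eff


def nuclear_volume_from_cross_section(area: float) -> float:
    """Sphere volume from a nuclear cross-section area (µm² -> µm³)."""
    if area <= 0:
        raise ValueError("cross-section area must be > 0")
    r = math.sqrt(area / math.pi)
    return 4.0 / 3.0 * math.pi * r**3


def predict_bound_fraction(
    k_on_s_star: float, k_off_s: float, k_on_u_star: float, k_off_u: float
) -> float:
    """Overall long-bound fraction predicted from kinetic rates.

    p_b,s = (k*_s/k_s) / (k*_s/k_s + k*_u/k_u + 1).  Unspecific rates of
    zero reduce to the one-class Langmuir isotherm.
    """
    if min(k_off_s, k_off_u) <= 0 or min(k_on_s_star, k_on_u_star) < 0:
        raise ValueError("rates must be positive (on-rates may be zero)")
    rs = k_on_s_star / k_off_s
    ru = k_on_u_star / k_off_u
    return rs / (rs + ru + 1.0)


def bound_fraction_from_fractions(f_b: float, state_fraction_s: float) -> float:
    """p_b,s = f_b * A^s_s (measured-fraction route)."""
    return f_b * state_fraction_s


def fractions_from_rates(
    k_on_s_star: float, k_off_s: float, k_on_u_star: float, k_off_u: float
) -> tuple[float, float, float]:
    """(p_f, p_b_u, p_b_s) of the equilibrium three-state partition."""
    rs = k_on_s_star / k_off_s
    ru = k_on_u_star / k_off_u
    z = 1.0 + ru + rs
    return 1.0 / z, ru / z, rs / z


def propagate_gaussian(
    func: Callable[..., float],
    values: Sequence[float],
    sds: Sequence[float],
    rel_step: float = 1e-6,
) -> tuple[float, float]:
    """First-order (delta-method) Gaussian error propagation.

    Partial derivatives are taken numerically by central differences with a
    relative step; inputs are treated as independent.  Returns
    (func(values), propagated s.d.).
    """
    values = np.asarray(values, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if values.shape != sds.shape:
        raise ValueError("values and sds must have the same length")
    center = float(func(*values))
    var = 0.0
    for i, (v, s) in enumerate(zip(values, sds)):
        if s == 0:
            continue
        h = rel_step * max(abs(v), 1.0)
        hi = values.copy()
        lo = values.copy()
        hi[i] += h
        lo[i] -= h
        grad = (func(*hi) - func(*lo)) / (2.0 * h)
        var += (grad * s) ** 2
    return center, math.sqrt(var)
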