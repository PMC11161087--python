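"""Schnakenberg kinetics and Turing linear stability analysis.

The two-species reaction terms are

    f(u, v) = a - u + u^2 v        (activator)
    g(u, v) = b - u^2 v            (inhibitor)

a classic activator-inhibitor system that, with a sufficiently large
diffusion ratio D_v/D_u, undergoes a diffusion-driven (Turing) instability
of its homogeneous steady state and forms stationary spot patterns.  This
module evaluates the kinetics, the homogeneous steady state and its
Jacobian, and the dispersion relation of the linearized system, from which
the instability conditions, the fastest-growing wavenumber and the critical
diffusion ratio follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "KineticParameters",
    "DispersionResult",
    "evaluate_kinetics",
    "homogeneous_steady_state",
    "jacobian_at_steady_state",
    "growth_rate",
    "critical_diffusion_ratio",
    "dispersion_relation",
]


@dataclass(frozen=True)
class KineticParameters:
    """Schnakenberg constants and the two diffusion coefficients.

    Parameters
    ----------
    a : float
        Basal activator production rate (dimensionless). Default 0.3.
    b : float
        Inhibitor-side production rate (dimensionless). Default 0.8.
    D_u : float
        Activator diffusion coefficient (length^2/time). Default 1.0.
    D_v : float
        Inhibitor diffusion coefficient (length^2/time). Default 40.0,
        comfortably above the critical ratio (~28.5 x D_u for the default
        kinetics) so the system sits in the spot-forming Turing regime.
    """

    a: float = 0.3
    b: float = 0.8
    D_u: float = 1.0
    D_v: float = 40.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if self.D_u <= 0 or self.D_v <= 0:
            raise ValueError(
                f"diffusion coefficients must be > 0, got D_u={self.D_u}, D_v={self.D_v}"
            )
        if self.a + self.b <= 0:
            raise ValueError("a + b must be > 0 for the steady state to exist")


@dataclass
class DispersionResult:
    """Dispersion relation of the linearized reaction-diffusion system.

    ``growth_rates[j]`` is the largest real part of the eigenvalues of
    ``J - k^2 diag(D_u, D_v)`` at ``k = wavenumbers[j]``.
    """

    wavenumbers: np.ndarray
    growth_rates: np.ndarray
    k_crit: float
    is_turing_unstable: bool
    d_crit: float
    k_crit_mode: float | None = None  # nearest admissible mode of the domain
    warning: str | None = None
    admissible_wavenumbers: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    def __post_init__(self) -> None:
        if len(self.wavenumbers) != len(self.growth_rates):
            raise ValueError("wavenumbers and growth_rates must have equal length")


def evaluate_kinetics(p: KineticParameters, u, v):
    """Evaluate (f, g) = (a - u + u^2 v, b - u^2 v) elementwise.

    Raises
    ------
    ValueError
        If any concentration is negative.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0):
        raise ValueError(f"negative activator concentration: min u = {u.min()}")
    if np.any(v < 0):
        raise ValueError(f"negative inhibitor concentration: min v = {v.min()}")
    uuv = u * u * v
    f = p.a - u + uuv
    g = p.b - uuv
    if f.ndim == 0:
        return float(f), float(g)
    return f, g


def homogeneous_steady_state(p: KineticParameters) -> tuple[float, float]:
    """Unique positive homogeneous steady state (u*, v*) = (a+b, b/(a+b)^2)."""
    s = p.a + p.b
    if s == 0:
        raise ValueError("a + b = 0: steady state undefined")
    return s, p.b / (s * s)


def jacobian_at_steady_state(p: KineticParameters) -> np.ndarray:
    """Jacobian [[f_u, f_v], [g_u, g_v]] of the kinetics at (u*, v*)."""
    u, v = homogeneous_steady_state(p)
    return np.array(
        [
            [-1.0 + 2.0 * u * v, u * u],
            [-2.0 * u * v, -u * u],
        ]
    )


def growth_rate(p: KineticParameters, k) -> np.ndarray | float:
    """Re(lambda_max) of J - k^2 diag(D_u, D_v), from the 2x2 closed form."""
    k = np.asarray(k, dtype=float)
    ksq = k * k
    J = jacobian_at_steady_state(p)
    fu, fv = J[0]
    gu, gv = J[1]
    tr = (fu - ksq * p.D_u) + (gv - ksq * p.D_v)
    det = (fu - ksq * p.D_u) * (gv - ksq * p.D_v) - fv * gu
    disc = tr * tr - 4.0 * det
    re = np.where(disc >= 0, 0.5 * (tr + np.sqrt(np.maximum(disc, 0.0))), 0.5 * tr)
    if re.ndim == 0:
        return float(re)
    return re


def critical_diffusion_ratio(p: KineticParameters) -> float:
    """Ratio d = D_v/D_u at marginal Turing instability.

    Solves the marginal condition ``d f_u + g_v = 2 sqrt(d det J)`` for the
    ratio; equivalently the larger root of
    ``f_u^2 d^2 + (2 f_u g_v - 4 det J) d + g_v^2 = 0``.
    Returns ``inf`` when no finite ratio destabilizes the state
    (no activator self-enhancement, f_u <= 0).
    """
    J = jacobian_at_steady_state(p)
    fu, gv = J[0, 0], J[1, 1]
    detJ = float(np.linalg.det(J))
    if fu <= 0 or detJ <= 0:
        return math.inf
    A = fu * fu
    B = 2.0 * fu * gv - 4.0 * detJ
    C = gv * gv
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return math.inf
    d = (-B + math.sqrt(disc)) / (2.0 * A)
    # the marginal state needs d*f_u + g_v > 0; the larger root satisfies it
    if d * fu + gv <= 0:
        return math.inf
    return d


def admissible_wavenumbers(
    width_x: float, width_y: float, k_max: float
) -> np.ndarray:
    """Wavenumber magnitudes of the rectangle's linear eigenmodes up to k_max.

    Zero-flux in x admits cosine modes k_x = pi n / width_x; periodicity in y
    admits k_y = 2 pi m / width_y.  Returns sorted unique k = |(k_x, k_y)| > 0.
    """
    n_max = int(np.ceil(k_max * width_x / np.pi))
    m_max = int(np.ceil(k_max * width_y / (2 * np.pi)))
    kx = np.pi * np.arange(n_max + 1) / width_x
    ky = 2 * np.pi * np.arange(m_max + 1) / width_y
    kk = np.hypot(kx[:, None], ky[None, :]).ravel()
    kk = np.unique(kk[(kk > 0) & (kk <= k_max)])
    return kk


def dispersion_relation(
    p: KineticParameters,
    k_max: float = 2.0,
    n_samples: int = 256,
    domain: tuple[float, float] | None = None,
) -> DispersionResult:
    """Sample the dispersion relation and locate the fastest-growing mode.

    Parameters
    ----------
    p : KineticParameters
    k_max : float
        Upper end of the sampled wavenumber range (must be > 0).
    n_samples : int
        Number of uniformly spaced samples in [0, k_max] (>= 2).
    domain : (width_x, width_y), optional
        When given, the discrete admissible modes of the rectangle (cosine
        in x, periodic in y) are added to the sample set and the admissible
        mode nearest to the continuous ``k_crit`` is reported.
    """
    if k_max <= 0:
        raise ValueError("k_max must be > 0")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")

    ks = np.linspace(0.0, k_max, n_samples)
    adm = np.empty(0)
    if domain is not None:
        adm = admissible_wavenumbers(domain[0], domain[1], k_max)
        ks = np.unique(np.concatenate([ks, adm]))
    rates = np.asarray(growth_rate(p, ks))

    warning = None
    rate_at_zero = growth_rate(p, 0.0)
    stable_without_diffusion = rate_at_zero < 0
    if not stable_without_diffusion:
        warning = "unstable_without_diffusion"

    # refine the continuous maximizer around the best sample
    j = int(np.argmax(rates))
    lo = ks[max(j - 1, 0)]
    hi = ks[min(j + 1, len(ks) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda k: -growth_rate(p, k), bounds=(lo, hi), method="bounded"
        )
        k_crit = float(res.x) if -res.fun >= rates[j] else float(ks[j])
    else:
        k_crit = float(ks[j])

    positive_growth = bool(np.max(rates[ks > 0], initial=-np.inf) > 0)
    is_unstable = bool(stable_without_diffusion and positive_growth)

    k_mode = None
    if adm.size:
        k_mode = float(adm[np.argmin(np.abs(adm - k_crit))])

    return DispersionResult(
        wavenumbers=ks,
        growth_rates=rates,
        k_crit=k_crit,
        is_turing_unstable=is_unstable,
        d_crit=critical_diffusion_ratio(p),
        k_crit_mode=k_mode,
        warning=warning,
        admissible_wavenumbers=adm,
    )
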