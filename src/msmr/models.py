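"""Closed-form mSMR model functions.

The mean single-molecule rate (mSMR) relates Mandel's Q parameter of a
binned photon trace to the sampling time T:

    mu(T) = Q(T) / T = gamma2 * mu0 * Gamma_diff(T) * Gamma_iso(T)

where ``mu0`` is the detected count rate of a single molecule at the
maximum of the detection volume, ``gamma2 = 1/(2*sqrt(2))`` is the shape
factor of a 3D Gaussian point spread function (PSF), and the
dimensionless binning functions ``Gamma`` describe how a correlation
kernel g(tau) integrates over a finite sampling time:

    Gamma(T) = (2 / T^2) * Integral_0^T (T - tau) g(tau) dtau

For free 3D diffusion through a Gaussian detection volume with lateral
1/e^2 radius r0 and axial radius z0 (aspect ratio r = z0/r0 >= 1) the
kernel is

    g_3DG(tau) = [ (1 + tau/tauD) * sqrt(1 + tau/(r^2 tauD)) ]^-1

and Gamma_diff has the closed form implemented in
:func:`binning_diffusion`.  Reversible dark-state (on/off isomerization
or triplet-like) blinking with dark fraction F and relaxation time tauF
contributes a second multiplicative kernel, g_iso(t) = 1 +
F/(1-F)*exp(-t/tauF), whose binning function is
:func:`binning_isomerization`.

Adaptive-quadrature counterparts (``*_numeric``) of the closed forms are
provided as independent numerical oracles; they integrate the kernels
directly and share no code path with the closed forms.

Units: times in seconds, rates in counts/second, lengths in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .errors import ConfigError

__all__ = [
    "GAMMA2_3DG",
    "PSFGeometry",
    "ModelParams",
    "gamma_factor",
    "gamma_factor_numeric",
    "g_diffusion_3dg",
    "g_isomerization",
    "binning_diffusion",
    "binning_diffusion_numeric",
    "binning_isomerization",
    "binning_isomerization_numeric",
    "msmr_model",
    "q_model",
]

#: Shape factor gamma_2 of a 3D Gaussian PSF, 1/(2*sqrt(2)).
GAMMA2_3DG = 1.0 / (2.0 * math.sqrt(2.0))

#: |beta - 1| below which the r = 1 branch of the diffusion binning
#: function is used (the artanh branch suffers 0/0 cancellation there).
BETA_BRANCH_TOL = 1e-6

#: alpha = T/tauD below which the series expansion of Gamma_diff is used.
ALPHA_SERIES_TOL = 5e-3

#: T/tauF below which the series expansion of Gamma_iso is used.
ISO_SERIES_TOL = 1e-4


@dataclass(frozen=True)
class PSFGeometry:
    """3D Gaussian detection-volume geometry.

    Parameters
    ----------
    r0 : float
        Lateral 1/e^2 radius, micrometres.
    z0 : float
        Axial 1/e^2 radius, micrometres.  Must satisfy z0 >= r0 so that
        the aspect ratio r = z0/r0 is >= 1 (prolate or spherical volume).
    """

    r0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.z0 > 0):
            raise ConfigError(f"PSF radii must be positive, got r0={self.r0}, z0={self.z0}")
        if self.z0 < self.r0:
            raise ConfigError(
                f"axial radius z0={self.z0} smaller than lateral r0={self.r0} "
                "(aspect ratio r = z0/r0 < 1 is not supported)"
            )

    @property
    def aspect_ratio(self) -> float:
        """r = z0 / r0, dimensionless, >= 1."""
        return self.z0 / self.r0

    @property
    def beta(self) -> float:
        """beta = r0^2 / z0^2 = r^-2, in (0, 1]."""
        return (self.r0 / self.z0) ** 2


@dataclass(frozen=True)
class ModelParams:
    """Physical parameter vector of the full mSMR model.

    Parameters
    ----------
    mu0 : float
        Single-molecule brightness rate at the PSF maximum, counts/s.
    tau_d : float
        Mean diffusion time through the lateral detection area, seconds.
    r : float
        Axial/lateral PSF aspect ratio z0/r0, dimensionless, >= 1.
    F : float
        Dark-state fraction, in [0, 1).  F = 0 disables the
        isomerization term.
    tau_f : float
        Isomerization relaxation time 1/(k_on + k_off), seconds.
    gamma2 : float
        PSF shape factor; 1/(2*sqrt(2)) for a 3D Gaussian.
    """

    mu0: float
    tau_d: float
    r: float = 1.0
    F: float = 0.0
    tau_f: float = 1e-5
    gamma2: float = GAMMA2_3DG

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ConfigError(f"mu0 must be > 0, got {self.mu0}")
        if not self.tau_d > 0:
            raise ConfigError(f"tau_d must be > 0, got {self.tau_d}")
        if not self.r >= 1:
            raise ConfigError(f"aspect ratio r must be >= 1, got {self.r}")
        if not (0 <= self.F < 1):
            raise ConfigError(f"dark fraction F must be in [0, 1), got {self.F}")
        if not self.tau_f > 0:
            raise ConfigError(f"tau_f must be > 0, got {self.tau_f}")
        if not (0 < self.gamma2 <= 1):
            raise ConfigError(f"gamma2 must be in (0, 1], got {self.gamma2}")


# ---------------------------------------------------------------------------
# PSF shape factors
# ---------------------------------------------------------------------------

def gamma_factor(order: int, geometry: PSFGeometry | None = None) -> float:
    """Shape factor gamma_r of the 3D Gaussian PSF.

    gamma_r = Integral(PSF^r) / Integral(PSF) = r^(-3/2) for a Gaussian,
    independent of the geometry; in particular gamma_1 = 1 and
    gamma_2 = 1/(2*sqrt(2)).

    Parameters
    ----------
    order : int
        Cumulant order r >= 1.
    geometry : PSFGeometry, optional
        Accepted for interface symmetry with :func:`gamma_factor_numeric`;
        the Gaussian closed form does not depend on it.
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ConfigError(f"gamma_factor order must be an integer >= 1, got {order!r}")
    return float(order) ** -1.5


def gamma_factor_numeric(order: int, geometry: PSFGeometry, half_width: float = 8.0) -> float:
    """Quadrature oracle for gamma_r: direct 3D integration of the PSF.

    Integrates PSF^order and PSF over a wide box (``half_width`` times
    the respective 1/e^2 radius in each direction) using separable 1D
    adaptive quadrature, and returns the ratio.
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ConfigError(f"gamma_factor order must be an integer >= 1, got {order!r}")

    def axis_integral(radius: float, power: int) -> float:
        val, _ = quad(lambda x: math.exp(-2.0 * power * x * x / radius**2),
                      -half_width * radius, half_width * radius, epsabs=0, epsrel=1e-12)
        return val

    num = axis_integral(geometry.r0, order) ** 2 * axis_integral(geometry.z0, order)
    den = axis_integral(geometry.r0, 1) ** 2 * axis_integral(geometry.z0, 1)
    return num / den


# ---------------------------------------------------------------------------
# Correlation kernels
# ---------------------------------------------------------------------------

def g_diffusion_3dg(tau, tau_d: float, r: float):
    """Diffusion correlation kernel for a 3D Gaussian PSF.

    g(tau) = [(1 + tau/tauD) * sqrt(1 + tau/(r^2 tauD))]^-1; equals 1 at
    tau = 0 and decreases strictly towards 0.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ConfigError("tau must be >= 0")
    if not tau_d > 0:
        raise ConfigError(f"tau_d must be > 0, got {tau_d}")
    if not r >= 1:
        raise ConfigError(f"aspect ratio r must be >= 1, got {r}")
    s = tau / tau_d
    out = 1.0 / ((1.0 + s) * np.sqrt(1.0 + s / (r * r)))
    return out if out.ndim else float(out)


def g_isomerization(t, F: float, tau_f: float):
    """On/off blinking kernel: g(t) = 1 + F/(1-F) * exp(-t/tauF)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("t must be >= 0")
    if not (0 <= F < 1):
        raise ConfigError(f"dark fraction F must be in [0, 1), got {F}")
    if not tau_f > 0:
        raise ConfigError(f"tau_f must be > 0, got {tau_f}")
    out = 1.0 + F / (1.0 - F) * np.exp(-t / tau_f)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Binning functions (closed forms)
# ---------------------------------------------------------------------------

def _gamma_diff_series(alpha: np.ndarray, beta: float) -> np.ndarray:
    # Gamma = 1 + sum_m 2 c_m alpha^m / ((m+1)(m+2)) with
    # c_m = (-1)^m * sum_{j<=m} C(2j,j) (beta/4)^j  (Taylor of the kernel).
    partial = 0.0
    out = np.ones_like(alpha)
    a_pow = np.ones_like(alpha)
    for m in range(0, 5):
        partial += math.comb(2 * m, m) * (beta / 4.0) ** m
        if m == 0:
            continue
        a_pow = a_pow * alpha
        out = out + (2.0 * (-1) ** m * partial / ((m + 1) * (m + 2))) * a_pow
    return out


def _gamma_diff_r1(alpha: np.ndarray) -> np.ndarray:
    return 8.0 / alpha**2 * (alpha / 2.0 - np.sqrt(1.0 + alpha) + 1.0)


def _gamma_diff_artanh(alpha: np.ndarray, beta: float) -> np.ndarray:
    s = math.sqrt(1.0 - beta)
    w = np.sqrt(1.0 + alpha * beta)
    arg = s * (w - 1.0) / (beta + w - 1.0)
    if np.any(arg <= -1.0) or np.any(arg >= 1.0):
        raise ConfigError("artanh argument outside (-1, 1); invalid alpha/beta combination")
    return 4.0 / (alpha**2 * beta) * (beta * (1.0 + alpha) / s * np.arctanh(arg) - w + 1.0)


def binning_diffusion(T, tau_d: float, r: float):
    """Diffusion binning function Gamma_diff,3DG(T).

    Closed form of (2/T^2) * Integral_0^T (T - tau) g_3DG(tau) dtau with
    alpha = T/tauD and beta = r^-2:

    * r = 1 branch:  (8/alpha^2) * (alpha/2 - sqrt(1+alpha) + 1)
    * r > 1 branch:  artanh form (used when |beta - 1| >= 1e-6)
    * alpha < 5e-3:  5-term Taylor series (both closed forms lose ~1e-8
      relative accuracy to cancellation near alpha ~ 1e-3)

    Monotone non-increasing in T, with Gamma -> 1 as T -> 0 and
    Gamma -> 0 as T -> infinity.
    """
    T = np.asarray(T, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if np.any(T <= 0):
        raise ConfigError("sampling time T must be > 0")
    if not tau_d > 0:
        raise ConfigError(f"tau_d must be > 0, got {tau_d}")
    if not r >= 1:
        raise ConfigError(f"aspect ratio r must be >= 1, got {r}")
    alpha = T / tau_d
    beta = 1.0 / (r * r)
    out = np.empty_like(alpha)
    small = alpha < ALPHA_SERIES_TOL
    if np.any(small):
        out[small] = _gamma_diff_series(alpha[small], beta)
    big = ~small
    if np.any(big):
        if abs(beta - 1.0) < BETA_BRANCH_TOL:
            out[big] = _gamma_diff_r1(alpha[big])
        else:
            out[big] = _gamma_diff_artanh(alpha[big], beta)
    return float(out[0]) if scalar else out


def binning_isomerization(T, F: float, tau_f: float):
    """Blinking binning function Gamma_iso(T).

    Gamma_iso(T) = 1 + (2/T^2) * [F tauF T - F tauF^2 (1 - exp(-T/tauF))] / (1-F)

    Approaches 1/(1-F) as T -> 0 and 1 as T -> infinity.  For
    T/tauF < 1e-4 a Taylor series is used to avoid the x + expm1(-x)
    cancellation at double precision.
    """
    T = np.asarray(T, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if np.any(T <= 0):
        raise ConfigError("sampling time T must be > 0")
    if not (0 <= F < 1):
        raise ConfigError(f"dark fraction F must be in [0, 1), got {F}")
    if not tau_f > 0:
        raise ConfigError(f"tau_f must be > 0, got {tau_f}")
    if F == 0:
        out = np.ones_like(T)
        return float(out[0]) if scalar else out
    x = T / tau_f
    pref = F / (1.0 - F)
    out = np.empty_like(x)
    small = x < ISO_SERIES_TOL
    if np.any(small):
        xs = x[small]
        # 2/x^2 * (x + expm1(-x)) = 1 - x/3 + x^2/12 - x^3/60 + x^4/360
        out[small] = 1.0 + pref * (1.0 - xs / 3.0 + xs**2 / 12.0 - xs**3 / 60.0 + xs**4 / 360.0)
    big = ~small
    if np.any(big):
        xb = x[big]
        out[big] = 1.0 + pref * (2.0 / xb**2) * (xb + np.expm1(-xb))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Quadrature oracles
# ---------------------------------------------------------------------------

def binning_diffusion_numeric(T: float, tau_d: float, r: float, epsrel: float = 1e-12) -> float:
    """Adaptive-quadrature oracle for Gamma_diff (integrates the kernel)."""
    if not (T > 0 and tau_d > 0 and r >= 1):
        raise ConfigError("require T > 0, tau_d > 0, r >= 1")
    val, _ = quad(lambda u: (1.0 - u) * g_diffusion_3dg(u * T, tau_d, r),
                  0.0, 1.0, epsabs=0, epsrel=epsrel, limit=500)
    return 2.0 * val


def binning_isomerization_numeric(T: float, F: float, tau_f: float, epsrel: float = 1e-12) -> float:
    """Adaptive-quadrature oracle for Gamma_iso (integrates the kernel)."""
    if not (T > 0 and 0 <= F < 1 and tau_f > 0):
        raise ConfigError("require T > 0, 0 <= F < 1, tau_f > 0")
    val, _ = quad(lambda u: (1.0 - u) * g_isomerization(u * T, F, tau_f),
                  0.0, 1.0, epsabs=0, epsrel=epsrel, limit=500)
    return 2.0 * val


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

def msmr_model(T, params: ModelParams):
    """Model mSMR: mu(T) = gamma2 * mu0 * Gamma_diff(T) * Gamma_iso(T).

    With F = 0 this reduces to the pure-diffusion model
    mu(T) = gamma2 * mu0 * Gamma_diff,3DG(T).
    """
    out = params.gamma2 * params.mu0 * binning_diffusion(T, params.tau_d, params.r)
    if params.F > 0:
        out = out * binning_isomerization(T, params.F, params.tau_f)
    return out


def q_model(T, params: ModelParams):
    """Model Mandel Q: Q(T) = T * mu(T); tends to 0 as T -> 0."""
    return np.asarray(T, dtype=float) * msmr_model(T, params) if np.ndim(T) else T * msmr_model(T, params)
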