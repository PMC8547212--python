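"""Nonlinear least-squares fitting of empirical mSMR curves.

The central object is :class:`MSMRRegressor`, a scikit-learn-style
estimator: ``fit(T, mu)`` minimizes sum w_i (mu_i - mu_model(T_i))^2
over the free physical parameters and exposes the result as fitted
attributes (``mu0_``, ``tau_d_``, ...).  ``fit_msmr`` is a thin wrapper
taking an :class:`~msmr.traces.MSMRCurve`.

The PSF aspect ratio r is fixed by default and should come from a
calibration measurement: the model is nearly insensitive to r above
~3 (the r = 5 and r = 10 curves practically coincide), so leaving it
free there is an identifiability trap and triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigError, FitError
from .models import GAMMA2_3DG, ModelParams, msmr_model
from .traces import MSMRCurve

__all__ = [
    "FitResult",
    "MSMRRegressor",
    "fit_msmr",
    "initial_guess",
    "diffusion_coefficient",
    "aggregate_fits",
]

_PARAM_NAMES = ("mu0", "tau_d", "r", "F", "tau_f")

#: optimizer bounds keeping the search off divergent model regions
_BOUNDS = {
    "mu0": (1e-3, 1e9),
    "tau_d": (1e-7, 10.0),
    "r": (1.0, 100.0),
    "F": (0.0, 0.99),
    "tau_f": (1e-8, 1e-2),
}


@dataclass(frozen=True)
class FitResult:
    """Result of one mSMR curve fit.

    ``params`` holds the full fitted parameter vector (fixed entries
    keep their input value); ``std_errors`` maps each free parameter to
    its covariance-derived standard error.
    """

    params: ModelParams
    std_errors: dict
    fixed_mask: frozenset
    residual_norm: float
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if any(se < 0 for se in self.std_errors.values() if np.isfinite(se)):
            raise FitError("negative standard error")


class MSMRRegressor(RegressorMixin, BaseEstimator):
    """Least-squares mSMR model fit as a scikit-learn estimator.

    Parameters
    ----------
    r : float
        PSF aspect ratio z0/r0, fixed by default (see module docstring).
    include_iso : bool
        Fit the on/off blinking term (frees F and tau_f); otherwise
        F = 0 is held fixed and the pure-diffusion model is used.
    fixed : dict, optional
        Parameter-name -> value pairs held fixed in addition to the
        defaults (``{"r": r}``, plus F/tau_f when ``include_iso`` is
        false).  Putting ``"r"`` in ``free`` instead frees it.
    free : set, optional
        Names to force free (only sensible for ``"r"``).
    initial : ModelParams, optional
        Starting point; derived from the data when absent.
    gamma2 : float
        PSF shape factor.
    max_nfev : int
        Maximum model evaluations.

    Attributes
    ----------
    params_ : ModelParams
        Fitted parameter vector.
    mu0_, tau_d_, F_, tau_f_ : float
        Convenience views of ``params_``.
    std_errors_ : dict
    residual_norm_ : float
    converged_ : bool
    result_ : FitResult
    """

    def __init__(self, r: float = 1.0, include_iso: bool = False,
                 fixed: dict | None = None, free: set | None = None,
                 initial: ModelParams | None = None, gamma2: float = GAMMA2_3DG,
                 max_nfev: int = 10_000):
        self.r = r
        self.include_iso = include_iso
        self.fixed = fixed
        self.free = free
        self.initial = initial
        self.gamma2 = gamma2
        self.max_nfev = max_nfev

    # -- scikit-learn plumbing -------------------------------------------

    def _validate_input(self, X, y):
        T = np.asarray(X, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:
            T = T[:, 0]
        if T.ndim != 1:
            raise ConfigError("X must be 1D sampling times or an (n, 1) column")
        mu = np.asarray(y, dtype=float)
        if mu.shape != T.shape:
            raise ConfigError("X and y lengths differ")
        if np.any(T <= 0):
            raise ConfigError("sampling times must be > 0")
        if np.any(np.diff(T) <= 0):
            order = np.argsort(T)
            T, mu = T[order], mu[order]
        return T, mu

    def fit(self, X, y, sample_weight=None):
        """Fit the mSMR model to (sampling time, mu) points."""
        T, mu = self._validate_input(X, y)
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != T.shape or np.any(w < 0):
                raise ConfigError("sample_weight must be non-negative, same length as X")
        else:
            w = np.ones_like(T)
        if np.all(mu <= 0):
            raise FitError("degenerate curve: all mu <= 0, nothing to fit")

        fixed = dict(self.fixed or {})
        fixed.setdefault("r", self.r)
        if not self.include_iso:
            fixed.setdefault("F", 0.0)
            fixed.setdefault("tau_f", 1e-5)
        for name in self.free or ():
            fixed.pop(name, None)
        free_names = [n for n in _PARAM_NAMES if n not in fixed]
        if "r" in free_names and fixed.get("r", self.r) >= 3:
            warnings.warn("the model is nearly insensitive to r above ~3; "
                          "fix r from a calibration instead", stacklevel=2)
        if T.size < len(free_names) + 1:
            raise FitError(f"need at least {len(free_names) + 1} points "
                           f"for {len(free_names)} free parameters")

        init = self.initial or initial_guess_from_points(T, mu, gamma2=self.gamma2,
                                                         r=fixed.get("r", self.r))
        x0, lo, hi = [], [], []
        for n in free_names:
            v = float(getattr(init, n))
            b = _BOUNDS[n]
            x0.append(min(max(v, b[0]), b[1]))
            lo.append(b[0])
            hi.append(b[1])

        sw = np.sqrt(w)

        def build(x) -> ModelParams:
            kw = dict(fixed)
            kw.update(zip(free_names, x))
            kw.setdefault("r", self.r)
            return ModelParams(gamma2=self.gamma2, **kw)

        def resid(x):
            return sw * (msmr_model(T, build(x)) - mu)

        res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10,
                            gtol=1e-10, max_nfev=self.max_nfev)
        params = build(res.x)
        ssr = float(2 * res.cost)
        dof = T.size - len(free_names)
        std = {}
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (ssr / dof if dof > 0 else np.nan)
            std = {n: float(np.sqrt(max(cov[i, i], 0.0)))
                   for i, n in enumerate(free_names)}
        except np.linalg.LinAlgError:
            std = {n: float("nan") for n in free_names}

        self.params_ = params
        self.mu0_ = params.mu0
        self.tau_d_ = params.tau_d
        self.F_ = params.F
        self.tau_f_ = params.tau_f
        self.std_errors_ = std
        self.residual_norm_ = ssr
        self.converged_ = bool(res.status > 0)
        self.n_points_ = int(T.size)
        self.result_ = FitResult(params=params, std_errors=std,
                                 fixed_mask=frozenset(fixed),
                                 residual_norm=ssr, n_points=int(T.size),
                                 converged=self.converged_)
        return self

    def predict(self, X):
        """Model mu(T) at the given sampling times."""
        if not hasattr(self, "params_"):
            raise FitError("estimator is not fitted")
        T = np.asarray(X, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:
            T = T[:, 0]
        return msmr_model(T, self.params_)


def fit_msmr(curve: MSMRCurve, initial: ModelParams | None = None,
             fixed: dict | None = None, include_iso: bool = False,
             weights=None, r: float = 1.0, gamma2: float = GAMMA2_3DG) -> FitResult:
    """Fit an mSMR curve; thin wrapper over :class:`MSMRRegressor`."""
    est = MSMRRegressor(r=r, include_iso=include_iso, fixed=fixed,
                        initial=initial, gamma2=gamma2)
    est.fit(curve.T, curve.mu, sample_weight=weights)
    return est.result_


def initial_guess_from_points(T: np.ndarray, mu: np.ndarray,
                              gamma2: float = GAMMA2_3DG, r: float = 1.0) -> ModelParams:
    """Data-driven starting parameters.

    mu0 from the largest positive mu (the short-T plateau is gamma2*mu0);
    tau_d from the log-interpolated half-plateau crossing, falling back
    to the largest T for monotone-flat curves.  F and tau_f start at 0.1
    and a decade below tau_d.
    """
    pos = mu > 0
    if not np.any(pos):
        return ModelParams(mu0=1e4, tau_d=1e-3, r=r, F=0.1, tau_f=1e-4, gamma2=gamma2)
    plateau = float(mu[pos].max())
    mu0 = plateau / gamma2
    half = plateau / 2.0
    below = np.flatnonzero(mu < half)
    tau_d = float(T[-1])
    if below.size and below[0] > 0:
        i = below[0]
        if mu[i] > 0:
            f = (np.log(mu[i - 1]) - np.log(half)) / (np.log(mu[i - 1]) - np.log(mu[i]))
            f = min(max(f, 0.0), 1.0)
        else:
            f = 0.5  # crossing into noise/negative territory: take the midpoint
        tau_d = float(np.exp(np.log(T[i - 1]) + f * (np.log(T[i]) - np.log(T[i - 1]))))
    tau_d = min(max(tau_d, _BOUNDS["tau_d"][0]), _BOUNDS["tau_d"][1])
    tau_f = min(max(tau_d / 10.0, _BOUNDS["tau_f"][0]), _BOUNDS["tau_f"][1])
    return ModelParams(mu0=mu0, tau_d=tau_d, r=r, F=0.1, tau_f=tau_f, gamma2=gamma2)


def initial_guess(curve: MSMRCurve, gamma2: float = GAMMA2_3DG,
                  r: float = 1.0) -> ModelParams:
    """Starting parameters for a curve (see initial_guess_from_points)."""
    if len(curve) < 4:
        raise FitError("need at least 4 points for an initial guess")
    return initial_guess_from_points(curve.T, curve.mu, gamma2=gamma2, r=r)


def diffusion_coefficient(tau_d: float, r0_um: float) -> float:
    """D = r0^2 / (4 tau_d), um^2/s, from the fitted diffusion time."""
    if not (tau_d > 0 and r0_um > 0):
        raise ConfigError("tau_d and r0 must be > 0")
    return r0_um**2 / (4.0 * tau_d)


def aggregate_fits(results: list[FitResult]) -> dict:
    """Per-parameter mean and sample std over converged replicate fits.

    All converged results must share the same fixed mask (the
    fit-then-average replicate convention).  Returns
    ``{"mean": {...}, "std": {...}, "n_converged": int, "n_excluded": int}``.
    """
    conv = [r_ for r_ in results if r_.converged]
    if len(conv) < 2:
        raise FitError(f"need >= 2 converged fits, got {len(conv)}")
    mask = conv[0].fixed_mask
    if any(r_.fixed_mask != mask for r_ in conv):
        raise FitError("converged fits have differing fixed-parameter masks")
    free = [n for n in _PARAM_NAMES if n not in mask]
    values = {n: np.array([getattr(r_.params, n) for r_ in conv]) for n in free}
    return {
        "mean": {n: float(v.mean()) for n, v in values.items()},
        "std": {n: float(v.std(ddof=1)) for n, v in values.items()},
        "n_converged": len(conv),
        "n_excluded": len(results) - len(conv),
    }
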