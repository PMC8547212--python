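"""Detector-artefact and background corrections.

Single-photon avalanche diodes distort photon-count statistics in two
ways: *afterpulsing* (a detection triggers a spurious extra count with
probability P_A, raising Q) and *dead time* (the detector is blind for
t_dead after each detection, lowering Q).  The first two measured
moments are corrected jointly to first order:

    <k>   = <k>_m  (1 - P_A - delta) + delta <k^2>_m
    <k^2> = <k^2>_m (1 - 2 P_A - 3 delta) + 2 delta <k^3>_m
            + (delta - P_A) <k>_m

with the dimensionless dead time delta = t_dead / T.  Validity requires
<k>_m * delta << 1.

Uncorrelated background light scales the mSMR amplitude down; the
correction multiplies mu(T) (or the fitted mu0) by (1 - <b>/<k>)^-1,
where <b> is the background count per bin from a blank measurement.

The module also provides synthetic artefact *injection* helpers used to
test correction direction and magnitude on simulated traces (the
corrections themselves never use them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigError,
    CorrectionInvalidError,
    CorrectionUndefinedError,
)
from .traces import MSMRCurve, PhotonTrace

__all__ = [
    "DetectorParams",
    "correct_moments",
    "background_chi2",
    "background_correct_mu0",
    "background_correct_curve",
    "inject_dead_time",
    "inject_afterpulsing",
    "inject_background",
]

#: <k>_m * delta above which a warning is issued / the correction refuses.
VALIDITY_WARN = 0.1
VALIDITY_FAIL = 0.5


@dataclass(frozen=True)
class DetectorParams:
    """Detector artefact parameters.

    Parameters
    ----------
    t_dead : float
        Detector dead time, seconds (e.g. 70e-9 for a typical SPAD).
    p_afterpulse : float
        First-order afterpulsing probability, in [0, 1).
    background_rate : float
        Background count rate from a blank measurement, counts/second.
    """

    t_dead: float = 0.0
    p_afterpulse: float = 0.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.t_dead < 0:
            raise ConfigError(f"t_dead must be >= 0, got {self.t_dead}")
        if not 0 <= self.p_afterpulse < 1:
            raise ConfigError(f"p_afterpulse must be in [0, 1), got {self.p_afterpulse}")
        if self.background_rate < 0:
            raise ConfigError(f"background_rate must be >= 0, got {self.background_rate}")


def correct_moments(m1: float, m2: float, m3: float, T: float,
                    det: DetectorParams) -> tuple[float, float]:
    """First-order afterpulsing + dead-time correction of measured moments.

    Returns the corrected (<k>, <k^2>).  With P_A = delta = 0 this is the
    exact identity.  Raises :class:`CorrectionInvalidError` when
    <k>_m * delta > 0.5 (the first-order expansion is then meaningless);
    warns above 0.1.
    """
    if not T > 0:
        raise ConfigError(f"sampling time T must be > 0, got {T}")
    delta = det.t_dead / T
    pa = det.p_afterpulse
    load = m1 * delta
    if load > VALIDITY_FAIL:
        raise CorrectionInvalidError(
            f"moment correction invalid at T={T:g}s: <k>*delta = {load:.3g} > {VALIDITY_FAIL}")
    if load > VALIDITY_WARN:
        warnings.warn(f"moment correction marginal at T={T:g}s: <k>*delta = {load:.3g}",
                      stacklevel=2)
    m1_true = m1 * (1.0 - pa - delta) + delta * m2
    m2_true = m2 * (1.0 - 2.0 * pa - 3.0 * delta) + 2.0 * delta * m3 + (delta - pa) * m1
    return m1_true, m2_true


def background_chi2(mean_counts: float, background_counts: float) -> float:
    """FCS-style background factor chi^2 = (1 + b/(k - b))^2."""
    if background_counts < 0:
        raise ConfigError("background_counts must be >= 0")
    if background_counts >= mean_counts:
        raise CorrectionUndefinedError(
            f"background ({background_counts:g}) >= signal ({mean_counts:g})")
    return (1.0 + background_counts / (mean_counts - background_counts)) ** 2


def background_correct_mu0(mu0_measured: float, mean_counts: float,
                           background_counts: float) -> float:
    """Background-corrected brightness: mu0 / (1 - b/k); always >= mu0."""
    if background_counts < 0:
        raise ConfigError("background_counts must be >= 0")
    if background_counts >= mean_counts:
        raise CorrectionUndefinedError(
            f"background ({background_counts:g}) >= signal ({mean_counts:g})")
    return mu0_measured / (1.0 - background_counts / mean_counts)


def background_correct_curve(curve: MSMRCurve, background_rate: float) -> MSMRCurve:
    """Scale a curve's mu(T) and Q(T) by (1 - <b>/<k>)^-1.

    <b> = background_rate * T per bin.  For a stationary trace the ratio
    <b>/<k> is the same at every sampling time (both scale linearly in
    T); this is asserted to 1e-9 relative before the single constant
    scale factor is applied.  The ratio uses the *measured* first
    moments stored in the curve.
    """
    if background_rate < 0:
        raise ConfigError("background_rate must be >= 0")
    if background_rate == 0:
        return curve
    b = background_rate * curve.T
    if np.any(b >= curve.m1):
        T_bad = curve.T[np.argmax(b >= curve.m1)]
        raise CorrectionUndefinedError(
            f"background exceeds signal at T={T_bad:g}s")
    ratio = b / curve.m1
    spread = ratio.max() - ratio.min()
    if spread > 1e-9 * ratio.max():
        raise CorrectionUndefinedError(
            f"background/signal ratio varies with T (spread {spread:.3g}); "
            "trace is not stationary")
    scale = 1.0 / (1.0 - ratio.mean())
    flags = dict(curve.corrected)
    flags["background"] = True
    return MSMRCurve(T=curve.T, m1=curve.m1, m2=curve.m2, m3=curve.m3,
                     n_bins=curve.n_bins, Q=curve.Q * scale, mu=curve.mu * scale,
                     corrected=flags)


# ---------------------------------------------------------------------------
# Synthetic artefact injection (test-support; the model never uses these)
# ---------------------------------------------------------------------------

def inject_dead_time(trace: PhotonTrace, t_dead: float,
                     rng: np.random.Generator) -> PhotonTrace:
    """Thin counts so no two retained events fall within t_dead.

    Per-bin approximation at trace resolution: the k events of a bin are
    given uniform arrival times within the bin, sorted, and greedily
    thinned; cross-bin blanking is neglected (adequate for
    t_dead << bin_width * typical count spacing).
    """
    if t_dead < 0:
        raise ConfigError("t_dead must be >= 0")
    if t_dead == 0:
        return trace
    w = trace.bin_width
    counts = trace.counts.copy()
    for i in np.flatnonzero(counts >= 2):
        times = np.sort(rng.uniform(0.0, w, size=counts[i]))
        kept = 1
        last = times[0]
        for t in times[1:]:
            if t - last >= t_dead:
                kept += 1
                last = t
        counts[i] = kept
    return PhotonTrace(counts, w, trace.origin_time)


def inject_afterpulsing(trace: PhotonTrace, p_afterpulse: float,
                        rng: np.random.Generator) -> PhotonTrace:
    """Add a spurious extra count per detection with probability P_A.

    Each afterpulse lands in the same bin or the next with equal
    probability (afterpulse delays are sub-bin to ~bin scale); spill
    past the last bin is dropped.
    """
    if not 0 <= p_afterpulse < 1:
        raise ConfigError("p_afterpulse must be in [0, 1)")
    if p_afterpulse == 0:
        return trace
    extras = rng.binomial(trace.counts, p_afterpulse)
    same = rng.binomial(extras, 0.5)
    nxt = extras - same
    counts = trace.counts + same
    counts[1:] += nxt[:-1]
    return PhotonTrace(counts, trace.bin_width, trace.origin_time)


def inject_background(trace: PhotonTrace, background_rate: float,
                      rng: np.random.Generator) -> PhotonTrace:
    """Add uncorrelated Poisson background at the given rate."""
    if background_rate < 0:
        raise ConfigError("background_rate must be >= 0")
    if background_rate == 0:
        return trace
    extra = rng.poisson(background_rate * trace.bin_width, size=len(trace))
    return PhotonTrace(trace.counts + extra, trace.bin_width, trace.origin_time)
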