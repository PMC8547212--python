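"""Photon-trace containers and the empirical mSMR curve.

A measurement is a sequence of non-negative integer photon counts in
equal-width time bins.  The empirical mSMR is obtained by rebinning the
trace at every integer-divisor sampling time T, computing the raw count
moments at each T, and evaluating

    Q(T)  = (<k^2> - <k>^2 - <k>) / <k>
    mu(T) = Q(T) / T
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InsufficientDataError,
    ProcessingError,
    UndefinedQError,
)

__all__ = [
    "PhotonTrace",
    "MSMRCurve",
    "integer_divisors",
    "rebin",
    "raw_moments",
    "mandel_q",
    "msmr_curve",
    "bin_timestamps",
    "average_curves",
]

log = logging.getLogger(__name__)

#: Column order of the curve table (and of the curve CSV on disk).
CURVE_COLUMNS = ["T_s", "m1", "m2", "m3", "n_bins", "Q", "mu_cps"]

CORRECTION_FLAGS = ("deadtime", "afterpulse", "background")


@dataclass(frozen=True)
class PhotonTrace:
    """Binned photon-count trace.

    Parameters
    ----------
    counts : ndarray of int
        Non-negative photon counts, one per time bin.
    bin_width : float
        Bin width in seconds (the minimum sampling time).
    origin_time : float
        Start time of the first bin, seconds.
    """

    counts: np.ndarray
    bin_width: float
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ProcessingError("trace counts must be a non-empty 1D array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ProcessingError("trace counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ProcessingError("trace counts must be non-negative")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        if not self.bin_width > 0:
            raise ProcessingError(f"bin_width must be > 0, got {self.bin_width}")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        """Total observation time T_obs = n * bin_width, seconds."""
        return self.counts.size * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate, counts/second."""
        return float(self.counts.sum()) / self.duration


@dataclass(frozen=True)
class MSMRCurve:
    """Empirical mSMR curve: per-sampling-time moments, Q and mu.

    ``m1, m2, m3`` are the *measured* raw moments of the rebinned counts
    at each sampling time; when detector corrections were applied, ``Q``
    and ``mu`` are computed from the corrected moments while the stored
    moments stay measured.  ``corrected`` records which corrections were
    applied.
    """

    T: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray
    n_bins: np.ndarray
    Q: np.ndarray
    mu: np.ndarray
    corrected: dict = field(default_factory=lambda: {k: False for k in CORRECTION_FLAGS})

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.size < 1:
            raise ProcessingError("empty curve")
        if np.any(np.diff(T) <= 0):
            raise ProcessingError("curve sampling times must be strictly increasing")
        for name in ("m1", "m2", "m3", "Q", "mu"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != T.shape:
                raise ProcessingError(f"curve column {name} has mismatched length")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "n_bins", np.asarray(self.n_bins, dtype=np.int64))
        flags = {k: bool(self.corrected.get(k, False)) for k in CORRECTION_FLAGS}
        object.__setattr__(self, "corrected", flags)

    def __len__(self) -> int:
        return self.T.size

    def to_frame(self) -> pd.DataFrame:
        """Curve as a DataFrame with one row per sampling time."""
        df = pd.DataFrame({
            "T_s": self.T, "m1": self.m1, "m2": self.m2, "m3": self.m3,
            "n_bins": self.n_bins, "Q": self.Q, "mu_cps": self.mu,
        })
        for k in CORRECTION_FLAGS:
            df[f"corr_{k}"] = self.corrected[k]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MSMRCurve":
        flags = {k: bool(df[f"corr_{k}"].iloc[0]) if f"corr_{k}" in df else False
                 for k in CORRECTION_FLAGS}
        return cls(T=df["T_s"].to_numpy(), m1=df["m1"].to_numpy(), m2=df["m2"].to_numpy(),
                   m3=df["m3"].to_numpy(), n_bins=df["n_bins"].to_numpy(),
                   Q=df["Q"].to_numpy(), mu=df["mu_cps"].to_numpy(), corrected=flags)


def integer_divisors(n: int) -> np.ndarray:
    """All positive divisors of n in ascending order (trial division)."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ConfigError(f"n must be a positive integer, got {n!r}")
    small, large = [], []
    i = 1
    while i * i <= n:
        if n % i == 0:
            small.append(i)
            if i != n // i:
                large.append(n // i)
        i += 1
    return np.array(small + large[::-1], dtype=np.int64)


def rebin(trace: PhotonTrace, factor: int) -> PhotonTrace:
    """Sum every ``factor`` consecutive bins into one.

    The factor must divide the trace length exactly (no silent
    truncation); total counts are conserved.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ConfigError(f"rebin factor must be a positive integer, got {factor!r}")
    n = len(trace)
    if n % factor != 0:
        raise ProcessingError(f"rebin factor {factor} does not divide trace length {n}")
    if factor == 1:
        return trace
    counts = trace.counts.reshape(n // factor, factor).sum(axis=1)
    return PhotonTrace(counts, trace.bin_width * factor, trace.origin_time)


def raw_moments(trace: PhotonTrace, max_order: int = 3) -> tuple[float, ...]:
    """Raw moments m_j = (1/n) * sum_i k_i^j for j = 1..max_order.

    Sums are accumulated exactly: counts are histogrammed with bincount
    and the per-value powers are taken in unbounded Python integers, so
    <k^3> of long bright traces cannot overflow or lose precision.
    """
    if not 1 <= max_order <= 3:
        raise ConfigError(f"max_order must be in 1..3, got {max_order}")
    counts = trace.counts
    n = counts.size
    if n == 0:
        raise ProcessingError("cannot compute moments of an empty trace")
    freq = np.bincount(counts)
    values = np.flatnonzero(freq)
    out = []
    for j in range(1, max_order + 1):
        total = sum(int(f) * int(v) ** j for v, f in zip(values, freq[values]))
        out.append(total / n)
    return tuple(out)


def mandel_q(m1: float, m2: float) -> float:
    """Mandel Q from the first two raw moments: (m2 - m1^2 - m1)/m1.

    Q = 0 for Poisson counts; negative values are subpoissonian,
    positive superpoissonian.
    """
    if m1 == 0:
        raise UndefinedQError("Mandel Q undefined for zero mean count")
    return (m2 - m1 * m1 - m1) / m1


def msmr_curve(trace: PhotonTrace, t_max_fraction: float | None = None,
               corrections=None, min_points: int = 4) -> MSMRCurve:
    """Empirical mSMR curve of a trace over all divisor sampling times.

    For each divisor d of the trace length with sampling time
    T = d * bin_width <= t_max_fraction * T_obs, the trace is rebinned,
    raw moments are computed, optionally corrected for detector dead
    time and afterpulsing, and Q(T) and mu(T) = Q(T)/T are evaluated.

    Parameters
    ----------
    trace : PhotonTrace
    t_max_fraction : float, optional
        Largest included sampling time as a fraction of the observation
        time.  Default 0.01, so every retained T has at least 100
        contributing bins (the variance of the second-moment estimator
        grows quickly below that).
    corrections : DetectorParams, optional
        When given, the measured moments are corrected for dead time and
        afterpulsing (jointly, per their coupled first-order equations)
        before Q is formed.  Background correction is a separate,
        curve-level step (:func:`msmr.corrections.background_correct_curve`).
    """
    if t_max_fraction is None:
        t_max_fraction = 0.01
    if not 0 < t_max_fraction <= 1:
        raise ConfigError(f"t_max_fraction must be in (0, 1], got {t_max_fraction}")
    if len(trace) < 2:
        raise ProcessingError("trace must have at least 2 bins")

    from .corrections import correct_moments  # deferred: avoid module cycle

    n = len(trace)
    max_factor = int(n * t_max_fraction)
    rows = []
    n_dropped = 0
    for d in integer_divisors(n):
        if d > max_factor:
            break
        rb = rebin(trace, int(d))
        m1, m2, m3 = raw_moments(rb, max_order=3)
        if m1 == 0:
            n_dropped += 1
            continue
        T = float(d) * trace.bin_width
        if corrections is not None:
            m1c, m2c = correct_moments(m1, m2, m3, T, corrections)
        else:
            m1c, m2c = m1, m2
        if m1c <= 0:
            n_dropped += 1
            continue
        Q = mandel_q(m1c, m2c)
        rows.append((T, m1, m2, m3, len(rb), Q, Q / T))
    if n_dropped:
        log.info("msmr_curve: dropped %d sampling times with zero/non-positive mean", n_dropped)
    if log.isEnabledFor(logging.DEBUG):
        for row in rows:
            log.debug("T=%.6g s: m1=%.6g m2=%.6g n_bins=%d Q=%.6g mu=%.6g",
                      row[0], row[1], row[2], row[4], row[5], row[6])
    if len(rows) < min_points:
        raise InsufficientDataError(
            f"only {len(rows)} valid sampling times (need >= {min_points}); "
            "trace too short or too sparse")
    cols = list(zip(*rows))
    flags = {k: False for k in CORRECTION_FLAGS}
    if corrections is not None:
        flags["deadtime"] = corrections.t_dead > 0
        flags["afterpulse"] = corrections.p_afterpulse > 0
    return MSMRCurve(T=np.array(cols[0]), m1=np.array(cols[1]), m2=np.array(cols[2]),
                     m3=np.array(cols[3]), n_bins=np.array(cols[4]),
                     Q=np.array(cols[5]), mu=np.array(cols[6]), corrected=flags)


def bin_timestamps(timestamps, bin_width: float, duration: float | None = None,
                   origin_time: float = 0.0) -> PhotonTrace:
    """Bin raw photon arrival times into a trace.

    Bins are half-open, [t, t + bin_width); events at or beyond the end
    of the observation window are dropped with a warning.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size and np.any(np.diff(ts) < 0):
        raise ProcessingError("timestamps must be sorted ascending")
    if not bin_width > 0:
        raise ConfigError(f"bin_width must be > 0, got {bin_width}")
    rel = ts - origin_time
    if np.any(rel < 0):
        raise ProcessingError("timestamp before origin_time")
    if duration is None:
        duration = float(np.ceil(rel[-1] / bin_width) * bin_width) if ts.size else bin_width
        if ts.size and rel[-1] >= duration:  # event exactly on the boundary
            duration += bin_width
    n = int(round(duration / bin_width))
    if n < 1:
        raise ConfigError("observation window shorter than one bin")
    keep = rel < n * bin_width
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} events at/after the end "
                      "of the observation window", stacklevel=2)
        rel = rel[keep]
    idx = np.floor(rel / bin_width).astype(np.int64)
    counts = np.bincount(idx, minlength=n)
    return PhotonTrace(counts, bin_width, origin_time)


def average_curves(curves: list[MSMRCurve]) -> MSMRCurve:
    """Pointwise average of replicate curves sharing one sampling grid.

    Moments, Q and mu are averaged entrywise; n_bins is summed.  Used for
    the average-then-fit replicate convention.
    """
    if not curves:
        raise ConfigError("no curves to average")
    T0 = curves[0].T
    for c in curves[1:]:
        if len(c) != len(curves[0]) or not np.allclose(c.T, T0, rtol=1e-12, atol=0):
            raise ProcessingError("curves must share an identical sampling-time grid")
        if c.corrected != curves[0].corrected:
            raise ProcessingError("curves must share identical correction flags")
    return MSMRCurve(
        T=T0,
        m1=np.mean([c.m1 for c in curves], axis=0),
        m2=np.mean([c.m2 for c in curves], axis=0),
        m3=np.mean([c.m3 for c in curves], axis=0),
        n_bins=np.sum([c.n_bins for c in curves], axis=0),
        Q=np.mean([c.Q for c in curves], axis=0),
        mu=np.mean([c.mu for c in curves], axis=0),
        corrected=dict(curves[0].corrected),
    )
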