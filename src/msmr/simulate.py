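"""Monte Carlo photon-trace simulator.

Brownian diffusion of point emitters in a box, observed through a 3D
Gaussian detection volume.  Per time slice Delta_t = eps^2 / (6 D_fast)
(Einstein-Smoluchowski, with eps the maximum step, 20 nm by default so
the walk remains a valid Wiener-process discretisation), every particle
takes one lattice step of species-specific length sqrt(6 D_i Delta_t)
along one of the six axis directions (probability 1/6 each), positions
wrap periodically at the box faces, and the particle emits
Poisson(mu0 * Delta_t * PSF(r)) photons.  Slice counts are summed over
particles and aggregated to the requested output bin width.

The box spans ``box_multiplier`` (default 12) times r0 laterally and z0
axially, so PSF tails at the boundary are negligible and the uniform
initial placement is already the stationary density under periodic
wrapping.

An optional two-state blinking toggle (rates k_on, k_off per species)
switches emitters between bright and dark, giving dark fraction
F = k_off/(k_on + k_off) and relaxation time tau_F = 1/(k_on + k_off);
it exists to exercise the isomerization term of the model and is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationError
from .models import PSFGeometry
from .traces import PhotonTrace

__all__ = ["Species", "SimulationConfig", "time_slice", "psf_value", "simulate_trace"]

_DIR_VECS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)

#: slices per vectorized chunk; fixed so the RNG draw order (hence the
#: trace, given a seed) never depends on memory heuristics
_CHUNK = 1 << 16


@dataclass(frozen=True)
class Species:
    """One diffusing emitter species.

    D in um^2/s, ``count`` particles in the box, ``mu0`` detected counts
    per second for a particle at the PSF maximum.  Optional blinking
    rates k_on/k_off in 1/s (both zero = always bright).
    """

    D: float
    count: int
    mu0: float
    k_on: float = 0.0
    k_off: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise SimulationError(f"diffusion coefficient must be >= 0, got {self.D}")
        if self.count < 0:
            raise SimulationError(f"particle count must be >= 0, got {self.count}")
        if self.mu0 < 0:
            raise SimulationError(f"mu0 must be >= 0, got {self.mu0}")
        if self.k_on < 0 or self.k_off < 0:
            raise SimulationError("blinking rates must be >= 0")
        if (self.k_on == 0) != (self.k_off == 0):
            raise SimulationError("blinking needs both k_on and k_off > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full simulation input.

    ``max_step_nm`` is the lattice step of the fastest species (<= 20 nm
    for Wiener validity); slower species get proportionally shorter
    steps at the shared time slice.  ``output_bin_width`` defaults to
    1 us rounded to the nearest positive integer multiple of the time
    slice.  ``time_slice_s`` overrides the Einstein-Smoluchowski slice
    and is required when no species diffuses (test hook for immobile
    emitters).
    """

    species: tuple
    geometry: PSFGeometry
    duration: float
    box_multiplier: float = 12.0
    max_step_nm: float = 20.0
    output_bin_width: float | None = None
    seed: int = 0
    time_slice_s: float | None = None
    initial_positions: tuple | None = None  # per-species (count, 3) arrays, um, relative to the PSF center

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise SimulationError("at least one species required")
        if not self.duration > 0:
            raise SimulationError(f"duration must be > 0, got {self.duration}")
        if not 0 < self.max_step_nm <= 20.0:
            raise SimulationError(
                f"max_step_nm must be in (0, 20], got {self.max_step_nm}")
        if self.box_multiplier <= 0:
            raise SimulationError("box_multiplier must be > 0")


def time_slice(config: SimulationConfig) -> tuple[float, np.ndarray]:
    """Time slice Delta_t and per-species lattice steps (um).

    Delta_t = eps^2 / (6 D_fastest) with eps = max_step; each species
    then steps sqrt(6 D_i Delta_t) <= eps.  With no diffusing species,
    ``config.time_slice_s`` must be set (steps are all zero).
    """
    d_max = max(s.D for s in config.species)
    eps_um = config.max_step_nm * 1e-3
    if d_max <= 0:
        if config.time_slice_s is None:
            raise SimulationError(
                "no diffusing species: set time_slice_s explicitly")
        dt = config.time_slice_s
    else:
        dt = eps_um**2 / (6.0 * d_max)
        if config.time_slice_s is not None:
            dt = config.time_slice_s
    steps = np.array([np.sqrt(6.0 * s.D * dt) for s in config.species])
    if np.any(steps > eps_um * (1 + 1e-12)):
        raise SimulationError("time_slice_s too large: species step exceeds max_step")
    return dt, steps


def psf_value(position, geometry: PSFGeometry):
    """Normalized 3D Gaussian PSF, exp(-2(x^2+y^2)/r0^2 - 2 z^2/z0^2)."""
    pos = np.asarray(position, dtype=float)
    x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
    out = np.exp(-2.0 * (x * x + y * y) / geometry.r0**2 - 2.0 * z * z / geometry.z0**2)
    return float(out) if out.ndim == 0 else out


def _resolve_binning(config: SimulationConfig, dt: float) -> tuple[int, int]:
    """(slices per output bin, total slices truncated to a whole bin)."""
    if config.output_bin_width is None:
        k = max(1, round(1e-6 / dt))
    else:
        if config.output_bin_width < dt * (1 - 1e-9):
            raise SimulationError(
                f"output_bin_width {config.output_bin_width:g}s below time slice {dt:g}s")
        k = round(config.output_bin_width / dt)
        if abs(k * dt - config.output_bin_width) > 1e-9 * config.output_bin_width:
            raise SimulationError(
                "output_bin_width must be an integer multiple of the time slice "
                f"({dt:g}s)")
    n_slices = int(round(config.duration / dt))
    if n_slices < 1000:
        raise SimulationError(
            f"duration spans only {n_slices} slices; need >= 1000")
    n_slices -= n_slices % k
    return k, n_slices


def _blink_mask(n_slices: int, count: int, k_on: float, k_off: float,
                dt: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean bright/dark occupancy, shape (n_slices, count).

    Continuous-time two-state switching sampled at slice starts: dwell
    times are exponential with rate k_off (bright) / k_on (dark); the
    initial state is drawn from the stationary distribution.
    """
    total_t = n_slices * dt
    p_bright = k_on / (k_on + k_off)
    mask = np.empty((n_slices, count), dtype=bool)
    edges = np.arange(n_slices) * dt
    for p in range(count):
        state = rng.uniform() < p_bright
        t_acc, dwells = 0.0, []
        s = state
        while t_acc < total_t:
            rate = k_off if s else k_on
            d = rng.exponential(1.0 / rate)
            dwells.append(d)
            t_acc += d
            s = not s
        switch_times = np.cumsum(dwells)
        n_switch_before = np.searchsorted(switch_times, edges, side="right")
        mask[:, p] = state ^ (n_switch_before % 2 == 1)
    return mask


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Run the lattice-walk simulation and return the binned trace.

    Deterministic given ``config.seed`` (one seeded generator; the
    vectorization chunk size is a fixed constant so the draw order never
    varies).
    """
    geo = config.geometry
    dt, steps = time_slice(config)
    k, n_slices = _resolve_binning(config, dt)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    box = np.array([config.box_multiplier * geo.r0,
                    config.box_multiplier * geo.r0,
                    config.box_multiplier * geo.z0])
    center = box / 2.0

    positions = []
    for i, sp in enumerate(config.species):
        if config.initial_positions is not None:
            p0 = np.array(config.initial_positions[i], dtype=float) + center
            if p0.shape != (sp.count, 3):
                raise SimulationError(
                    f"initial_positions[{i}] must have shape ({sp.count}, 3)")
        else:
            p0 = rng.uniform(0.0, 1.0, size=(sp.count, 3)) * box
        positions.append(p0)

    blink = [
        _blink_mask(n_slices, sp.count, sp.k_on, sp.k_off, dt, rng)
        if sp.k_on > 0 else None
        for sp in config.species
    ]

    counts = np.empty(n_slices, dtype=np.int64)
    done = 0
    while done < n_slices:
        S = min(_CHUNK, n_slices - done)
        lam = np.zeros(S)
        for i, sp in enumerate(config.species):
            if sp.count == 0:
                continue
            if steps[i] > 0:
                dirs = rng.integers(0, 6, size=(S, sp.count))
                disp = _DIR_VECS[dirs] * steps[i]
                np.cumsum(disp, axis=0, out=disp)
                pos = (positions[i][None, :, :] + disp) % box
                positions[i] = pos[-1]
            else:
                pos = np.broadcast_to(positions[i], (S, sp.count, 3))
            if sp.mu0 == 0:
                continue
            psf = psf_value(pos - center, geo)
            if blink[i] is not None:
                psf = psf * blink[i][done:done + S]
            lam += (sp.mu0 * dt) * psf.sum(axis=1)
        counts[done:done + S] = rng.poisson(lam)
        done += S

    if k > 1:
        counts = counts.reshape(-1, k).sum(axis=1)
    return PhotonTrace(counts, k * dt)
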