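"""2D elastodynamic finite-difference time-domain solver.

Velocity–stress formulation on a staggered grid (Virieux scheme), second
order in time and space, in plane strain.  Stresses sigma_xx and sigma_yy
live at cell centers, sigma_xy at cell corners, and the velocity
components at the cell edges; material parameters are averaged onto the
staggered points (arithmetic mean of density, harmonic mean of shear
modulus), which keeps the discrete operator self-adjoint across material
interfaces.

Domain edges are terminated either by a convolutional perfectly matched
layer (CPML, the default — outgoing waves are absorbed so no energy
re-enters the model) or by rigid walls (``boundary="rigid"``), which make
the model a closed lossless cavity and are used for energy-conservation
checks.

The source is an additive normal-stress (pressure) injection over a line
aperture on the top surface; receivers record the acoustic pressure
``-(sigma_xx + sigma_yy)/2`` at single cells every time step.

Near-incompressible soft tissues (Poisson's ratio approaching 0.5) make
the medium contrast large: the time step obeys the global CFL bound set
by the fastest material (cortical bone), and the tiny soft-tissue shear
moduli are kept rather than zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fracture_geometry import ModelGrid

__all__ = [
    "SourceSpec",
    "WaveformRecord",
    "SimulationRun",
    "InstabilityError",
    "stable_time_step",
    "make_source_waveform",
    "run",
]

MM = 1e-3
US = 1e-6


class InstabilityError(RuntimeError):
    """Raised when the field amplitude grows without bound."""


@dataclass(frozen=True)
class WaveformRecord:
    """One receiver's pressure time series at uniform sampling."""

    label: str
    dt: float  # s
    samples: np.ndarray  # pressure amplitude

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass(frozen=True)
class SourceSpec:
    """Line source on the top surface.

    A 1-MHz, 3-us Hann-windowed toneburst over a 10-mm aperture by
    default; ``waveform`` may override the time series (unit peak is the
    convention; it is exactly zero outside [0, duration]).
    """

    aperture: float = 10.0  # mm
    f0: float = 1.0  # MHz
    duration: float = 3.0  # us
    waveform: np.ndarray | None = None


def stable_time_step(dx: float, c_max: float, cfl: float = 0.95) -> float:
    """CFL-stable time step ``cfl * dx / (c_max * sqrt(2))`` (SI units)."""
    if dx <= 0 or c_max <= 0:
        raise ValueError("dx and c_max must be positive")
    if not (0 < cfl <= 1):
        raise ValueError("cfl must lie in (0, 1]")
    return cfl * dx / (c_max * math.sqrt(2.0))


def make_source_waveform(f0: float, duration: float, dt: float) -> np.ndarray:
    """Hann-windowed toneburst, unit peak, zero outside [0, duration].

    Parameters are ``f0`` in MHz, ``duration`` in us, ``dt`` in s.
    """
    f0_hz = f0 * 1e6
    dur_s = duration * US
    if dur_s < 1.0 / f0_hz:
        raise ValueError("duration must cover at least one period of f0")
    if dt > 1.0 / (10.0 * f0_hz):
        raise ValueError(f"dt={dt} too coarse: need >= 10 samples per period of {f0} MHz")
    n = int(round(dur_s / dt))
    t = np.arange(n) * dt
    w = np.sin(2.0 * np.pi * f0_hz * t) * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / dur_s))
    peak = np.max(np.abs(w))
    return w / peak


@dataclass
class SimulationRun:
    """Result of one forward simulation."""

    grid: ModelGrid
    dt: float  # s
    duration: float  # us
    records: dict[str, WaveformRecord]
    source: SourceSpec
    cfl: float
    pml_cells: int
    snapshots: list[np.ndarray] = field(default_factory=list)
    snapshot_times: list[float] = field(default_factory=list)
    energy: np.ndarray | None = None

    def record(self, label: str) -> WaveformRecord:
        return self.records[label]


def _cpml_profiles(n: int, npml: int, half: bool, sigma_max: float,
                   alpha_max: float, dt: float, m: int = 3):
    """CPML recursion coefficients b, a along one axis.

    Evaluated at integer (cell) or half (edge) positions; zero damping
    outside the two npml-cell absorbing strips.
    """
    pos = np.arange(n, dtype=float) + (0.5 if half else 0.0)
    d = np.zeros(n)
    if npml > 0:
        left = (npml - pos) / npml
        right = (pos - (n - 1 - npml)) / npml
        d = np.clip(np.maximum(left, right), 0.0, 1.0)
    sig = sigma_max * d**m
    alpha = alpha_max * (1.0 - d)
    b = np.exp(-(sig + alpha) * dt)
    denom = sig + alpha
    a = np.where(denom > 0, sig / np.where(denom > 0, denom, 1.0) * (b - 1.0), 0.0)
    a[d == 0] = 0.0
    return b, a


def run(
    grid: ModelGrid,
    source: SourceSpec | None = None,
    duration: float = 20.0,
    cfl: float = 0.95,
    pml_cells: int = 40,
    boundary: str = "pml",
    record_energy: bool = False,
    snapshot_every: float | None = None,
    source_cells: tuple[int, np.ndarray] | None = None,
    extra_receivers: list[tuple[str, int, int]] | None = None,
    amplitude: float = 1.0,
    plane_source: bool = False,
) -> SimulationRun:
    """Propagate the source through ``grid`` and record receiver pressure.

    ``duration`` is in us.  ``source_cells`` (row, columns, unpadded grid
    indices) overrides the default top-surface aperture, enabling point
    sources.  With ``boundary="rigid"`` the edges reflect and ``pml_cells``
    is ignored; with the default CPML boundary the grid is padded by
    ``pml_cells`` on every side (edge materials extended outward).
    Raises :class:`InstabilityError` on unbounded amplitude growth.
    """
    if source is None:
        source = SourceSpec()
    if boundary not in ("pml", "rigid"):
        raise ValueError(f"unknown boundary {boundary!r}")
    npml = pml_cells if boundary == "pml" else 0

    h = grid.dx * MM
    mats = grid.materials
    c_max = max(m.c_l for m in mats)
    if cfl <= 0:
        raise ValueError("cfl must be positive")
    # cfl > 1 is deliberately permitted so instability handling can be
    # exercised; such runs abort with InstabilityError.
    dt = cfl * h / (c_max * math.sqrt(2.0))
    nt = int(round(duration * US / dt))

    if source.waveform is not None:
        wav = np.asarray(source.waveform, dtype=float)
    else:
        wav = make_source_waveform(source.f0, source.duration, dt)
    w = np.zeros(nt)
    w[: min(len(wav), nt)] = wav[: min(len(wav), nt)]

    # pad the material map with the PML collar (edge replication)
    idx = np.pad(grid.index, npml, mode="edge")
    ny, nx = idx.shape

    c11 = np.array([m.c11 for m in mats])[idx]
    c12 = np.array([m.c12 for m in mats])[idx]
    mu = np.array([m.c33 for m in mats])[idx]
    rho = np.array([m.rho for m in mats])[idx]

    # staggered material parameters
    bx = 2.0 / (rho[:, :-1] + rho[:, 1:])          # 1/rho at vx points
    by = 2.0 / (rho[:-1, :] + rho[1:, :])          # 1/rho at vy points
    mu4 = np.stack([mu[:-1, :-1], mu[:-1, 1:], mu[1:, :-1], mu[1:, 1:]])
    with np.errstate(divide="ignore"):
        mu_xy = np.where(np.all(mu4 > 0, axis=0),
                         4.0 / np.sum(1.0 / np.where(mu4 > 0, mu4, 1.0), axis=0), 0.0)

    sxx = np.zeros((ny, nx))
    syy = np.zeros((ny, nx))
    sxy = np.zeros((ny - 1, nx - 1))
    vx = np.zeros((ny, nx - 1))
    vy = np.zeros((ny - 1, nx))

    use_pml = npml > 0
    if use_pml:
        f0_hz = source.f0 * 1e6
        sigma_max = -(3 + 1) * c_max * math.log(1e-6) / (2.0 * npml * h)
        alpha_max = math.pi * f0_hz
        bxi, axi = _cpml_profiles(nx, npml, False, sigma_max, alpha_max, dt)
        bxh, axh = _cpml_profiles(nx - 1, npml, True, sigma_max, alpha_max, dt)
        byi, ayi = _cpml_profiles(ny, npml, False, sigma_max, alpha_max, dt)
        byh, ayh = _cpml_profiles(ny - 1, npml, True, sigma_max, alpha_max, dt)
        p_sxx_x = np.zeros_like(vx)
        p_sxy_y = np.zeros_like(vx)
        p_syy_y = np.zeros_like(vy)
        p_sxy_x = np.zeros_like(vy)
        p_vx_x = np.zeros_like(sxx)
        p_vy_y = np.zeros_like(sxx)
        p_vx_y = np.zeros_like(sxy)
        p_vy_x = np.zeros_like(sxy)

    # source aperture cells (shift into the padded frame)
    if plane_source:
        # span the full padded width (including the PML collar): the field
        # is then x-invariant and propagates as a clean 1D plane wave
        src_row, src_cols = 0 + npml, np.arange(nx)
    elif source_cells is None:
        src_row, src_cols = grid.source_cells()
        src_row, src_cols = src_row + npml, np.asarray(src_cols) + npml
    else:
        src_row, src_cols = source_cells
        src_row, src_cols = src_row + npml, np.asarray(src_cols) + npml

    rec_cells = grid.receiver_cells()
    if extra_receivers:
        rec_cells = rec_cells + list(extra_receivers)
    rec_rows = np.array([r + npml for _, r, _ in rec_cells], dtype=int)
    rec_cols = np.array([c + npml for _, _, c in rec_cells], dtype=int)
    rec_buf = np.zeros((len(rec_cells), nt))

    snap_every_steps = None
    snapshots: list[np.ndarray] = []
    snap_times: list[float] = []
    if snapshot_every is not None:
        snap_every_steps = max(int(round(snapshot_every * US / dt)), 1)

    energy = np.zeros(nt) if record_energy else None
    if record_energy:
        # plane-strain compliance for the (sxx, syy) block
        det = c11 * c11 - c12 * c12
        s11 = c11 / det
        s12 = -c12 / det
        rho_x = 1.0 / bx
        rho_y = 1.0 / by
        with np.errstate(divide="ignore"):
            inv_mu_xy = np.where(mu_xy > 0, 1.0 / np.where(mu_xy > 0, mu_xy, 1.0), 0.0)

    dt_h = dt / h
    # Volume-injection source: the stress increment is scaled by the local
    # plane-strain volumetric modulus (c11 + c12)/2, which makes the
    # pressure-source/pressure-receiver pairing exactly reciprocal in
    # heterogeneous media.  Normalized by the aperture mean so the
    # injected amplitude stays on the waveform's own scale.
    k_vol = (c11 + c12) / 2.0
    k_ref = float(np.max([(m.c11 + m.c12) / 2.0 for m in mats]))
    src_scale = k_vol[src_row, src_cols] / k_ref
    src_gain = amplitude
    src_peak = src_gain * float(np.max(src_scale)) * (np.max(np.abs(w)) if np.any(w) else 0.0)
    n_src = len(wav)

    for n in range(nt):
        if record_energy:
            vx_prev = vx.copy()
            vy_prev = vy.copy()
            # strain energy of the stress state at integer time n
            e_s = 0.5 * np.sum(s11 * (sxx * sxx + syy * syy) + 2.0 * s12 * sxx * syy)
            e_s += 0.5 * np.sum(inv_mu_xy * sxy * sxy)

        # velocity update (v: n-1/2 -> n+1/2)
        d1 = sxx[:, 1:] - sxx[:, :-1]
        d2 = np.diff(sxy, axis=0, prepend=0.0)
        d2 = np.vstack([d2, -sxy[-1:, :]])
        if use_pml:
            p_sxx_x *= bxh[None, :]
            p_sxx_x += axh[None, :] * d1
            d1 = d1 + p_sxx_x
            p_sxy_y *= byi[:, None]
            p_sxy_y += ayi[:, None] * d2
            d2 = d2 + p_sxy_y
        vx += dt_h * bx * (d1 + d2)

        d1 = syy[1:, :] - syy[:-1, :]
        d2 = np.diff(sxy, axis=1, prepend=0.0)
        d2 = np.hstack([d2, -sxy[:, -1:]])
        if use_pml:
            p_syy_y *= byh[:, None]
            p_syy_y += ayh[:, None] * d1
            d1 = d1 + p_syy_y
            p_sxy_x *= bxi[None, :]
            p_sxy_x += axi[None, :] * d2
            d2 = d2 + p_sxy_x
        vy += dt_h * by * (d1 + d2)

        if record_energy:
            e_k = 0.5 * np.sum(rho_x * vx_prev * vx)
            e_k += 0.5 * np.sum(rho_y * vy_prev * vy)
            energy[n] = (e_k + e_s) * h * h

        # stress update (sigma: n -> n+1)
        dvx = np.hstack([vx[:, :1], np.diff(vx, axis=1), -vx[:, -1:]])
        dvy = np.vstack([vy[:1, :], np.diff(vy, axis=0), -vy[-1:, :]])
        if use_pml:
            p_vx_x *= bxi[None, :]
            p_vx_x += axi[None, :] * dvx
            dvx = dvx + p_vx_x
            p_vy_y *= byi[:, None]
            p_vy_y += ayi[:, None] * dvy
            dvy = dvy + p_vy_y
        sxx += dt_h * (c11 * dvx + c12 * dvy)
        syy += dt_h * (c12 * dvx + c11 * dvy)

        dxy1 = vx[1:, :] - vx[:-1, :]
        dxy2 = vy[:, 1:] - vy[:, :-1]
        if use_pml:
            p_vx_y *= byh[:, None]
            p_vx_y += ayh[:, None] * dxy1
            dxy1 = dxy1 + p_vx_y
            p_vy_x *= bxh[None, :]
            p_vy_x += axh[None, :] * dxy2
            dxy2 = dxy2 + p_vy_x
        sxy += dt_h * mu_xy * (dxy1 + dxy2)

        # pressure-source injection on the aperture
        if n < n_src and w[n] != 0.0:
            sxx[src_row, src_cols] -= src_gain * w[n] * src_scale
            syy[src_row, src_cols] -= src_gain * w[n] * src_scale

        p_rec = -(sxx[rec_rows, rec_cols] + syy[rec_rows, rec_cols]) / 2.0
        rec_buf[:, n] = p_rec

        if snap_every_steps is not None and (n + 1) % snap_every_steps == 0:
            p_full = -(sxx + syy) / 2.0
            if npml > 0:
                p_full = p_full[npml:-npml, npml:-npml]
            snapshots.append(p_full.copy())
            snap_times.append((n + 1) * dt)

        if (n + 1) % 100 == 0 or n == nt - 1:
            amp = float(np.max(np.abs(sxx)))
            if not math.isfinite(amp):
                raise InstabilityError(f"non-finite field at step {n + 1}")
            if src_peak > 0 and amp > 1e3 * src_peak:
                raise InstabilityError(
                    f"amplitude grew to {amp:.3g} (> 1e3 x source peak "
                    f"{src_peak:.3g}) at step {n + 1}"
                )

    records = {
        label: WaveformRecord(label=label, dt=dt, samples=rec_buf[i])
        for i, (label, _, _) in enumerate(rec_cells)
    }
    return SimulationRun(
        grid=grid,
        dt=dt,
        duration=duration,
        records=records,
        source=source,
        cfl=cfl,
        pml_cells=npml,
        snapshots=snapshots,
        snapshot_times=snap_times,
        energy=energy,
    )
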