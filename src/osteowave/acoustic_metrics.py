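"""Receiver-signal parameters: TOF_FAS, SPL and RMS, plus dose arithmetic.

Three quantities summarize each receiver's pressure record:

* ``TOF_FAS`` — time of flight of the first arriving signal.  The onset is
  the first sample whose absolute amplitude exceeds a threshold fraction
  of the record's own peak, refined to sub-sample precision by a parabola
  fitted through the five absolute-amplitude points centered on that
  crossing.
* ``SPL`` — sound pressure level ``20*log10(A_k / A_ref)`` in dB, peak
  amplitude of receiver k relative to the reference receiver (R1).
* ``RMS`` — root-mean-square amplitude over a fixed window (10.9 us by
  default) starting at the detected onset.

A vertical-ray travel-time oracle through the layer stack and the
duty-cycle arithmetic of pulsed therapeutic ultrasound (spatial-average
temporal-average intensity vs on-pulse intensity) round out the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elastic_fdtd import SimulationRun, WaveformRecord
from .fracture_geometry import LayerStack

__all__ = [
    "ReceiverMetrics",
    "DoseSpec",
    "NoArrivalError",
    "detect_fas",
    "spl",
    "rms",
    "layered_travel_time",
    "analyze_run",
    "sata_to_pulse_intensity",
]

US = 1e-6
DEFAULT_RMS_WINDOW = 10.9  # us
DEFAULT_THRESHOLD = 0.05  # fraction of the record's own peak


class NoArrivalError(ValueError):
    """Raised when a record never crosses the detection threshold."""


def detect_fas(record: WaveformRecord, threshold_fraction: float = DEFAULT_THRESHOLD) -> float:
    """Onset time (s) of the first arriving signal.

    The first sample with ``|a| >= threshold_fraction * max|a|`` anchors a
    parabola fitted by least squares to the five absolute-amplitude
    samples centered there; the onset is the parabola's threshold
    crossing, clamped to within one sample of the anchor.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    a = np.abs(record.samples)
    if len(a) == 0:
        raise NoArrivalError("empty record")
    peak = a.max()
    if peak <= 0.0:
        raise NoArrivalError("all-zero record")
    thr = threshold_fraction * peak
    above = np.nonzero(a >= thr)[0]
    if len(above) == 0:
        raise NoArrivalError("record never reaches the detection threshold")
    n0 = int(above[0])

    lo = max(n0 - 2, 0)
    hi = min(n0 + 3, len(a))
    xs = np.arange(lo, hi, dtype=float)
    ys = a[lo:hi]
    t_cross = float(n0)
    if len(xs) >= 3:
        # quadratic least squares through the five (or edge-clipped) points
        coef = np.polyfit(xs - n0, ys, 2)
        roots = np.roots(np.array([coef[0], coef[1], coef[2] - thr]))
        real = roots[np.abs(roots.imag) < 1e-9].real
        # earliest crossing within one sample of the anchor
        cand = real[(real >= -1.0) & (real <= 1.0)]
        if len(cand):
            t_cross = n0 + float(cand.min())
        elif n0 > 0 and a[n0 - 1] < thr <= a[n0]:
            # parabola misses the threshold: linear interpolation fallback
            frac = (thr - a[n0 - 1]) / (a[n0] - a[n0 - 1])
            t_cross = n0 - 1 + float(frac)
    t_cross = min(max(t_cross, n0 - 1.0), n0 + 1.0)
    return max(t_cross, 0.0) * record.dt


def spl(record_k: WaveformRecord, record_ref: WaveformRecord) -> float:
    """Peak sound pressure level of ``record_k`` in dB re the reference peak."""
    peak_ref = float(np.max(np.abs(record_ref.samples)))
    if peak_ref <= 0.0:
        raise ValueError("reference record has zero peak")
    peak_k = float(np.max(np.abs(record_k.samples)))
    if peak_k == 0.0:
        return float("-inf")
    return 20.0 * math.log10(peak_k / peak_ref)


def rms(record: WaveformRecord, fas: float, window: float = DEFAULT_RMS_WINDOW) -> float:
    """RMS amplitude over the samples in ``[fas, fas + window]`` (window in us)."""
    if window <= 0:
        raise ValueError("window must be positive")
    w_s = window * US
    n = len(record.samples)
    if fas + w_s > record.duration:
        warnings.warn(
            f"RMS window [{fas:.3g}, {fas + w_s:.3g}] s truncated to the "
            f"{record.duration:.3g}-s record",
            stacklevel=2,
        )
    i0 = int(math.ceil(fas / record.dt - 1e-9))
    i1 = int(math.floor((fas + w_s) / record.dt + 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, n - 1)
    if i1 < i0:
        raise ValueError("empty RMS window")
    seg = record.samples[i0 : i1 + 1]
    return float(np.sqrt(np.mean(seg * seg)))


def layered_travel_time(
    stack: LayerStack,
    depth: float,
    velocities: dict[str, float],
    through_gap: bool = True,
) -> float:
    """Vertical-ray travel time (s) from the surface to ``depth`` (mm).

    Sum of thickness/velocity over the layers crossed.  With
    ``through_gap=True`` the ray runs on the fracture axis, where the
    interrupted bone band is a single layer named ``gap``; its velocity
    is looked up under ``"gap"``, falling back to ``"bone marrow"``.
    """
    layers = stack.axis_layers() if through_gap else stack.layers
    if depth < 0 or depth > stack.total_thickness + 1e-9:
        raise ValueError(f"depth {depth} mm outside the stack")
    t = 0.0
    z = 0.0
    for name, th in layers:
        if name == "gap" and name not in velocities:
            name = "bone marrow"
        c = velocities[name]
        dz = min(th, depth - z)
        if dz <= 0:
            break
        t += (dz * 1e-3) / c
        z += th
        if z >= depth:
            break
    return t


@dataclass(frozen=True)
class ReceiverMetrics:
    """Per-receiver summary of one simulation."""

    label: str
    tof_fas: float  # s
    spl: float  # dB re reference receiver
    rms: float  # amplitude units of the record
    tof_comparable: bool = True  # False for the reference receiver R1


def analyze_run(
    run: SimulationRun,
    threshold_fraction: float = DEFAULT_THRESHOLD,
    rms_window: float = DEFAULT_RMS_WINDOW,
    reference: str = "R1",
) -> pd.DataFrame:
    """TOF_FAS, SPL and RMS for every receiver of a simulation.

    SPL is referenced to ``reference`` (R1, whose SPL is 0 dB by
    construction).  R1's own TOF is reported but flagged non-comparable:
    the reference receiver sits inside the source aperture, so its onset
    reflects the source switch-on rather than a propagation delay.
    """
    ref = run.records[reference]
    rows = []
    for label, rec in run.records.items():
        fas = detect_fas(rec, threshold_fraction)
        rows.append(
            {
                "receiver": label,
                "tof_fas_s": fas,
                "spl_db": spl(rec, ref),
                "rms": rms(rec, fas, rms_window),
                "tof_comparable": label != reference,
            }
        )
    df = pd.DataFrame(rows)
    order = {lbl: i for i, (lbl, _, _) in enumerate(run.grid.receiver_cells())}
    if order and set(df["receiver"]).issuperset(order):
        df["_o"] = df["receiver"].map(lambda x: order.get(x, len(order)))
        df = df.sort_values("_o").drop(columns="_o").reset_index(drop=True)
    return df


@dataclass(frozen=True)
class DoseSpec:
    """Pulsed-ultrasound dose: SATA intensity, duty cycle and pulse timing."""

    intensity_sata: float = 40.0  # mW/cm^2
    duty: float = 0.20  # fraction
    prf: float = 100.0  # Hz
    pulse_width: float = 0.002  # s
    frequency: float = 1.0  # MHz

    def __post_init__(self) -> None:
        if not (0.0 < self.duty <= 1.0):
            raise ValueError("duty cycle must lie in (0, 1]")
        if not math.isclose(self.duty, self.prf * self.pulse_width, rel_tol=1e-6):
            raise ValueError(
                f"duty {self.duty} != prf * pulse_width = {self.prf * self.pulse_width}"
            )


def sata_to_pulse_intensity(dose: DoseSpec) -> float:
    """On-pulse (temporal-peak-phase) intensity SATA / duty, mW/cm^2."""
    return dose.intensity_sata / dose.duty
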