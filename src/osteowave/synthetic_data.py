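"""Seeded generators for test fixtures with known ground truth.

Two families of fixtures:

* receiver-like waveforms — a Hann-windowed toneburst with a prescribed
  onset, amplitude and additive white noise, standing in for recorded
  pressure signals so onset detection can be validated against a known
  truth;
* animal-study tables — per-animal serum biochemistry drawn from group
  (mean, SD, n) specifications, and paired two-rater ordinal radiographic
  scores with a controllable inter-rater agreement probability.

Every generator is a pure function of its spec: the seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elastic_fdtd import WaveformRecord
from .experiment_stats import SCORE_RANGES

__all__ = ["SyntheticWaveformSpec", "SyntheticStudySpec", "make_toneburst", "make_study"]


@dataclass(frozen=True)
class SyntheticWaveformSpec:
    """Delayed noisy toneburst: onset/dt/duration in s, f0 in MHz."""

    onset: float = 5e-6
    f0: float = 1.0  # MHz
    cycles: int = 3
    amplitude: float = 1.0
    noise_sd: float = 0.0
    dt: float = 1e-8
    duration: float = 2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        burst = self.cycles / (self.f0 * 1e6)
        if self.onset < 0 or self.onset + burst > self.duration:
            raise ValueError("burst must fit inside [0, duration]")


def make_toneburst(spec: SyntheticWaveformSpec) -> tuple[WaveformRecord, float]:
    """Windowed sinusoid starting at ``spec.onset`` plus white noise.

    Returns the record together with the ground-truth onset time.
    Raises if ``dt`` violates the Nyquist limit for ``f0``.
    """
    f0_hz = spec.f0 * 1e6
    if spec.dt > 1.0 / (2.0 * f0_hz):
        raise ValueError(f"dt={spec.dt} exceeds the Nyquist limit for {spec.f0} MHz")
    n = int(round(spec.duration / spec.dt))
    t = np.arange(n) * spec.dt
    burst_len = spec.cycles / f0_hz
    tau = t - spec.onset
    active = (tau >= 0.0) & (tau <= burst_len)
    w = np.zeros(n)
    w[active] = (
        spec.amplitude
        * np.sin(2.0 * np.pi * f0_hz * tau[active])
        * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[active] / burst_len))
    )
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        w = w + rng.normal(0.0, spec.noise_sd, size=n)
    rec = WaveformRecord(label="synthetic", dt=spec.dt, samples=w)
    return rec, spec.onset


def _default_score_probs() -> dict[str, tuple[float, ...]]:
    # early-healing distributions: mostly low-to-mid periosteal/union
    # scores, remodeling rarely beyond the first stage
    return {
        "periosteal": (0.15, 0.40, 0.35, 0.10),
        "union": (0.20, 0.45, 0.25, 0.10),
        "remodeling": (0.70, 0.25, 0.05),
    }


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Two-group animal study: serum markers plus paired ordinal scores.

    Defaults mirror the published study's structure: a treated group
    (USG, n=8 retained samples) vs control (CG, n=7), alkaline
    phosphatase 86.38 +/- 18.94 vs 82.86 +/- 10.03 U/L, serum calcium
    9.90 +/- 0.35 vs 10.04 +/- 0.26 mg/dL, two blinded raters scoring
    three ordinal radiographic categories.
    """

    n_usg: int = 8
    n_cg: int = 7
    alp_usg: tuple[float, float] = (86.38, 18.94)  # (mean, sd) U/L
    alp_cg: tuple[float, float] = (82.86, 10.03)
    calcium_usg: tuple[float, float] = (9.90, 0.35)  # mg/dL
    calcium_cg: tuple[float, float] = (10.04, 0.26)
    score_probs_usg: dict[str, tuple[float, ...]] = field(default_factory=_default_score_probs)
    score_probs_cg: dict[str, tuple[float, ...]] = field(default_factory=_default_score_probs)
    rater_agreement: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rater_agreement <= 1.0):
            raise ValueError("rater_agreement must lie in [0, 1]")
        for probs in (self.score_probs_usg, self.score_probs_cg):
            for cat, p in probs.items():
                if cat not in SCORE_RANGES:
                    raise ValueError(f"unknown score category {cat!r}")
                if len(p) != SCORE_RANGES[cat] + 1:
                    raise ValueError(f"{cat} needs {SCORE_RANGES[cat] + 1} probabilities")
                if abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(f"{cat} probabilities must sum to 1")


def make_study(spec: SyntheticStudySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (biochemistry table, two-rater score table).

    Biochemical values are Gaussian per group.  Rater 1 draws each
    category from the group's probability table; rater 2 repeats rater
    1's score with probability ``rater_agreement`` and otherwise redraws
    from the same category distribution.
    """
    rng = np.random.default_rng(spec.seed)
    bio_rows = []
    score_rows = []
    groups = [
        ("USG", spec.n_usg, spec.alp_usg, spec.calcium_usg, spec.score_probs_usg),
        ("CG", spec.n_cg, spec.alp_cg, spec.calcium_cg, spec.score_probs_cg),
    ]
    animal = 0
    for group, n, alp, ca, probs in groups:
        for _ in range(n):
            animal += 1
            aid = f"A{animal:03d}"
            bio_rows.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "alp_u_per_l": rng.normal(*alp),
                    "calcium_mg_per_dl": rng.normal(*ca),
                }
            )
            r1 = {}
            r2 = {}
            for cat, p in probs.items():
                levels = np.arange(len(p))
                s1 = int(rng.choice(levels, p=p))
                if rng.random() < spec.rater_agreement:
                    s2 = s1
                else:
                    s2 = int(rng.choice(levels, p=p))
                r1[cat] = s1
                r2[cat] = s2
            for rater, scores in (("R1", r1), ("R2", r2)):
                score_rows.append(
                    {"animal_id": aid, "group": group, "rater": rater, **scores}
                )
    bio = pd.DataFrame(bio_rows)
    scores = pd.DataFrame(score_rows)
    scores["total"] = scores[list(SCORE_RANGES)].sum(axis=1)
    return bio, scores
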