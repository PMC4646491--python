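"""Enucleation time courses: control kinetics, drug effects, washout.

The vehicle-control culture enucleates roughly linearly after the sort
and plateaus around 70% by 6 h.  A compound modifies that curve
according to its mechanism:

* ``arrest`` — a constant fractional suppression that persists through
  the late (10 h) readout;
* ``delay`` — the same suppression at the 5 h readout, but decaying with
  a recovery halftime so the treated culture catches up to control;
* ``toxic`` / ``none`` — enucleation of surviving cells is unchanged.

Washout experiments release an arrested culture at the washout time,
after which it resumes enucleating at the control rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import CompoundProfile


@dataclass(frozen=True)
class KineticsTruth:
    """Control-curve parameters: linear rise to a plateau."""

    plateau: float = 0.70  # peak enucleation fraction
    t_plateau: float = 6.0  # h at which the plateau is reached
    readout_time: float = 5.0  # h; suppression is anchored at this readout

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau <= 1.0):
            raise ValueError("plateau must be in [0, 1]")
        if self.t_plateau <= 0:
            raise ValueError("t_plateau must be positive")

    @property
    def rate(self) -> float:
        """Linear rise rate (fraction / h)."""
        return self.plateau / self.t_plateau

    def control(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("timepoints must be non-negative")
        return np.minimum(self.rate * t, self.plateau)


def treated_curve(
    profile: CompoundProfile,
    timepoints: np.ndarray,
    kinetics: KineticsTruth,
    concentration_uM: float = 1.0,
) -> np.ndarray:
    """Noise-free treated enucleation fractions at the given timepoints."""
    t = np.asarray(timepoints, dtype=float)
    ctrl = kinetics.control(t)
    inhibition = profile.inhibition_at(concentration_uM)
    if profile.mechanism in ("none", "toxic") or inhibition == 0.0:
        return ctrl
    if profile.mechanism == "arrest":
        supp = np.full_like(t, inhibition)
    else:  # delay: suppression decays after the anchor readout
        dt = np.maximum(0.0, t - kinetics.readout_time)
        supp = inhibition * np.power(0.5, dt / profile.recovery_halftime)
    treated = (1.0 - supp) * ctrl
    # enucleation is irreversible, so the measured fraction cannot decrease
    return np.maximum.accumulate(treated)


def simulate_kinetics(
    profile: CompoundProfile,
    timepoints,
    kinetics: KineticsTruth | None = None,
    seed: int | np.random.Generator = 0,
    n_experiments: int = 3,
    noise_sd: float = 0.03,
    concentration_uM: float = 1.0,
) -> pd.DataFrame:
    """Simulate replicate enucleation time courses, treated vs control.

    Returns a tidy DataFrame: experiment, timepoint_h, arm
    ('treated' | 'control'), enucleation_pct.  Noise is per-experiment,
    per-timepoint Gaussian on the fraction scale, clipped to [0, 1].
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValueError("timepoints must be non-empty")
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    kinetics = KineticsTruth() if kinetics is None else kinetics
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctrl = kinetics.control(t)
    trt = treated_curve(profile, t, kinetics, concentration_uM)
    rows = []
    for exp in range(1, n_experiments + 1):
        for arm, clean in (("treated", trt), ("control", ctrl)):
            noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=t.size), 0.0, 1.0)
            for ti, v in zip(t, noisy):
                rows.append((exp, float(ti), arm, 100.0 * float(v)))
    return pd.DataFrame(rows, columns=["experiment", "timepoint_h", "arm", "enucleation_pct"])


def simulate_washout(
    profile: CompoundProfile,
    post_washout_timepoints=(0.5, 1.0, 3.0, 5.0),
    washout_time: float = 5.0,
    kinetics: KineticsTruth | None = None,
    seed: int | np.random.Generator = 0,
    n_experiments: int = 3,
    noise_sd: float = 0.03,
    concentration_uM: float = 1.0,
    reversible: bool = True,
) -> pd.DataFrame:
    """Simulate enucleation after compound washout.

    The culture is treated until ``washout_time``; afterwards a
    reversible compound's cells resume enucleating at the control rate
    (capped at the plateau), while an irreversible one stays at its
    suppressed level.  Control wells sit at / rise to the plateau.
    Returns the same tidy layout as :func:`simulate_kinetics`, with
    timepoints measured in hours after washout.
    """
    post = np.asarray(post_washout_timepoints, dtype=float)
    if post.size == 0:
        raise ValueError("need at least one post-washout timepoint")
    kinetics = KineticsTruth() if kinetics is None else kinetics
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = float(treated_curve(profile, np.array([washout_time]), kinetics, concentration_uM)[0])
    ctrl = kinetics.control(washout_time + post)
    if reversible:
        trt = np.minimum(start + kinetics.rate * post, kinetics.plateau)
    else:
        trt = np.full_like(post, start)
    rows = []
    for exp in range(1, n_experiments + 1):
        for arm, clean in (("treated", trt), ("control", ctrl)):
            noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=post.size), 0.0, 1.0)
            for ti, v in zip(post, noisy):
                rows.append((exp, float(ti), arm, 100.0 * float(v)))
    return pd.DataFrame(rows, columns=["experiment", "timepoint_h", "arm", "enucleation_pct"])


def simulate_dose_response(
    profile: CompoundProfile,
    concentrations_uM,
    kinetics: KineticsTruth | None = None,
    seed: int | np.random.Generator = 0,
    n_experiments: int = 3,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Simulate the 5 h enucleation readout across a concentration series."""
    conc = np.asarray(concentrations_uM, dtype=float)
    if conc.size == 0:
        raise ValueError("need at least one concentration")
    kinetics = KineticsTruth() if kinetics is None else kinetics
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = kinetics.control(np.array([kinetics.readout_time]))[0]
    clean = np.array([base * (1.0 - profile.inhibition_at(c)) for c in conc])
    rows = []
    for exp in range(1, n_experiments + 1):
        noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=conc.size), 0.0, 1.0)
        for c, v in zip(conc, noisy):
            rows.append((exp, float(c), 100.0 * float(v)))
    return pd.DataFrame(rows, columns=["experiment", "concentration_uM", "enucleation_pct"])
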