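"""Whole-cell K⁺ current prediction and IV analysis.

Predicts the whole-cell KV2.1 current density expected when only a
fraction f of the channels in the sarcolemma are conductive, by linearly
scaling a reference current-voltage (IV) relation computed at 100%
functional channels.  Also provides drug-subtraction (isolating the
blocker-sensitive current component) and IV extraction from voltage-step
recordings.

The reference densities at +50 mV built into :data:`MALE_REFERENCE_IV`
and :data:`FEMALE_REFERENCE_IV` are the 100%-functional model outputs for
male (7006 pA/pF) and female (17,293 pA/pF) arterial myocytes; the full
excitation model that produced them is not reimplemented here — only the
functional-fraction scaling layer is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ReferenceIV:
    """Current density (pA/pF) versus voltage at 100% functional channels."""

    voltages_mV: tuple[float, ...]
    current_density_pA_pF: tuple[float, ...]
    sex_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mV, dtype=float)
        if v.size != len(self.current_density_pA_pF):
            raise ValueError("voltages and densities must align")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("voltages must be strictly increasing")

    def density_at(self, voltage_mV: float) -> float:
        v = np.asarray(self.voltages_mV, dtype=float)
        idx = np.nonzero(np.isclose(v, voltage_mV))[0]
        if idx.size == 0:
            raise KeyError(f"no reference density at {voltage_mV} mV")
        return float(self.current_density_pA_pF[int(idx[0])])


#: Single-point reference IVs at +50 mV (100% functional channels).
MALE_REFERENCE_IV = ReferenceIV((50.0,), (7006.0,), sex_label="male")
FEMALE_REFERENCE_IV = ReferenceIV((50.0,), (17_293.0,), sex_label="female")


@dataclass
class FractionPrediction:
    """Linearly scaled IV at a functional fraction f.

    ``predicted_density`` holds the unrounded values; ``reported`` holds
    the values rounded to the printed precision (integer pA/pF at or
    above 100, one decimal below).
    """

    fraction_functional: float
    voltages_mV: tuple[float, ...]
    predicted_density: tuple[float, ...]
    reported: tuple[float, ...]


@dataclass
class StepRecording:
    """Current traces from a family of voltage steps sharing one time base."""

    time_ms: np.ndarray
    currents_pA: np.ndarray  # (n_samples, n_steps)
    voltages_mV: np.ndarray
    capacitance_pF: float
    holding_potential_mV: float = -70.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        if self.currents_pA.shape != (self.time_ms.size, self.voltages_mV.size):
            raise ValueError("currents must be (n_samples, n_steps)")
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")


def report_precision(value: float) -> float:
    """Round a density to its printed precision.

    Integer pA/pF for magnitudes of 100 or more, one decimal below.
    """
    if abs(value) >= 100:
        return float(round(value))
    return float(round(value, 1))


def scale_current(ref: ReferenceIV, fraction: float) -> FractionPrediction:
    """Scale a 100%-functional reference IV by a functional fraction.

    The prediction is linear in f at every voltage: halving the number of
    conductive channels halves the macroscopic current density.  Rounding
    to the printed precision happens only in the ``reported`` field.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    scaled = tuple(fraction * d for d in ref.current_density_pA_pF)
    return FractionPrediction(
        fraction_functional=fraction,
        voltages_mV=ref.voltages_mV,
        predicted_density=scaled,
        reported=tuple(report_precision(s) for s in scaled),
    )


def drug_subtraction(pre_drug: StepRecording, post_drug: StepRecording) -> StepRecording:
    """Blocker-sensitive current: pre-drug traces minus post-drug traces.

    Requires matched protocols (identical voltages and time base); the
    capacitance of the pre-drug recording is propagated so the result can
    be normalized to a density.
    """
    if not np.array_equal(pre_drug.voltages_mV, post_drug.voltages_mV):
        raise ValueError("voltage protocols do not match")
    if not np.allclose(pre_drug.time_ms, post_drug.time_ms):
        raise ValueError("time bases do not match")
    return StepRecording(
        time_ms=pre_drug.time_ms.copy(),
        currents_pA=pre_drug.currents_pA - post_drug.currents_pA,
        voltages_mV=pre_drug.voltages_mV.copy(),
        capacitance_pF=pre_drug.capacitance_pF,
        holding_potential_mV=pre_drug.holding_potential_mV,
    )


def build_iv(
    rec: StepRecording,
    window_ms: tuple[float, float] | None = None,
    junction_potential_mV: float = 0.0,
) -> ReferenceIV:
    """Current density versus voltage from a step recording.

    Per step, the current statistic is the mean over ``window_ms``
    (default: the final 50 ms of the trace) divided by the capacitance.
    An optional liquid-junction-potential correction offsets the voltage
    axis (13 mV for K⁺-based solutions, 9.4 mV for Ba²⁺, off by default).
    """
    t = rec.time_ms
    if window_ms is None:
        window_ms = (t[-1] - 50.0, t[-1])
    lo, hi = window_ms
    if lo < t[0] or hi > t[-1] or hi <= lo:
        raise ValueError(f"window {window_ms} is outside the trace [{t[0]}, {t[-1]}] ms")
    mask = (t >= lo) & (t <= hi)
    mean_current = rec.currents_pA[mask].mean(axis=0)
    density = mean_current / rec.capacitance_pF
    voltages = rec.voltages_mV - junction_potential_mV
    return ReferenceIV(tuple(voltages), tuple(density))


def boltzmann_conductance_currents(
    voltages_mV: np.ndarray,
    time_ms: np.ndarray,
    g_max_nS: float = 100.0,
    v_half_mV: float = 0.0,
    slope_mV: float = 10.0,
    reversal_mV: float = -80.0,
    rise_tau_ms: float = 20.0,
) -> np.ndarray:
    """Closed-form synthetic K⁺ currents for testing IV extraction.

    Boltzmann-activated conductance with a single-exponential rise:
    ``I(V, t) = g(V)·(V − E_rev)·(1 − exp(−t/τ))`` in pA.
    """
    voltages_mV = np.asarray(voltages_mV, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    g = g_max_nS / (1.0 + np.exp(-(voltages_mV - v_half_mV) / slope_mV))
    steady = g * (voltages_mV - reversal_mV)  # nS·mV = pA
    rise = 1.0 - np.exp(-time_ms / rise_tau_ms)
    return rise[:, None] * steady[None, :]
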