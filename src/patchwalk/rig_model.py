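"""Virtual patch-clamp rig: detection criteria, QC rules, and stimulus protocols.

Implements the quantitative decision rules an automated patcher applies while
walking a pipette onto a neuron:

* **Neuron hunting** — the pipette descends in 0.1 um steps while its
  resistance is monitored; a cumulative rise of 0.2 MOhm over a 5-step window
  signals contact with a soma.
* **Gigasealing** — the seal is formed once pipette resistance reaches
  1 GOhm; the rig then waits 5 s before attempting break-in.
* **Break-in** — short suction pulses (100-1000 ms at -345 mBar) rupture the
  membrane patch; success means resistance drops under 800 MOhm with a low
  holding current (|I| < 200 pA at -70 mV).
* **Recording QC** — a paired recording is included only if initial access
  resistance is below 40 MOhm, and aborted if access rises above 50 MOhm.

Stimulus protocols are built as pure data: the firing-pattern current-clamp
family (3 s pulses, -20 to +280 pA in 20 pA steps) and the connectivity test
(5 presynaptic action potentials at 20 Hz against a -70 mV voltage-clamped
postsynaptic cell, averaged over 3 sweeps, run in both directions).

Postsynaptic current waveforms are not synthesized; connectivity outcomes are
Boolean, mapped from the slice's latent ground truth through a detection
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ResistanceTrace",
    "DetectionThresholds",
    "QCRule",
    "StimulusProtocol",
    "ConnectivityProtocol",
    "QCResult",
    "detect_neuron",
    "gigaseal_reached",
    "breakin_success",
    "qc_evaluate",
    "build_firing_protocol",
    "build_whole_cell_current_clamp",
    "build_connectivity_stimulus",
    "measure_connection",
    "synth_hunt_trace",
]


@dataclass(frozen=True)
class ResistanceTrace:
    """Pipette resistance (MOhm) sampled at successive descending steps."""

    resistance_mohm: np.ndarray
    step_um: float = 0.1

    def __post_init__(self) -> None:
        r = np.asarray(self.resistance_mohm, dtype=float)
        if r.ndim != 1:
            raise ValueError("resistance trace must be 1-D")
        if len(r) and r.min() <= 0:
            raise ValueError("resistances must be positive")
        object.__setattr__(self, "resistance_mohm", r)

    def __len__(self) -> int:
        return len(self.resistance_mohm)


class DetectionThresholds(BaseModel):
    """All quantitative stage criteria of the automated patching pipeline."""

    hunt_delta_mohm: float = Field(default=0.2, gt=0)
    hunt_window_steps: int = Field(default=5, ge=1)
    hunt_step_um: float = Field(default=0.1, gt=0)
    gigaseal_r_mohm: float = Field(default=1000.0, gt=0)
    gigaseal_wait_s: float = Field(default=5.0, ge=0)
    breakin_r_max_mohm: float = Field(default=800.0, gt=0)
    holding_i_max_pa: float = Field(default=200.0, gt=0)  # magnitude bound at -70 mV
    breakin_pulse_min_ms: float = Field(default=100.0, gt=0)
    breakin_pulse_max_ms: float = Field(default=1000.0, gt=0)
    breakin_pressure_mbar: float = -345.0

    @model_validator(mode="after")
    def _check(self) -> "DetectionThresholds":
        if self.breakin_pulse_min_ms > self.breakin_pulse_max_ms:
            raise ValueError("break-in pulse range inverted")
        return self


class QCRule(BaseModel):
    """Access-resistance quality control for paired recordings."""

    access_include_max_mohm: float = Field(default=40.0, gt=0)
    access_abort_max_mohm: float = Field(default=50.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "QCRule":
        if self.access_include_max_mohm >= self.access_abort_max_mohm:
            raise ValueError("include threshold must be below abort threshold")
        return self


@dataclass(frozen=True)
class QCResult:
    include: bool
    abort_index: Optional[int]


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered current-clamp sweeps: (amplitude pA, duration s) plus a pre-step."""

    sweeps: tuple[tuple[float, float], ...]
    pre_step_pa: float = 0.0
    pre_step_duration_s: float = 0.0
    pre_step_lead_s: float = 0.0

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def amplitudes_pa(self) -> tuple[float, ...]:
        return tuple(a for a, _ in self.sweeps)


class ConnectivityProtocol(BaseModel):
    """Bidirectional paired connectivity test parameters."""

    n_pulses: int = Field(default=5, ge=1)
    pulse_rate_hz: float = Field(default=20.0, gt=0)
    post_holding_mv: float = -70.0
    n_sweeps: int = Field(default=3, ge=1)
    directions: int = 2

    @property
    def inter_pulse_interval_s(self) -> float:
        return 1.0 / self.pulse_rate_hz


def detect_neuron(
    trace: ResistanceTrace, thresholds: DetectionThresholds | None = None
) -> Optional[int]:
    """Earliest step index where resistance rose by the hunt delta over the window.

    Returns the first ``k`` with ``R[k] - R[k - window] >= delta``, or None if
    no window qualifies (including traces shorter than the window).
    """
    thr = thresholds or DetectionThresholds()
    r = trace.resistance_mohm
    w = thr.hunt_window_steps
    if len(r) <= w:
        return None
    rises = r[w:] - r[:-w]
    hits = np.nonzero(rises >= thr.hunt_delta_mohm)[0]
    return int(hits[0]) + w if len(hits) else None


def gigaseal_reached(r_mohm: float, thresholds: DetectionThresholds | None = None) -> bool:
    """True once seal resistance reaches the gigaseal threshold (1 GOhm)."""
    if r_mohm <= 0:
        raise ValueError("resistance must be positive")
    thr = thresholds or DetectionThresholds()
    return r_mohm >= thr.gigaseal_r_mohm


def breakin_success(
    r_mohm: float, i_hold_pa: float, thresholds: DetectionThresholds | None = None
) -> bool:
    """Whole-cell reached: resistance under 800 MOhm and holding current low.

    "Low" holding current is a magnitude bound: |I| < 200 pA at the -70 mV
    holding potential.
    """
    thr = thresholds or DetectionThresholds()
    return r_mohm < thr.breakin_r_max_mohm and abs(i_hold_pa) < thr.holding_i_max_pa


def qc_evaluate(access_series_mohm: Sequence[float], rule: QCRule | None = None) -> QCResult:
    """Include iff initial access < 40 MOhm; abort at first crossing above 50 MOhm."""
    rule = rule or QCRule()
    series = np.asarray(access_series_mohm, dtype=float)
    if series.size == 0:
        raise ValueError("access series must be non-empty")
    include = bool(series[0] < rule.access_include_max_mohm)
    above = np.nonzero(series > rule.access_abort_max_mohm)[0]
    return QCResult(include=include, abort_index=int(above[0]) if len(above) else None)


def build_firing_protocol() -> StimulusProtocol:
    """Firing-pattern family: 3 s pulses from -20 to +280 pA in 20 pA steps.

    Each of the 16 sweeps is preceded, 500 ms before pulse onset, by a 2 s
    -20 pA hyperpolarizing step.
    """
    amplitudes = np.arange(-20.0, 280.0 + 1e-9, 20.0)
    return StimulusProtocol(
        sweeps=tuple((float(a), 3.0) for a in amplitudes),
        pre_step_pa=-20.0,
        pre_step_duration_s=2.0,
        pre_step_lead_s=0.5,
    )


def build_whole_cell_current_clamp() -> StimulusProtocol:
    """Single-sweep whole-cell check: 0 pA 1 s, -300..+300 pA step 1 s, 0 pA 1 s.

    Represented as the three segments of one sweep; the step amplitude is the
    range endpoint pair encoded as separate sweeps at -300 and +300 pA.
    """
    return StimulusProtocol(
        sweeps=((0.0, 1.0), (-300.0, 1.0), (300.0, 1.0), (0.0, 1.0)),
    )


def build_connectivity_stimulus(protocol: ConnectivityProtocol | None = None) -> dict:
    """Describe the paired connectivity test as plain data (JSON-exportable).

    Five presynaptic pulses at 20 Hz (50 ms apart), postsynaptic cell
    voltage-clamped at -70 mV; two directed runs per pair, three sweeps each.
    """
    proto = protocol or ConnectivityProtocol()
    ipi = proto.inter_pulse_interval_s
    return {
        "pulse_onsets_s": [round(i * ipi, 9) for i in range(proto.n_pulses)],
        "n_pulses": proto.n_pulses,
        "pulse_rate_hz": proto.pulse_rate_hz,
        "post_holding_mv": proto.post_holding_mv,
        "n_sweeps": proto.n_sweeps,
        "directions": proto.directions,
    }


def measure_connection(
    pre_index: int,
    post_index: int,
    ground_truth,
    detect_prob: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> bool:
    """Outcome of one directed connectivity test against the latent truth.

    Reports connected iff the ground truth holds AND a Bernoulli(detect_prob)
    draw succeeds — detect_prob models missed weak synapses; the default 1
    means a probed true connection is always found.
    """
    if not (0 <= detect_prob <= 1):
        raise ValueError("detect_prob must be in [0, 1]")
    truth = ground_truth.is_connected(pre_index, post_index)
    if not truth:
        return False
    if detect_prob >= 1.0:
        return True
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return bool(gen.random() < detect_prob)


def synth_hunt_trace(
    neuron_at_step: Optional[int],
    baseline_r_mohm: float = 5.0,
    noise_sd_mohm: float = 0.0,
    seed: int | np.random.Generator = 0,
    thresholds: DetectionThresholds | None = None,
    n_steps: int = 60,
) -> ResistanceTrace:
    """Synthesize a neuron-hunting resistance trace.

    Flat (noisy) baseline; from ``neuron_at_step`` the resistance climbs at
    1.2x the detection slope (contact pushes resistance past the threshold
    rate, as on a real descent onto a soma) and plateaus at twice the hunt
    delta above baseline.  With zero noise :func:`detect_neuron` fires exactly
    at ``neuron_at_step + window - 1``: one step earlier the windowed rise is
    only 0.8x the delta.  ``neuron_at_step=None`` produces a pure baseline
    with no neuron.
    """
    if baseline_r_mohm <= 0:
        raise ValueError("baseline resistance must be positive")
    if noise_sd_mohm < 0:
        raise ValueError("noise SD must be non-negative")
    thr = thresholds or DetectionThresholds()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r = np.full(n_steps, baseline_r_mohm, dtype=float)
    if neuron_at_step is not None:
        if not (0 <= neuron_at_step < n_steps):
            raise ValueError("neuron_at_step out of range")
        w = thr.hunt_window_steps
        slope = 1.2 * thr.hunt_delta_mohm / w
        for i in range(neuron_at_step, n_steps):
            rise = slope * (i - neuron_at_step + 1)
            r[i] = baseline_r_mohm + min(rise, 2.0 * thr.hunt_delta_mohm)
    if noise_sd_mohm > 0:
        r = r + rng.normal(0.0, noise_sd_mohm, size=n_steps)
        r = np.maximum(r, 1e-3)
    return ResistanceTrace(resistance_mohm=r, step_um=thr.hunt_step_um)
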