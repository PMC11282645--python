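"""Synthesis of the oscillatory CSF flow waveform.

CSF in the spinal subarachnoid space oscillates in synchrony with the
cardiac and respiratory cycles with nearly zero net flow.  The driving
waveform used throughout this package is a superposition of a cardiac
component (a skewed two-harmonic pulse standing in for a cervical
phase-contrast MRI measurement) and a slower sinusoidal respiratory
component whose amplitude and frequency are fixed ratios of the cardiac
ones.  The combined waveform is normalized so that its stroke volume (the
fluid volume displaced per cardiac cycle) matches a target value.

Defaults model an adult cynomolgus monkey: heart rate 120 bpm,
respiratory amplitude 0.52 and frequency 1/4.29 of cardiac (about
28 breaths/min), and a stroke volume of 0.2597 ml.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "FlowWaveform",
    "WaveformConfig",
    "cardiac_component",
    "combined_waveform",
    "stroke_volume",
    "waveform_rmse",
]

#: tolerated residual net flow after zero-mean enforcement, ml/s
NET_FLOW_TOL = 1e-6


@dataclass(frozen=True)
class FlowWaveform:
    """A uniformly sampled CSF flow-rate record Q(t).

    Attributes
    ----------
    t : ndarray
        Sample times in s, uniformly spaced.
    q : ndarray
        Flow rate in ml/s (positive = cranially directed).
    cardiac_period : float
        Cardiac cycle length in s.
    respiratory_period : float
        Respiratory cycle length in s (equals ``cardiac_period`` times the
        frequency ratio; NaN for a cardiac-only record is not used —
        cardiac-only records carry the configured ratio anyway).
    """

    t: np.ndarray
    q: np.ndarray
    cardiac_period: float
    respiratory_period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        if t.shape != q.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("t and q must be 1D arrays of equal length >= 2")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("waveform must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "q_ml_per_s": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cardiac_period: float, respiratory_period: float):
        df = pd.read_csv(path)
        return cls(
            t=df["t_s"].to_numpy(float),
            q=df["q_ml_per_s"].to_numpy(float),
            cardiac_period=cardiac_period,
            respiratory_period=respiratory_period,
        )


@dataclass(frozen=True)
class WaveformConfig:
    """Parameters of the synthesized CSF flow waveform.

    ``cardiac_template`` is either the name of a built-in parametric shape
    ("two_harmonic" or "sinusoid") or a sampled one-period flow series
    (array-like) which is resampled onto the cardiac period and mean-removed.
    """

    heart_rate_bpm: float = 120.0
    amplitude_ratio: float = 0.52
    frequency_ratio: float = 4.29
    target_stroke_volume_ml: float = 0.2597
    sample_rate_hz: float = 200.0
    duration_s: float = 60.0
    cardiac_template: str | np.ndarray = "two_harmonic"

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude_ratio must be non-negative")
        for name in ("frequency_ratio", "target_stroke_volume_ml",
                     "sample_rate_hz", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cardiac_period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def respiratory_period_s(self) -> float:
        return self.cardiac_period_s * self.frequency_ratio


def _two_harmonic_shape(phase: np.ndarray) -> np.ndarray:
    # Systolic-skewed pulse: fundamental plus a 0.3-weight second harmonic.
    return np.sin(2 * np.pi * phase) + 0.3 * np.sin(4 * np.pi * phase + 0.6)


_TEMPLATES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "two_harmonic": _two_harmonic_shape,
    "sinusoid": lambda phase: np.sin(2 * np.pi * phase),
}


def _time_grid(config: WaveformConfig) -> np.ndarray:
    n = int(round(config.duration_s * config.sample_rate_hz)) + 1
    return np.arange(n) / config.sample_rate_hz


def cardiac_component(config: WaveformConfig) -> FlowWaveform:
    """Zero-mean periodic cardiac flow component at unit peak amplitude.

    The shape is either a built-in parametric template or a user-supplied
    sampled series covering one period, which is periodically interpolated
    onto the output grid after mean removal.
    """
    t = _time_grid(config)
    period = config.cardiac_period_s
    phase = (t / period) % 1.0
    if isinstance(config.cardiac_template, str):
        try:
            shape = _TEMPLATES[config.cardiac_template]
        except KeyError:
            raise ValueError(
                f"unknown cardiac template {config.cardiac_template!r}; "
                f"available: {sorted(_TEMPLATES)}"
            ) from None
        q = shape(phase)
    else:
        samples = np.asarray(config.cardiac_template, dtype=float)
        if samples.ndim != 1 or samples.size < 3:
            raise ValueError("sampled cardiac template must be 1D with >= 3 points")
        sample_phase = np.arange(samples.size) / samples.size
        # periodic linear interpolation over one cycle
        q = np.interp(phase, np.append(sample_phase, 1.0),
                      np.append(samples, samples[0]))
    q = q - np.mean(q)
    amp = np.max(np.abs(q))
    if amp == 0:
        raise ValueError("cardiac template has zero amplitude")
    return FlowWaveform(
        t=t,
        q=q / amp,
        cardiac_period=period,
        respiratory_period=config.respiratory_period_s,
    )


def combined_waveform(config: WaveformConfig | None = None) -> FlowWaveform:
    """Cardiac + respiratory CSF waveform normalized to the target stroke volume.

    The respiratory component is a sinusoid with amplitude
    ``amplitude_ratio`` times the cardiac peak amplitude and frequency
    ``1/frequency_ratio`` times cardiac.  The superposition is mean-removed
    and rescaled so that ``stroke_volume`` of the result equals
    ``target_stroke_volume_ml`` (scaling preserves the zero mean).
    """
    cfg = config or WaveformConfig()
    card = cardiac_component(cfg)
    resp_amp = cfg.amplitude_ratio * np.max(np.abs(card.q))
    resp = resp_amp * np.sin(2 * np.pi * card.t / cfg.respiratory_period_s)
    if cfg.amplitude_ratio == 0:
        # keep bit-identity with a rescaled cardiac component; its residual
        # mean after periodic mean removal is already far below NET_FLOW_TOL
        q = card.q
    else:
        q = card.q + resp
        q = q - np.mean(q)
    w = FlowWaveform(
        t=card.t,
        q=q,
        cardiac_period=cfg.cardiac_period_s,
        respiratory_period=cfg.respiratory_period_s,
    )
    sv = stroke_volume(w)
    if sv <= 0:
        raise ValueError("cannot normalize a waveform with zero stroke volume")
    w = replace(w, q=w.q * (cfg.target_stroke_volume_ml / sv))
    residual = np.mean(w.q)
    if abs(residual) > NET_FLOW_TOL:  # pragma: no cover - safety net
        w = replace(w, q=w.q - residual)
    return w


def stroke_volume(w: FlowWaveform) -> float:
    """Stroke volume in ml: mean per-cycle integral of the positive flow.

    The record is cut into whole cardiac cycles; within each cycle the
    positive part of Q is integrated by the trapezoidal rule, and the
    per-cycle volumes are averaged.  Requires at least one full cycle.
    """
    samples_per_cycle = w.cardiac_period / w.dt
    n_cycles = int(np.floor((w.t.size - 1) / samples_per_cycle))
    if n_cycles < 1:
        raise ValueError("record shorter than one cardiac period")
    q_pos = np.clip(w.q, 0.0, None)
    vols = []
    for k in range(n_cycles):
        i0 = int(round(k * samples_per_cycle))
        i1 = int(round((k + 1) * samples_per_cycle))
        vols.append(np.trapezoid(q_pos[i0 : i1 + 1], w.t[i0 : i1 + 1]))
    return float(np.mean(vols))


def waveform_rmse(a: FlowWaveform, b: FlowWaveform) -> float:
    """Root-mean-square difference between two records on the same grid, ml/s."""
    if a.t.shape != b.t.shape or not np.allclose(a.t, b.t):
        raise ValueError("waveforms are not on the same time grid")
    return float(np.sqrt(np.mean((a.q - b.q) ** 2)))
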