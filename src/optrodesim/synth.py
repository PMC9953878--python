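"""Synthetic paired LFP / photometry sessions with DBS-evoked structure.

Generates 40-s sessions (10 s baseline, 20 s stimulation at 3 Hz, 10 s
rest) whose statistical structure mirrors in vivo thalamic-DBS recordings:

* LFP (1 kHz): Gaussian background noise; at every stimulation pulse a
  brief biphasic artifact followed, after a short latency, by an
  exponentially decaying evoked deflection whose amplitude grows with the
  stimulation current.
* Photometry: flat baseline F0 with a delayed saturating calcium response —
  the fractional change rises with GCaMP-like kinetics starting
  ``fluorescence_onset_delay_s`` (default 5 s) after stimulation onset,
  plateaus at ``dff_amplitude``, and decays after stimulation ends.

Everything is seeded and deterministic; amplitudes, kinetics and noise
levels are all configuration fields.  These are phenomenological kernels,
not biophysical neuron/indicator models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dosimetry import StimulationProtocol
from .grid import InvalidParameterError
from .signals import TimeSeries

#: The four stimulation intensities of the standard dose-response protocol.
DEFAULT_CURRENTS_UA = (50.0, 100.0, 200.0, 300.0)


@dataclass(frozen=True)
class SessionSpec:
    """Full parameterization of one synthetic session.

    Times are seconds.  The evoked kernel is
    ``-amplitude * exp(-(t - latency)/decay_tau)`` for t >= latency after
    each pulse (negative-going deflection, as evoked LFPs typically are;
    the sum-LFP statistic uses magnitudes so the sign is conventional).
    The stimulation artifact is a one-sample-per-phase biphasic spike.
    """

    protocol: StimulationProtocol = field(
        default_factory=lambda: StimulationProtocol(current_a=100e-6))
    duration_s: float = 40.0
    baseline_s: tuple[float, float] = (0.0, 10.0)
    stimulation_s: tuple[float, float] = (10.0, 30.0)
    lfp_rate_hz: float = 1000.0
    photometry_rate_hz: float = 1000.0
    evoked_amplitude_v: float = 100e-6
    evoked_latency_s: float = 5e-3
    evoked_decay_tau_s: float = 8e-3
    artifact_amplitude_v: float = 500e-6
    lfp_noise_sd_v: float = 20e-6
    f0: float = 1.0
    dff_amplitude: float = 0.1
    gcamp_rise_tau_s: float = 1.5
    gcamp_decay_tau_s: float = 3.0
    fluorescence_onset_delay_s: float = 5.0
    photometry_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.baseline_s[0] < self.baseline_s[1] <= self.stimulation_s[0]
                < self.stimulation_s[1] <= self.duration_s):
            raise InvalidParameterError("segment boundaries must be ordered")
        for tau in (self.evoked_decay_tau_s, self.gcamp_rise_tau_s, self.gcamp_decay_tau_s):
            if tau <= 0:
                raise InvalidParameterError("time constants must be positive")
        if self.lfp_rate_hz <= 0 or self.photometry_rate_hz <= 0:
            raise InvalidParameterError("sampling rates must be positive")
        if self.f0 <= 0:
            raise InvalidParameterError("baseline fluorescence F0 must be positive")

    def pulse_times_s(self) -> np.ndarray:
        """Stimulus pulse onsets: 1/frequency spacing from stimulation start."""
        t0, t1 = self.stimulation_s
        f = self.protocol.frequency_hz
        if f <= 0:
            return np.empty(0)
        n = int(np.floor((t1 - t0) * f + 1e-9))
        return t0 + np.arange(n) / f


def gen_lfp(spec: SessionSpec) -> TimeSeries:
    """Synthesize the LFP channel of a session."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.lfp_rate_hz))
    rate = spec.lfp_rate_hz
    x = rng.normal(0.0, spec.lfp_noise_sd_v, n) if spec.lfp_noise_sd_v > 0 else np.zeros(n)

    kernel_len = int(round(min(0.3, 1.0 / max(spec.protocol.frequency_hz, 1e-9)) * rate))
    tk = np.arange(kernel_len) / rate
    evoked = np.where(tk >= spec.evoked_latency_s,
                      -spec.evoked_amplitude_v
                      * np.exp(-(tk - spec.evoked_latency_s) / spec.evoked_decay_tau_s),
                      0.0)
    for tp in spec.pulse_times_s():
        i0 = int(round(tp * rate))
        if i0 >= n:
            continue
        stop = min(n, i0 + kernel_len)
        x[i0:stop] += evoked[:stop - i0]
        x[i0] += spec.artifact_amplitude_v
        if i0 + 1 < n:
            x[i0 + 1] -= spec.artifact_amplitude_v
    return TimeSeries(samples=x, rate_hz=rate, channel_label="lfp")


def photometry_response_shape(spec: SessionSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free fractional response s(t) in [0, 1] (plateau = 1).

    Zero until ``onset_delay`` after stimulation start; then a saturating
    exponential rise with ``gcamp_rise_tau``; after stimulation end the
    response decays with ``gcamp_decay_tau`` from its end-of-train value.
    """
    t_on = spec.stimulation_s[0] + spec.fluorescence_onset_delay_s
    t_off = spec.stimulation_s[1]
    s = np.zeros_like(t)
    rising = (t >= t_on) & (t < t_off)
    s[rising] = 1.0 - np.exp(-(t[rising] - t_on) / spec.gcamp_rise_tau_s)
    if t_off > t_on:
        s_end = 1.0 - np.exp(-(t_off - t_on) / spec.gcamp_rise_tau_s)
    else:
        s_end = 0.0
    after = t >= t_off
    s[after] = s_end * np.exp(-(t[after] - t_off) / spec.gcamp_decay_tau_s)
    return s


def gen_photometry(spec: SessionSpec) -> TimeSeries:
    """Synthesize the photometry channel of a session."""
    # independent noise stream from the LFP channel of the same session
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    n = int(round(spec.duration_s * spec.photometry_rate_hz))
    t = np.arange(n) / spec.photometry_rate_hz
    s = photometry_response_shape(spec, t)
    f = spec.f0 * (1.0 + spec.dff_amplitude * s)
    if spec.photometry_noise_sd > 0:
        f = f + rng.normal(0.0, spec.photometry_noise_sd, n)
    return TimeSeries(samples=f, rate_hz=spec.photometry_rate_hz,
                      channel_label="photometry")


@dataclass(frozen=True)
class Session:
    """One paired synthetic recording and the spec that produced it."""

    spec: SessionSpec
    lfp: TimeSeries
    photometry: TimeSeries


def gen_session(spec: SessionSpec) -> Session:
    return Session(spec=spec, lfp=gen_lfp(spec), photometry=gen_photometry(spec))


def linear_response(current_a: float,
                    evoked_v_per_a: float = 1.0,
                    dff_per_a: float = 1000.0) -> tuple[float, float]:
    """Default dose-response: evoked LFP and dF/F amplitudes linear in current.

    Defaults give 50-300 uV evoked deflections and dF/F plateaus of
    0.05-0.3 across the 50-300 uA protocol range.
    """
    return evoked_v_per_a * current_a, dff_per_a * current_a


def gen_session_set(currents_ua=DEFAULT_CURRENTS_UA, seed: int = 0,
                    base_spec: SessionSpec | None = None,
                    response_model=linear_response) -> list[Session]:
    """One paired session per stimulation current.

    ``response_model(current_a) -> (evoked_amplitude_v, dff_amplitude)``
    sets the per-session amplitudes (default linear in current).  The
    stimulation artifact also scales linearly with current.  Per-session
    seeds derive deterministically from the master seed.
    """
    currents_ua = list(currents_ua)
    if len(currents_ua) < 2:
        raise InvalidParameterError("need at least two stimulation currents")
    base = base_spec if base_spec is not None else SessionSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(currents_ua)) % (2**31)
    sessions = []
    for c_ua, s in zip(currents_ua, child_seeds):
        current_a = c_ua * 1e-6
        evoked_v, dff_amp = response_model(current_a)
        artifact_v = base.artifact_amplitude_v * (current_a / 100e-6)
        spec = replace(base,
                       protocol=replace(base.protocol, current_a=current_a),
                       evoked_amplitude_v=evoked_v, dff_amplitude=dff_amp,
                       artifact_amplitude_v=artifact_v, seed=int(s))
        sessions.append(gen_session(spec))
    return sessions
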