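"""Presynaptic glutamate pulse train.

The stimulation signal is the model's only time-varying input: a periodic
rectangular pulse train of synaptic glutamate.  The standard protocol is
5 Hz, 4 ms pulses of 0.2 mM for 10 s.  Pulses are rectangular, the first
pulse starts at t = 0, and pulse membership uses half-open intervals
[onset, onset + width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputDomainError, ParameterError


@dataclass
class StimulusProtocol:
    """Periodic glutamate pulse train.

    Parameters
    ----------
    frequency : float
        Pulse rate in Hz.
    pulse_width : float
        Duration of each pulse in ms; must not exceed the period.
    amplitude : float
        Glutamate concentration during a pulse (mM).
    duration : float
        Total stimulation time in seconds; the signal is zero afterwards.
    """

    frequency: float = 5.0
    pulse_width: float = 4.0
    amplitude: float = 0.2
    duration: float = 10.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.frequency > 0:
            raise ParameterError("frequency must be > 0")
        if not self.pulse_width > 0:
            raise ParameterError("pulse_width must be > 0")
        if self.pulse_width > 1000.0 / self.frequency:
            raise ParameterError(
                "pulse_width must not exceed the period (pulses must not overlap)")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if not self.duration > 0:
            raise ParameterError("duration must be > 0")

    @property
    def period(self) -> float:
        """Pulse period in ms."""
        return 1000.0 / self.frequency

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration

    def replace(self, **kw) -> "StimulusProtocol":
        d = dict(frequency=self.frequency, pulse_width=self.pulse_width,
                 amplitude=self.amplitude, duration=self.duration)
        d.update(kw)
        return StimulusProtocol(**d)


def glutamate_at(protocol: StimulusProtocol, t):
    """Glutamate concentration (mM) at time ``t`` (ms).

    Accepts a scalar or an array; negative times are an input-domain error.
    The signal equals ``amplitude`` while ``t mod period`` lies in
    ``[0, pulse_width)`` and ``t`` is within the stimulation window, else 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InputDomainError("time must be non-negative")
    phase = np.mod(t_arr, protocol.period)
    on = (phase < protocol.pulse_width) & (t_arr < protocol.duration_ms)
    out = np.where(on, protocol.amplitude, 0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def pulse_onsets(protocol: StimulusProtocol) -> np.ndarray:
    """Onset times (ms) of all pulses within the stimulation window."""
    n = int(np.ceil(protocol.duration_ms / protocol.period))
    onsets = np.arange(n) * protocol.period
    return onsets[onsets < protocol.duration_ms]
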