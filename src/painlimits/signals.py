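"""Force-signal conditioning for algometer and pendulum trials.

The raw load-cell signal of a trial is filtered with a zero-phase
Butterworth low-pass of the appropriate channel frequency class (CFC),
its baseline offset is removed so the force is zero at initial contact,
and -- for pendulum impacts -- the reading is scaled by the inertia
factor that accounts for the contact-body mass in front of the load
cell.  The trial's measurand is then the maximum contact force: the
largest Euclidean norm over time for impacts, or the force at the
subject's switch press for the quasi-static algometer ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import InvalidArgumentError, MissingEventError, NoContactError

#: -3 dB cutoff in Hz per channel-class unit (automotive channel-class
#: convention: CFC n -> 1.65 n Hz)
CFC_CUTOFF_FACTOR = 1.65

#: channel classes used by the two instruments
CFC_CLASSES = {"CFC1": 1.0, "CFC100": 100.0}

#: contact-onset detector: threshold floor in N and sustained-run length
ONSET_FLOOR_N = 0.5
ONSET_SD_MULTIPLE = 5.0
ONSET_SUSTAIN_SAMPLES = 5


@dataclass
class ForceSignal:
    """A uniformly sampled force recording of one load test.

    ``values`` has shape (n_samples, n_axes) with n_axes 1 (algometer)
    or 3 (pendulum).  ``event_index`` marks the switch press in
    algometer trials.  ``m_b``/``m_i`` are the pendulum-body and
    contact-body masses needed for inertia compensation.
    """

    time: np.ndarray
    values: np.ndarray
    sampling_rate: float
    event_index: int | None = None
    m_b: float | None = None
    m_i: float | None = None
    onset_index: int | None = None
    filtered: bool = False
    offset_removed: bool = False
    inertia_compensated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.values.shape[1] > 3:
            self.values = self.values.T
        if self.values.shape[1] not in (1, 3):
            raise InvalidArgumentError("force signals must have 1 or 3 axes")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_axes(self) -> int:
        return self.values.shape[1]

    def norm(self) -> np.ndarray:
        """Euclidean norm of the force over the axes, per sample."""
        return np.linalg.norm(self.values, axis=1)

    def copy(self) -> "ForceSignal":
        return replace(self, values=self.values.copy(), meta=dict(self.meta))


def cfc_filter(signal: ForceSignal, cfc_class: str) -> ForceSignal:
    """Apply a zero-phase, net fourth-order Butterworth low-pass.

    The -3 dB cutoff is 1.65x the channel-class value (CFC1 -> 1.65 Hz,
    CFC100 -> 165 Hz), realized as a second-order design run forward and
    backward over the signal (reflect padding), which doubles the order
    and cancels the phase.
    """
    if cfc_class not in CFC_CLASSES:
        raise InvalidArgumentError(
            f"unknown channel class {cfc_class!r}; expected one of {sorted(CFC_CLASSES)}"
        )
    fc = CFC_CUTOFF_FACTOR * CFC_CLASSES[cfc_class]
    nyquist = signal.sampling_rate / 2.0
    if fc >= nyquist:
        raise InvalidArgumentError(
            f"cutoff {fc} Hz is not below the Nyquist frequency {nyquist} Hz"
        )
    if signal.n_samples < 40:
        raise InvalidArgumentError("signal too short for a stable filter pass")
    b, a = butter(2, fc / nyquist)
    out = signal.copy()
    out.values = filtfilt(b, a, signal.values, axis=0, padtype="even")
    out.filtered = True
    return out


def eliminate_offset(signal: ForceSignal, baseline_window: float) -> ForceSignal:
    """Remove the baseline offset and locate the contact onset.

    The per-axis mean over the leading ``baseline_window`` seconds is
    subtracted.  The onset is the last sample at or below the detection
    threshold before the force norm first exceeds it for
    ``ONSET_SUSTAIN_SAMPLES`` consecutive samples; the threshold is
    ``max(5 x baseline sd, 0.5 N)``.
    """
    n_base = int(round(baseline_window * signal.sampling_rate))
    if n_base < 2 or n_base >= signal.n_samples:
        raise InvalidArgumentError("baseline window must precede the contact")
    out = signal.copy()
    baseline = signal.values[:n_base]
    out.values = signal.values - baseline.mean(axis=0)
    sd = float(np.linalg.norm(baseline.std(axis=0)))
    threshold = max(ONSET_SD_MULTIPLE * sd, ONSET_FLOOR_N)

    norm = out.norm()
    above = norm > threshold
    run = np.convolve(above.astype(int), np.ones(ONSET_SUSTAIN_SAMPLES, int),
                      mode="valid")
    hits = np.nonzero(run == ONSET_SUSTAIN_SAMPLES)[0]
    hits = hits[hits >= n_base - 1] if hits.size else hits
    if hits.size == 0:
        raise NoContactError("no contact onset found above the detection threshold")
    first_above = int(hits[0])
    # the sustained crossing lags the true contact by the rise time to the
    # threshold; backtrack to where the signal last sat at the noise floor
    floor = max(sd, 0.1)
    i = first_above
    while i > 0 and norm[i - 1] > floor:
        i -= 1
    out.onset_index = max(i - 1, 0)
    out.offset_removed = True
    return out


def compensate_inertia(signal: ForceSignal) -> ForceSignal:
    """Scale the measured force by ``V_f = 1 + m_i / m_b``.

    The load cell sits between the pendulum body (mass ``m_b``) and the
    contact body (mass ``m_i``); during an impact it only senses the
    pendulum-body share, so the contact-tip force is the reading times
    ``V_f``.  Guarded against double application.
    """
    if signal.inertia_compensated:
        raise InvalidArgumentError("inertia compensation already applied")
    if signal.m_b is None or signal.m_i is None:
        raise InvalidArgumentError("m_b and m_i are required for inertia compensation")
    if signal.m_b <= 0 or signal.m_i < 0:
        raise InvalidArgumentError("masses must be positive (m_i may be zero)")
    out = signal.copy()
    out.values = signal.values * (1.0 + signal.m_i / signal.m_b)
    out.inertia_compensated = True
    return out


def max_contact_force(signal: ForceSignal, mode: str) -> float:
    """Extract the trial's maximum contact force in N.

    ``mode="impact"``: maximum over time of the force norm.
    ``mode="algometer"``: maximum restricted to samples up to the
    switch-press event, i.e. the force that evoked the painful feeling.
    """
    if mode not in ("impact", "algometer"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    norm = signal.norm()
    if mode == "algometer":
        if signal.event_index is None:
            raise MissingEventError("algometer mode requires an event index")
        norm = norm[: signal.event_index + 1]
        if norm.size == 0:
            raise MissingEventError("event index precedes the first sample")
    return float(norm.max())
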