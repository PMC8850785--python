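"""Synthetic trial generator with known ground-truth pain thresholds.

The raw human-subject recordings behind the published limit tables are
not public.  This module generates statistically equivalent stand-ins:
subject rosters, quasi-static algometer ramps, stepped pendulum-impact
staircases, and pressure-film frame stacks, all driven by the expanded
log-logistic threshold law

    y = exp(beta0 + g*beta1 + alpha*log(U/(1-U))),   U ~ Uniform(0,1),

so every downstream stage (signal conditioning, censoring, model
fitting, limit tables) can be tested against known truth.

The tissue under load is modelled as a linear spring with stiffness
``c_H`` and additive Gaussian force noise; under that model the peak
force of a pendulum impact is ``sqrt(m_P * c_H) * v_P``.  This is a
deliberate simplification -- no viscoelasticity, no hyper-elastic
stiffening -- adequate for exercising the statistical pipeline, not for
predicting tissue response.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .errors import InvalidArgumentError, SimulationLimitError
from .pressure import FILM_BITS, FILM_RANGE, FilmGeometry, PressureFrame
from .signals import ForceSignal


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ThresholdSpec:
    """Ground-truth threshold distribution for one location x condition."""

    body_location_id: int
    load_type: str
    contact_type: str
    beta0: float
    beta1: float
    alpha: float

    def __post_init__(self) -> None:
        if not 1 <= self.body_location_id <= 29:
            raise InvalidArgumentError("body location id must be in 1..29")
        if self.load_type not in reference.LOAD_TYPES:
            raise InvalidArgumentError(f"unknown load type {self.load_type!r}")
        if self.contact_type not in reference.CONTACT_TYPES:
            raise InvalidArgumentError(f"unknown contact type {self.contact_type!r}")
        if self.alpha <= 0:
            raise InvalidArgumentError("shape parameter alpha must be positive")
        if self.beta1 < 0:
            raise InvalidArgumentError("gender effect beta1 must be non-negative")

    @property
    def units(self) -> str:
        return reference.units_for(self.contact_type)

    @classmethod
    def from_reference(cls, body_location_id: int, load_type: str,
                       contact_type: str) -> "ThresholdSpec":
        """Spec with the bundled fitted parameters as ground truth."""
        row = reference.ROW_OF_LOCATION.get(body_location_id)
        if row is None:
            raise InvalidArgumentError(
                f"location {body_location_id} has no fitted parameters"
            )
        p = reference.THRESHOLD_PARAMS[(row, load_type, contact_type)]
        return cls(body_location_id, load_type, contact_type,
                   p.beta0, p.beta1, p.alpha)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    gender_code: int  # 0 female, 1 male
    group: str = "G1"
    age: float | None = None
    height: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.gender_code not in (0, 1):
            raise InvalidArgumentError("gender code must be 0 or 1")
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidArgumentError(f"{name} must be positive when present")


@dataclass
class ProtocolConfig:
    """Parameters of the two loading protocols and the measurement chain.

    Defaults follow the study protocol: 1 mm/s algometer deformation
    rate, pendulum velocity steps of 0.05 m/s (0.01 m/s on the head) up
    to 1.25 m/s, pendulum masses 16.5 and 6.5 kg.  ``contact_stiffness``
    is the linear tissue stiffness c_H in N/m; per-location values are
    simulator configuration, not claims about tissue.
    """

    deformation_rate: float = 1e-3           # m/s
    velocity_step: float = 0.05              # m/s
    velocity_step_head: float = 0.01         # m/s
    velocity_max: float = 1.25               # m/s
    velocity_start: float | None = None      # default: one step above zero
    pendulum_masses: tuple = (16.5, 6.5)     # kg, heavier series first
    contact_stiffness: float = 3.0e4         # N/m
    contact_body_mass: float = 0.3           # kg (m_I)
    noise_sd: float = 0.5                    # N
    offset_sd: float = 1.0                   # N, per-trial baseline offset
    reaction_delay: float = 0.0              # s
    baseline_duration: float = 1.0           # s of pre-contact signal
    algometer_rate_hz: float = 100.0
    pendulum_rate_hz: float = 10000.0
    ramp_max_s: float = 600.0
    tilt_deg: float = 2.0                    # impact-axis misalignment bound

    def __post_init__(self) -> None:
        if not 0 < self.velocity_step <= self.velocity_max:
            raise InvalidArgumentError("require 0 < velocity_step <= velocity_max")
        if not 0 < self.velocity_step_head <= self.velocity_max:
            raise InvalidArgumentError("require 0 < velocity_step_head <= velocity_max")
        if any(m <= 0 for m in self.pendulum_masses):
            raise InvalidArgumentError("pendulum masses must be positive")
        if self.contact_stiffness <= 0:
            raise InvalidArgumentError("contact stiffness must be positive")
        if self.contact_body_mass < 0:
            raise InvalidArgumentError("contact-body mass must be non-negative")


@dataclass
class TrialSeries:
    """Raw recording of one load test plus protocol metadata."""

    time: np.ndarray
    force: np.ndarray                  # (n_samples, n_axes)
    sampling_rate: float
    load_type: str
    contact_type: str = "blunt"
    event_index: int | None = None     # algometer switch press
    v_p: float | None = None           # pendulum impact velocity m/s
    m_p: float | None = None           # total pendulum mass kg
    m_b: float | None = None           # pendulum-body mass kg
    m_i: float | None = None           # contact-body mass kg
    pain: bool | None = None
    subject_id: str | None = None
    body_location_id: int | None = None
    repeat_index: int | None = None
    true_threshold: float | None = None
    true_peak: float | None = None     # noiseless contact-force peak
    meta: dict = field(default_factory=dict)

    def to_signal(self) -> ForceSignal:
        return ForceSignal(
            time=self.time,
            values=self.force,
            sampling_rate=self.sampling_rate,
            event_index=self.event_index,
            m_b=self.m_b,
            m_i=self.m_i,
            meta={"load_type": self.load_type, "v_p": self.v_p, "m_p": self.m_p},
        )


# ---------------------------------------------------------------------------
# population and threshold draws

def sample_population(n: int, male_fraction: float, seed: int,
                      group: str = "G1") -> list:
    """Draw a deterministic roster of ``n`` subjects.

    The number of males is ``round(n * male_fraction)``; the order of
    genders in the roster, and the demographic covariates, are drawn
    from a generator seeded with ``seed``.
    """
    if n < 1:
        raise InvalidArgumentError("population size must be at least 1")
    if not 0.0 <= male_fraction <= 1.0:
        raise InvalidArgumentError("male fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_male = int(round(n * male_fraction))
    genders = np.array([1] * n_male + [0] * (n - n_male))
    rng.shuffle(genders)
    subjects = []
    for i, g in enumerate(genders):
        subjects.append(SubjectRecord(
            subject_id=f"S{i + 1:03d}",
            gender_code=int(g),
            group=group,
            age=float(np.clip(rng.normal(40.0, 14.0), 16.0, 67.0)),
            height=float(np.clip(rng.normal(1.76, 0.09), 1.45, 2.10)),
            weight=float(np.clip(rng.normal(79.0, 16.0), 40.0, 150.0)),
        ))
    return subjects


def threshold_from_uniform(spec: ThresholdSpec, gender_code: int, u: float) -> float:
    """Invert the expanded log-logistic CDF at probability ``u``."""
    if not 0.0 < u < 1.0:
        raise InvalidArgumentError("u must lie strictly in (0, 1)")
    return math.exp(spec.beta0 + gender_code * spec.beta1
                    + spec.alpha * math.log(u / (1.0 - u)))


def draw_threshold(spec: ThresholdSpec, gender_code: int,
                   rng: np.random.Generator) -> float:
    """Draw one pain threshold from the expanded log-logistic law."""
    if gender_code not in (0, 1):
        raise InvalidArgumentError("gender code must be 0 or 1")
    return threshold_from_uniform(spec, gender_code, float(rng.uniform()))


# ---------------------------------------------------------------------------
# algometer (quasi-static pinching ramp)

def simulate_algometer_trial(threshold: float, config: ProtocolConfig,
                             rng: np.random.Generator) -> TrialSeries:
    """Simulate one pinching ramp ended by the subject's switch press.

    The contact force ramps linearly at ``c_H * deformation_rate`` N/s
    over a constant-offset noisy baseline; the switch event is recorded
    when the noiseless force first reaches the threshold, plus the
    configured reaction delay.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    fs = config.algometer_rate_hz
    slope = config.contact_stiffness * config.deformation_rate  # N/s
    t_reach = threshold / slope
    if t_reach > config.ramp_max_s:
        raise SimulationLimitError(
            f"threshold {threshold:.1f} N not reachable within "
            f"{config.ramp_max_s} s at {slope:.2f} N/s"
        )
    t_event = config.baseline_duration + t_reach + config.reaction_delay
    event_index = int(math.ceil(t_event * fs))
    n = event_index + int(round(0.2 * fs)) + 1
    t = np.arange(n) / fs
    ramp = np.clip(t - config.baseline_duration, 0.0, None) * slope
    offset = rng.normal(0.0, config.offset_sd)
    noise = rng.normal(0.0, config.noise_sd, size=n)
    force = ramp + offset + noise
    return TrialSeries(
        time=t,
        force=force[:, None],
        sampling_rate=fs,
        load_type="pinching",
        event_index=event_index,
        true_threshold=threshold,
        true_peak=float(ramp[event_index]),
        meta={"offset": offset, "slope": slope},
    )


# ---------------------------------------------------------------------------
# pendulum (stepped impact staircase)

def _impact_pulse(peak: float, m_p: float, c_h: float, config: ProtocolConfig,
                  rng: np.random.Generator) -> TrialSeries:
    """One impact trial: half-sine contact pulse on a noisy baseline."""
    fs = config.pendulum_rate_hz
    contact_t = math.pi * math.sqrt(m_p / c_h)  # half period of the spring-mass
    n_base = int(round(config.baseline_duration * fs))
    n_contact = max(int(round(contact_t * fs)), 8)
    n_tail = int(round(0.05 * fs))
    n = n_base + n_contact + n_tail
    t = np.arange(n) / fs

    m_i = min(config.contact_body_mass, 0.5 * m_p)
    m_b = m_p - m_i
    v_f = 1.0 + m_i / m_b

    pulse = np.zeros(n)
    tc = (np.arange(n_contact) + 0.5) / n_contact
    pulse[n_base:n_base + n_contact] = peak * np.sin(math.pi * tc)

    # slight random misalignment of the impact axis (norm-preserving)
    tilt = math.radians(rng.uniform(0.0, config.tilt_deg))
    azim = rng.uniform(0.0, 2.0 * math.pi)
    direction = np.array([
        math.sin(tilt) * math.cos(azim),
        math.sin(tilt) * math.sin(azim),
        math.cos(tilt),
    ])
    measured = (pulse[:, None] / v_f) * direction[None, :]
    measured += rng.normal(0.0, config.offset_sd, size=(1, 3))
    measured += rng.normal(0.0, config.noise_sd, size=(n, 3))
    return TrialSeries(
        time=t,
        force=measured,
        sampling_rate=fs,
        load_type="impact",
        m_p=m_p,
        m_b=m_b,
        m_i=m_i,
        true_peak=peak,
    )


def simulate_pendulum_staircase(threshold: float, config: ProtocolConfig,
                                rng: np.random.Generator,
                                head: bool = False) -> list:
    """Simulate the stepped-velocity impact protocol for every mass.

    Returns one staircase (list of :class:`TrialSeries`) per configured
    pendulum mass.  Within a staircase the impact velocity increases in
    fixed steps from the starting velocity; the series ends at the first
    trial whose noiseless contact peak reaches the threshold (pain) or
    at the maximum velocity (a right-censored outcome).
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    step = config.velocity_step_head if head else config.velocity_step
    start = config.velocity_start if config.velocity_start is not None else step
    c_h = config.contact_stiffness
    staircases = []
    for m_p in config.pendulum_masses:
        series = []
        v = start
        k = 0
        while v <= config.velocity_max + 1e-12:
            peak = math.sqrt(m_p * c_h) * v
            trial = _impact_pulse(peak, m_p, c_h, config, rng)
            trial.v_p = v
            trial.pain = peak >= threshold
            trial.true_threshold = threshold
            trial.repeat_index = k
            series.append(trial)
            if trial.pain:
                break
            k += 1
            v = start + k * step
        staircases.append(series)
    return staircases


def staircase_peaks(threshold: float, config: ProtocolConfig,
                    rng: np.random.Generator, head: bool = False) -> list:
    """Observation-level staircase: measured peaks without waveforms.

    Returns per mass a list of ``(measured_peak, pain)`` tuples, where
    the measured peak is the noiseless spring-model peak plus Gaussian
    measurement noise.  Statistically equivalent to running
    :func:`simulate_pendulum_staircase` through the signal-conditioning
    chain, at a small fraction of the cost.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    step = config.velocity_step_head if head else config.velocity_step
    start = config.velocity_start if config.velocity_start is not None else step
    out = []
    for m_p in config.pendulum_masses:
        series = []
        v = start
        k = 0
        while v <= config.velocity_max + 1e-12:
            peak = math.sqrt(m_p * config.contact_stiffness) * v
            measured = max(peak + rng.normal(0.0, config.noise_sd), 1e-6)
            pain = peak >= threshold
            series.append((measured, pain))
            if pain:
                break
            k += 1
            v = start + k * step
        out.append(series)
    return out


# ---------------------------------------------------------------------------
# pressure-film frames

def simulate_pressure_frames(trial: TrialSeries, geometry: FilmGeometry,
                             rng: np.random.Generator,
                             frame_rate: float = 2070.0,
                             profile_sigma_mm: float | None = 4.0,
                             quantize: bool = True,
                             max_frames: int = 2000) -> list:
    """Render the trial's contact force as a pressure-film frame stack.

    The instantaneous contact force is spread over the film with a fixed
    unimodal profile (an isotropic Gaussian of width ``profile_sigma_mm``
    centered on the face; ``None`` gives a uniform profile), so that the
    sensel sum times sensel area equals the force before masking.  Blind
    spots are zeroed, and values are quantized to the film's 8-bit scale
    and clipped at its range.
    """
    if trial.force is None or len(trial.force) == 0:
        raise InvalidArgumentError("trial has no force channel")
    area = geometry.sensel_area_cm2
    n_cells = geometry.rows * geometry.cols

    # spatial weights, normalized to one over the full face
    if profile_sigma_mm is None:
        weights = np.full((geometry.rows, geometry.cols), 1.0 / n_cells)
    else:
        ii = (np.arange(geometry.rows) + 0.5) * geometry.pitch_mm
        jj = (np.arange(geometry.cols) + 0.5) * geometry.pitch_mm
        cy = geometry.rows * geometry.pitch_mm / 2.0
        cx = geometry.cols * geometry.pitch_mm / 2.0
        g = np.exp(-(((ii - cy)[:, None] ** 2) + ((jj - cx)[None, :] ** 2))
                   / (2.0 * profile_sigma_mm ** 2))
        weights = g / g.sum()

    # contact force over time: measured norm, inertia-restored for impacts
    force = np.linalg.norm(np.atleast_2d(trial.force), axis=1)
    if force.ndim == 0 or force.shape[0] != trial.time.shape[0]:
        force = np.linalg.norm(trial.force, axis=1)
    if trial.load_type == "impact" and trial.m_b and trial.m_i is not None:
        force = force * (1.0 + trial.m_i / trial.m_b)
    force = np.clip(force, 0.0, None)

    t_end = float(trial.time[-1])
    n_frames = int(t_end * frame_rate) + 1
    times = np.arange(n_frames) / frame_rate
    if n_frames > max_frames:
        times = np.linspace(0.0, t_end, max_frames)
    sampled = np.interp(times, trial.time, force)

    step = FILM_RANGE / (2 ** FILM_BITS - 1)
    frames = []
    for ts, f in zip(times, sampled):
        grid = f * weights / area
        grid = np.where(geometry.coverage, grid, 0.0)
        levels = None
        if quantize:
            levels = np.clip(np.round(grid / step), 0, 2 ** FILM_BITS - 1)
            grid = levels * step
        grid = np.clip(grid, 0.0, FILM_RANGE)
        frames.append(PressureFrame(
            grid=grid,
            coverage_mask=geometry.coverage.copy(),
            view_labels=geometry.view_labels,
            projection=geometry.projection,
            timestamp=float(ts),
            sensel_area_cm2=area,
            levels=levels,
        ))
    return frames


# ---------------------------------------------------------------------------
# external interfaces (CSV + JSON sidecar)

def write_trial(trial: TrialSeries, path) -> None:
    """Write a trial as CSV plus a JSON metadata sidecar.

    Columns: ``time_s, fx_N[, fy_N, fz_N], event_flag``.
    """
    path = Path(path)
    axes = trial.force.shape[1]
    headers = ["time_s"] + ["fx_N", "fy_N", "fz_N"][:axes] + ["event_flag"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(headers)
        for i in range(trial.force.shape[0]):
            flag = 1 if trial.event_index is not None and i == trial.event_index else 0
            writer.writerow([f"{trial.time[i]:.6f}",
                             *(f"{v:.6f}" for v in trial.force[i]), flag])
    meta = {
        "sampling_rate_hz": trial.sampling_rate,
        "load_type": trial.load_type,
        "contact_type": trial.contact_type,
        "subject_id": trial.subject_id,
        "body_location_id": trial.body_location_id,
        "repeat_index": trial.repeat_index,
        "v_P": trial.v_p,
        "m_P": trial.m_p,
        "m_B": trial.m_b,
        "m_I": trial.m_i,
        "pain": trial.pain,
        "event_index": trial.event_index,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trial(path) -> TrialSeries:
    """Read a trial written by :func:`write_trial`."""
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", names=True)
    meta = json.loads(path.with_suffix(".json").read_text())
    axis_cols = [c for c in ("fx_N", "fy_N", "fz_N") if c in data.dtype.names]
    force = np.column_stack([data[c] for c in axis_cols])
    flags = np.nonzero(data["event_flag"])[0]
    return TrialSeries(
        time=np.asarray(data["time_s"]),
        force=force,
        sampling_rate=meta["sampling_rate_hz"],
        load_type=meta["load_type"],
        contact_type=meta.get("contact_type", "blunt"),
        event_index=int(flags[0]) if flags.size else None,
        v_p=meta.get("v_P"),
        m_p=meta.get("m_P"),
        m_b=meta.get("m_B"),
        m_i=meta.get("m_I"),
        pain=meta.get("pain"),
        subject_id=meta.get("subject_id"),
        body_location_id=meta.get("body_location_id"),
        repeat_index=meta.get("repeat_index"),
    )


def write_frames(frames, geometry: FilmGeometry, directory) -> None:
    """Write a frame stack as per-frame CSV grids plus geometry JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        np.savetxt(directory / f"frame_{i:05d}.csv", frame.grid,
                   delimiter=",", fmt="%.4f")
    geo = {
        "rows": geometry.rows,
        "cols": geometry.cols,
        "pitch_mm": geometry.pitch_mm,
        "corner_radius_mm": geometry.corner_radius_mm,
        "sensel_area_cm2": geometry.sensel_area_cm2,
        "mask": geometry.coverage.astype(int).tolist(),
        "view_labels": [list(row) for row in geometry.view_labels],
        "timestamps": [f.timestamp for f in frames],
    }
    (directory / "geometry.json").write_text(json.dumps(geo, indent=2))
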