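"""Censored observations, midpoint imputation, and sample assembly.

The stepped pendulum protocol only brackets a subject's pain threshold:
the true value lies between the measured peak of the penultimate test
(no pain, left bound L) and that of the last test (pain, right bound R).
If the very first impact hurts the observation is left-censored (L = 0);
if the protocol tops out without pain it is right-censored (R -> inf).
Algometer observations are exact -- the switch press pins down the force
that evoked pain.

Midpoint imputation collapses an observation to a point estimate:

    y = R/2          if L = 0 (left-censored)
        L            if R -> inf (right-censored)
        (L + R)/2    otherwise,

repeats (including both pendulum masses) are averaged per subject, and
subjects are pooled into one sample per (body location, load type,
contact type) according to the group plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import reference
from .errors import ConfigurationError, InvalidArgumentError, MalformedSeriesError

CENSOR_TYPES = ("exact", "interval", "left", "right")


@dataclass(frozen=True)
class IntervalObservation:
    """One censored pain-threshold observation (N or N/cm^2)."""

    L: float
    R: float
    censor_type: str
    subject_id: str | None = None
    repeat_index: int | None = None

    def __post_init__(self) -> None:
        if self.censor_type not in CENSOR_TYPES:
            raise InvalidArgumentError(f"unknown censor type {self.censor_type!r}")
        if self.L < 0:
            raise InvalidArgumentError("lower bound must be non-negative")
        if self.censor_type == "interval" and not self.L < self.R:
            raise InvalidArgumentError("interval observations need L < R")
        if self.censor_type == "exact" and self.L != self.R:
            raise InvalidArgumentError("exact observations need L == R")
        if self.censor_type == "left" and self.L != 0.0:
            raise InvalidArgumentError("left-censored observations need L == 0")
        if self.censor_type == "right" and not math.isinf(self.R):
            raise InvalidArgumentError("right-censored observations need R == inf")

    @property
    def imputed_y(self) -> float:
        return impute_midpoint(self)


@dataclass(frozen=True)
class SubjectMean:
    """Per-subject mean of imputed repeats under one condition."""

    subject_id: str
    gender_code: int
    y_bar: float
    n_repeats: int
    right_censored: bool = False  # every repeat topped out without pain

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise InvalidArgumentError("a subject mean needs at least one repeat")


@dataclass
class Sample:
    """All subject means for one (body location, load, contact) cell."""

    body_location: str  # fitted row label, e.g. "13" or "17/18"
    load_type: str
    contact_type: str
    members: list
    observations: list = field(default_factory=list)  # raw repeat intervals

    def __post_init__(self) -> None:
        ids = [m.subject_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise InvalidArgumentError("one member per subject is required")

    @property
    def N(self) -> int:
        return len(self.members)

    @property
    def units(self) -> str:
        return reference.units_for(self.contact_type)


def intervals_from_staircase(peaks, pain_flags, subject_id=None,
                             repeat_index=None) -> IntervalObservation:
    """Convert one staircase of measured peaks into a censored observation.

    ``peaks`` are the processed maximum forces (or peak pressures) of the
    staircase trials in protocol order; ``pain_flags`` the corresponding
    pain reports.  Pain may occur only in the final trial.
    """
    peaks = list(peaks)
    flags = list(pain_flags)
    if not peaks or len(peaks) != len(flags):
        raise MalformedSeriesError("need matching non-empty peaks and pain flags")
    if any(flags[:-1]):
        raise MalformedSeriesError("pain flag raised before the final trial")
    if not flags[-1]:
        return IntervalObservation(L=peaks[-1], R=math.inf, censor_type="right",
                                   subject_id=subject_id, repeat_index=repeat_index)
    if len(peaks) == 1:
        return IntervalObservation(L=0.0, R=peaks[0], censor_type="left",
                                   subject_id=subject_id, repeat_index=repeat_index)
    left, right = peaks[-2], peaks[-1]
    if left >= right:
        # measurement noise can in principle invert adjacent steps;
        # collapse to a degenerate interval just below the pain trial
        left = right * (1.0 - 1e-9)
    return IntervalObservation(L=left, R=right, censor_type="interval",
                               subject_id=subject_id, repeat_index=repeat_index)


def impute_midpoint(obs: IntervalObservation) -> float:
    """Midpoint imputation of a censored observation."""
    if obs.censor_type == "exact":
        return obs.L
    if obs.censor_type == "left":
        return obs.R / 2.0
    if obs.censor_type == "right":
        return obs.L
    return (obs.L + obs.R) / 2.0


def average_repeats(observations, gender_code: int) -> SubjectMean:
    """Mean of the imputed repeats of one subject under one condition.

    Repeats from different pendulum masses are pooled into the same
    mean.  A subject whose every repeat is right-censored stays in the
    sample (the mean of the imputed values then equals the mean lower
    bound) and is flagged.
    """
    observations = list(observations)
    if not observations:
        raise InvalidArgumentError("cannot average an empty repeat list")
    subjects = {o.subject_id for o in observations}
    if len(subjects) > 1:
        raise InvalidArgumentError("repeats must belong to a single subject")
    values = [impute_midpoint(o) for o in observations]
    return SubjectMean(
        subject_id=observations[0].subject_id or "unknown",
        gender_code=gender_code,
        y_bar=sum(values) / len(values),
        n_repeats=len(values),
        right_censored=all(o.censor_type == "right" for o in observations),
    )


def assemble_sample(trial_table: pd.DataFrame, body_location: str,
                    load_type: str, contact_type: str,
                    group_map: dict | None = None) -> Sample:
    """Pool per-repeat observations into the sample of one condition cell.

    ``trial_table`` needs one row per repeat with columns ``subject_id``,
    ``gender_code``, ``group``, ``body_location``, ``load_type``,
    ``contact_type``, ``L``, ``R``, ``censor_type``.  Only subjects of
    the groups mapped to the condition contribute.  The neck muscle was
    never tested, and the pectoral muscle has no female members.
    """
    group_map = reference.GROUP_MAP if group_map is None else group_map
    if body_location == str(reference.EXCLUDED_LOCATION):
        raise ConfigurationError(
            "the neck muscle was excluded from load tests; its limits are "
            "estimated from the temple"
        )
    key = (body_location, load_type, contact_type)
    if key not in group_map:
        raise ConfigurationError(f"no subject group mapped to condition {key}")
    group = group_map[key]

    rows = trial_table[
        (trial_table["body_location"].astype(str) == body_location)
        & (trial_table["load_type"] == load_type)
        & (trial_table["contact_type"] == contact_type)
        & (trial_table["group"] == group)
    ]
    if body_location == "9":
        rows = rows[rows["gender_code"] == 1]

    members, observations = [], []
    for subject_id, sub in rows.groupby("subject_id", sort=True):
        obs = [
            IntervalObservation(
                L=float(r.L), R=float(r.R), censor_type=str(r.censor_type),
                subject_id=str(subject_id), repeat_index=i,
            )
            for i, r in enumerate(sub.itertuples(index=False))
        ]
        gender = int(sub["gender_code"].iloc[0])
        members.append(average_repeats(obs, gender))
        observations.extend(obs)
    return Sample(
        body_location=body_location,
        load_type=load_type,
        contact_type=contact_type,
        members=members,
        observations=observations,
    )
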