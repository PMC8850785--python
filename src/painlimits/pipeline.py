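"""End-to-end orchestration: simulate -> process -> censor -> fit -> limits.

One :func:`run_pipeline` call reproduces the whole study workflow on
synthetic data: it draws subject rosters per group, simulates the
algometer and pendulum protocols for every configured body location and
condition with the bundled fitted parameters as ground truth, converts
the trials to censored observations, fits the expanded threshold model
per cell, applies the two-condition gender-relevance rule, and writes
limit tables and comparison statistics to a run directory.

All randomness flows from a single root seed through per-cell derived
streams, so a rerun with the same configuration is byte-identical.

Two levels of simulation detail are available: ``"signal"`` synthesizes
raw waveforms and runs them through the full conditioning chain
(filtering, offset elimination, inertia compensation), while the
default ``"peaks"`` level draws the processed peak values directly from
the same measurement model, which is statistically equivalent and far
cheaper -- appropriate for parameter-recovery studies over many cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .censoring import assemble_sample, intervals_from_staircase
from .errors import ConfigurationError, FitFailureError
from .limits import (
    build_limit_table,
    pearson_k,
    relative_difference,
    round_for_standard,
    study_comparison_table,
    write_fits_json,
    write_limit_table,
)
from .model import fit_aft, gender_relevance
from .signals import cfc_filter, compensate_inertia, eliminate_offset, max_contact_force
from .synthetic import (
    ProtocolConfig,
    ThresholdSpec,
    draw_threshold,
    sample_population,
    simulate_algometer_trial,
    simulate_pendulum_staircase,
    staircase_peaks,
)

logger = logging.getLogger("painlimits")

#: default number of algometer repeats per subject and condition
N_PINCH_REPEATS = 3

#: fraction of the male-fraction scale spanned by each group
_GROUP_MALE_FRACTION = {
    g: m / (f + m) for g, (f, m) in reference.GROUP_COMPOSITION.items()
}


@dataclass
class PipelineConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    q: float = 0.75
    x_g: float = 0.7
    sigma: float = 0.05
    family: str = "log-logistic"
    fit_mode: str = "exact-on-imputed"     # or "interval"
    detail: str = "peaks"                  # or "signal"
    locations: tuple = reference.MEASURED_ROWS
    conditions: tuple = reference.CONDITIONS
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    #: peak pressure per unit contact force for the semi-sharp face, cm^-2
    pressure_per_force: float = 0.8
    #: lognormal sd of per-trial variation of the pressure concentration
    pressure_jitter: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigurationError("q must lie in (0, 1)")
        if not 0 <= self.x_g <= 1:
            raise ConfigurationError("x_g must lie in [0, 1]")
        if not 0 < self.sigma < 1:
            raise ConfigurationError("sigma must lie in (0, 1)")
        if self.detail not in ("peaks", "signal"):
            raise ConfigurationError("detail must be 'peaks' or 'signal'")
        bad = [r for r in self.locations if r not in reference.MEASURED_ROWS]
        if bad:
            raise ConfigurationError(f"unknown body locations: {bad}")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["locations"] = list(self.locations)
        payload["conditions"] = [list(c) for c in self.conditions]
        payload["protocol"]["pendulum_masses"] = list(
            self.protocol.pendulum_masses)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        proto = payload.pop("protocol", {})
        if "pendulum_masses" in proto:
            proto["pendulum_masses"] = tuple(proto["pendulum_masses"])
        payload["protocol"] = ProtocolConfig(**proto)
        payload["locations"] = tuple(payload.get("locations",
                                                 reference.MEASURED_ROWS))
        payload["conditions"] = tuple(
            tuple(c) for c in payload.get("conditions", reference.CONDITIONS))
        return cls(**payload)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_stiffness(row: str, config: ProtocolConfig) -> float:
    """Per-location linear tissue stiffness for the simulator, N/m.

    Chosen so the mixed-population median blunt-impact threshold is
    reached at 50% of the maximum velocity with the lighter pendulum
    mass: the staircase then brackets the bulk of the distribution with
    moderate censoring at both ends.  Simulator configuration only.
    """
    p = reference.THRESHOLD_PARAMS[(row, "impact", "blunt")]
    median = math.exp(p.beta0 + 0.5 * p.beta1)
    m_light = min(config.pendulum_masses)
    v_mid = 0.5 * config.velocity_max
    return (median / v_mid) ** 2 / m_light


# ---------------------------------------------------------------------------
# trial-level simulation and processing

def _measured_exact_pinch(threshold_force, config, rng, detail):
    """Measured force at the switch press of one algometer repeat."""
    if detail == "peaks":
        return max(threshold_force + rng.normal(0.0, config.noise_sd), 1e-6)
    trial = simulate_algometer_trial(threshold_force, config, rng)
    sig = trial.to_signal()
    sig = cfc_filter(sig, "CFC1")
    sig = eliminate_offset(sig, 0.9 * config.baseline_duration)
    return max_contact_force(sig, "algometer")


def _measured_staircases(threshold_force, config, rng, detail, head):
    """Measured peaks and pain flags per pendulum mass."""
    if detail == "peaks":
        return staircase_peaks(threshold_force, config, rng, head=head)
    out = []
    for series in simulate_pendulum_staircase(threshold_force, config, rng,
                                              head=head):
        processed = []
        for trial in series:
            sig = trial.to_signal()
            sig = cfc_filter(sig, "CFC100")
            sig = eliminate_offset(sig, 0.9 * config.baseline_duration)
            sig = compensate_inertia(sig)
            processed.append((max_contact_force(sig, "impact"), trial.pain))
        out.append(processed)
    return out


def simulate_condition(row: str, load_type: str, contact_type: str,
                       roster, config: PipelineConfig,
                       rng: np.random.Generator) -> list:
    """Simulate all repeats of one condition cell; returns table rows.

    Semi-sharp thresholds are drawn in pressure units and converted to
    the equivalent contact force through the pressure-concentration
    factor of the film face; the measured peaks are mapped back the
    same way, so the emitted observations are in the limit's units.
    """
    spec_row = ThresholdSpec(
        body_location_id=int(row.split("/")[0]),
        load_type=load_type, contact_type=contact_type,
        **reference.THRESHOLD_PARAMS[(row, load_type, contact_type)]._asdict(),
    )
    proto = dataclasses.replace(config.protocol,
                                contact_stiffness=default_stiffness(
                                    row, config.protocol))
    head = int(row.split("/")[0]) in reference.HEAD_LOCATIONS
    ppf = config.pressure_per_force
    pressure_based = contact_type == "semi-sharp"
    records = []
    for subject in roster:
        if row == "9" and subject.gender_code == 0:
            continue
        threshold = draw_threshold(spec_row, subject.gender_code, rng)
        force_threshold = threshold / ppf if pressure_based else threshold
        if load_type == "pinching":
            for j in range(N_PINCH_REPEATS):
                value = _measured_exact_pinch(force_threshold, proto, rng,
                                              config.detail)
                if pressure_based:
                    value *= ppf * math.exp(
                        rng.normal(0.0, config.pressure_jitter))
                records.append({"subject_id": subject.subject_id,
                                "gender_code": subject.gender_code,
                                "group": subject.group,
                                "body_location": row,
                                "load_type": load_type,
                                "contact_type": contact_type,
                                "L": value, "R": value,
                                "censor_type": "exact"})
        else:
            for series in _measured_staircases(force_threshold, proto, rng,
                                               config.detail, head):
                peaks = [p for p, _ in series]
                flags = [f for _, f in series]
                if pressure_based:
                    scale = ppf * math.exp(
                        rng.normal(0.0, config.pressure_jitter))
                    peaks = [p * scale for p in peaks]
                obs = intervals_from_staircase(peaks, flags,
                                               subject_id=subject.subject_id)
                records.append({"subject_id": subject.subject_id,
                                "gender_code": subject.gender_code,
                                "group": subject.group,
                                "body_location": row,
                                "load_type": load_type,
                                "contact_type": contact_type,
                                "L": obs.L, "R": obs.R,
                                "censor_type": obs.censor_type})
    return records


# ---------------------------------------------------------------------------
# full run

def make_rosters(seed: int) -> dict:
    """Deterministic subject rosters matching the study's group sizes."""
    rosters = {}
    for i, (group, (n_f, n_m)) in enumerate(sorted(
            reference.GROUP_COMPOSITION.items())):
        n = n_f + n_m
        roster = sample_population(n, n_m / n, seed=seed + 1000 + i,
                                   group=group)
        rosters[group] = roster
    return rosters


def simulate_observations(config: PipelineConfig) -> pd.DataFrame:
    """Simulate the per-repeat observation table only (no fitting)."""
    rosters = make_rosters(config.seed)
    root = np.random.SeedSequence(config.seed)
    cells = [(row, load, contact)
             for row in config.locations
             for load, contact in config.conditions]
    records = []
    for (row, load, contact), stream in zip(cells, root.spawn(len(cells) + 1)):
        group = reference.GROUP_MAP[(row, load, contact)]
        rng = np.random.default_rng(stream)
        records.extend(simulate_condition(row, load, contact,
                                          rosters[group], config, rng))
    return pd.DataFrame(records)


def fit_observation_table(trial_table: pd.DataFrame,
                          config: PipelineConfig) -> dict:
    """Fit every condition cell present in an observation table."""
    fits = {}
    keys = trial_table[["body_location", "load_type", "contact_type"]] \
        .drop_duplicates().itertuples(index=False)
    for row, load, contact in keys:
        sample = assemble_sample(trial_table, str(row), load, contact)
        genders = {m.gender_code for m in sample.members}
        fits[(str(row), load, contact)] = fit_aft(
            sample, family=config.family,
            constrain_beta1_zero=len(genders) < 2, mode=config.fit_mode)
    return fits


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic study and write the results.

    Returns a dict with the trial table, samples, fits, relevance
    decisions, the limit table (raw and standard-rounded), and the
    comparison statistics; the same artifacts are written under
    ``out_dir`` as CSV/JSON together with a provenance record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> dict:
    rosters = make_rosters(config.seed)
    root = np.random.SeedSequence(config.seed)

    # --- simulate + censor
    records = []
    cells = [(row, load, contact)
             for row in config.locations
             for load, contact in config.conditions]
    streams = root.spawn(len(cells) + 1)
    for (row, load, contact), stream in zip(cells, streams):
        group = reference.GROUP_MAP[(row, load, contact)]
        rng = np.random.default_rng(stream)
        cell_records = simulate_condition(row, load, contact,
                                          rosters[group], config, rng)
        records.extend(cell_records)
        logger.info("simulated %s %s/%s: %d repeats", row, load, contact,
                    len(cell_records))
    trial_table = pd.DataFrame(records)

    samples = {}
    for row, load, contact in cells:
        sample = assemble_sample(trial_table, row, load, contact)
        samples[(row, load, contact)] = sample
        tallies = trial_table[
            (trial_table["body_location"] == row)
            & (trial_table["load_type"] == load)
            & (trial_table["contact_type"] == contact)
        ]["censor_type"].value_counts().to_dict()
        logger.info("sample %s %s/%s: N=%d censoring=%s", row, load, contact,
                    sample.N, tallies)

    # --- fit + relevance
    fits, p_values = {}, {}
    for key, sample in samples.items():
        genders = {m.gender_code for m in sample.members}
        constrained = len(genders) < 2
        try:
            fit = fit_aft(sample, family=config.family,
                          constrain_beta1_zero=constrained,
                          mode=config.fit_mode)
        except FitFailureError:
            logger.warning("fit failed for %s", key)
            continue
        fits[key] = fit
        if not constrained and fit.p_beta1 is not None:
            p_values.setdefault(key[0], []).append(fit.p_beta1)
        logger.info("fit %s: beta0=%.3f beta1=%.3f alpha=%.3f p=%s", key,
                    fit.beta0, fit.beta1, fit.alpha, fit.p_beta1)

    relevance = {}
    for row in config.locations:
        ps = p_values.get(row, [])
        relevance[row] = gender_relevance(ps, row, config.sigma).relevant \
            if ps else False

    # irrelevant locations are refitted with the gender effect fixed at zero
    final_fits = {}
    for key, fit in fits.items():
        if not relevance[key[0]] and not fit.constrained:
            final_fits[key] = fit_aft(samples[key], family=config.family,
                                      constrain_beta1_zero=True,
                                      mode=config.fit_mode)
        else:
            final_fits[key] = fit

    # --- limits
    table = build_limit_table(final_fits, q=config.q, x_g=config.x_g,
                              relevance=relevance)
    has_temple = ("2" in config.locations
                  and any(k[0] == "2" for k in final_fits))
    rounded = round_for_standard(table) if has_temple else None

    # --- comparison
    comparison = {"w": {}, "w_mean": {}}
    for contact in ("blunt", "semi-sharp"):
        try:
            per_loc, mean = relative_difference(final_fits, contact,
                                                q=config.q, x_g=config.x_g,
                                                relevance=relevance)
            comparison["w"][contact] = per_loc
            comparison["w_mean"][contact] = mean
        except Exception:
            pass
    study = study_comparison_table()

    # force-pressure correlation from a control-style semi-sharp trial set
    rng = np.random.default_rng(streams[-1])
    k_values = {}
    for row in config.locations:
        key = (row, "pinching", "semi-sharp")
        if key not in samples:
            continue
        spec = ThresholdSpec(
            body_location_id=int(row.split("/")[0]),
            load_type="pinching", contact_type="semi-sharp",
            **reference.THRESHOLD_PARAMS[key]._asdict(),
        )
        forces, pressures = [], []
        for subject in rosters["G5"]:
            pressure = draw_threshold(spec, subject.gender_code, rng)
            force = pressure / config.pressure_per_force
            jitter = math.exp(rng.normal(0.0, config.pressure_jitter))
            forces.append(force + rng.normal(0.0, config.protocol.noise_sd))
            pressures.append(pressure * jitter)
        k_values[row] = pearson_k(forces, pressures)
    comparison["pearson_k"] = k_values

    # --- outputs
    trial_table.to_csv(out_dir / "observations.csv", index=False,
                       float_format="%.6f")
    write_limit_table(table, out_dir / "limits.csv")
    if rounded is not None:
        write_limit_table(rounded, out_dir / "limits_rounded.csv")
    write_fits_json(final_fits, out_dir / "fits.json")
    study.to_csv(out_dir / "study_comparison.csv", index=False,
                 float_format="%.6f")
    (out_dir / "comparison.json").write_text(json.dumps({
        "w_mean": comparison["w_mean"],
        "w": {c: dict(sorted(v.items())) for c, v in comparison["w"].items()},
        "pearson_k": dict(sorted(k_values.items())),
    }, indent=2))
    (out_dir / "provenance.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "detail": config.detail,
        "n_cells": len(cells),
        "n_repeats": len(trial_table),
        "relevance": {r: bool(v) for r, v in sorted(relevance.items())},
    }, indent=2))
    config.to_yaml(out_dir / "config.yaml")

    return {
        "trial_table": trial_table,
        "samples": samples,
        "fits": final_fits,
        "relevance": relevance,
        "limit_table": table,
        "rounded_table": rounded,
        "comparison": comparison,
        "study_comparison": study,
    }
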