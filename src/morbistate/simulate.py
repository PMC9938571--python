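"""Seeded synthetic panel cohorts with the structure the analysis assumes.

Two generator modes:

``state`` mode
    Each participant follows a progressive continuous-time Markov chain with
    *known* transition intensities (an :class:`~morbistate.multistate.IntensityModel`),
    observed only at survey waves, with exactly dated deaths.  This is the
    parameter-recovery workhorse: fit the multistate model to the generated
    panel and compare against the generating intensities.

``disease`` mode
    Chronic-disease onsets are drawn per disease from constant annual
    hazards (optionally scaled by the relationship group), reported
    cumulatively at each wave, with a Gompertz-like mortality hazard that
    rises with age and with the number of accumulated conditions.  This
    exercises the burden-index, clustering, Cox and descriptive stages.

The cohort emulates the structure of a CHARLS-like panel: baseline at age
45+, follow-up waves 2, 2 and 3 years apart, roughly a 40/60 split between
the downward and two-way relationship groups.  Marginal prevalences of the
named diseases are synthetic, not calibrated to any survey.

Reproducibility: one fixed root seed per cohort, split per participant by
counter (``default_rng([seed, i])``), so participant ``i``'s draws do not
depend on cohort ordering or size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .burden import DiseaseWeightTable
from .multistate import IntensityModel, StateSpace

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "PanelRecord",
    "simulate_individual_path",
    "observe_at_waves",
    "simulate_cohort",
    "microsimulate_occupancy",
    "default_disease_table",
    "default_weight_table",
    "default_state_config",
    "default_disease_config",
]

#: synthetic per-disease settings: annual onset hazard, baseline prevalence
#: and a severity weight.  The disease names mirror the chronic conditions a
#: CHARLS-like survey asks about; hazards, prevalences and weights are
#: synthetic values chosen for structural realism, not literature values.
DEFAULT_DISEASES: dict[str, dict[str, float]] = {
    "hypertension": {"hazard": 0.040, "prevalence": 0.20, "weight": 2.9},
    "dyslipidemia": {"hazard": 0.025, "prevalence": 0.08, "weight": 1.5},
    "diabetes": {"hazard": 0.015, "prevalence": 0.05, "weight": 2.2},
    "cancer": {"hazard": 0.004, "prevalence": 0.005, "weight": 5.5},
    "chronic_lung_disease": {"hazard": 0.018, "prevalence": 0.07, "weight": 3.1},
    "liver_disease": {"hazard": 0.008, "prevalence": 0.03, "weight": 2.4},
    "heart_disease": {"hazard": 0.020, "prevalence": 0.07, "weight": 3.6},
    "stroke": {"hazard": 0.012, "prevalence": 0.02, "weight": 4.8},
    "kidney_disease": {"hazard": 0.010, "prevalence": 0.04, "weight": 2.7},
    "digestive_disease": {"hazard": 0.025, "prevalence": 0.12, "weight": 1.8},
    "emotional_disorder": {"hazard": 0.005, "prevalence": 0.01, "weight": 2.0},
    "memory_disease": {"hazard": 0.008, "prevalence": 0.01, "weight": 4.2},
    "arthritis": {"hazard": 0.035, "prevalence": 0.18, "weight": 2.1},
    "asthma": {"hazard": 0.006, "prevalence": 0.03, "weight": 2.6},
}


def default_disease_table() -> dict[str, dict[str, float]]:
    return {k: dict(v) for k, v in DEFAULT_DISEASES.items()}


def default_weight_table() -> DiseaseWeightTable:
    """Synthetic severity-weight table for tests and examples (not literature)."""
    return DiseaseWeightTable({k: v["weight"] for k, v in DEFAULT_DISEASES.items()})


@dataclass(frozen=True)
class Trajectory:
    """One simulated progressive path: jump times, states entered, death time."""

    participant_id: int | str
    baseline_state: str
    jump_times: tuple[float, ...]
    states_after_jump: tuple[str, ...]
    death_time: float | None = None

    def __post_init__(self) -> None:
        jt = tuple(float(t) for t in self.jump_times)
        if any(jt[i] >= jt[i + 1] for i in range(len(jt) - 1)):
            raise ValueError("jump times must be strictly increasing")
        if len(jt) != len(self.states_after_jump):
            raise ValueError("one state per jump")
        if self.death_time is not None and jt and self.death_time <= jt[-1]:
            raise ValueError("death must come after the last living jump")

    def state_at(self, t: float) -> str:
        """Living state occupied at time ``t`` (undefined after death)."""
        state = self.baseline_state
        for jt, s in zip(self.jump_times, self.states_after_jump):
            if jt <= t:
                state = s
            else:
                break
        return state


@dataclass(frozen=True)
class PanelRecord:
    participant_id: int | str
    wave_index: int
    years_since_baseline: float
    vital_status: str
    state: str


def simulate_individual_path(
    intensity_model: IntensityModel,
    covariates: Mapping[str, float],
    horizon_years: float,
    rng: np.random.Generator,
    *,
    initial_state: str | None = None,
    participant_id: int | str = 0,
    age_covariate: str | None = None,
) -> Trajectory:
    """Draw one progressive path from the continuous-time Markov chain.

    Competing exponential clocks: the next-jump time is exponential with the
    total outflow rate, the destination categorical with probabilities
    proportional to the per-transition intensities.  If ``age_covariate`` is
    given, that covariate is advanced by one year at every whole year since
    baseline (piecewise-constant intensities), matching the fitting
    convention.
    """
    if horizon_years <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon_years}")
    unknown = set(covariates) - set(intensity_model.covariate_names)
    if unknown:
        raise KeyError(f"unknown covariate name(s): {sorted(unknown)}")
    if age_covariate is not None and age_covariate not in intensity_model.covariate_names:
        raise KeyError(f"age covariate {age_covariate!r} not in the intensity model")
    sp = intensity_model.state_space
    state = initial_state or sp.living[0]
    sp.index(state)  # validates
    t = 0.0
    jumps: list[float] = []
    states: list[str] = []
    death_time: float | None = None
    while t < horizon_years - 1e-12:
        covs = dict(covariates)
        if age_covariate is not None:
            covs[age_covariate] = float(covariates[age_covariate]) + math.floor(t)
        Q = intensity_model.intensity_matrix(covs)
        i = sp.index(state)
        out = -Q[i, i]
        boundary = (
            min(math.floor(t) + 1.0, horizon_years)
            if age_covariate is not None
            else horizon_years
        )
        if out <= 0.0:
            if age_covariate is None:
                break
            t = boundary
            continue
        dt = rng.exponential(1.0 / out)
        if t + dt >= boundary - 1e-12:
            t = boundary
            continue
        t = t + dt
        dests = [j for j in range(sp.n_states) if j != i and Q[i, j] > 0]
        probs = np.array([Q[i, j] for j in dests]) / out
        dest = int(rng.choice(dests, p=probs))
        dest_state = sp.states[dest]
        if dest_state == sp.death:
            death_time = t
            break
        jumps.append(t)
        states.append(dest_state)
        state = dest_state
    return Trajectory(
        participant_id=participant_id,
        baseline_state=initial_state or sp.living[0],
        jump_times=tuple(jumps),
        states_after_jump=tuple(states),
        death_time=death_time,
    )


def observe_at_waves(
    trajectory: Trajectory,
    wave_offsets: Sequence[float],
    death_state_label: str = "S6",
) -> list[PanelRecord]:
    """Panel records at each wave the participant is alive, plus one exact
    death record if death falls inside the follow-up window."""
    offsets = [float(w) for w in wave_offsets]
    if any(offsets[i] >= offsets[i + 1] for i in range(len(offsets) - 1)):
        raise ValueError("wave offsets must be strictly increasing")
    records: list[PanelRecord] = []
    dt = trajectory.death_time
    for w, off in enumerate(offsets):
        if dt is not None and off >= dt:
            records.append(
                PanelRecord(
                    participant_id=trajectory.participant_id,
                    wave_index=w,
                    years_since_baseline=float(dt),
                    vital_status="dead",
                    state=death_state_label,
                )
            )
            break
        records.append(
            PanelRecord(
                participant_id=trajectory.participant_id,
                wave_index=w,
                years_since_baseline=off,
                vital_status="alive",
                state=trajectory.state_at(off),
            )
        )
    return records


# --------------------------------------------------------------------- config


def _default_age_distribution() -> dict:
    # right-skewed over [45, 90): most participants in their late 40s-50s,
    # a small tail past 65 (as in the study population)
    return {"dist": "beta", "a": 1.5, "b": 6.0, "low": 45.0, "high": 90.0}


def _default_covariate_spec() -> dict:
    return {
        "gender_man": {"type": "bernoulli", "p": 0.51},
        "urban": {"type": "bernoulli", "p": 0.58},
        "education": {
            "type": "categorical",
            "levels": ["less_than_lower_secondary", "upper_secondary", "tertiary"],
            "probs": [0.83, 0.15, 0.02],
        },
        "partnered": {"type": "bernoulli", "p": 0.96},
        "social_participation": {"type": "bernoulli", "p": 0.50},
        "physical_activity": {"type": "bernoulli", "p": 0.55},
        "drinking": {"type": "bernoulli", "p": 0.37},
        "smoking": {"type": "bernoulli", "p": 0.40},
        "log_consumption": {"type": "normal", "mean": 9.0, "sd": 0.8},
    }


def _default_mortality() -> dict:
    # annual hazard: base_rate at age 60 with no conditions, Gompertz-like
    # increase with age, multiplicative loading per accumulated condition
    return {
        "base_rate": 0.008,
        "age_slope": 0.09,
        "per_condition_log_hr": 0.12,
        "group_log_hr": 0.0,
    }


@dataclass
class SimulationConfig:
    """Configuration for one synthetic cohort."""

    n_participants: int = 6800
    seed: int = 0
    mode: str = "disease"  # "state" or "disease"
    wave_offsets_years: tuple[float, ...] = (0.0, 2.0, 4.0, 7.0)
    baseline_age_distribution: dict = field(default_factory=_default_age_distribution)
    group_probability: float = 0.60
    covariate_spec: dict = field(default_factory=_default_covariate_spec)
    true_intensities: IntensityModel | None = None
    initial_state: str | None = None
    disease_table: dict = field(default_factory=default_disease_table)
    disease_group_hr: float = 0.83
    mortality: dict = field(default_factory=_default_mortality)

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        w = tuple(float(x) for x in self.wave_offsets_years)
        if w[0] != 0.0 or any(w[i] >= w[i + 1] for i in range(len(w) - 1)):
            raise ValueError("wave offsets must start at 0 and strictly increase")
        self.wave_offsets_years = w
        if not 0.0 < self.group_probability < 1.0:
            raise ValueError("group_probability must be in (0, 1)")
        if self.mode not in ("state", "disease"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.mode == "state" and self.true_intensities is None:
            raise ValueError("state mode requires true_intensities")
        for name, entry in self.disease_table.items():
            if entry["hazard"] < 0:
                raise ValueError(f"hazard for {name!r} must be >= 0")
            if not 0 <= entry.get("prevalence", 0.0) < 1:
                raise ValueError(f"prevalence for {name!r} must be in [0, 1)")
        if self.disease_group_hr <= 0:
            raise ValueError("disease_group_hr must be > 0")

    @property
    def horizon(self) -> float:
        return self.wave_offsets_years[-1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_intensities"] = (
            self.true_intensities.to_dict() if self.true_intensities else None
        )
        d["wave_offsets_years"] = list(self.wave_offsets_years)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        d = dict(data)
        if d.get("true_intensities"):
            d["true_intensities"] = IntensityModel.from_dict(d["true_intensities"])
        d["wave_offsets_years"] = tuple(d.get("wave_offsets_years", (0, 2, 4, 7)))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_state_config(
    n_participants: int = 3000, seed: int = 0, group_hr: float = 0.83
) -> SimulationConfig:
    """State-mode config on a 3-living-state progressive space.

    The relationship-group effect (default hazard ratio 0.83 for the two-way
    group) acts on the S1->S2 progression intensity.
    """
    space = StateSpace(
        living=("S1", "S2", "S3"),
        death="S4",
        allowed=frozenset({("S1", "S2"), ("S2", "S3"), ("S1", "S4"), ("S2", "S4"), ("S3", "S4")}),
    )
    truth = IntensityModel.from_rates(
        space,
        rates={
            ("S1", "S2"): 0.12,
            ("S2", "S3"): 0.10,
            ("S1", "S4"): 0.015,
            ("S2", "S4"): 0.035,
            ("S3", "S4"): 0.08,
        },
        beta={("S1", "S2"): {"two_way": float(np.log(group_hr))}},
        covariate_names=("two_way",),
    )
    return SimulationConfig(
        n_participants=n_participants,
        seed=seed,
        mode="state",
        true_intensities=truth,
        covariate_spec={},
    )


def default_disease_config(n_participants: int = 6800, seed: int = 0) -> SimulationConfig:
    return SimulationConfig(n_participants=n_participants, seed=seed, mode="disease")


# --------------------------------------------------------------------- cohort


def _draw_age(spec: Mapping, rng: np.random.Generator) -> float:
    if spec.get("dist", "beta") == "beta":
        u = rng.beta(spec["a"], spec["b"])
        return float(spec["low"] + (spec["high"] - spec["low"]) * u)
    if spec["dist"] == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    raise ValueError(f"unknown age distribution {spec.get('dist')!r}")


def _draw_covariates(spec: Mapping, rng: np.random.Generator) -> dict:
    out: dict = {}
    for name, s in spec.items():
        kind = s["type"]
        if kind == "bernoulli":
            out[name] = int(rng.random() < s["p"])
        elif kind == "categorical":
            out[name] = str(rng.choice(s["levels"], p=s["probs"]))
        elif kind == "normal":
            out[name] = float(rng.normal(s["mean"], s["sd"]))
        else:
            raise ValueError(f"unknown covariate type {kind!r} for {name!r}")
    return out


def _piecewise_death_time(
    breaks: np.ndarray, hazards: np.ndarray, rng: np.random.Generator
) -> float | None:
    """Death time under a piecewise-constant hazard on [breaks[0], breaks[-1]]."""
    target = rng.exponential(1.0)
    cum = 0.0
    for k in range(len(hazards)):
        seg = breaks[k + 1] - breaks[k]
        add = hazards[k] * seg
        if cum + add >= target:
            return float(breaks[k] + (target - cum) / hazards[k])
        cum += add
    return None


def _simulate_disease_participant(
    pid: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    age0 = _draw_age(cfg.baseline_age_distribution, rng)
    two_way = int(rng.random() < cfg.group_probability)
    covs = _draw_covariates(cfg.covariate_spec, rng)
    names = list(cfg.disease_table)
    horizon = cfg.horizon
    prevalent = {
        d for d in names if rng.random() < cfg.disease_table[d].get("prevalence", 0.0)
    }
    onsets: dict[str, float] = {}
    for d in names:
        if d in prevalent:
            continue
        h = cfg.disease_table[d]["hazard"] * (cfg.disease_group_hr if two_way else 1.0)
        if h <= 0:
            continue
        t = rng.exponential(1.0 / h)
        if t <= horizon:
            onsets[d] = float(t)
    # piecewise-constant mortality hazard: breaks at whole years and onsets
    mort = cfg.mortality
    onset_times = sorted(onsets.values())
    breaks = np.unique(
        np.concatenate(
            [np.arange(0.0, horizon + 1e-9), np.array(onset_times), [horizon]]
        )
    )
    hazards = []
    for k in range(len(breaks) - 1):
        t0 = breaks[k]
        n_cond = len(prevalent) + sum(1 for t in onset_times if t <= t0 + 1e-12)
        loghaz = (
            math.log(mort["base_rate"])
            + mort["age_slope"] * (age0 + math.floor(t0) - 60.0)
            + mort["per_condition_log_hr"] * n_cond
            + mort["group_log_hr"] * two_way
        )
        hazards.append(math.exp(loghaz))
    death_time = _piecewise_death_time(breaks, np.array(hazards), rng)

    base = {"age": round(age0, 2), "two_way": two_way, **covs}
    rows: list[dict] = []
    for w, off in enumerate(cfg.wave_offsets_years):
        if death_time is not None and off >= death_time:
            row = {
                "id": pid,
                "wave_index": w,
                "years_since_baseline": round(death_time, 4),
                "vital_status": "dead",
                **base,
            }
            for d in names:
                present = d in prevalent or onsets.get(d, np.inf) <= death_time
                row[f"disease_{d}"] = int(present)
            rows.append(row)
            break
        row = {
            "id": pid,
            "wave_index": w,
            "years_since_baseline": off,
            "vital_status": "alive",
            **base,
        }
        for d in names:
            present = d in prevalent or onsets.get(d, np.inf) <= off
            row[f"disease_{d}"] = int(present)
        rows.append(row)
    return rows


def _simulate_state_participant(
    pid: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    age0 = _draw_age(cfg.baseline_age_distribution, rng)
    two_way = int(rng.random() < cfg.group_probability)
    covs = _draw_covariates(cfg.covariate_spec, rng)
    im = cfg.true_intensities
    model_covs = {}
    for name in im.covariate_names:
        if name == "two_way":
            model_covs[name] = two_way
        elif name == "age":
            model_covs[name] = age0
        elif name in covs:
            model_covs[name] = covs[name]
        else:
            raise KeyError(f"intensity model covariate {name!r} not generated")
    traj = simulate_individual_path(
        im,
        model_covs,
        cfg.horizon,
        rng,
        initial_state=cfg.initial_state,
        participant_id=pid,
        age_covariate="age" if "age" in im.covariate_names else None,
    )
    base = {"age": round(age0, 2), "two_way": two_way, **covs}
    rows = []
    for rec in observe_at_waves(
        traj, cfg.wave_offsets_years, death_state_label=im.state_space.death
    ):
        rows.append(
            {
                "id": pid,
                "wave_index": rec.wave_index,
                "years_since_baseline": round(rec.years_since_baseline, 4),
                "vital_status": rec.vital_status,
                "state": rec.state,
                **base,
            }
        )
    return rows


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a full panel cohort; deterministic given ``config.seed``.

    Returns the panel data frame (one row per participant-wave, plus one
    exact-death row per decedent) and a ground-truth record of the
    generating parameters.
    """
    rows: list[dict] = []
    for i in range(config.n_participants):
        rng = np.random.default_rng([config.seed, i])
        if config.mode == "disease":
            rows.extend(_simulate_disease_participant(i, config, rng))
        else:
            rows.extend(_simulate_state_participant(i, config, rng))
    panel = pd.DataFrame(rows)
    ground_truth = {"config": config.to_dict()}
    return panel, ground_truth


def microsimulate_occupancy(
    per_age_matrices: np.ndarray,
    n_paths: int,
    rng: np.random.Generator,
    start_state: int = 0,
    return_person_years: bool = False,
    a_omega: float = 0.5,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Cohort microsimulation over annual transition matrices.

    ``per_age_matrices`` has shape (n_ages, n_states, n_states); every path
    starts in ``start_state`` and steps once per age through the matching
    matrix.  Returns occupancy counts of shape (n_ages + 1, n_states), and,
    if requested, per-path person-years in each state computed with the same
    linear within-interval convention as the life table (half a year for
    each end of an occupied interval, ``a_omega`` extra years for paths
    still alive at the closing age).  Serves as the stochastic cross-check
    of the deterministic life-table recursion.
    """
    M = np.asarray(per_age_matrices, dtype=float)
    n_ages, n_states, _ = M.shape
    cum = np.cumsum(M, axis=2)
    states = np.full(n_paths, start_state, dtype=np.int64)
    occupancy = np.zeros((n_ages + 1, n_states), dtype=np.int64)
    occupancy[0] = np.bincount(states, minlength=n_states)
    years = (
        np.zeros((n_paths, n_states)) if return_person_years else None
    )
    rows_idx = np.arange(n_paths)
    for a in range(n_ages):
        u = rng.random(n_paths)
        nxt = (u[:, None] > cum[a][states]).sum(axis=1)
        if years is not None:
            np.add.at(years, (rows_idx, states), 0.5)
            np.add.at(years, (rows_idx, nxt), 0.5)
        states = nxt
        occupancy[a + 1] = np.bincount(states, minlength=n_states)
    if years is None:
        return occupancy
    np.add.at(years, (rows_idx, states), a_omega)
    return occupancy, years
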