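"""End-to-end analysis pipeline.

Orchestrates: simulate (or load) a panel cohort -> Table-1-style
descriptives -> burden index + exhaustive clusters + k-means burden states
-> Cox time-to-multimorbidity -> progressive multistate Markov fit ->
multistate life tables (LE / HLE / years lost per relationship group).

Every stage writes its artifacts as plain delimited text or YAML into the
output directory, so any stage can be rerun or inspected in isolation, and
the whole run is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    DiseaseWeightTable,
    assign_state,
    enumerate_clusters,
    kmeans_1d,
)
from .descriptives import cohort_characteristics_table
from .lifetable import age_specific_probabilities, build_life_table
from .multistate import MultistateModel, StateSpace
from .simulate import SimulationConfig, default_weight_table, simulate_cohort
from .survival import CoxPHModel, derive_time_to_multimorbidity, kaplan_meier

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; completed artifacts are kept on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs; the seed is recorded in every
    output manifest."""

    out_dir: str
    seed: int = 0
    # input: either a panel CSV or a simulation config (default: simulate)
    input_panel: str | None = None
    simulation: SimulationConfig | None = None
    n_participants: int = 6800
    weight_table: str | None = None  # YAML/CSV path; default synthetic table
    k: int = 5
    kmeans_fit_on: str = "observed"  # or "clusters"
    group_col: str = "two_way"
    descriptive_covariates: tuple[str, ...] = (
        "age_over_65",
        "gender_man",
        "partnered",
        "education",
        "urban",
        "drinking",
        "smoking",
    )
    cox_covariates: tuple[str, ...] = ("two_way", "age", "gender_man", "urban")
    msm_covariates: tuple[str, ...] = ("two_way", "age")
    msm_transition_set: str = "adjacent"  # or "full"
    exclude_baseline_multimorbid_from_msm: bool = False
    healthy_states: tuple[str, ...] = ("S1",)
    radix: float = 100_000.0
    closure_age: int = 110
    lifetable_ages: tuple[int, ...] = (45, 55, 65, 75)
    on_no_events: str = "continue"  # or "abort"

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(
            n_participants=self.n_participants, seed=self.seed, mode="disease"
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["simulation"] = (
            self.simulation.to_dict() if self.simulation is not None else None
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in (
            "descriptive_covariates",
            "cox_covariates",
            "msm_covariates",
            "healthy_states",
            "lifetable_ages",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns a dict of artifacts and results.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts from completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    artifacts: dict = {"out_dir": str(out)}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def flush_log() -> None:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    log(f"morbistate {__version__} | python {sys.version.split()[0]}")
    log(f"seed: {config.seed}")
    config.to_yaml(out / "config_resolved.yaml")

    stage = "simulate"
    try:
        if config.input_panel is not None:
            panel = pd.read_csv(config.input_panel)
            log(f"[{stage}] loaded panel from {config.input_panel}: {len(panel)} rows")
        else:
            sim = config.resolved_simulation()
            panel, truth = simulate_cohort(sim)
            with open(out / "ground_truth.yaml", "w") as fh:
                yaml.safe_dump(truth, fh)
            log(
                f"[{stage}] simulated cohort: {sim.n_participants} participants, "
                f"{len(panel)} panel rows, mode={sim.mode}, seed={sim.seed}"
            )
        _write_csv(panel, out / "cohort.csv")
        artifacts["panel"] = panel
    except Exception as err:
        flush_log()
        raise PipelineError(stage, err) from err

    stage = "describe"
    try:
        desc_panel = panel.copy()
        if "age" in desc_panel.columns and "age_over_65" not in desc_panel.columns:
            desc_panel["age_over_65"] = (desc_panel["age"] > 65).astype(int)
        covs = [c for c in config.descriptive_covariates if c in desc_panel.columns]
        descriptives = cohort_characteristics_table(
            desc_panel, config.group_col, covs
        )
        _write_csv(descriptives, out / "descriptives.csv")
        artifacts["descriptives"] = descriptives
        base = desc_panel[desc_panel["wave_index"] == 0]
        n_by_group = base.groupby(config.group_col)["id"].nunique()
        log(f"[{stage}] baseline n by {config.group_col}: {n_by_group.to_dict()}")
    except Exception as err:
        flush_log()
        raise PipelineError(stage, err) from err

    stage = "index"
    try:
        if config.weight_table is None:
            weights = default_weight_table()
        elif str(config.weight_table).endswith((".yml", ".yaml")):
            weights = DiseaseWeightTable.from_yaml(config.weight_table)
        else:
            weights = DiseaseWeightTable.from_csv(config.weight_table)
        weights.to_yaml(out / "weight_table.yaml")
        disease_cols = [c for c in panel.columns if c.startswith("disease_")]
        diseases = [c.removeprefix("disease_") for c in disease_cols]
        clusters = enumerate_clusters(diseases, weights)
        cluster_df = pd.DataFrame(
            {
                "cluster": ["+".join(c) for c, _ in clusters],
                "size": [len(c) for c, _ in clusters],
                "index": [v for _, v in clusters],
            }
        )
        _write_csv(cluster_df, out / "clusters.csv")
        wvec = np.array([weights[d] for d in diseases])
        person_index = panel[disease_cols].to_numpy() @ wvec
        if config.kmeans_fit_on == "clusters":
            fit_values = cluster_df["index"].to_numpy()
        elif config.kmeans_fit_on == "observed":
            fit_values = person_index
        else:
            raise ValueError(f"unknown kmeans_fit_on {config.kmeans_fit_on!r}")
        partition = kmeans_1d(fit_values, config.k)
        partition.to_yaml(out / "partition.yaml")
        death_label = f"S{config.k + 1}"
        states = np.array(
            [assign_state(v, partition) for v in person_index], dtype=object
        )
        state_panel = panel.copy()
        state_panel["burden_index"] = person_index
        state_panel["n_conditions"] = panel[disease_cols].sum(axis=1)
        state_panel["state"] = np.where(
            state_panel["vital_status"] == "dead", death_label, states
        )
        _write_csv(state_panel, out / "state_panel.csv")
        artifacts.update(
            weight_table=weights,
            partition=partition,
            state_panel=state_panel,
            clusters=cluster_df,
        )
        log(
            f"[{stage}] {len(clusters)} clusters; k={config.k}; "
            f"boundaries={[round(b, 3) for b in partition.boundaries]}; "
            f"within-SS={partition.within_cluster_ss:.3f} (fit on {config.kmeans_fit_on})"
        )
    except Exception as err:
        flush_log()
        raise PipelineError(stage, err) from err

    stage = "cox"
    try:
        records = derive_time_to_multimorbidity(panel)
        _write_csv(records, out / "survival_records.csv")
        artifacts["survival_records"] = records
        n_events = int(records["event"].sum()) if len(records) else 0
        if n_events == 0:
            log(f"[{stage}] no events: multimorbidity never observed; Cox skipped")
            if config.on_no_events == "abort":
                raise ValueError("no multimorbidity events in the cohort")
            artifacts["cox"] = None
        else:
            km = kaplan_meier(records, group_col=config.group_col)
            _write_csv(km, out / "km_curves.csv")
            cox_covs = [c for c in config.cox_covariates if c in records.columns]
            cox_res = CoxPHModel(records, cox_covs).fit()
            cox_res.to_yaml(out / "cox_summary.yaml")
            _write_csv(cox_res.hazard_ratio_table(), out / "cox_hr.csv")
            _write_csv(cox_res.proportional_hazards_test(), out / "ph_test.csv")
            artifacts["cox"] = cox_res
            hr = cox_res.hazard_ratio_table().set_index("covariate")
            log(
                f"[{stage}] {len(records)} at-risk participants, {n_events} events; "
                f"HR[{config.group_col}]={hr.loc[config.group_col, 'hr']:.3f} "
                f"({hr.loc[config.group_col, 'hr_lower']:.3f}-"
                f"{hr.loc[config.group_col, 'hr_upper']:.3f})"
            )
    except PipelineError:
        raise
    except Exception as err:
        flush_log()
        raise PipelineError(stage, err) from err

    stage = "msm"
    try:
        msm_panel = state_panel.copy()
        if "age" in msm_panel.columns:
            msm_panel["age"] = msm_panel["age"].round().astype(int)
        if config.exclude_baseline_multimorbid_from_msm:
            base = msm_panel[msm_panel["wave_index"] == 0]
            keep = base.loc[base["n_conditions"] < 2, "id"]
            msm_panel = msm_panel[msm_panel["id"].isin(keep)]
        living = tuple(f"S{i + 1}" for i in range(config.k))
        if config.msm_transition_set == "adjacent":
            space = StateSpace.adjacent_plus_death(config.k)
        elif config.msm_transition_set == "full":
            space = StateSpace(living=living, death=death_label)
        else:
            raise ValueError(
                f"unknown msm_transition_set {config.msm_transition_set!r}"
            )
        msm_covs = [c for c in config.msm_covariates if c in msm_panel.columns]
        model = MultistateModel(
            msm_panel,
            state_space=space,
            covariate_names=msm_covs,
            age_covariate="age" if "age" in msm_covs else None,
        )
        msm_res = model.fit()
        msm_res.to_yaml(out / "msm_fit.yaml")
        hr_table = msm_res.hazard_ratio_table(covariate=config.group_col)
        _write_csv(hr_table, out / "msm_transition_hr.csv")
        artifacts["msm"] = msm_res
        log(
            f"[{stage}] retained transitions: "
            + ", ".join(f"{r}->{s}" for r, s in model.transitions)
            + f"; loglike={msm_res.loglike:.2f}; converged={msm_res.converged}"
        )
    except PipelineError:
        raise
    except Exception as err:
        flush_log()
        raise PipelineError(stage, err) from err

    stage = "lifetable"
    try:
        ages = np.arange(45, config.closure_age)
        summaries = []
        for gval, gname in ((0, "downward"), (1, "two_way")):
            covs = {config.group_col: gval}
            for c in msm_covs:
                if c not in covs and c != "age":
                    covs[c] = 0.0
            P = age_specific_probabilities(
                msm_res,
                ages,
                covariates=covs,
                age_covariate="age" if "age" in msm_covs else None,
            )
            lt = build_life_table(
                P,
                radix=config.radix,
                start_age=45,
                state_labels=living + (death_label,),
                group=gname,
            )
            _write_csv(lt.to_frame(), out / f"lifetable_{gname}.csv")
            summaries.append(
                lt.summary_frame(
                    ages=config.lifetable_ages, healthy_states=config.healthy_states
                )
            )
            artifacts[f"lifetable_{gname}"] = lt
        summary = pd.concat(summaries, ignore_index=True)
        _write_csv(summary, out / "lifetable_summary.csv")
        artifacts["lifetable_summary"] = summary
        at45 = summary[summary["age"] == 45]
        for _, row in at45.iterrows():
            log(
                f"[{stage}] {row['group']}: LE(45)={row['LE']:.2f} "
                f"HLE(45)={row['HLE']:.2f} years_lost={row['years_lost']:.2f} "
                f"(healthy={row['healthy_states']})"
            )
    except Exception as err:
        flush_log()
        raise PipelineError(stage, err) from err

    log("pipeline complete")
    flush_log()
    artifacts["log"] = log_lines
    return artifacts
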