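"""Canned experiment manifests: the simulation campaigns and a runner.

Six built-in campaigns cover the in-silico study design: the tumor-free BMU
under 80 % inhibition, pre-treatment of a TRP lesion at 20 % and 80 %
efficacy, post-treatment (day 80) at 80 % and 99 %, a homogeneous TP lesion
(ligand-only clone, inhibitor-insensitive division), the heterogeneous
patient seeding (clonal ratio TP 1 : TRP 231 : TR 6 : TN 4), and an
emboli-size threshold sweep. Replicate counts default to the full campaign
sizes (24–29 per arm); pass ``replicates=`` for desk-scale runs.

Per-replicate seeds derive from the manifest master seed via
``SeedSequence.spawn``, so re-running a manifest with the same master seed
reproduces every table bitwise regardless of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SeedSpec, Simulation, TreatmentPlan
from .lattice import Phenotype
from .metrics import compare_arms, value_at_day
from .params import ParamSet, default_params

__all__ = ["ExperimentManifest", "builtin_manifests", "get_manifest",
           "run_experiment", "PATIENT_CLONAL_RATIO"]

#: clonal ratio measured in a single patient specimen
PATIENT_CLONAL_RATIO = {Phenotype.TP: 1, Phenotype.TRP: 231,
                        Phenotype.TR: 6, Phenotype.TN: 4}


@dataclass(frozen=True)
class ExperimentManifest:
    name: str
    arms: dict[str, tuple[TreatmentPlan, SeedSpec | None]]
    replicates: int
    horizon_days: int
    master_seed: int = 1000
    compare_metric: str = "n_cancer"
    compare_days: tuple[int, ...] = (250,)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def to_dict(self) -> dict:
        def seed_dict(s: SeedSpec | None):
            if s is None:
                return None
            return {"clonal_counts": {p.name: c
                                      for p, c in s.clonal_counts.items()},
                    "seed_day": s.seed_day}
        return {
            "name": self.name,
            "replicates": self.replicates,
            "horizon_days": self.horizon_days,
            "master_seed": self.master_seed,
            "compare_metric": self.compare_metric,
            "compare_days": list(self.compare_days),
            "arms": {a: {"plan": {"mode": p.mode, "efficacy": p.efficacy,
                                  "start_day": p.start_day},
                         "seed": seed_dict(s)}
                     for a, (p, s) in self.arms.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentManifest":
        arms = {}
        for a, spec in d["arms"].items():
            plan = TreatmentPlan(**spec["plan"])
            seed = None
            if spec["seed"] is not None:
                seed = SeedSpec(
                    {Phenotype[p]: c
                     for p, c in spec["seed"]["clonal_counts"].items()},
                    spec["seed"]["seed_day"])
            arms[a] = (plan, seed)
        return cls(name=d["name"], arms=arms, replicates=d["replicates"],
                   horizon_days=d["horizon_days"],
                   master_seed=d["master_seed"],
                   compare_metric=d["compare_metric"],
                   compare_days=tuple(d["compare_days"]))


def builtin_manifests() -> list[ExperimentManifest]:
    """The six named campaigns."""
    trp9 = SeedSpec.trp(9)
    tp9 = SeedSpec({Phenotype.TP: 9})
    patient = SeedSpec.from_ratio(PATIENT_CLONAL_RATIO, 242)
    return [
        ExperimentManifest(
            name="normal_bmu",
            arms={"control": (TreatmentPlan(), None),
                  "pre_e80": (TreatmentPlan("pre", 0.8), None)},
            replicates=29, horizon_days=75,
            compare_metric="bone_area_um2", compare_days=(75,)),
        ExperimentManifest(
            name="pretreat_trp",
            arms={"control": (TreatmentPlan(), trp9),
                  "pre_e20": (TreatmentPlan("pre", 0.2), trp9),
                  "pre_e80": (TreatmentPlan("pre", 0.8), trp9)},
            replicates=24, horizon_days=250, compare_days=(100, 250)),
        ExperimentManifest(
            name="posttreat_trp",
            arms={"control": (TreatmentPlan(), trp9),
                  "post_e80": (TreatmentPlan("post", 0.8), trp9),
                  "post_e99": (TreatmentPlan("post", 0.99), trp9)},
            replicates=24, horizon_days=250, compare_days=(100, 250)),
        ExperimentManifest(
            name="tp_only",
            arms={"control": (TreatmentPlan(), tp9),
                  "pre_e80": (TreatmentPlan("pre", 0.8), tp9),
                  "post_e80": (TreatmentPlan("post", 0.8), tp9)},
            replicates=24, horizon_days=250, compare_days=(100, 250)),
        ExperimentManifest(
            name="patient_41458",
            arms={"control": (TreatmentPlan(), patient),
                  "pre_e80": (TreatmentPlan("pre", 0.8), patient),
                  "post_e80": (TreatmentPlan("post", 0.8), patient)},
            replicates=24, horizon_days=250, compare_days=(100, 250)),
        ExperimentManifest(
            name="emboli_threshold",
            arms={f"size_{n}": (TreatmentPlan(), SeedSpec.trp(n))
                  for n in range(1, 13)},
            replicates=20, horizon_days=150, compare_days=(150,)),
    ]


def get_manifest(name: str) -> ExperimentManifest:
    for m in builtin_manifests():
        if m.name == name:
            return m
    raise KeyError(f"unknown experiment {name!r}; known: "
                   f"{[m.name for m in builtin_manifests()]}")


def run_experiment(manifest: ExperimentManifest,
                   params: ParamSet | None = None,
                   replicates: int | None = None,
                   out_dir: str | Path | None = None,
                   stop_when_established: bool = False,
                   ) -> dict[str, pd.DataFrame]:
    """Run all arms × replicates of a manifest; return summary tables.

    Returns ``{"records": per-replicate records, "final": final-day metric
    per replicate, "comparisons": treated-vs-control tables}``. With
    ``out_dir`` the tables plus the resolved parameter set are also written
    to CSV/JSON for provenance.
    """
    params = params or default_params()
    n_rep = replicates or manifest.replicates
    seed_root = np.random.SeedSequence(manifest.master_seed)
    arm_names = sorted(manifest.arms)
    arm_seeds = {a: s for a, s in zip(
        arm_names, seed_root.spawn(len(arm_names)))}
    records: dict[str, pd.DataFrame] = {}
    for arm in arm_names:
        plan, seed_spec = manifest.arms[arm]
        reps = []
        child_seeds = arm_seeds[arm].generate_state(n_rep) % (2**31 - 1)
        for rep in range(n_rep):
            p = params.replace(horizon_days=manifest.horizon_days)
            sim = Simulation(p, plan, seed_spec,
                             rng_seed=int(child_seeds[rep]))
            reps.append(sim.run(replicate_id=rep,
                                horizon_days=manifest.horizon_days,
                                stop_when_established=stop_when_established))
        records[arm] = pd.concat(reps, ignore_index=True)

    final_rows = []
    for arm in arm_names:
        vals = value_at_day(records[arm], manifest.compare_metric,
                            manifest.horizon_days)
        for rep, v in vals.items():
            final_rows.append({"arm": arm, "replicate_id": rep,
                               manifest.compare_metric: v})
    final = pd.DataFrame(final_rows)

    comp_rows = []
    if "control" in records and n_rep >= 3:
        for arm in arm_names:
            if arm == "control":
                continue
            for day in manifest.compare_days:
                c = compare_arms(records["control"], records[arm],
                                 manifest.compare_metric, day)
                comp_rows.append({
                    "arm": arm, "day": day, "metric": c.metric,
                    "control_mean": c.control_mean,
                    "treated_mean": c.treated_mean,
                    "control_sem": c.control_sem,
                    "treated_sem": c.treated_sem,
                    "percent_change": c.percent_change,
                    "p_value": c.p_value})
    comparisons = pd.DataFrame(comp_rows)

    out = {"records": pd.concat(
        [df.assign(arm=a) for a, df in records.items()], ignore_index=True),
        "final": final, "comparisons": comparisons}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out["records"].to_csv(out_dir / "records.csv", index=False)
        final.to_csv(out_dir / "final.csv", index=False)
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        params.save_json(out_dir / "params.json")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2) + "\n")
    return out
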