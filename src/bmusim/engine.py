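"""Simulation orchestration: time stepping, seeding, treatment scheduling.

A run advances the lattice in fixed 1-hour steps with the intra-step order
fields → osteoclast lineage → osteoblast lineage → cancer, all randomness
drawn from a single per-replicate generator so that identical inputs and
seed give bitwise-identical outputs.

Treatment arms are described by :class:`TreatmentPlan`: ``pre`` applies the
constant-efficacy inhibitor from day 1, ``post`` from day 80 (after the
vicious cycle is established), ``none`` never. Tumors are seeded on day 1
in every arm as a connected emboli abutting the bone surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import bioavailable_tgfb, normalize_tgfb, step_fields
from .lattice import (CANCER_PHENOTYPES, CellAgent, GridState, Phenotype,
                      audit, bone_adjacent_mask, make_initial_bmu,
                      place_agent)
from .params import ParamSet
from .stroma import stromal_step
from .tumor import cancer_secretion_sources, tumor_step

try:  # uniform_filter for local cancer density around stromal cells
    from scipy.ndimage import uniform_filter
except ImportError:  # pragma: no cover
    uniform_filter = None

__all__ = [
    "TreatmentPlan", "SeedSpec", "seed_tumor", "efficacy_at",
    "Simulation", "run_simulation", "EVENT_CLASSES",
]

EVENT_CLASSES = (
    "msc_division", "pob_division", "pob_differentiation", "pob_apoptosis",
    "aob_formation", "aob_retirement",
    "poc_fusion", "resorption", "aoc_apoptosis",
    "cancer_division", "cancer_apoptosis",
)

POST_TREATMENT_START_DAY = 80


@dataclass(frozen=True)
class TreatmentPlan:
    """Constant-efficacy TGFβ inhibition window."""

    mode: str = "none"            # none | pre | post
    efficacy: float = 0.0         # fraction of TGFβ made unavailable
    start_day: int | None = None  # defaults: pre -> 1, post -> 80

    def __post_init__(self) -> None:
        if self.mode not in ("none", "pre", "post"):
            raise ValueError(f"unknown treatment mode {self.mode!r}")
        if not 0.0 <= self.efficacy <= 0.99:
            raise ValueError("efficacy must lie in [0, 0.99]")
        if self.start_day is not None and self.start_day < 1:
            raise ValueError("start_day must be >= 1")

    @property
    def active_from(self) -> int | None:
        if self.mode == "none":
            return None
        if self.start_day is not None:
            return self.start_day
        return 1 if self.mode == "pre" else POST_TREATMENT_START_DAY


def efficacy_at(day: float, plan: TreatmentPlan | None) -> float:
    """Inhibitor efficacy on a given simulation day (0 when inactive)."""
    if day < 1:
        raise ValueError("days are counted from 1")
    if plan is None or plan.active_from is None or day < plan.active_from:
        return 0.0
    return plan.efficacy


@dataclass(frozen=True)
class SeedSpec:
    """Tumor emboli: size, clonal composition and seeding day."""

    clonal_counts: dict[Phenotype, int] = field(default_factory=dict)
    seed_day: int = 1

    def __post_init__(self) -> None:
        for ph, n in self.clonal_counts.items():
            if ph not in CANCER_PHENOTYPES:
                raise ValueError(f"{ph} is not a cancer phenotype")
            if n < 0:
                raise ValueError("clonal counts must be >= 0")

    @property
    def emboli_size(self) -> int:
        return sum(self.clonal_counts.values())

    @classmethod
    def trp(cls, n: int = 9, seed_day: int = 1) -> "SeedSpec":
        return cls({Phenotype.TRP: n}, seed_day)

    @classmethod
    def from_ratio(cls, ratio: dict[Phenotype, float], n: int,
                   seed_day: int = 1) -> "SeedSpec":
        """Clonal counts for ``n`` cells in proportion to ``ratio``.

        Largest-remainder apportionment, so seeding ``n = sum(ratio)`` cells
        from an integer ratio reproduces the ratio exactly (e.g. the patient
        ratio TP 1 : TRP 231 : TR 6 : TN 4 at n = 242).
        """
        total = float(sum(ratio.values()))
        quota = {ph: n * r / total for ph, r in ratio.items()}
        counts = {ph: int(q) for ph, q in quota.items()}
        remainder = n - sum(counts.values())
        by_frac = sorted(ratio, key=lambda ph: quota[ph] - counts[ph],
                         reverse=True)
        for ph in by_frac[:remainder]:
            counts[ph] += 1
        return cls({ph: c for ph, c in counts.items() if c > 0}, seed_day)


def seed_tumor(grid: GridState, spec: SeedSpec,
               rng: np.random.Generator) -> GridState:
    """Place the emboli as a connected cluster abutting the bone surface.

    Disseminated cancer cells home to active remodeling niches, so the
    cluster is placed beside the surface site with the most osteoclast
    precursors nearby (ties broken at random); if no precursors have
    reached the surface the site is uniform among bone-adjacent sites.
    """
    n = spec.emboli_size
    if n < 1:
        return grid
    surface = bone_adjacent_mask(grid.bone) & grid.empty_marrow_mask()
    starts = np.argwhere(surface)
    if len(starts) == 0:
        raise ValueError("no empty bone-adjacent site to seed the tumor")
    poc = (grid.phen == int(Phenotype.POC)).astype(float)
    if uniform_filter is not None and poc.any():
        local = uniform_filter(poc, size=5, mode="constant")
        w = local[starts[:, 0], starts[:, 1]]
        best = np.flatnonzero(w == w.max())
        start = tuple(starts[best[rng.integers(len(best))]])
    else:
        start = tuple(starts[rng.integers(len(starts))])
    # grow a connected blob of empty sites outward from the start
    sites = [start]
    chosen = {start}
    frontier = [start]
    while len(sites) < n:
        cand: set[tuple[int, int]] = set()
        for x, y in frontier:
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    ox, oy = x + dx, y + dy
                    if (dx or dy) and 0 <= ox < grid.nx and 0 <= oy < grid.ny \
                            and not grid.bone[ox, oy] \
                            and grid.phen[ox, oy] == 0 \
                            and (ox, oy) not in chosen:
                        cand.add((ox, oy))
        if not cand:
            raise ValueError(
                f"insufficient space for an emboli of {n} cells")
        ordered = sorted(cand)
        take = min(n - len(sites), len(ordered))
        pick = rng.choice(len(ordered), size=take, replace=False)
        new = [ordered[i] for i in sorted(pick)]
        sites.extend(new)
        chosen.update(new)
        frontier = new
    phenos: list[Phenotype] = []
    for ph, c in spec.clonal_counts.items():
        phenos.extend([ph] * c)
    phenos = [phenos[i] for i in rng.permutation(n)]
    for (x, y), ph in zip(sites, phenos):
        place_agent(grid, CellAgent(id=-1, phenotype=ph,
                                    position=(int(x), int(y))))
    return grid


class Simulation:
    """One replicate of the BMU, optionally tumor-seeded and treated."""

    def __init__(self, params: ParamSet,
                 plan: TreatmentPlan | None = None,
                 seed_spec: SeedSpec | None = None,
                 rng_seed: int | None = None,
                 *, freeze_fields: bool = False,
                 disable_stroma: bool = False,
                 audit_every_step: bool = False):
        self.params = params
        self.plan = plan or TreatmentPlan()
        self.seed_spec = seed_spec
        self.rng = np.random.default_rng(
            params.rng_seed if rng_seed is None else rng_seed)
        self.freeze_fields = freeze_fields
        self.disable_stroma = disable_stroma
        self.audit_every_step = audit_every_step
        self.grid = make_initial_bmu(params, self.rng)
        self.t_hours = 0.0
        self.counters = {k: 0 for k in EVENT_CLASSES}
        self._seeded = False
        self.initial_cancer = 0
        self.daily_cancer: dict[int, int] = {}

    @property
    def day(self) -> float:
        """Simulation day, counted from 1."""
        return self.t_hours / 24.0 + 1.0

    def _sources(self) -> dict[str, np.ndarray | float]:
        g, p = self.grid, self.params
        tgfb_src = np.full(g.phen.shape, p.tgfb_ambient_source_ng_ml_h)
        ob = (g.phen == int(Phenotype.POB)) | (g.phen == int(Phenotype.AOB))
        tgfb_src += ob * p.tgfb_secretion_ob_ng_ml_h
        # an actively resorbing aOC keeps making matrix TGFβ bioavailable
        aoc = g.phen == int(Phenotype.AOC)
        if aoc.any():
            active = aoc & bone_adjacent_mask(g.bone)
            tgfb_src += active * p.tgfb_resorption_source_ng_ml_h
        cancer = g.cancer_mask()
        if cancer.any():
            tgfb_src += cancer_secretion_sources(g, p)
        stromal = ((g.phen == int(Phenotype.MSC))
                   | (g.phen == int(Phenotype.POB)))
        rankl_src = stromal * p.rankl_secretion_stromal_h
        if cancer.any():
            dens = uniform_filter(cancer.astype(float),
                                  size=p.rankl_cancer_window, mode="constant")
            rankl_src = (rankl_src
                         * (1.0 + p.rankl_cancer_amplification * dens)
                         + cancer * p.rankl_secretion_cancer_h)
        return {"tgfb": tgfb_src, "rankl": rankl_src}

    def step(self) -> None:
        g, p = self.grid, self.params
        if self.seed_spec is not None and not self._seeded \
                and self.day >= self.seed_spec.seed_day:
            seed_tumor(g, self.seed_spec, self.rng)
            self._seeded = True
            self.initial_cancer = int(g.cancer_mask().sum())
        e = efficacy_at(self.day, self.plan)
        if not self.freeze_fields:
            step_fields(g.fields, self._sources(), p.dt_hours, p.site_size_um)
        t_bio = bioavailable_tgfb(normalize_tgfb(g.fields.tgfb, p), e)
        np.clip(t_bio, p.tgfb_floor_ng_ml / p.tgfb_saturation_ng_ml / 100.0,
                1.0, out=t_bio)  # keep response-law domain strictly positive
        if not self.disable_stroma:
            stromal_step(g, t_bio, e, self.rng, self.counters, p)
        tumor_step(g, e > 0.0, e, self.rng, self.counters, p)
        self.t_hours += p.dt_hours
        g.day = self.day
        if self.audit_every_step:
            audit(g)

    def record(self, replicate_id: int = 0) -> dict:
        g = self.grid
        row = {"replicate_id": replicate_id, "day": self.day,
               "bone_area_um2": g.bone_area_um2}
        cancer_total = 0
        for ph in Phenotype:
            c = g.count(ph)
            row[f"n_{ph.name}"] = c
            if ph in CANCER_PHENOTYPES:
                cancer_total += c
        row["n_cancer"] = cancer_total
        for ph in CANCER_PHENOTYPES:
            row[f"frac_{ph.name}"] = (row[f"n_{ph.name}"] / cancer_total
                                      if cancer_total else 0.0)
        for k in EVENT_CLASSES:
            row[f"cum_{k}"] = self.counters[k]
        return row

    def run(self, replicate_id: int = 0, *, horizon_days: int | None = None,
            stop_when_established: bool = False) -> pd.DataFrame:
        """Step to the horizon, recording metrics at the configured interval.

        With ``stop_when_established`` the run ends as soon as the tumor
        meets the sustained-growth (vicious-cycle) criterion — useful for
        emboli-threshold sweeps.
        """
        from .metrics import vicious_cycle_established
        p = self.params
        horizon = horizon_days if horizon_days is not None else p.horizon_days
        steps_per_day = int(round(24.0 / p.dt_hours))
        rec_every = max(1, int(round(p.record_interval_days * steps_per_day)))
        total_steps = horizon * steps_per_day
        rows = [self.record(replicate_id)]
        for istep in range(total_steps):
            self.step()
            if (istep + 1) % steps_per_day == 0:
                self.daily_cancer[int(round(self.day)) - 1] = \
                    int(self.grid.cancer_mask().sum())
            if (istep + 1) % rec_every == 0:
                rows.append(self.record(replicate_id))
                if stop_when_established and self._seeded:
                    extinct = rows[-1]["n_cancer"] == 0
                    if extinct or vicious_cycle_established(
                            self.daily_cancer, self.initial_cancer):
                        break
        return pd.DataFrame(rows)


def run_simulation(params: ParamSet, plan: TreatmentPlan | None = None,
                   seed_spec: SeedSpec | None = None,
                   rng_seed: int | None = None, replicate_id: int = 0,
                   **run_kw) -> tuple[pd.DataFrame, GridState]:
    """Convenience wrapper: build, run, and return (metrics, final grid)."""
    sim = Simulation(params, plan, seed_spec, rng_seed)
    records = sim.run(replicate_id, **run_kw)
    return records, sim.grid
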