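"""Cancer clone update rules: BDN-driven division, starvation, secretion.

Four clonal phenotypes of bone-metastatic prostate cancer are modeled by
their use of the TGFβ axis:

========  ==================  =====================  ==================
clone     baseline division   division under full    starvation
          time (days)         inhibition (days)      lifespan (days)
========  ==================  =====================  ==================
TRP       1.5                 2.0                    14
TR        1.75                2.0                    10
TP        1.75                1.75 (unchanged)       10
TN        2.0                 2.0  (unchanged)       12
========  ==================  =====================  ==================

TRP and TP secrete TGFβ ligand; TRP and TR carry the receptor, so only
their division times respond to the inhibitor.  The inhibitor's effect on
division time is linearly interpolated in efficacy between the baseline and
the fully inhibited value (the endpoints are the measured quantities;
intermediate efficacies are simulated, so a continuous interpolation is the
minimal assumption and is the principal modeling choice here).

Division probability per step is ``1 − exp(−rate·dt)`` with
``rate = (1 / effective_time) · clamp(1 + log10 BDN, 0, 1)``: zero division
without nutrients, maximal at nutrient saturation. Phenotype is heritable
and immutable; cancer cells are sessile (daughters occupy adjacent sites,
matching emboli growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import response_direct
from .lattice import (EMPTY, CellAgent, GridState, Phenotype, place_agent,
                      remove_agent)
from .params import ParamSet

__all__ = [
    "PhenotypeSpec", "phenotype_table", "cancer_division_probability",
    "starvation_update", "cancer_secretion_sources", "tumor_step",
]

_MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class PhenotypeSpec:
    """Static description of one cancer clone."""

    name: str
    baseline_division_days: float
    inhibited_division_days: float
    starvation_lifespan_days: float
    secretes_tgfb: bool
    has_receptor: bool


def phenotype_table(params: ParamSet) -> dict[Phenotype, PhenotypeSpec]:
    """The four clonal phenotypes, built from the parameter set."""
    return {
        Phenotype.TRP: PhenotypeSpec(
            "TRP", params.div_TRP_days, params.div_TRP_inhibited_days,
            params.lifespan_TRP_days, secretes_tgfb=True, has_receptor=True),
        Phenotype.TR: PhenotypeSpec(
            "TR", params.div_TR_days, params.div_TR_inhibited_days,
            params.lifespan_TR_days, secretes_tgfb=False, has_receptor=True),
        Phenotype.TP: PhenotypeSpec(
            "TP", params.div_TP_days, params.div_TP_inhibited_days,
            params.lifespan_TP_days, secretes_tgfb=True, has_receptor=False),
        Phenotype.TN: PhenotypeSpec(
            "TN", params.div_TN_days, params.div_TN_inhibited_days,
            params.lifespan_TN_days, secretes_tgfb=False, has_receptor=False),
    }


def cancer_division_probability(spec: PhenotypeSpec, bdn, inhibitor_active:
                                bool, efficacy: float, dt: float,
                                floor: float = 0.01):
    """Per-step division probability for one clone at local nutrient level.

    ``bdn`` may be a scalar or array in [0, 1]. Receptor-less clones (TP,
    TN) have ``inhibited == baseline`` so the inhibitor cannot change their
    rate by construction.
    """
    bdn = np.asarray(bdn, dtype=float)
    if np.any(bdn < 0) or np.any(bdn > 1):
        raise ValueError("bdn must lie in [0, 1]")
    days = spec.baseline_division_days
    if inhibitor_active:
        days = days + efficacy * (spec.inhibited_division_days - days)
    rate = (1.0 / (days * 24.0)) * response_direct(np.clip(bdn, floor, 1.0))
    p = np.where(bdn > 0.0, 1.0 - np.exp(-rate * dt), 0.0)
    return float(p) if p.ndim == 0 else p


def starvation_update(cell: CellAgent, bdn: float, dt: float,
                      spec: PhenotypeSpec,
                      contact_threshold: float = 0.01) -> CellAgent:
    """Advance one cancer cell's starvation clock; may mark it dead.

    Contact with nutrients (``bdn >= contact_threshold``) resets the clock;
    otherwise it advances by ``dt`` and the cell dies once the clock exceeds
    the clone's starvation lifespan.
    """
    if cell.phenotype not in (Phenotype.TRP, Phenotype.TR, Phenotype.TP,
                              Phenotype.TN):
        raise ValueError("starvation applies to cancer phenotypes only")
    if bdn >= contact_threshold:
        cell.starvation_hours = 0.0
    else:
        cell.starvation_hours += dt
    if cell.starvation_hours > spec.starvation_lifespan_days * 24.0:
        cell.alive = False
    return cell


def cancer_secretion_sources(grid: GridState, params: ParamSet) -> np.ndarray:
    """Per-site TGFβ secretion rate (ng/ml/h) from ligand-producing clones."""
    producing = ((grid.phen == int(Phenotype.TRP))
                 | (grid.phen == int(Phenotype.TP)))
    return producing * params.tgfb_secretion_cancer_ng_ml_h


def tumor_step(grid: GridState, inhibitor_active: bool, efficacy: float,
               rng: np.random.Generator, counters: dict,
               params: ParamSet) -> None:
    """One tumor update: starvation, division, nutrient uptake.

    Starvation clocks and division draws are evaluated against the local
    BDN at the start of the sweep; daughters inherit the parent phenotype
    and occupy a uniformly chosen empty Moore neighbor (division is blocked
    by crowding). Ligand secretion is applied through the field source terms
    assembled by the engine; uptake is applied here as a local sink.
    """
    dt = params.dt_hours
    specs = phenotype_table(params)
    pos = np.argwhere(grid.cancer_mask())
    if len(pos) == 0:
        return
    xs, ys = pos[:, 0], pos[:, 1]
    bdn = grid.fields.bdn[xs, ys]
    bdn_norm = np.clip(bdn, 0.0, 1.0)
    phen = grid.phen[xs, ys]

    # --- starvation clocks (vectorized form of starvation_update) --------
    fed = bdn >= params.bdn_contact_threshold
    starv = grid.starv_h[xs, ys]
    starv = np.where(fed, 0.0, starv + dt)
    grid.starv_h[xs, ys] = starv
    lifespan_h = np.empty(len(pos))
    for ph, spec in specs.items():
        lifespan_h[phen == int(ph)] = spec.starvation_lifespan_days * 24.0
    dead = starv > lifespan_h

    # --- division draws ---------------------------------------------------
    p_div = np.zeros(len(pos))
    for ph, spec in specs.items():
        sel = (phen == int(ph)) & ~dead
        if sel.any():
            p_div[sel] = cancer_division_probability(
                spec, bdn_norm[sel], inhibitor_active, efficacy, dt,
                floor=params.bdn_division_floor)
    draws = rng.random(len(pos))
    dividing = draws < p_div

    # --- apply events in a random sweep order ----------------------------
    grid.age_h[xs[~dead], ys[~dead]] += dt
    events = np.where(dead | dividing)[0]
    order = events[rng.permutation(len(events))]
    for i in order:
        x, y = int(xs[i]), int(ys[i])
        if dead[i]:
            remove_agent(grid, int(grid.agent_id[x, y]))
            counters["cancer_apoptosis"] += 1
            continue
        opts = [(x + dx, y + dy) for dx, dy in _MOORE
                if 0 <= x + dx < grid.nx and 0 <= y + dy < grid.ny
                and not grid.bone[x + dx, y + dy]
                and grid.phen[x + dx, y + dy] == EMPTY]
        if not opts:
            continue   # contact inhibition
        tx, ty = opts[rng.integers(len(opts))]
        place_agent(grid, CellAgent(id=-1, phenotype=Phenotype(int(phen[i])),
                                    position=(tx, ty)))
        counters["cancer_division"] += 1

    # --- nutrient uptake --------------------------------------------------
    alive = ~dead
    if alive.any():
        np.subtract.at(grid.fields.bdn, (xs[alive], ys[alive]),
                       params.bdn_uptake_per_cell_h * dt)
        np.maximum(grid.fields.bdn, 0.0, out=grid.fields.bdn)
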