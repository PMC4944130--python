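"""Bone-stroma update rules: MSC, pOB, aOB, pOC, aOC.

The two coupling laws the stroma contributes to the model are

* precursor division/fusion is inversely proportional to bioavailable TGFβ:
  ``rate = Div_max · clamp(−log10 T, 0, 1)`` — applied identically to pOB
  division and to pOC fusion attempts, so active resorption (high local
  TGFβ) limits further osteoclastogenesis and osteoblast expansion;
* adult-osteoclast survival is directly proportional to bioavailable TGFβ:
  per-step survival ``Surv_max · clamp(1 + log10 T, 0, 1)`` — aOCs persist
  only while the matrix they resorb keeps local TGFβ near saturation, and
  any degree of inhibition shortens their lifetime sharply.

Bone resorption and formation are site-quantized: an aOC removes one
adjacent bone site per ``resorption_interval_h`` (releasing the matrix-bound
TGFβ and nutrient quanta) and an aOB deposits one adjacent bone site per
``aob_formation_interval_h``, preferring concave surface sites so resorption
pits refill before new apposition.

Rates are converted to per-step probabilities with ``p = 1 − exp(−rate·dt)``
(exact for exponential waiting times). Stochastic decisions within each
lineage are drawn synchronously against the start-of-sweep state; the
resulting events (placements, removals, moves) are applied sequentially in
a random order, so crowding conflicts are resolved without sweep bias.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .fields import release_from_bone, response_direct, response_inverse
from .lattice import (EMPTY, CellAgent, GridState, Phenotype,
                      bone_adjacent_mask, move_agent, place_agent,
                      remove_agent)
from .params import ParamSet

__all__ = [
    "rate_to_prob", "precursor_division_rate", "aoc_survival_probability",
    "attempt_fusion", "resorb_step", "osteoblast_lifecycle_step",
    "stromal_step",
]

_MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_VN = ((-1, 0), (1, 0), (0, -1), (0, 1))
_LABEL8 = np.ones((3, 3), dtype=int)

_POB = int(Phenotype.POB)
_AOB = int(Phenotype.AOB)
_POC = int(Phenotype.POC)
_AOC = int(Phenotype.AOC)
_MSC = int(Phenotype.MSC)


def rate_to_prob(rate, dt: float):
    """Exponential-waiting-time conversion, p = 1 − exp(−rate·dt)."""
    if isinstance(rate, float):
        return 1.0 - math.exp(-rate * dt)
    return 1.0 - np.exp(-np.asarray(rate, dtype=float) * dt)


def precursor_division_rate(t, max_rate: float):
    """Precursor law: ``max_rate · response_inverse(T)``.

    Used for pOB division and for pOC fusion attempts alike; zero at TGFβ
    saturation, maximal in its absence.
    """
    return max_rate * response_inverse(t)


def aoc_survival_probability(t, surv_max: float):
    """Per-step aOC survival, ``surv_max · response_direct(T)``."""
    return surv_max * response_direct(t)


# ---------------------------------------------------------------------------
# small geometry helpers (hot paths: no property lookups, plain ints)
# ---------------------------------------------------------------------------

def _free_moore(grid: GridState, x: int, y: int) -> list[tuple[int, int]]:
    nx, ny = grid.phen.shape
    bone, phen = grid.bone, grid.phen
    out = []
    for dx, dy in _MOORE:
        ox, oy = x + dx, y + dy
        if 0 <= ox < nx and 0 <= oy < ny and not bone[ox, oy] \
                and phen[ox, oy] == EMPTY:
            out.append((ox, oy))
    return out


def _has_bone_vn(grid: GridState, x: int, y: int) -> bool:
    nx, ny = grid.bone.shape
    bone = grid.bone
    for dx, dy in _VN:
        ox, oy = x + dx, y + dy
        if 0 <= ox < nx and 0 <= oy < ny and bone[ox, oy]:
            return True
    return False


def _bone_vn_count(grid: GridState, x: int, y: int) -> int:
    nx, ny = grid.bone.shape
    bone = grid.bone
    n = 0
    for dx, dy in _VN:
        ox, oy = x + dx, y + dy
        if 0 <= ox < nx and 0 <= oy < ny and bone[ox, oy]:
            n += 1
    return n


def _moore_count(mask: np.ndarray) -> np.ndarray:
    """Per-site count of Moore neighbors set in ``mask``."""
    p = np.pad(mask.astype(np.uint8), 1)
    return (p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
            + p[1:-1, :-2] + p[1:-1, 2:]
            + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:])


def _home_or_random_move(grid: GridState, x: int, y: int, chemo_p: float,
                         rng: np.random.Generator) -> None:
    """Move one site: toward the bone surface (lowest free neighbor) with
    probability ``chemo_p``, else uniformly among free neighbors."""
    opts = _free_moore(grid, x, y)
    if not opts:
        return
    if rng.random() < chemo_p:
        ymin = min(oy for _, oy in opts)
        if ymin < y:   # descend toward the surface; drift on plateaus
            opts = [o for o in opts if o[1] == ymin]
    tx, ty = opts[rng.integers(len(opts))]
    move_agent(grid, int(grid.agent_id[x, y]), (tx, ty))


def _poc_walk(grid: GridState, mv: np.ndarray, surf: np.ndarray,
              chemo_p: float, rng: np.random.Generator,
              kind: int = _POC, patrol: bool = True) -> None:
    """Batched precursor walk against a start-of-sweep occupancy snapshot.

    Surface-resident precursors patrol along the surface, drifting up the
    RANKL gradient toward active lesions (pOC only); marrow precursors
    descend toward the surface. Moves are committed in random priority,
    one winner per contested target site. Also used for pOB homing with
    ``patrol=False`` (pOBs settle once bone-adjacent instead).
    """
    nx, ny = grid.phen.shape
    n = len(mv)
    free = (grid.phen == EMPTY) & ~grid.bone
    fp = np.zeros((nx + 2, ny + 2), dtype=bool)
    fp[1:-1, 1:-1] = free
    sp = np.zeros_like(fp)
    sp[1:-1, 1:-1] = surf
    rp = np.full((nx + 2, ny + 2), -np.inf)
    rp[1:-1, 1:-1] = grid.fields.rankl
    X, Y = mv[:, 0] + 1, mv[:, 1] + 1
    offs = np.asarray(_MOORE)
    NX = X[None, :] + offs[:, 0:1]          # (8, n) neighbor coordinates
    NY = Y[None, :] + offs[:, 1:2]
    opts = fp[NX, NY]
    on_surf = sp[X, Y] if patrol else np.zeros(n, dtype=bool)
    chemo = rng.random(n) < chemo_p
    if patrol:
        # surface patrol: stay on the surface, follow the RANKL gradient
        surf_opts = opts & sp[NX, NY]
        gains = np.where(surf_opts, rp[NX, NY], -np.inf)
        best = gains.max(axis=0)
        graded = on_surf & chemo & (best > rp[X, Y])
        opts = np.where(on_surf[None, :], surf_opts, opts)
        opts[:, graded] &= gains[:, graded] == best[graded]
    # marrow homing: descend to the lowest free neighbor
    ny_opt = np.where(opts, NY - 1, np.iinfo(np.int64).max)
    ymin = ny_opt.min(axis=0)
    desc = ~on_surf & chemo & (ymin < mv[:, 1])
    opts[:, desc] &= ny_opt[:, desc] == ymin[desc]
    movable = opts.any(axis=0)
    if not movable.any():
        return
    u = rng.random((8, n))
    u[~opts] = -1.0
    pick = u.argmax(axis=0)
    cols = np.arange(n)
    tx = NX[pick, cols] - 1
    ty = NY[pick, cols] - 1
    # one winner per contested target, random priority
    priority = rng.permutation(n)
    tflat = np.where(movable, tx * ny + ty, -1)
    order = np.lexsort((priority, tflat))
    ts = tflat[order]
    first = np.ones(n, dtype=bool)
    first[1:] = ts[1:] != ts[:-1]
    win = order[first & movable[order]]
    if not len(win):
        return
    sx, sy = mv[win, 0], mv[win, 1]
    dx_, dy_ = tx[win], ty[win]
    aids = grid.agent_id[sx, sy].copy()
    ages = grid.age_h[sx, sy].copy()
    grid.phen[sx, sy] = EMPTY
    grid.agent_id[sx, sy] = -1
    grid.age_h[sx, sy] = 0.0
    grid.nuclei[sx, sy] = 0
    grid.phen[dx_, dy_] = kind
    grid.agent_id[dx_, dy_] = aids
    grid.age_h[dx_, dy_] = ages
    grid.nuclei[dx_, dy_] = 1
    reg = grid.registry
    for aid, a, b in zip(aids.tolist(), dx_.tolist(), dy_.tolist()):
        reg[aid] = (a, b)


# ---------------------------------------------------------------------------
# osteoclast lineage
# ---------------------------------------------------------------------------

def attempt_fusion(grid: GridState, members: list[tuple[int, int]],
                   t_bio_local: float, rng: np.random.Generator,
                   params: ParamSet) -> int | None:
    """Attempt to fuse a bone-adjacent pOC cluster into one aOC.

    ``members`` must contain at least ``fusion_threshold`` mutually adjacent
    pOCs of which the first is bone-adjacent (the fusion site). With
    probability ``1 − exp(−Div_pOC · response_inverse(T) · dt)`` the closest
    ``fusion_threshold`` precursors merge into a multinucleated aOC whose
    resorption clock starts expired (resorption begins immediately at the
    surface). Returns the new agent id, or None if no fusion occurred.
    """
    k = params.fusion_threshold
    if len(members) < k:
        raise ValueError(f"fusion needs >= {k} pOCs, got {len(members)}")
    rate = precursor_division_rate(float(t_bio_local),
                                   params.div_pOC_max_per_h)
    if rng.random() >= rate_to_prob(rate, params.dt_hours):
        return None
    sx, sy = members[0]
    order = sorted(members, key=lambda p: (p[0] - sx) ** 2 + (p[1] - sy) ** 2)
    for x, y in order[:k]:
        remove_agent(grid, int(grid.agent_id[x, y]))
    aid = place_agent(grid, CellAgent(id=-1, phenotype=Phenotype.AOC,
                                      position=(sx, sy), nuclei=k))
    grid.clock_h[sx, sy] = (params.resorption_interval_h
                            * params.aoc_initial_resorptions)
    return aid


def resorb_step(grid: GridState, pos: tuple[int, int],
                rng: np.random.Generator, params: ParamSet) -> bool:
    """One aOC action step: resorb an adjacent bone site when due.

    Removes one von Neumann-adjacent bone site once the resorption clock has
    run down, releases the matrix-bound TGFβ/BDN quanta there, and advances
    the aOC into the freshly opened cavity. Returns True if a site was
    resorbed.
    """
    x, y = pos
    nx, ny = grid.bone.shape
    bone_nb = [(x + dx, y + dy) for dx, dy in _VN
               if 0 <= x + dx < nx and 0 <= y + dy < ny
               and grid.bone[x + dx, y + dy]]
    if not bone_nb:
        grid.idle_h[x, y] += params.dt_hours
        return False
    grid.idle_h[x, y] = 0.0
    grid.clock_h[x, y] += params.dt_hours
    if grid.clock_h[x, y] < params.resorption_interval_h:
        return False
    grid.clock_h[x, y] -= params.resorption_interval_h
    tx, ty = bone_nb[rng.integers(len(bone_nb))]
    grid.bone[tx, ty] = False
    release_from_bone(grid.fields, (tx, ty), params)
    move_agent(grid, int(grid.agent_id[x, y]), (tx, ty))
    return True


def _osteoclast_lineage(grid: GridState, t_bio: np.ndarray, efficacy: float,
                        rng: np.random.Generator, counters: dict,
                        params: ParamSet) -> None:
    dt = params.dt_hours
    phen = grid.phen
    # --- pOC recruitment, driven by total RANKL --------------------------
    n_poc = int((phen == _POC).sum())
    lam = params.poc_recruit_coeff * float(grid.fields.rankl.sum()) * dt
    n_new = min(int(rng.poisson(lam)), params.poc_max - n_poc)
    if n_new > 0:
        # inverse-CDF sampling of empty marrow sites, RANKL-weighted
        w = np.where(grid.empty_marrow_mask(),
                     grid.fields.rankl + 1e-9, 0.0).ravel()
        cum = np.cumsum(w)
        total = cum[-1]
        if total > 0:
            ncol = grid.phen.shape[1]
            for r in rng.random(n_new):
                flat = int(np.searchsorted(cum, r * total))
                x, y = divmod(flat, ncol)
                if grid.phen[x, y] == EMPTY and not grid.bone[x, y]:
                    place_agent(grid, CellAgent(
                        id=-1, phenotype=Phenotype.POC, position=(x, y)))
    # --- pOC aging/death, then walk: home to the surface, stick to peers -
    poc_mask = phen == _POC
    if poc_mask.any():
        surf = bone_adjacent_mask(grid.bone)
        # settle on the surface beside a peer, or mound onto a surface-bound
        # peer: clusters can then assemble in narrow gaps between cancer
        # cells at the tumor-bone interface
        surf_poc = poc_mask & surf
        settled = poc_mask & ((surf & (_moore_count(poc_mask) > 0))
                              | (_moore_count(surf_poc) > 0))
        pos = np.argwhere(poc_mask)
        grid.age_h[poc_mask] += dt
        dead = grid.age_h[pos[:, 0], pos[:, 1]] \
            > params.poc_lifespan_days * 24.0
        for x, y in pos[dead]:
            remove_agent(grid, int(grid.agent_id[x, y]))
        movers = (~dead & ~settled[pos[:, 0], pos[:, 1]]
                  & (rng.random(len(pos)) < params.poc_move_prob))
        mv = pos[movers]
        if len(mv):
            _poc_walk(grid, mv, surf, params.poc_chemotaxis_prob, rng)

    # --- fusion of bone-adjacent clusters --------------------------------
    poc_mask = phen == _POC
    if int(poc_mask.sum()) >= params.fusion_threshold:
        surf = bone_adjacent_mask(grid.bone)
        labels, n_lab = ndimage.label(poc_mask, structure=_LABEL8)
        if n_lab:
            pos = np.argwhere(poc_mask)
            labs = labels[pos[:, 0], pos[:, 1]]
            sizes = np.bincount(labs, minlength=n_lab + 1)
            order = np.argsort(labs, kind="stable")
            spos = pos[order]
            bounds = np.concatenate(([0], np.cumsum(sizes[1:])))
            for lab in range(1, n_lab + 1):
                if sizes[lab] < params.fusion_threshold:
                    continue
                seg = spos[bounds[lab - 1]:bounds[lab]]
                comp = [tuple(p) for p in seg]
                # a large aggregation supports one independent fusion
                # attempt per fusion_threshold precursors it contains
                for _ in range(len(comp) // params.fusion_threshold):
                    if len(comp) < params.fusion_threshold:
                        break
                    anchors = [p for p in comp if surf[p]]
                    if not anchors:
                        break
                    anchor = anchors[rng.integers(len(anchors))]
                    members = [anchor] + [p for p in comp if p != anchor]
                    aid = attempt_fusion(grid, members, float(t_bio[anchor]),
                                         rng, params)
                    if aid is not None:
                        counters["poc_fusion"] += 1
                        comp = [p for p in comp if grid.phen[p] == _POC]

    # --- aOC resorption and TGFβ-dependent survival ----------------------
    aoc_pos = np.argwhere(phen == _AOC)
    sat = params.tgfb_saturation_ng_ml
    t_floor = params.tgfb_floor_ng_ml / sat
    for i in rng.permutation(len(aoc_pos)):
        x, y = int(aoc_pos[i, 0]), int(aoc_pos[i, 1])
        aid = int(grid.agent_id[x, y])
        grid.age_h[x, y] += dt
        if resorb_step(grid, (x, y), rng, params):
            counters["resorption"] += 1
        ax, ay = grid.registry[aid]   # may have advanced into the cavity
        # survival reads the live field so the quantum just released by this
        # aOC's own resorption counts toward its persistence
        t_live = min(max(float(grid.fields.tgfb[ax, ay]) / sat, t_floor),
                     1.0) * (1.0 - efficacy)
        surv = aoc_survival_probability(t_live, params.surv_aOC_max)
        expired = grid.age_h[ax, ay] > params.aoc_lifespan_days * 24.0
        idle = grid.idle_h[ax, ay] > params.aoc_idle_lifespan_h
        if expired or idle or rng.random() >= surv:
            remove_agent(grid, aid)
            counters["aoc_apoptosis"] += 1


# ---------------------------------------------------------------------------
# osteoblast lineage
# ---------------------------------------------------------------------------

def osteoblast_lifecycle_step(grid: GridState, pos: tuple[int, int],
                              t_bio: np.ndarray, rng: np.random.Generator,
                              counters: dict, params: ParamSet,
                              n_pob: int | None = None) -> int:
    """Advance one MSC/pOB/aOB agent by one step (reference rule).

    MSC divide asymmetrically (MSC + pOB daughter) at a fixed slow rate,
    throttled by the marrow-niche ceiling ``pob_max``. pOB divide at the
    TGFβ-inverse precursor rate (same ceiling), home toward the bone
    surface, and differentiate to aOB once bone-adjacent and below the TGFβ
    differentiation threshold; they die if they exhaust their lifespan
    undifferentiated. aOB deposit one adjacent bone site per formation
    interval (concave pit sites first) and retire at end of life.

    Returns the updated pOB census so a sweep can track the niche ceiling.
    The engine's lineage sweep applies these same rules with vectorized
    draws; this per-agent form is the readable reference and is exercised
    directly by the unit tests.
    """
    x, y = pos
    kind = int(grid.phen[x, y])
    dt = params.dt_hours
    if n_pob is None:
        n_pob = int((grid.phen == _POB).sum())
    grid.age_h[x, y] += dt

    if kind == _MSC:
        p = rate_to_prob(1.0 / (params.msc_asym_division_days * 24.0), dt)
        if n_pob < params.pob_max and rng.random() < p:
            n_pob += _try_place(grid, x, y, Phenotype.POB, rng, counters,
                                "msc_division")
        return n_pob

    if kind == _POB:
        if grid.age_h[x, y] > params.pob_lifespan_days * 24.0:
            remove_agent(grid, int(grid.agent_id[x, y]))
            counters["pob_apoptosis"] += 1
            return n_pob - 1
        t_here = float(t_bio[x, y])
        rate = precursor_division_rate(t_here, params.div_pOB_max_per_h)
        if n_pob < params.pob_max and rng.random() < rate_to_prob(rate, dt):
            n_pob += _try_place(grid, x, y, Phenotype.POB, rng, counters,
                                "pob_division")
        bone_adj = _has_bone_vn(grid, x, y)
        if bone_adj and t_here < params.pob_diff_threshold \
                and rng.random() < rate_to_prob(params.pob_diff_rate_per_h,
                                                dt):
            grid.phen[x, y] = _AOB
            grid.age_h[x, y] = 0.0
            grid.clock_h[x, y] = 0.0
            counters["pob_differentiation"] += 1
            return n_pob - 1
        if not bone_adj and rng.random() < params.pob_move_prob:
            _home_or_random_move(grid, x, y, params.pob_chemotaxis_prob, rng)
        return n_pob

    if kind == _AOB:
        if grid.age_h[x, y] > params.aob_lifespan_days * 24.0:
            remove_agent(grid, int(grid.agent_id[x, y]))
            counters["aob_retirement"] += 1
            return n_pob
        grid.clock_h[x, y] += dt
        if grid.clock_h[x, y] >= params.aob_formation_interval_h:
            target = _deposit_target(grid, x, y, rng)
            if target is not None:
                grid.clock_h[x, y] -= params.aob_formation_interval_h
                grid.bone[target] = True
                counters["aob_formation"] += 1
            else:
                # walk along the surface looking for a place to build
                opts = [(ox, oy) for ox, oy in _free_moore(grid, x, y)
                        if _has_bone_vn(grid, ox, oy)]
                if opts:
                    tx, ty = opts[rng.integers(len(opts))]
                    move_agent(grid, int(grid.agent_id[x, y]), (tx, ty))
        return n_pob
    return n_pob


def _try_place(grid: GridState, x: int, y: int, phenotype: Phenotype,
               rng: np.random.Generator, counters: dict, event: str) -> int:
    opts = _free_moore(grid, x, y)
    if not opts:
        return 0   # contact inhibition
    tx, ty = opts[rng.integers(len(opts))]
    place_agent(grid, CellAgent(id=-1, phenotype=phenotype,
                                position=(tx, ty)))
    counters[event] += 1
    return 1


def _deposit_target(grid: GridState, x: int, y: int,
                    rng: np.random.Generator) -> tuple[int, int] | None:
    """Empty bone-adjacent neighbor site; concave (pit) sites preferred."""
    nx, ny = grid.bone.shape
    best: list[tuple[int, int]] = []
    best_n = 0
    for dx, dy in _MOORE:
        ox, oy = x + dx, y + dy
        if not (0 <= ox < nx and 0 <= oy < ny):
            continue
        if grid.bone[ox, oy] or grid.phen[ox, oy] != EMPTY:
            continue
        n = _bone_vn_count(grid, ox, oy)
        if n > best_n:
            best, best_n = [(ox, oy)], n
        elif n == best_n and n > 0:
            best.append((ox, oy))
    if not best:
        return None
    return best[rng.integers(len(best))]


def _osteoblast_lineage(grid: GridState, t_bio: np.ndarray,
                        rng: np.random.Generator, counters: dict,
                        params: ParamSet) -> None:
    """Vectorized-draw equivalent of per-agent osteoblast_lifecycle_step."""
    dt = params.dt_hours
    phen = grid.phen
    n_pob = int((phen == _POB).sum())

    # MSC: asymmetric divisions
    msc_pos = np.argwhere(phen == _MSC)
    if len(msc_pos):
        grid.age_h[phen == _MSC] += dt
        p = rate_to_prob(1.0 / (params.msc_asym_division_days * 24.0), dt)
        hits = np.where(rng.random(len(msc_pos)) < p)[0]
        for i in hits[rng.permutation(len(hits))]:
            if n_pob >= params.pob_max:
                break
            n_pob += _try_place(grid, int(msc_pos[i, 0]), int(msc_pos[i, 1]),
                                Phenotype.POB, rng, counters, "msc_division")

    # pOB: death, division, differentiation, homing — synchronous draws
    pob_pos = np.argwhere(phen == _POB)
    if len(pob_pos):
        xs, ys = pob_pos[:, 0], pob_pos[:, 1]
        grid.age_h[xs, ys] += dt
        t_here = t_bio[xs, ys]
        dead = grid.age_h[xs, ys] > params.pob_lifespan_days * 24.0
        div_p = rate_to_prob(
            params.div_pOB_max_per_h * response_inverse(t_here), dt)
        draws = rng.random((3, len(pob_pos)))
        dividing = (draws[0] < div_p) & ~dead
        surf = bone_adjacent_mask(grid.bone)
        bone_adj = surf[xs, ys]
        diff_p = rate_to_prob(params.pob_diff_rate_per_h, dt)
        differentiating = (bone_adj & (t_here < params.pob_diff_threshold)
                           & (draws[1] < diff_p) & ~dead)
        events = np.where(dead | dividing | differentiating)[0]
        for i in events[rng.permutation(len(events))]:
            x, y = int(xs[i]), int(ys[i])
            if dead[i]:
                remove_agent(grid, int(grid.agent_id[x, y]))
                counters["pob_apoptosis"] += 1
                n_pob -= 1
            elif dividing[i]:
                if n_pob < params.pob_max:
                    n_pob += _try_place(grid, x, y, Phenotype.POB, rng,
                                        counters, "pob_division")
            elif differentiating[i]:
                grid.phen[x, y] = _AOB
                grid.age_h[x, y] = 0.0
                grid.clock_h[x, y] = 0.0
                counters["pob_differentiation"] += 1
                n_pob -= 1
        moving = (~bone_adj & (draws[2] < params.pob_move_prob)
                  & ~dead & ~dividing & ~differentiating)
        if moving.any():
            _poc_walk(grid, pob_pos[moving], surf, params.pob_chemotaxis_prob,
                      rng, kind=_POB, patrol=False)

    # aOB: deposition and retirement (small population, per-agent loop)
    aob_pos = np.argwhere(phen == _AOB)
    for i in rng.permutation(len(aob_pos)):
        x, y = int(aob_pos[i, 0]), int(aob_pos[i, 1])
        if grid.phen[x, y] != _AOB:
            continue
        osteoblast_lifecycle_step(grid, (x, y), t_bio, rng, counters,
                                  params, n_pob)


def stromal_step(grid: GridState, t_bio: np.ndarray, efficacy: float,
                 rng: np.random.Generator, counters: dict,
                 params: ParamSet) -> None:
    """One full stromal update: osteoclast lineage, then osteoblast lineage."""
    _osteoclast_lineage(grid, t_bio, efficacy, rng, counters, params)
    _osteoblast_lineage(grid, t_bio, rng, counters, params)
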