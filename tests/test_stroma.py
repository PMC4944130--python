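"""Stromal rules: precursor laws, fusion, resorption, osteoblast lifecycle."""

import numpy as np
import pytest

from bmusim.engine import Simulation
from bmusim.fields import normalize_tgfb
from bmusim.lattice import (CellAgent, Phenotype, bone_adjacent_mask,
                            place_agent)
from bmusim.params import default_params
from bmusim.stroma import (aoc_survival_probability, attempt_fusion,
                           precursor_division_rate, rate_to_prob,
                           resorb_step, osteoblast_lifecycle_step)


class TestPrecursorLaw:
    def test_zero_at_saturation(self):
        assert precursor_division_rate(1.0, 1 / 36) == 0.0

    def test_max_without_tgfb(self):
        assert precursor_division_rate(0.1, 1 / 36) == pytest.approx(1 / 36)

    def test_intermediate(self):
        assert precursor_division_rate(0.5, 1 / 36) == pytest.approx(
            -np.log10(0.5) / 36)


class TestAocSurvival:
    def test_full_survival_at_saturation(self):
        assert aoc_survival_probability(1.0, 1.0) == 1.0

    def test_zero_at_floor(self):
        assert aoc_survival_probability(0.1, 1.0) == 0.0

    def test_intermediate(self):
        assert aoc_survival_probability(0.5, 1.0) == pytest.approx(
            1 + np.log10(0.5))


class TestRateToProb:
    def test_exponential_form(self):
        assert rate_to_prob(0.1, 2.0) == pytest.approx(1 - np.exp(-0.2))

    def test_array_form(self):
        r = np.array([0.0, 0.5])
        assert rate_to_prob(r, 1.0) == pytest.approx(1 - np.exp(-r))


def _place_poc_cluster(grid, k, x0=8):
    """k pOCs in a row on the bone surface; returns their positions."""
    surf = np.argwhere(bone_adjacent_mask(grid.bone))
    y = surf[0, 1]
    pos = [(x0 + i, int(y)) for i in range(k)]
    for p in pos:
        if grid.phen[p] == 0:
            place_agent(grid, CellAgent(id=-1, phenotype=Phenotype.POC,
                                        position=p))
    return pos


class TestFusion:
    def test_below_threshold_rejected(self, toy_grid, rng):
        pos = _place_poc_cluster(toy_grid, 3)
        with pytest.raises(ValueError):
            attempt_fusion(toy_grid, pos, 0.1, rng, toy_grid.params)

    def test_fusion_blocked_at_tgfb_saturation(self, toy_grid, rng):
        pos = _place_poc_cluster(toy_grid, 5)
        for _ in range(200):
            assert attempt_fusion(toy_grid, pos, 1.0, rng,
                                  toy_grid.params) is None

    def test_fusion_consumes_threshold_pocs_and_makes_multinucleated_aoc(
            self, toy_grid, rng):
        p = toy_grid.params
        pos = _place_poc_cluster(toy_grid, p.fusion_threshold)
        aid = None
        for _ in range(500):
            aid = attempt_fusion(toy_grid, pos, 0.1, rng, p)
            if aid is not None:
                break
        assert aid is not None
        assert toy_grid.count(Phenotype.POC) == toy_grid.params.init_poc
        aoc = toy_grid.agent_at(toy_grid.registry[aid])
        assert aoc.phenotype is Phenotype.AOC
        assert aoc.nuclei == p.fusion_threshold
        # resorption clock pre-loaded: first lacuna starts immediately
        assert toy_grid.clock_h[toy_grid.registry[aid]] >= \
            p.resorption_interval_h

    def test_empirical_fusion_frequency_matches_closed_form(self, toy_params,
                                                            rng):
        """Monte-Carlo: fusion frequency at T=0.5 ~ 1-exp(-rate*dt)."""
        from bmusim.lattice import make_initial_bmu
        p_th = rate_to_prob(
            precursor_division_rate(0.5, toy_params.div_pOC_max_per_h), 1.0)
        n, hits = 3000, 0
        grid = make_initial_bmu(toy_params, rng)
        pos = _place_poc_cluster(grid, toy_params.fusion_threshold)
        for _ in range(n):
            aid = attempt_fusion(grid, pos, 0.5, rng, toy_params)
            if aid is not None:
                hits += 1
                # rebuild the cluster for the next trial
                from bmusim.lattice import remove_agent
                remove_agent(grid, aid)
                _place_poc_cluster(grid, toy_params.fusion_threshold)
        sd = np.sqrt(n * p_th * (1 - p_th))
        assert abs(hits - n * p_th) < 4 * sd


class TestResorption:
    def test_resorbs_one_adjacent_site_when_due(self, toy_grid, rng):
        p = toy_grid.params
        surf = np.argwhere(bone_adjacent_mask(toy_grid.bone)
                           & toy_grid.empty_marrow_mask())
        pos = tuple(surf[3])
        aid = place_agent(toy_grid, CellAgent(
            id=-1, phenotype=Phenotype.AOC, position=pos, nuclei=5))
        toy_grid.clock_h[pos] = p.resorption_interval_h
        n_bone = toy_grid.bone.sum()
        tgfb_before = toy_grid.fields.tgfb.sum()
        assert resorb_step(toy_grid, pos, rng, p)
        assert toy_grid.bone.sum() == n_bone - 1
        # matrix quanta released and the aOC advanced into the cavity
        assert toy_grid.fields.tgfb.sum() == pytest.approx(
            tgfb_before + p.tgfb_release_ng_ml)
        new_pos = toy_grid.registry[aid]
        assert not toy_grid.bone[new_pos]

    def test_no_adjacent_bone_is_idle(self, toy_grid, rng):
        p = toy_grid.params
        free = np.argwhere(toy_grid.empty_marrow_mask())
        pos = tuple(free[-1])  # far from the slab
        place_agent(toy_grid, CellAgent(id=-1, phenotype=Phenotype.AOC,
                                        position=pos, nuclei=5))
        n_bone = toy_grid.bone.sum()
        assert not resorb_step(toy_grid, pos, rng, p)
        assert toy_grid.bone.sum() == n_bone
        assert toy_grid.idle_h[pos] == p.dt_hours

    def test_k_events_release_k_quanta(self, toy_grid, rng):
        p = toy_grid.params
        surf = np.argwhere(bone_adjacent_mask(toy_grid.bone)
                           & toy_grid.empty_marrow_mask())
        pos = tuple(surf[5])
        aid = place_agent(toy_grid, CellAgent(
            id=-1, phenotype=Phenotype.AOC, position=pos, nuclei=5))
        bdn0 = toy_grid.fields.bdn.sum()
        k = 0
        for _ in range(int(3 * p.resorption_interval_h)):
            cur = toy_grid.registry[aid]
            k += resorb_step(toy_grid, tuple(cur), rng, p)
        assert k == 3
        assert toy_grid.fields.bdn.sum() == pytest.approx(
            bdn0 + k * p.bdn_release)


class TestOsteoblastLifecycle:
    def test_pob_division_blocked_at_saturation(self, toy_grid, rng):
        p = toy_grid.params
        t_bio = np.ones_like(toy_grid.fields.tgfb)
        pos = tuple(np.argwhere(toy_grid.phen == int(Phenotype.POB))[0])
        counters = {k: 0 for k in ("pob_division", "pob_differentiation",
                                   "pob_apoptosis", "aob_formation",
                                   "aob_retirement")}
        n0 = toy_grid.count(Phenotype.POB)
        for _ in range(50):
            if toy_grid.phen[pos] != int(Phenotype.POB):
                break
            osteoblast_lifecycle_step(toy_grid, pos, t_bio, rng, counters, p)
        assert counters["pob_division"] == 0

    def test_pob_differentiates_below_threshold_when_bone_adjacent(
            self, toy_grid, rng):
        p = toy_grid.params
        surf = np.argwhere(bone_adjacent_mask(toy_grid.bone)
                           & toy_grid.empty_marrow_mask())
        pos = tuple(surf[0])
        place_agent(toy_grid, CellAgent(id=-1, phenotype=Phenotype.POB,
                                        position=pos))
        t_bio = np.full_like(toy_grid.fields.tgfb, p.pob_diff_threshold / 3)
        counters = {k: 0 for k in ("pob_division", "pob_differentiation",
                                   "pob_apoptosis", "aob_formation",
                                   "aob_retirement")}
        for _ in range(1000):
            if toy_grid.phen[pos] == int(Phenotype.AOB):
                break
            osteoblast_lifecycle_step(toy_grid, pos, t_bio, rng, counters, p,
                                      n_pob=p.pob_max)  # block divisions
        assert toy_grid.phen[pos] == int(Phenotype.AOB)
        assert counters["pob_differentiation"] == 1

    def test_aob_deposits_bone_on_schedule(self, toy_grid, rng):
        p = toy_grid.params
        surf = np.argwhere(bone_adjacent_mask(toy_grid.bone)
                           & toy_grid.empty_marrow_mask())
        pos = tuple(surf[4])
        place_agent(toy_grid, CellAgent(id=-1, phenotype=Phenotype.AOB,
                                        position=pos))
        toy_grid.clock_h[pos] = p.aob_formation_interval_h
        counters = {k: 0 for k in ("pob_division", "pob_differentiation",
                                   "pob_apoptosis", "aob_formation",
                                   "aob_retirement")}
        n_bone = toy_grid.bone.sum()
        t_bio = np.full_like(toy_grid.fields.tgfb, 0.2)
        osteoblast_lifecycle_step(toy_grid, pos, t_bio, rng, counters, p)
        assert toy_grid.bone.sum() == n_bone + 1
        assert counters["aob_formation"] == 1


class TestPinnedFieldInvariants:
    def _sim(self, tgfb_ng_ml):
        p = default_params(grid_width_um=300, grid_height_um=450,
                           msc_count=10, init_pob=8, init_poc=10,
                           pob_max=40, poc_max=40)
        sim = Simulation(p, rng_seed=3, freeze_fields=True)
        sim.grid.fields.tgfb[:] = tgfb_ng_ml
        return sim

    def test_saturated_tgfb_blocks_divisions_and_fusions(self):
        sim = self._sim(tgfb_ng_ml=50.0)  # pinned above saturation
        sim.run(horizon_days=15)
        assert sim.counters["pob_division"] == 0
        assert sim.counters["poc_fusion"] == 0

    def test_floor_tgfb_kills_aocs_immediately(self, toy_params, rng):
        """At the TGFβ floor the per-step survival is zero."""
        assert aoc_survival_probability(
            float(normalize_tgfb(0.0, toy_params)), 1.0) == 0.0
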