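"""Cancer clone rules: division law, starvation, secretion, heritability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmusim.engine import SeedSpec, Simulation
from bmusim.lattice import CellAgent, Phenotype
from bmusim.params import default_params
from bmusim.tumor import (cancer_division_probability, phenotype_table,
                          starvation_update)


@pytest.fixture
def specs(params):
    return phenotype_table(params)


class TestPhenotypeTable:
    def test_clone_definitions(self, specs):
        trp = specs[Phenotype.TRP]
        assert (trp.baseline_division_days, trp.inhibited_division_days,
                trp.starvation_lifespan_days) == (1.5, 2.0, 14)
        assert trp.secretes_tgfb and trp.has_receptor
        tr = specs[Phenotype.TR]
        assert (tr.baseline_division_days, tr.inhibited_division_days,
                tr.starvation_lifespan_days) == (1.75, 2.0, 10)
        assert not tr.secretes_tgfb and tr.has_receptor
        tp = specs[Phenotype.TP]
        assert (tp.baseline_division_days, tp.inhibited_division_days,
                tp.starvation_lifespan_days) == (1.75, 1.75, 10)
        assert tp.secretes_tgfb and not tp.has_receptor
        tn = specs[Phenotype.TN]
        assert (tn.baseline_division_days, tn.inhibited_division_days,
                tn.starvation_lifespan_days) == (2.0, 2.0, 12)
        assert not tn.secretes_tgfb and not tn.has_receptor


class TestDivisionLaw:
    def test_max_rate_at_nutrient_saturation(self, specs):
        p = cancer_division_probability(specs[Phenotype.TRP], 1.0, False,
                                        0.0, dt=1.0)
        assert p == pytest.approx(1 - np.exp(-1 / (1.5 * 24)))

    def test_zero_without_nutrients(self, specs):
        for ph in specs:
            assert cancer_division_probability(specs[ph], 0.0, False, 0.0,
                                               dt=1.0) == 0.0

    def test_full_inhibition_slows_trp_to_two_days(self, specs):
        p = cancer_division_probability(specs[Phenotype.TRP], 1.0, True,
                                        0.99, dt=1.0)
        eff_days = 1.5 + 0.99 * 0.5
        assert p == pytest.approx(1 - np.exp(-1 / (eff_days * 24)))

    def test_tp_rate_unchanged_by_inhibitor(self, specs):
        a = cancer_division_probability(specs[Phenotype.TP], 1.0, True,
                                        0.99, dt=1.0)
        b = cancer_division_probability(specs[Phenotype.TP], 1.0, False,
                                        0.0, dt=1.0)
        assert a == b == pytest.approx(1 - np.exp(-1 / (1.75 * 24)))

    def test_bdn_out_of_range(self, specs):
        with pytest.raises(ValueError):
            cancer_division_probability(specs[Phenotype.TN], 1.2, False,
                                        0.0, dt=1.0)

    @given(b1=st.floats(0, 1), b2=st.floats(0, 1),
           e1=st.floats(0, 0.99), e2=st.floats(0, 0.99))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_bdn_and_efficacy(self, b1, b2, e1, e2):
        trp = phenotype_table(default_params())[Phenotype.TRP]
        lo, hi = sorted((b1, b2))
        assert cancer_division_probability(trp, lo, False, 0, 1.0) <= \
            cancer_division_probability(trp, hi, False, 0, 1.0)
        e_lo, e_hi = sorted((e1, e2))
        assert cancer_division_probability(trp, 0.7, True, e_hi, 1.0) <= \
            cancer_division_probability(trp, 0.7, True, e_lo, 1.0)

    def test_monte_carlo_matches_exponential_waiting(self, specs, rng):
        p_th = cancer_division_probability(specs[Phenotype.TR], 0.5, False,
                                           0.0, dt=1.0)
        n = 10_000
        hits = (rng.random(n) < p_th).sum()
        # binomial 99.7 % interval
        sd = np.sqrt(n * p_th * (1 - p_th))
        assert abs(hits - n * p_th) < 3 * sd


class TestStarvation:
    def _cell(self, ph=Phenotype.TRP):
        return CellAgent(id=0, phenotype=ph, position=(0, 0))

    def test_trp_dies_after_14_days_without_contact(self, specs):
        cell = self._cell()
        spec = specs[Phenotype.TRP]
        for _ in range(14 * 24 + 1):
            cell = starvation_update(cell, 0.0, 1.0, spec)
        assert not cell.alive

    def test_tn_dies_after_12_days(self, specs):
        cell = self._cell(Phenotype.TN)
        spec = specs[Phenotype.TN]
        for _ in range(12 * 24 + 1):
            cell = starvation_update(cell, 0.0, 1.0, spec)
        assert not cell.alive

    def test_contact_resets_clock(self, specs):
        cell = self._cell(Phenotype.TR)
        spec = specs[Phenotype.TR]
        for _ in range(9 * 24):
            cell = starvation_update(cell, 0.0, 1.0, spec)
        cell = starvation_update(cell, 1.0, 1.0, spec)
        assert cell.alive and cell.starvation_hours == 0.0

    def test_only_cancer_starves(self, specs):
        with pytest.raises(ValueError):
            starvation_update(self._cell(Phenotype.MSC), 0.0, 1.0,
                              specs[Phenotype.TRP])


class TestTumorStepIntegration:
    def _pinned_sim(self, seed_spec, rng_seed, efficacy_plan=None, bdn=1.0):
        from bmusim.engine import TreatmentPlan
        p = default_params(grid_width_um=300, grid_height_um=300,
                           msc_count=2, init_pob=2, init_poc=2)
        sim = Simulation(p, efficacy_plan, seed_spec, rng_seed=rng_seed,
                         freeze_fields=True, disable_stroma=True)
        sim.grid.fields.bdn[:] = bdn
        return sim

    def test_phenotype_heritable_and_immutable(self):
        sim = self._pinned_sim(SeedSpec({Phenotype.TN: 5}), 7)
        df = sim.run(horizon_days=20)
        last = df.iloc[-1]
        assert last["n_cancer"] == last["n_TN"] > 5
        assert last[["n_TRP", "n_TR", "n_TP"]].sum() == 0

    def test_zero_cancer_means_no_cancer_events(self):
        sim = self._pinned_sim(None, 7)
        sim.run(horizon_days=5)
        assert sim.counters["cancer_division"] == 0
        assert sim.counters["cancer_apoptosis"] == 0

    def test_growth_rate_tracks_doubling_time(self):
        """Log-linear growth of a fed TRP lesion ~ ln2 / 1.5 days until
        crowding; pooled over replicates, slope within 15 %."""
        slopes = []
        for seed in range(10):
            sim = self._pinned_sim(SeedSpec.trp(1), 100 + seed)
            df = sim.run(horizon_days=9)
            daily = df.groupby(df["day"].astype(int))["n_cancer"].last()
            sel = daily[(daily.index >= 2) & (daily.index <= 8)]
            y = np.log(sel.to_numpy())
            slopes.append(np.polyfit(sel.index.to_numpy(), y, 1)[0])
        expected = np.log(2) / 1.5
        assert np.mean(slopes) == pytest.approx(expected, rel=0.15)

    def test_trp_outgrows_tn(self):
        wins = 0
        for seed in range(5):
            trp = self._pinned_sim(SeedSpec.trp(1), 50 + seed)
            tn = self._pinned_sim(SeedSpec({Phenotype.TN: 1}), 50 + seed)
            a = trp.run(horizon_days=14)["n_cancer"].iloc[-1]
            b = tn.run(horizon_days=14)["n_cancer"].iloc[-1]
            wins += a > b
        assert wins >= 4

    def test_tp_tn_trajectories_bitwise_invariant_to_efficacy(self):
        """With pinned fields and no stroma, the inhibitor cannot touch
        receptor-less clones: identical seeds give identical trajectories."""
        from bmusim.engine import TreatmentPlan
        seed_spec = SeedSpec({Phenotype.TP: 3, Phenotype.TN: 3})
        runs = []
        for plan in (None, TreatmentPlan("pre", 0.99)):
            sim = self._pinned_sim(seed_spec, 42, efficacy_plan=plan,
                                   bdn=0.6)
            runs.append(sim.run(horizon_days=30))
        a, b = runs
        assert (a["n_cancer"] == b["n_cancer"]).all()
        assert (a["n_TP"] == b["n_TP"]).all()
        assert a.equals(b)
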