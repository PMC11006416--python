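"""Synthetic drugs, pore-block conversion, population calibration, success rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apemu.biomarkers import BiomarkerRanges, compute_biomarkers, within_ranges
from apemu.errors import ValidationError
from apemu.pharmacology import (DrugChannelEffect, ReferenceDistribution,
                                SyntheticDrug, apply_drug, build_population,
                                pore_block, random_drug, success_classify,
                                synthetic_reference_distribution, table2_drugs,
                                tabulate_success)
from apemu.simulator import CONDUCTANCE_NAMES, ConductanceSet, PacingProtocol


class TestSyntheticDrug:
    def test_random_drug_contract(self):
        d = random_drug(seed=4)
        assert len(d.targets) == 4
        arr = d.as_array()
        touched = arr != 1.0
        assert touched.sum() == 4
        assert np.all(arr[touched] >= 0.5) and np.all(arr[touched] <= 1.5)

    def test_fixed_seed_reproducible(self):
        assert random_drug(seed=8).factors == random_drug(seed=8).factors

    def test_target_selection_is_uniform(self):
        """Over many draws each target appears with frequency 4/9 +/- 0.02."""
        rng = np.random.default_rng(0)
        counts = dict.fromkeys(CONDUCTANCE_NAMES, 0)
        n = 10_000
        for _ in range(n):
            for t in random_drug(seed=rng).targets:
                counts[t] += 1
        for name, c in counts.items():
            assert abs(c / n - 4 / 9) < 0.02, name

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            random_drug(n_targets=0)
        with pytest.raises(ValidationError):
            random_drug(low=1.5, high=0.5)
        with pytest.raises(ValidationError):
            SyntheticDrug({"gXX": 0.5})


class TestApplyDrug:
    def test_ead_grid_drug_on_baseline(self):
        """The strongest hERG-block drug: gKr 1 -> 0.05, pCa 1 -> 1.20."""
        drug = table2_drugs()[0]
        out = apply_drug(ConductanceSet(), drug)
        assert out.gKr == pytest.approx(0.05)
        assert out.pCa == pytest.approx(1.20)
        assert out.gNa == 1.0 and out.gK1 == 1.0

    def test_table2_grid_values(self):
        drugs = table2_drugs()
        assert [d.factors["gKr"] for d in drugs] == pytest.approx(
            [0.05 + 0.01 * k for k in range(10)])
        assert [d.factors["pCa"] for d in drugs] == pytest.approx(
            [1.20 + 0.02 * k for k in range(10)])

    def test_all_unity_drug_is_identity(self, rng):
        g = ConductanceSet.from_array(rng.uniform(0.3, 1.7, 9))
        out = apply_drug(g, SyntheticDrug({}))
        assert np.array_equal(out.as_array(), g.as_array())

    def test_composition_is_multiplicative(self):
        g = ConductanceSet()
        d1 = SyntheticDrug({"gKr": 0.8, "gNa": 0.9})
        d2 = SyntheticDrug({"gKr": 0.5, "pCa": 1.2})
        combined = SyntheticDrug({"gKr": 0.4, "gNa": 0.9, "pCa": 1.2})
        a = apply_drug(apply_drug(g, d1), d2).as_array()
        b = apply_drug(g, combined).as_array()
        assert np.allclose(a, b)

    def test_clipping_outside_simulator_domain_warns(self):
        g = ConductanceSet(pCa=1.8)
        with pytest.warns(UserWarning):
            out = apply_drug(g, SyntheticDrug({"pCa": 1.5}))
        assert out.pCa == 2.0

    def test_round_trip_with_scaling_factors(self, rng):
        """scaling_factors(control, apply_drug(control, s)) == s."""
        from apemu.emulator import normalize
        from apemu.inverse import scaling_factors

        g = ConductanceSet.from_array(rng.uniform(0.5, 1.2, 9))
        drug = random_drug(seed=3)
        drugged = apply_drug(g, drug)
        s = scaling_factors(normalize(g), normalize(drugged))
        assert np.allclose(s, drug.as_array(), rtol=1e-12)


class TestPoreBlock:
    def test_closed_forms(self):
        assert pore_block(DrugChannelEffect(0.0, 10.0, 1.0)) == 1.0
        assert pore_block(DrugChannelEffect(10.0, 10.0, 3.7)) == pytest.approx(0.5)
        assert pore_block(DrugChannelEffect(30.0, 10.0, 2.0)) == pytest.approx(0.1)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pore_block(DrugChannelEffect(10.0, 10.0, 1.0, unit="nM",
                                         ic50_unit="uM"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), ic50=st.floats(1e-3, 1e3),
           h=st.floats(0.1, 5.0))
    def test_always_in_unit_interval(self, c, ic50, h):
        s = pore_block(DrugChannelEffect(c, ic50, h))
        assert 0.0 < s <= 1.0

    def test_strictly_decreasing_in_concentration_and_hill(self):
        s = [pore_block(DrugChannelEffect(c, 10.0, 2.0)) for c in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(s[:-1], s[1:]))
        # above the IC50, larger hill coefficients block harder
        s = [pore_block(DrugChannelEffect(20.0, 10.0, h)) for h in (0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(s[:-1], s[1:]))


class TestPopulation:
    def test_members_pass_recheck(self, small_population, protocol):
        """Re-simulating every member reproduces the calibration pass."""
        ranges = BiomarkerRanges()
        for member in small_population.members:
            from apemu.simulator import simulate_ap

            tr = simulate_ap(member, protocol)
            assert within_ranges(compute_biomarkers(tr), ranges)

    def test_population_size_and_bounds(self, small_population):
        assert len(small_population) == 6
        for m in small_population.members:
            arr = m.as_array()
            assert np.all(arr >= 0.5) and np.all(arr <= 1.5)

    def test_vacuous_filter_accepts_first_candidate(self):
        wide = BiomarkerRanges(bounds={k: (-1e9, 1e9)
                                       for k in ("RMP", "dVmMax", "Peak", "APD40",
                                                 "APD50", "APD90", "Tri90_40")})
        pop = build_population(n=1, ranges=wide,
                               protocol=PacingProtocol(n_beats=30), seed=0)
        assert len(pop) == 1
        assert pop.provenance["candidates"] == 1


class TestSuccessRule:
    @pytest.fixture()
    def dist(self, rng):
        return ReferenceDistribution(samples=0.4 + 0.05 * rng.standard_normal(2000))

    def test_center_is_success(self, dist):
        assert success_classify(dist.mu, dist)

    def test_boundary_is_success_closed_interval(self, dist):
        edge = dist.mu + 0.15 + dist.sigma
        assert success_classify(edge, dist)
        assert not success_classify(edge + 1e-9, dist)

    def test_tabulation_mirrors_published_style_counts(self):
        """3 successful / 10 unsuccessful estimates give a 0.23 ratio."""
        flags = {"gKr": [True] * 3 + [False] * 10}
        table = tabulate_success(flags)
        assert table["gKr"]["successful"] == 3
        assert table["gKr"]["unsuccessful"] == 10
        assert table["gKr"]["ratio"] == 0.23

    def test_tabulation_conserves_counts(self, rng):
        flags = {n: rng.uniform(size=rng.integers(1, 9)) > 0.5
                 for n in CONDUCTANCE_NAMES[:4]}
        table = tabulate_success(flags)
        for n, fl in flags.items():
            assert table[n]["successful"] + table[n]["unsuccessful"] == len(fl)
        assert (table["Total"]["successful"] + table["Total"]["unsuccessful"]
                == sum(len(f) for f in flags.values()))

    def test_synthetic_reference_generator(self):
        d = synthetic_reference_distribution("dofetilide", "gKr",
                                             concentration=10.0,
                                             ic50_median=5.0, seed=0)
        assert d.samples.size == 2000
        assert 0.0 < d.mu < 1.0 and d.sigma > 0.0


def test_reference_distributions_csv_round_trip(tmp_path, rng):
    import pandas as pd

    from apemu.pharmacology import reference_distributions_from_csv

    rows = []
    for drug, target, mu in (("dofetilide", "gKr", 0.3), ("verapamil", "pCa", 0.6)):
        for v in mu + 0.05 * rng.standard_normal(50):
            rows.append({"drug": drug, "target": target, "sample_value": v})
    p = tmp_path / "ref.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    dists = reference_distributions_from_csv(p)
    assert set(dists) == {("dofetilide", "gKr"), ("verapamil", "pCa")}
    assert abs(dists[("dofetilide", "gKr")].mu - 0.3) < 0.05
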