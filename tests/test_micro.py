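"""Damage model: event sampling, SSB promotion, DSB clustering, track summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdsb.geometry import CellPopulation
from microdsb.micro import (
    MicroModelParams,
    cluster_dsb,
    promote_to_ssb,
    run_micro,
    sample_deposition_events,
    ssb_probability,
)
from microdsb.physics import StoppingPowerTable
from microdsb.synthetic import (
    PlantedPatternSpec,
    SyntheticPhaseSpaceSpec,
    make_isotropic_flux_phase_space,
    make_planted_ssb_pattern,
)
from tests_support import brute_force_dsb_count


class TestSSBProbability:
    @pytest.mark.parametrize(
        "energy,prob",
        [(3.0, 0.0), (5.0, 0.0), (21.25, 0.5), (37.5, 1.0), (100.0, 1.0)],
    )
    def test_ramp_values(self, energy, prob):
        assert ssb_probability(energy) == pytest.approx(prob)

    def test_vectorized_and_monotone(self):
        e = np.linspace(0, 60, 200)
        p = ssb_probability(e)
        assert np.all(np.diff(p) >= 0)
        assert p.min() == 0.0 and p.max() == 1.0


class TestDepositionEvents:
    @pytest.fixture()
    def flat_let_table(self):
        # constant 0.1 MeV/µm stopping power → homogeneous Poisson process
        return StoppingPowerTable(
            "alpha", np.array([1e-3, 20.0]), np.array([0.1, 0.1])
        )

    def test_event_density_is_let_over_epsilon(self, flat_let_table, rng):
        # LET 100 keV/µm, ⟨ε⟩ = 60 eV → 1666.7 events/µm
        params = MicroModelParams(event_mean_ev=60.0)
        chord = 3.0
        pos, e = sample_deposition_events(5.0, chord, flat_let_table, params, rng)
        expected = 1e5 / 60.0 * chord
        assert abs(len(e) - expected) < 3 * np.sqrt(expected)

    def test_zero_chord_no_events(self, flat_let_table, rng):
        pos, e = sample_deposition_events(5.0, 0.0, flat_let_table, MicroModelParams(), rng)
        assert len(e) == 0

    def test_wald_identity_energy_bookkeeping(self, alpha_table, rng):
        # Σ event energies ≈ CSDA energy loss along the in-nucleus segment
        params = MicroModelParams(event_mean_ev=86.1)
        e0, chord = 5.0, 4.0
        r0 = float(alpha_table.range_um(e0))
        loss = e0 - float(alpha_table.energy_from_range(r0 - chord))
        sums = []
        for _ in range(120):
            _, e = sample_deposition_events(e0, chord, alpha_table, params, rng)
            sums.append(e.sum() * 1e-6)  # eV → MeV
        mean = np.mean(sums)
        sem = np.std(sums, ddof=1) / np.sqrt(len(sums))
        assert abs(mean - loss) < 3 * sem + 0.002 * loss

    def test_bragg_end_limits_track(self, alpha_table, rng):
        # residual range 26 µm < 100 µm chord: no event beyond the Bragg end
        pos, e = sample_deposition_events(
            4.081, 100.0, alpha_table, MicroModelParams(), rng
        )
        r0 = float(alpha_table.range_um(4.081))
        assert pos[:, 0].max() <= r0 * 1e3 + 1e-6

    def test_positions_sorted_along_track(self, alpha_table, rng):
        pos, _ = sample_deposition_events(
            5.0, 3.0, alpha_table, MicroModelParams(), rng
        )
        assert np.all(np.diff(pos[:, 0]) >= 0)


class TestPromotion:
    def test_saturated_events_fully_sensitive_all_ssb(self, rng):
        params = MicroModelParams(sensitive_fraction=1.0)
        n = 5000
        cand = promote_to_ssb(np.zeros((n, 3)), np.full(n, 100.0), params, rng)
        assert cand.is_ssb.all()

    def test_zero_fraction_no_ssb(self, rng):
        params = MicroModelParams(sensitive_fraction=0.0)
        cand = promote_to_ssb(np.zeros((100, 3)), np.full(100, 100.0), params, rng)
        assert not cand.is_ssb.any()
        assert not cand.in_sensitive.any()

    def test_seven_percent_thinning_binomial(self, rng):
        n = 100_000
        params = MicroModelParams(sensitive_fraction=0.07)
        cand = promote_to_ssb(np.zeros((n, 3)), np.full(n, 100.0), params, rng)
        k = cand.is_ssb.sum()
        sigma = np.sqrt(n * 0.07 * 0.93)
        assert abs(k - 0.07 * n) < 3 * sigma

    def test_ssb_implies_sensitive(self, rng):
        params = MicroModelParams()
        e = rng.uniform(0, 60, 5000)
        cand = promote_to_ssb(np.zeros((5000, 3)), e, params, rng)
        assert np.all(~cand.is_ssb | cand.in_sensitive)


class TestClustering:
    def test_opposite_strand_pair_within_eps_is_one_dsb(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert len(cluster_dsb(pos, np.array([0, 1]))) == 1

    def test_isolated_ssb_is_no_dsb(self):
        assert cluster_dsb(np.array([[0.0, 0, 0]]), np.array([0])) == []

    def test_same_strand_pair_requires_both_strands(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert cluster_dsb(pos, np.array([1, 1])) == []
        loose = MicroModelParams(require_both_strands=False)
        assert len(cluster_dsb(pos, np.array([1, 1]), loose)) == 1

    def test_planted_pattern_recovers_k(self, rng):
        spec = PlantedPatternSpec(k=3, singletons=5)
        pos, strands, expected = make_planted_ssb_pattern(spec, rng)
        assert expected == 3
        assert len(cluster_dsb(pos, strands)) == expected
        assert brute_force_dsb_count(pos, strands) == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(0, 200),
        seed=st.integers(0, 10_000),
        scale=st.sampled_from([2.0, 5.0, 20.0]),
        require_both=st.booleans(),
    )
    def test_clustering_equals_brute_force_oracle(self, n, seed, scale, require_both):
        r = np.random.default_rng(seed)
        pos = r.uniform(0, scale, size=(n, 3))
        strands = r.integers(0, 2, n)
        params = MicroModelParams(require_both_strands=require_both)
        ours = len(cluster_dsb(pos, strands, params))
        oracle = brute_force_dsb_count(pos, strands, require_both=require_both)
        assert ours == oracle

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(2, 120), seed=st.integers(0, 10_000))
    def test_dropping_strand_rule_never_decreases_count(self, n, seed):
        r = np.random.default_rng(seed)
        pos = r.uniform(0, 10.0, size=(n, 3))
        strands = r.integers(0, 2, n)
        strict = len(cluster_dsb(pos, strands, MicroModelParams()))
        loose = len(
            cluster_dsb(pos, strands, MicroModelParams(require_both_strands=False))
        )
        assert loose >= strict

    def test_output_order_deterministic_under_permutation(self, rng):
        pos, strands, _ = make_planted_ssb_pattern(
            PlantedPatternSpec(k=4, singletons=3), rng
        )
        perm = rng.permutation(len(pos))
        a = cluster_dsb(pos, strands)
        b = cluster_dsb(pos[perm], strands[perm])
        assert len(a) == len(b)
        first_a = [tuple(pos[c.member_indices[0]]) for c in a]
        first_b = [tuple(pos[perm][c.member_indices[0]]) for c in b]
        assert first_a == sorted(first_a)
        assert first_b == sorted(first_b)


@pytest.fixture(scope="module")
def one_cell():
    return CellPopulation(np.array([[0.0, 0.0, 0.0]]))


class TestTrackSummaries:
    def _summaries(self, energy, count, seed, one_cell, tables):
        ps = make_isotropic_flux_phase_space(
            SyntheticPhaseSpaceSpec(energy_mev=energy, count=count, seed=seed),
            sphere_radius_um=one_cell.cell_radius,
        )
        return run_micro(ps, one_cell, tables, MicroModelParams(), seed + 1)

    def test_path_bounded_by_nucleus_diameter(self, one_cell, tables):
        summaries = self._summaries(6.0, 400, 3, one_cell, tables)
        assert summaries, "isotropic flux must produce nucleus crossings"
        assert all(s.path_um <= 6.2 + 1e-9 for s in summaries)
        assert all(s.n_dsb >= 0 for s in summaries)

    def test_threshold_rule(self, one_cell, tables):
        summaries = self._summaries(6.0, 400, 5, one_cell, tables)
        for s in summaries:
            assert s.passes_threshold == ((s.path_um > 0.75) and (s.n_dsb >= 7))

    def test_low_energy_track_stops_inside_nucleus(self, one_cell, tables, alpha_table):
        summaries = self._summaries(0.5, 300, 7, one_cell, tables)
        r = float(alpha_table.range_um(0.5))
        assert summaries
        assert all(s.path_um <= r + 1e-9 for s in summaries)

    def test_dsb_density_monotone_decreasing_in_alpha_energy(self, one_cell, tables):
        # LET(4.081 MeV) > LET(6.219 MeV) → higher DSB linear density
        def density(e, seed):
            ss = self._summaries(e, 500, seed, one_cell, tables)
            return sum(s.n_dsb for s in ss) / sum(s.path_um for s in ss)

        d_low = np.mean([density(4.081, s) for s in (11, 13)])
        d_high = np.mean([density(6.219, s) for s in (11, 13)])
        assert d_low > d_high

    def test_per_track_reproducibility(self, one_cell, tables):
        a = self._summaries(6.0, 100, 9, one_cell, tables)
        b = self._summaries(6.0, 100, 9, one_cell, tables)
        assert [s.n_dsb for s in a] == [s.n_dsb for s in b]
        assert [s.path_um for s in a] == [s.path_um for s in b]

    def test_ray_missing_nucleus_gives_no_summary(self, one_cell, tables):
        import pandas as pd

        from microdsb.macro import PS_COLUMNS

        # tangential record: impact parameter 3.5 µm > nucleus radius 3.1 µm
        row = {
            "particle": "alpha",
            "E_MeV": 6.0,
            "x_um": 3.5,
            "y_um": -3.75,
            "z_um": 0.0,
            "dx": 0.0,
            "dy": 1.0,
            "dz": 0.0,
            "origin_volume": "blood",
            "process": "synthetic",
            "cell_index": 0,
            "weight": 1.0,
        }
        ps = pd.DataFrame([row], columns=PS_COLUMNS)
        assert run_micro(ps, one_cell, tables, MicroModelParams(), 1) == []
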