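"""Chain construction, energy function, Metropolis sampling and domains."""

import itertools
import math
from collections import defaultdict

import numpy as np
import pytest

from txfactory.copolymer_sim import (
    BlockSpec,
    Conformation,
    SimParams,
    apply_treatment,
    build_chain,
    default_block_spec,
    domain_metrics,
    energy,
    run_mc,
)

E0 = dict(n_steps=0, seed=1)


def conf(coords, labels, lattice=(6, 6, 6)):
    return Conformation(coords=np.array(coords), labels=np.array(labels), lattice_size=lattice)


class TestBuildChain:
    def test_single_coil_block(self):
        c = build_chain(BlockSpec(blocks=(("coil", 9),)))
        assert len(c.coords) == 9 and not c.labels.any()

    def test_minimal_two_bead_chain(self):
        spec = BlockSpec(blocks=(("rod", 1), ("coil", 1)))
        c = build_chain(spec)
        assert len(c.coords) == 2
        assert spec.rod_fraction == 0.5

    def test_default_composition_rod_fraction(self):
        assert default_block_spec().rod_fraction == pytest.approx(0.12)

    @pytest.mark.parametrize("n", [1, 7, 121, 160, 1000])
    def test_serpentine_valid_at_many_sizes(self, n):
        build_chain(BlockSpec(blocks=(("coil", n),)))  # validates internally

    def test_chain_too_long_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            build_chain(BlockSpec(blocks=(("coil", 100),)), lattice_size=(3, 3, 3))

    def test_invalid_blocks_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec(blocks=(("loop", 3),))
        with pytest.raises(ValueError):
            BlockSpec(blocks=())


class TestEnergy:
    def test_extended_chain_is_zero(self):
        c = conf([(i, 0, 0) for i in range(5)], [True] * 5)
        assert energy(c, SimParams(epsilon_rr=3.0, kappa_rod=2.0, **E0)) == 0.0

    def test_single_rod_rod_contact(self):
        """Two rod ends of a U-shaped chain touch: one non-bonded contact."""
        c = conf([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], [True, False, False, True])
        assert energy(c, SimParams(epsilon_rr=1.0, kappa_rod=0.0, **E0)) == -1.0

    def test_right_angle_at_rod_bead(self):
        c = conf([(0, 0, 0), (1, 0, 0), (1, 1, 0)], [False, True, False])
        assert energy(c, SimParams(epsilon_rr=1.0, kappa_rod=2.0, **E0)) == 2.0

    def test_bend_at_coil_bead_is_free(self):
        c = conf([(0, 0, 0), (1, 0, 0), (1, 1, 0)], [True, False, True])
        assert energy(c, SimParams(epsilon_rr=1.0, kappa_rod=2.0, **E0)) == 0.0

    def test_bonded_neighbours_do_not_count_as_contacts(self):
        c = conf([(0, 0, 0), (1, 0, 0)], [True, True])
        assert energy(c, SimParams(epsilon_rr=5.0, kappa_rod=0.0, **E0)) == 0.0


class TestRunMC:
    def test_zero_steps_returns_input(self):
        c = build_chain(default_block_spec(rod_beads=3, intra_coil_beads=4,
                                           rods_per_cluster=2, spacer_coil_beads=10))
        res = run_mc(c, SimParams(n_steps=0, seed=3))
        assert np.array_equal(res.conformation.coords, c.coords)

    def test_input_not_mutated(self):
        c = build_chain(BlockSpec(blocks=(("rod", 5), ("coil", 10))))
        before = c.coords.copy()
        run_mc(c, SimParams(n_steps=20_000, seed=4, record_interval=5_000))
        assert np.array_equal(c.coords, before)

    def test_trace_matches_full_energy_recompute(self):
        """The incrementally updated energy agrees with a from-scratch
        evaluation of the final conformation."""
        spec = default_block_spec(rod_beads=5, intra_coil_beads=8,
                                  rods_per_cluster=3, spacer_coil_beads=20)
        params = SimParams(n_steps=200_000, seed=5, record_interval=200_000)
        res = run_mc(build_chain(spec), params)
        assert res.energies[-1] == pytest.approx(energy(res.conformation, params))

    def test_deterministic_given_seed(self):
        c = build_chain(BlockSpec(blocks=(("rod", 6), ("coil", 12), ("rod", 6))))
        p = SimParams(n_steps=50_000, seed=6, record_interval=10_000)
        a, b = run_mc(c, p), run_mc(c, p)
        assert np.array_equal(a.conformation.coords, b.conformation.coords)
        assert np.array_equal(a.energies, b.energies)

    def test_athermal_acceptance_exceeds_coupled(self):
        """With no energies every geometrically valid proposal is accepted;
        attraction and stiffness can only lower the acceptance rate."""
        c = build_chain(BlockSpec(blocks=(("rod", 30), ("coil", 30))))
        athermal = run_mc(c, SimParams(epsilon_rr=0.0, kappa_rod=0.0, n_steps=100_000,
                                       seed=7, record_interval=20_000))
        coupled = run_mc(c, SimParams(epsilon_rr=3.0, kappa_rod=2.0, n_steps=100_000,
                                      seed=7, record_interval=20_000))
        assert athermal.acceptance_rate > coupled.acceptance_rate
        assert athermal.acceptance_rate > 0.25

    def test_energy_decreases_from_extended_start(self):
        spec = default_block_spec(rod_beads=5, intra_coil_beads=10,
                                  rods_per_cluster=4, spacer_coil_beads=30)
        # a straight-line start on an elongated lattice: zero initial energy
        start = build_chain(spec, lattice_size=(spec.n_beads, 13, 13))
        res = run_mc(start,
                     SimParams(epsilon_rr=3.0, n_steps=1_500_000, seed=8, record_interval=100_000))
        assert res.energies[0] == 0.0
        assert res.energies[-1] < res.energies[0]

    def test_self_avoidance_preserved(self):
        spec = BlockSpec(blocks=(("rod", 10), ("coil", 20), ("rod", 10)))
        res = run_mc(build_chain(spec),
                     SimParams(n_steps=300_000, seed=9, record_interval=100_000,
                               move_set=("local_crankshaft", "end_rotation", "reptation")))
        res.conformation.validate()  # raises on any violation


class TestBoltzmannOracle:
    def test_stationary_distribution_matches_enumeration(self):
        """Empirical shape-class frequencies of a 4-bead all-rod chain on a
        5^3 box match exhaustive Boltzmann enumeration."""
        L, eps, kappa = 5, 1.5, 1.0
        dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

        def shape_class(pos):
            bends = 0
            for c in (1, 2):
                b1 = tuple(pos[c][k] - pos[c - 1][k] for k in range(3))
                b2 = tuple(pos[c + 1][k] - pos[c][k] for k in range(3))
                bends += b1 != b2
            contact = sum(abs(pos[0][k] - pos[3][k]) for k in range(3)) == 1
            return bends, contact

        weights = defaultdict(float)
        for p0 in itertools.product(range(L), repeat=3):
            for d1 in dirs:
                p1 = tuple(p0[k] + d1[k] for k in range(3))
                if not all(0 <= v < L for v in p1):
                    continue
                for d2 in dirs:
                    p2 = tuple(p1[k] + d2[k] for k in range(3))
                    if not all(0 <= v < L for v in p2) or p2 == p0:
                        continue
                    for d3 in dirs:
                        p3 = tuple(p2[k] + d3[k] for k in range(3))
                        if not all(0 <= v < L for v in p3) or p3 in (p0, p1):
                            continue
                        bends, contact = shape_class((p0, p1, p2, p3))
                        weights[(bends, contact)] += math.exp(eps * contact - kappa * bends)
        total = sum(weights.values())
        exact = {k: v / total for k, v in weights.items()}

        start = build_chain(BlockSpec(blocks=(("rod", 4),)), lattice_size=(L, L, L))
        res = run_mc(start, SimParams(epsilon_rr=eps, kappa_rod=kappa, n_steps=4_000_000,
                                      seed=7, record_interval=1_000_000, snapshot_interval=200))
        counts = defaultdict(int)
        for snap in res.snapshots:
            counts[shape_class(tuple(map(tuple, snap.coords)))] += 1
        n = sum(counts.values())
        assert n >= 10_000
        for k, p_exact in exact.items():
            assert counts[k] / n == pytest.approx(p_exact, abs=0.02)


class TestDomainMetrics:
    def test_single_block_single_domain(self):
        c = conf([(i, 0, 0) for i in range(4)], [True] * 4)
        m = domain_metrics(c)
        assert m.n_domains == 1 and m.largest_domain_fraction == 1.0

    def test_two_separate_rod_blocks(self):
        coords = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0), (5, 0, 0)]
        labels = [True, True, False, False, True, True]
        m = domain_metrics(conf(coords, labels))
        assert m.n_domains == 2 and m.largest_domain_fraction == 0.5

    def test_collinear_domain_has_maximal_asphericity(self):
        c = conf([(i, 0, 0) for i in range(6)], [True] * 6)
        assert domain_metrics(c).domain_asphericity == pytest.approx(1.0)

    def test_no_rod_beads_rejected(self):
        with pytest.raises(ValueError, match="rod"):
            domain_metrics(conf([(0, 0, 0), (1, 0, 0)], [False, False]))


class TestTreatments:
    def test_formamide_removes_attraction(self):
        p = SimParams(epsilon_rr=3.0, n_steps=0, seed=1)
        p2 = apply_treatment(p, "formamide")
        assert p2.epsilon_rr == 0.0 and "formamide" in p2.provenance

    @pytest.mark.parametrize("treatment", ["DRB", "heat_shock", "NaCl"])
    def test_other_treatments_keep_attraction(self, treatment):
        p = SimParams(epsilon_rr=3.0, n_steps=0, seed=1)
        assert apply_treatment(p, treatment).epsilon_rr == 3.0

    def test_unknown_treatment_lists_valid_names(self):
        with pytest.raises(ValueError, match="formamide"):
            apply_treatment(SimParams(n_steps=0, seed=1), "trichostatin")
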