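"""Unit tests for the synthetic-data generators and simulators."""

import numpy as np
import pytest

from segdyn.correlation import binarize_channel
from segdyn.synthetic import (
    LatticeConfig,
    generate_doublet_image,
    generate_dpa_record,
    generate_sphere_field,
    generate_spheroid_series,
    make_aggregate_config,
    mean_cluster_size,
    render_microscopy,
    simulate_ballistic_segregation,
    simulate_lattice_segregation,
)


def small_lattice_config(seed=1, **kw):
    n = 32 * 32
    J = np.array([[0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])
    defaults = dict(
        shape=(32, 32),
        composition={1: n // 2, 2: n - n // 2},
        energy_table=J,
        temperature=0.9,
        snapshot_sweeps=(10, 100),
        seed=seed,
    )
    defaults.update(kw)
    return LatticeConfig(**defaults)


class TestLattice:
    def test_composition_conserved(self):
        states = simulate_lattice_segregation(small_lattice_config())
        for st in states:
            comp = st.composition
            assert comp[1] == 512 and comp[2] == 512

    def test_same_seed_reproduces(self):
        s1 = simulate_lattice_segregation(small_lattice_config(seed=3))
        s2 = simulate_lattice_segregation(small_lattice_config(seed=3))
        np.testing.assert_array_equal(s1[-1].labels, s2[-1].labels)

    def test_different_seeds_differ(self):
        s1 = simulate_lattice_segregation(small_lattice_config(seed=3))
        s2 = simulate_lattice_segregation(small_lattice_config(seed=4))
        assert np.any(s1[-1].labels != s2[-1].labels)

    def test_interface_energy_decreases(self):
        # Demixing below Tc lowers the number of unlike-neighbour bonds.
        def unlike_bonds(lab):
            return sum(
                int(np.sum(lab != np.roll(lab, 1, axis=ax))) for ax in (0, 1)
            )

        states = simulate_lattice_segregation(
            small_lattice_config(snapshot_sweeps=(1, 500))
        )
        assert unlike_bonds(states[1].labels) < unlike_bonds(states[0].labels)

    def test_composition_must_fill_grid(self):
        with pytest.raises(ValueError):
            simulate_lattice_segregation(
                small_lattice_config(composition={1: 10, 2: 10})
            )

    def test_aggregate_config_runs_and_keeps_medium(self):
        cfg = make_aggregate_config(seed=2)
        st = simulate_lattice_segregation(cfg)[-1]
        assert 0 in st.composition and 1 in st.composition and 2 in st.composition
        assert st.periodic is False


class TestBallistic:
    def test_cluster_count_never_increases(self):
        states = simulate_ballistic_segregation(
            n_cells=200, cell_radius=5.0, speed=30.0, box=400.0,
            snapshot_times=(0.5, 1.0, 2.0, 4.0), seed=1,
        )
        counts = [s.n_clusters for s in states]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] < 200

    def test_mean_size_of_singletons(self):
        states = simulate_ballistic_segregation(
            n_cells=50, cell_radius=5.0, speed=30.0, box=500.0,
            snapshot_times=(1e-6,), seed=1,
        )
        # Before any merge every cluster is one disk: L = sqrt(pi) r.
        assert states[0].n_clusters == 50
        assert mean_cluster_size(states[0]) == pytest.approx(
            np.sqrt(np.pi) * 5.0, rel=1e-6
        )

    def test_overpacked_box_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            simulate_ballistic_segregation(
                n_cells=1000, cell_radius=5.0, speed=30.0, box=100.0,
                snapshot_times=(1.0,), seed=1,
            )

    def test_same_seed_reproduces(self):
        kw = dict(n_cells=100, cell_radius=5.0, speed=30.0, box=300.0,
                  snapshot_times=(1.0, 2.0), seed=9)
        s1 = simulate_ballistic_segregation(**kw)
        s2 = simulate_ballistic_segregation(**kw)
        np.testing.assert_allclose(s1[-1].positions, s2[-1].positions)
        np.testing.assert_array_equal(s1[-1].cluster_ids, s2[-1].cluster_ids)

    def test_cluster_members_move_rigidly(self):
        states = simulate_ballistic_segregation(
            n_cells=300, cell_radius=5.0, speed=30.0, box=300.0,
            snapshot_times=(2.0, 4.0), seed=5,
        )
        st = states[-1]
        # Pick a multi-disk cluster and check contact integrity: overlap
        # between members is bounded by one step of relative approach
        # (2 v dt = r), after which the pair moves rigidly and the
        # distance is frozen.
        ids, counts = np.unique(st.cluster_ids, return_counts=True)
        big = ids[np.argmax(counts)]
        pos = st.positions[st.cluster_ids == big]
        if len(pos) >= 2:
            d = pos[:, None, :] - pos[None, :, :]
            d -= st.box * np.round(d / st.box)
            dist = np.sqrt((d**2).sum(-1))
            dist[np.diag_indices_from(dist)] = np.inf
            r = 5.0
            assert dist.min() >= 2 * r - r - 1e-9


class TestSphereField:
    def test_truth_and_fill(self):
        stack, truth = generate_sphere_field(
            40.0, 0.05, (32, 96, 96), (10.0, 1.0, 1.0), 1
        )
        assert truth.true_R0 == 40.0
        mask = binarize_channel(stack, "A", method="otsu")
        assert 0.02 < mask.occupied_fraction < 0.08

    def test_unresolvable_diameter_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            generate_sphere_field(20.0, 0.1, (16, 64, 64), (10.0, 1.0, 1.0), 1)

    def test_fill_bounds_enforced(self):
        with pytest.raises(ValueError):
            generate_sphere_field(40.0, 0.7, (16, 64, 64), (10.0, 1.0, 1.0), 1)


class TestSpheroidSeries:
    def test_truth_interpolates_linearly(self):
        frames, truth = generate_spheroid_series(1000.0, 0.8, 0.0, 5, 1.29, 1)
        np.testing.assert_allclose(
            truth.true_perimeters, np.linspace(1000.0, 800.0, 5)
        )
        assert len(frames) == 5
        assert frames[1].timestamp == pytest.approx(1.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_spheroid_series(1000.0, 1.5, 0.0, 5, 1.29, 1)


class TestDoubletAndDPA:
    def test_non_intersecting_circles_rejected(self):
        with pytest.raises(ValueError):
            generate_doublet_image(5.0, 5.0, 20.0, 0.2, 1)

    def test_truth_angle_matches_geometry(self):
        _, truth = generate_doublet_image(10.0, 10.0, 10.0, 0.2, 1)
        assert truth.true_theta == pytest.approx(60.0, abs=1e-9)

    def test_dpa_separation_step(self):
        rec, truth = generate_dpa_record(3.5, 4.5, start_pressure=2.0, step=1.0)
        # Pressures 2,3,4,5,...: first step at or above 4.5 Pa is index 3.
        assert rec.separated_at == 3
        assert truth.true_separation_pressure == 4.5

    def test_dpa_never_separates(self):
        rec, _ = generate_dpa_record(3.5, 1e6, start_pressure=2.0, step=1.0)
        assert rec.separated_at is None

    def test_dpa_step_bounds(self):
        with pytest.raises(ValueError):
            generate_dpa_record(3.5, 4.5, step=10.0)


class TestRender:
    def test_channels_follow_types(self):
        states = simulate_ballistic_segregation(
            n_cells=60, cell_radius=5.0, speed=30.0, box=300.0,
            snapshot_times=(1.0,), seed=2, n_types=2,
        )
        stack = render_microscopy(states[0])
        assert set(stack.channels) == {"type1", "type2"}
        for ch in stack.channels.values():
            assert ch.max() > 0
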