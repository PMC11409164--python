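import numpy as np
import pytest

from shiftcryst.density import (
    AlignmentSpec,
    DensityError,
    accumulate_density,
    align_environment,
    export_cube,
    kabsch,
    read_cube,
)
from shiftcryst.ensemble import MolecularEnvironment


def density_oracle(aligned, element, point, w):
    """Direct double-sum evaluation of the averaged Gaussian density."""
    total = 0.0
    for positions, elements in aligned:
        for p, el in zip(positions, elements):
            if el == element:
                total += np.exp(-np.sum((np.asarray(point) - p) ** 2) / (2 * w * w))
    return total / len(aligned)


def rand_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        r, t = kabsch(pts, pts)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        rot = rand_rotation(rng)
        shift = rng.uniform(-5, 5, size=3)
        moved = pts @ rot.T + shift
        r, t = kabsch(moved, pts)
        recovered = moved @ r.T + t
        assert np.sqrt(((recovered - pts) ** 2).sum(axis=1)).max() < 1e-8

    def test_never_reflects_near_planar_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            pts[:, 2] *= 1e-6  # nearly planar
            target = pts @ rand_rotation(rng).T
            r, _t = kabsch(pts, target)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)


def env_from_coords(positions, elements, labels_n=None):
    n = len(positions)
    return MolecularEnvironment(
        env_id="t:0:0", central_mol_id=0,
        positions=np.asarray(positions, dtype=float),
        elements=np.asarray(elements, dtype=object),
        mol_ids=np.zeros(n, dtype=int), cutoff=7.0,
    )


class TestAlignEnvironment:
    def test_identity_alignment(self, small_world, small_envs):
        env = next(iter(small_envs.values()))
        spec = AlignmentSpec(("C1", "C2", "C3", "C4"), mode="kabsch")
        order = {l: i for i, l in enumerate(small_world.graph.labels)}
        central = np.flatnonzero(env.central_mask)
        template = env.positions[[central[order[l]] for l in spec.ref_atoms]]
        pos, (r, t) = align_environment(env, spec, small_world.graph, template)
        np.testing.assert_allclose(pos, env.positions, atol=1e-8)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-8)

    def test_inverts_known_rigid_motion(self, small_world, small_envs):
        env = next(iter(small_envs.values()))
        spec = AlignmentSpec(("C1", "C2", "C3", "C5"), mode="kabsch")
        order = {l: i for i, l in enumerate(small_world.graph.labels)}
        central = np.flatnonzero(env.central_mask)
        template = env.positions[[central[order[l]] for l in spec.ref_atoms]]
        rng = np.random.default_rng(5)
        rot = rand_rotation(rng)
        moved = MolecularEnvironment(
            env_id=env.env_id, central_mol_id=env.central_mol_id,
            positions=env.positions @ rot.T + np.array([3.0, -2.0, 9.0]),
            elements=env.elements, mol_ids=env.mol_ids, cutoff=env.cutoff,
        )
        pos, _ = align_environment(moved, spec, small_world.graph, template)
        assert np.abs(pos - env.positions).max() < 1e-8

    def test_bond_axis_frame(self, small_world, small_envs):
        env = next(iter(small_envs.values()))
        spec = AlignmentSpec(("N1", "H1"), mode="bond_axis", orientation_atom="C1")
        pos, _ = align_environment(env, spec, small_world.graph)
        order = {l: i for i, l in enumerate(small_world.graph.labels)}
        central = np.flatnonzero(env.central_mask)
        n1 = pos[central[order["N1"]]]
        h1 = pos[central[order["H1"]]]
        c1 = pos[central[order["C1"]]]
        np.testing.assert_allclose(n1, 0.0, atol=1e-10)       # first ref at origin
        assert h1[0] == pytest.approx(0.0, abs=1e-10)         # bond on +z
        assert h1[1] == pytest.approx(0.0, abs=1e-10)
        assert h1[2] > 0
        assert c1[1] == pytest.approx(0.0, abs=1e-10)         # orientation in xz, x > 0
        assert c1[0] > 0

    def test_collinear_kabsch_reference_is_error(self):
        from shiftcryst.molecule import AtomSpec, build_graph

        graph = build_graph(
            [AtomSpec("A", "C"), AtomSpec("B", "C"), AtomSpec("C", "C")],
            [("A", "B"), ("B", "C")],
        )
        env = env_from_coords([[0, 0, 0], [1, 0, 0], [2, 0, 0]], ["C", "C", "C"])
        spec = AlignmentSpec(("A", "B", "C"), mode="kabsch")
        with pytest.raises(DensityError, match="bond_axis"):
            align_environment(env, spec, graph, np.zeros((3, 3)))


class TestAccumulateDensity:
    def test_single_atom_at_origin_peaks_at_one(self):
        dmap = accumulate_density([(np.zeros((1, 3)), ["C"])], w=0.5, side=4.0, spacing=0.2)
        assert dmap.channels["C"].max() == pytest.approx(1.0)
        assert dmap.value_at("C", np.zeros(3)) == pytest.approx(1.0)

    def test_conserved_position_still_one_over_many_envs(self):
        aligned = [(np.zeros((1, 3)), ["C"])] * 7
        dmap = accumulate_density(aligned, w=0.5, side=4.0, spacing=0.2)
        assert dmap.channels["C"].max() == pytest.approx(1.0, abs=1e-12)

    def test_half_occupancy_gives_half(self):
        aligned = [(np.zeros((1, 3)), ["C"]), (np.array([[30.0, 0, 0]]), ["C"])]
        dmap = accumulate_density(aligned, w=0.5, side=4.0, spacing=0.2)
        assert dmap.value_at("C", np.zeros(3)) == pytest.approx(0.5, abs=1e-9)

    def test_closed_form_value_at_half_angstrom(self):
        dmap = accumulate_density([(np.zeros((1, 3)), ["C"])], w=0.5, side=4.0, spacing=0.25)
        # 0.5 Å from a lone atom: exp(-0.25 / (2 * 0.25))
        assert dmap.value_at("C", np.array([0.5, 0, 0])) == pytest.approx(0.6065, abs=1e-4)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(9)
        aligned = []
        for _ in range(4):
            n = int(rng.integers(2, 9))
            aligned.append((rng.uniform(-3, 3, size=(n, 3)),
                            list(rng.choice(["C", "O", "H"], size=n))))
        dmap = accumulate_density(aligned, w=0.5, side=8.0, spacing=0.4)
        axes = [dmap.axis(d) for d in range(3)]
        for _ in range(20):
            ijk = rng.integers(0, dmap.n_points, size=3)
            point = np.array([axes[d][ijk[d]] for d in range(3)])
            for el in ("C", "O", "H"):
                if el not in dmap.channels:
                    continue
                got = dmap.channels[el][tuple(ijk)]
                want = density_oracle(aligned, el, point, 0.5)
                assert got == pytest.approx(want, abs=1e-12)

    def test_channel_integral_scales_with_atom_count(self):
        one = [(np.zeros((1, 3)), ["C"])]
        three = [(np.array([[0.0, 0, 0], [1.5, 0, 0], [-1.5, 0, 0]]), ["C"] * 3)]
        m1 = accumulate_density(one, w=0.4, side=10.0, spacing=0.2)
        m3 = accumulate_density(three, w=0.4, side=10.0, spacing=0.2)
        ratio = m3.channels["C"].sum() / m1.channels["C"].sum()
        assert ratio == pytest.approx(3.0, rel=1e-3)

    def test_out_of_grid_atom_contributes_tail(self):
        dmap = accumulate_density([(np.array([[2.5, 0, 0]]), ["C"])],
                                  w=0.5, side=4.0, spacing=0.2)
        edge_value = dmap.value_at("C", np.array([2.0, 0.0, 0.0]))
        assert edge_value == pytest.approx(np.exp(-0.25 / 0.5), abs=1e-9)

    def test_split_hydrogen_channels(self):
        pos = np.array([[0.0, 0, 0], [1.1, 0, 0], [3.0, 0, 0], [3.0, 1.0, 0]])
        els = ["C", "H", "O", "H"]
        dmap = accumulate_density([(pos, els)], w=0.5, side=8.0, spacing=0.4, split_h=True)
        assert "H(C)" in dmap.channels and "H(X)" in dmap.channels

    def test_empty_input_is_error(self):
        with pytest.raises(DensityError):
            accumulate_density([], w=0.5)

    def test_spacing_coarser_than_width_is_error(self):
        with pytest.raises(DensityError):
            accumulate_density([(np.zeros((1, 3)), ["C"])], w=0.2, spacing=0.5)


class TestCubeExport:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        aligned = [(rng.uniform(-2, 2, size=(5, 3)), ["C"] * 5)]
        dmap = accumulate_density(aligned, w=0.5, side=6.0, spacing=0.3)
        path = tmp_path / "c.cube"
        export_cube(dmap, "C", path)
        grid, origin, spacing = read_cube(path)
        assert grid.shape == dmap.channels["C"].shape
        np.testing.assert_allclose(grid, dmap.channels["C"], rtol=1e-4, atol=1e-9)
        assert spacing == pytest.approx(0.3, abs=1e-6)
        assert grid.max() == pytest.approx(dmap.channels["C"].max(), rel=1e-4)
        assert np.unravel_index(grid.argmax(), grid.shape) == np.unravel_index(
            dmap.channels["C"].argmax(), dmap.channels["C"].shape
        )

    def test_grid_count_61_for_default_resolution(self, tmp_path):
        dmap = accumulate_density([(np.zeros((1, 3)), ["C"])], w=0.5, side=12.0, spacing=0.2)
        assert dmap.n_points == 61
        path = tmp_path / "d.cube"
        export_cube(dmap, "C", path)
        header_counts = open(path).readlines()[3].split()[0]
        assert header_counts == "61"

    def test_empty_channel_is_all_zero(self, tmp_path):
        dmap = accumulate_density([(np.zeros((1, 3)), ["C"])], w=0.5, side=4.0,
                                  spacing=0.2, elements_keep=["C", "O"])
        path = tmp_path / "o.cube"
        export_cube(dmap, "O", path)
        grid, _, _ = read_cube(path)
        assert np.all(grid == 0.0)

    def test_unknown_channel_is_error(self, tmp_path):
        dmap = accumulate_density([(np.zeros((1, 3)), ["C"])], w=0.5, side=4.0, spacing=0.2)
        with pytest.raises(DensityError):
            export_cube(dmap, "Zn", tmp_path / "x.cube")


def test_map_invariant_to_common_rigid_motion_before_alignment(small_world, small_envs):
    from shiftcryst.density import AlignmentSpec, accumulate_density, align_environment

    envs = list(small_envs.values())[:5]
    spec = AlignmentSpec(("N1", "H1"), mode="bond_axis", orientation_atom="C1")
    rng = np.random.default_rng(8)
    rot = rand_rotation(rng)
    shift = rng.uniform(-10, 10, size=3)

    def build(envs_in, transform):
        aligned = []
        for env in envs_in:
            e = env
            if transform:
                e = MolecularEnvironment(
                    env_id=env.env_id, central_mol_id=env.central_mol_id,
                    positions=env.positions @ rot.T + shift,
                    elements=env.elements, mol_ids=env.mol_ids, cutoff=env.cutoff,
                )
            pos, _ = align_environment(e, spec, small_world.graph)
            aligned.append((pos, list(e.elements)))
        return accumulate_density(aligned, w=0.5, side=8.0, spacing=0.4,
                                  elements_keep=["O"])

    a = build(envs, False)
    b = build(envs, True)
    np.testing.assert_allclose(a.channels["O"], b.channels["O"], atol=1e-9)
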