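"""PDB frame reading, funnel counts, cavity volume, residue distances."""

import math

import numpy as np
import pytest

from kacmeta.structure_region import (
    CavityProbe,
    RegionDefinition,
    StructureFrame,
    cavity_volume,
    funnel_lysine_counts,
    min_residue_distance,
    read_structure,
    volume_trajectory,
)
from kacmeta.synthetic_data import (
    generate_structure_fixture,
    soda_family,
    write_multimodel_pdb,
)

SPHERE_8A = 4.0 / 3.0 * math.pi * 8.0**3  # 2144.66 A^3


def frame_from_coords(coords, elements=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return StructureFrame(
        residue_numbers=np.arange(1, n + 1),
        residue_names=["ALA"] * n,
        atom_names=["CA"] * n,
        elements=list(elements or ["C"] * n),
        coords=coords,
        chain_ids=["A"] * n,
    )


class TestReadStructure:
    def test_two_model_file_yields_two_frames(self, tmp_path):
        frames, _ = generate_structure_fixture(n_atoms=4, n_models=2, seed=0)
        path = tmp_path / "two.pdb"
        write_multimodel_pdb(frames, path)
        back = read_structure(path)
        assert len(back) == 2
        assert back[1].frame_index == 1

    def test_atom_count_matches_atom_record_count(self, tmp_path):
        frames, _ = generate_structure_fixture(n_atoms=5, n_models=3, seed=1)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(frames, path)
        n_atom_lines = sum(1 for l in path.read_text().splitlines()
                           if l.startswith("ATOM"))
        back = read_structure(path)
        assert sum(f.n_atoms for f in back) == n_atom_lines

    def test_coordinates_round_trip(self, tmp_path):
        frames, _ = generate_structure_fixture(n_atoms=6, n_models=1, seed=2)
        path = tmp_path / "one.pdb"
        write_multimodel_pdb(frames, path)
        (back,) = read_structure(path)
        assert np.allclose(back.coords, frames[0].coords, atol=1e-3)
        assert back.elements == frames[0].elements

    def test_hetatm_only_file_is_error(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n")
        with pytest.raises(ValueError, match="no ATOM records"):
            read_structure(path)


class TestFunnelCounts:
    def test_region_covering_whole_sequence(self):
        seq = "KAKAKA"
        region = RegionDefinition("all", ((1, 6),))
        fk, fkac = funnel_lysine_counts(seq, region, [])
        assert fk == seq.count("K")
        assert fkac == 0

    def test_subregion_counts(self):
        region = RegionDefinition("r", ((3, 4),))
        fk, fkac = funnel_lysine_counts("KAKKAK", region, {3, 6})
        assert (fk, fkac) == (2, 1)

    def test_out_of_range_kac_position_is_error(self):
        region = RegionDefinition("r", ((1, 3),))
        with pytest.raises(ValueError, match="outside sequence"):
            funnel_lysine_counts("KAK", region, [9])

    def test_human_soda_has_most_funnel_kac(self):
        records = soda_family()
        counts = {}
        for species, rec in records.items():
            fk, fkac = funnel_lysine_counts(rec.sequence, rec.region,
                                            rec.kac_positions)
            assert (fk, fkac) == (rec.fk, rec.fkac)  # generator ledger
            assert fkac <= fk
            counts[species] = fkac
        assert max(counts, key=counts.get) == "Hs"


class TestCavityVolume:
    def test_empty_sphere_close_to_analytic(self):
        probe = CavityProbe((0.0, 0.0, 0.0), radius=8.0, grid_spacing=0.5)
        v = cavity_volume(None, probe)
        assert abs(v - SPHERE_8A) / SPHERE_8A < 0.02

    def test_grid_converges_to_analytic_volume(self):
        errors = []
        for spacing in (1.0, 0.5, 0.25):
            probe = CavityProbe((0.0, 0.0, 0.0), 8.0, spacing)
            errors.append(abs(cavity_volume(None, probe) - SPHERE_8A))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] / SPHERE_8A < 0.005

    def test_full_occlusion_by_central_atom(self):
        frame = frame_from_coords([[0, 0, 0]], elements=["C"])
        probe = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5, probe_radius=7.0)
        assert cavity_volume(frame, probe) == 0.0

    def test_monotone_under_atom_addition(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-4, 4, (6, 3))
        probe = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5)
        volumes = [cavity_volume(frame_from_coords(coords[:k]), probe)
                   for k in range(1, 7)]
        assert all(b <= a for a, b in zip(volumes, volumes[1:]))

    def test_matches_monte_carlo_oracle(self):
        """Grid volume within 3% of rejection-sampling integration."""
        rng = np.random.default_rng(41)
        for seed in (3, 4):
            frames, _ = generate_structure_fixture(n_atoms=3, seed=seed,
                                                   spread=4.0)
            frame = frames[0]
            probe = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5)
            v = cavity_volume(frame, probe)
            pts = rng.uniform(-8, 8, (200_000, 3))
            pts = pts[np.linalg.norm(pts, axis=1) <= 8.0]
            radii = frame.atom_radii()
            d = np.linalg.norm(pts[:, None, :] - frame.coords[None, :, :],
                               axis=2)
            mc = np.all(d > radii[None, :], axis=1).mean() * SPHERE_8A
            assert abs(v - mc) / mc < 0.03

    def test_invariant_under_rigid_translation(self):
        frames, _ = generate_structure_fixture(n_atoms=4, seed=5, spread=4.0)
        frame = frames[0]
        offset = (13.0, -7.0, 2.5)
        probe0 = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5)
        probe1 = CavityProbe(offset, 8.0, 0.5)
        assert cavity_volume(frame, probe0) == \
            cavity_volume(frame.translated(offset), probe1)


class TestMinResidueDistance:
    def test_three_four_five_triangle(self):
        frame = frame_from_coords([[0, 0, 0], [3, 4, 0]])
        assert min_residue_distance(frame, [1], [2]) == pytest.approx(5.0)

    def test_identical_residue_in_both_sets(self):
        frame = frame_from_coords([[1, 1, 1], [5, 5, 5]])
        assert min_residue_distance(frame, [1, 2], [2]) == 0.0

    def test_symmetric_in_residue_sets(self):
        frames, _ = generate_structure_fixture(n_atoms=8, seed=6)
        frame = frames[0]
        assert min_residue_distance(frame, [1, 2, 3], [6, 7]) == \
            min_residue_distance(frame, [6, 7], [1, 2, 3])

    def test_matches_brute_force_all_pairs(self):
        frames, _ = generate_structure_fixture(n_atoms=20, seed=8)
        frame = frames[0]
        a, b = [1, 4, 9, 12], [2, 7, 15, 20]
        brute = min(
            float(np.linalg.norm(frame.coords[i - 1] - frame.coords[j - 1]))
            for i in a for j in b)
        assert min_residue_distance(frame, a, b) == pytest.approx(brute)

    def test_unresolvable_residue_named_in_error(self):
        frame = frame_from_coords([[0, 0, 0]])
        with pytest.raises(KeyError, match="99"):
            min_residue_distance(frame, [1], [99])


class TestVolumeTrajectory:
    def test_identical_frames_have_zero_sd(self):
        frames, _ = generate_structure_fixture(n_atoms=3, n_models=4, seed=9,
                                               oscillation=0.0)
        probe = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5)
        series = volume_trajectory(frames, probe)
        assert series.sd == 0.0
        assert len(set(series.volumes)) == 1

    def test_mean_of_two_frames(self):
        frames, _ = generate_structure_fixture(n_atoms=3, n_models=1, seed=10)
        probe = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5)
        empty = frame_from_coords(np.zeros((0, 3)))
        v_full = cavity_volume(frames[0], probe)
        v_empty = cavity_volume(empty, probe)
        series = volume_trajectory([frames[0], empty], probe)
        assert series.mean == pytest.approx((v_full + v_empty) / 2)

    def test_series_equals_per_frame_recomputation(self):
        frames, _ = generate_structure_fixture(n_atoms=5, n_models=6, seed=11,
                                               oscillation=0.15)
        probe = CavityProbe((0.0, 0.0, 0.0), 8.0, 0.5)
        series = volume_trajectory(frames, probe)
        assert list(series.volumes) == [cavity_volume(f, probe) for f in frames]
        assert len(set(series.volumes)) > 1  # breathing visible
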