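"""Structure I/O, charge-state bookkeeping, and geometric observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protonpath.structures import (
    Atom,
    FrameSet,
    PqrParseError,
    Structure,
    TitratableSite,
    apply_charge_state,
    distance_series,
    read_frames,
    read_pqr,
    write_pqr,
    write_xyz_frames,
)


def make_atom(idx, pos, q=0.0, r=1.0):
    return Atom(index=idx, name="X", residue_label="RES", position=np.array(pos),
                charge=q, radius=r)


class TestPqrIO:
    def test_single_record_parsed(self, tmp_path):
        f = tmp_path / "one.pqr"
        f.write_text("ATOM 1 ION ION 1 0.000 0.000 0.000 1.0000 2.000\n")
        s = read_pqr(f)
        assert len(s) == 1
        assert s.net_charge == pytest.approx(1.0)
        assert s.atoms[0].radius == pytest.approx(2.0)
        assert np.allclose(s.atoms[0].position, 0.0)

    def test_chain_id_column_accepted(self, tmp_path):
        f = tmp_path / "chain.pqr"
        f.write_text("ATOM 1 OH TYR A 12 1.0 2.0 3.0 -0.5 1.6\n")
        s = read_pqr(f)
        assert s.atoms[0].name == "OH"
        assert np.allclose(s.atoms[0].position, [1.0, 2.0, 3.0])

    def test_round_trip_preserves_fields(self, tmp_path, small_structure):
        f = tmp_path / "rt.pqr"
        write_pqr(small_structure, f)
        back = read_pqr(f)
        assert len(back) == len(small_structure)
        assert np.allclose(back.positions, small_structure.positions, atol=5e-4)
        assert np.allclose(back.charges, small_structure.charges, atol=5e-5)
        assert np.allclose(back.radii, small_structure.radii, atol=5e-4)

    def test_malformed_record_names_line(self, tmp_path):
        f = tmp_path / "bad.pqr"
        f.write_text(
            "ATOM 1 A RES 1 0.0 0.0 0.0 0.0 1.0\n"
            "ATOM 2 B RES 1 0.0 xyz 0.0 0.0 1.0\n"
        )
        with pytest.raises(PqrParseError, match="line 2"):
            read_pqr(f)

    def test_negative_radius_rejected(self, tmp_path):
        f = tmp_path / "neg.pqr"
        f.write_text("ATOM 1 A RES 1 0.0 0.0 0.0 0.0 -1.0\n")
        with pytest.raises(PqrParseError, match="negative radius"):
            read_pqr(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "empty.pqr"
        f.write_text("")
        with pytest.raises(PqrParseError):
            read_pqr(f)

    def test_wrong_column_count_rejected(self, tmp_path):
        f = tmp_path / "cols.pqr"
        f.write_text("ATOM 1 A RES 0.0 0.0 0.0 1.0\n")
        with pytest.raises(PqrParseError, match="fields"):
            read_pqr(f)

    def test_empty_structure_not_writable(self, tmp_path):
        with pytest.raises(ValueError):
            write_pqr(Structure(atoms=[]), tmp_path / "x.pqr")

    def test_order_preserved(self, tmp_path, toy_site):
        structure, _, _ = toy_site
        f = tmp_path / "toy.pqr"
        write_pqr(structure, f)
        back = read_pqr(f)
        assert [a.name for a in back.atoms] == [a.name for a in structure.atoms]


class TestFrames:
    def test_xyz_two_blocks(self, tmp_path):
        f = tmp_path / "t.xyz"
        f.write_text(
            "3\nframe 0\nC 0 0 0\nC 1 0 0\nC 0 1 0\n"
            "3\nframe 1\nC 0 0 1\nC 1 0 1\nC 0 1 1\n"
        )
        fs = read_frames(f)
        assert fs.n_atoms == 3
        assert len(fs) == 2
        assert fs.frames[1][0][2] == pytest.approx(1.0)

    def test_single_model_pdb(self, tmp_path):
        f = tmp_path / "t.pdb"
        f.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "END\n"
        )
        fs = read_frames(f)
        assert fs.n_atoms == 1
        assert len(fs) == 1
        assert np.allclose(fs.frames[0][0], [1.0, 2.0, 3.0])

    def test_multi_model_pdb(self, tmp_path):
        def rec(x):
            return (
                f"ATOM  {1:5d}  CA  ALA A{1:4d}    {x:8.3f}{0.0:8.3f}{0.0:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}           C\n"
            )

        f = tmp_path / "mm.pdb"
        f.write_text(
            "MODEL     1\n" + rec(0.0) + "ENDMDL\n"
            "MODEL     2\n" + rec(2.0) + "ENDMDL\nEND\n"
        )
        fs = read_frames(f)
        assert len(fs) == 2
        assert fs.frames[1][0][0] == pytest.approx(2.0)

    def test_inconsistent_atom_count_rejected(self, tmp_path):
        f = tmp_path / "bad.xyz"
        f.write_text("3\nA\nC 0 0 0\nC 1 0 0\nC 0 1 0\n2\nB\nC 0 0 1\nC 1 0 1\n")
        with pytest.raises(ValueError, match="atom count"):
            read_frames(f)

    def test_short_block_rejected(self, tmp_path):
        f = tmp_path / "short.xyz"
        f.write_text("3\nA\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(ValueError):
            read_frames(f)

    def test_xyz_round_trip(self, tmp_path, two_frame_set):
        f = tmp_path / "rt.xyz"
        write_xyz_frames(two_frame_set, f)
        back = read_frames(f)
        assert back.n_atoms == two_frame_set.n_atoms
        for a, b in zip(back.frames, two_frame_set.frames):
            assert np.allclose(a, b, atol=1e-5)


class TestChargeStates:
    def test_net_charge_gap_is_plus_one(self, small_structure, simple_site):
        prot = apply_charge_state(small_structure, simple_site, "protonated")
        deprot = apply_charge_state(small_structure, simple_site, "deprotonated")
        assert prot.net_charge - deprot.net_charge == pytest.approx(1.0, abs=1e-6)

    def test_only_site_atoms_change(self, small_structure, simple_site):
        prot = apply_charge_state(small_structure, simple_site, "protonated")
        for k in range(len(small_structure)):
            if k in simple_site.atom_indices:
                continue
            assert prot.atoms[k].charge == small_structure.atoms[k].charge

    def test_input_unmodified(self, small_structure, simple_site):
        before = small_structure.charges.copy()
        apply_charge_state(small_structure, simple_site, "protonated")
        assert np.array_equal(small_structure.charges, before)

    def test_idempotent(self, small_structure, simple_site):
        once = apply_charge_state(small_structure, simple_site, "protonated")
        twice = apply_charge_state(once, simple_site, "protonated")
        assert np.array_equal(once.charges, twice.charges)

    def test_state_cycle_recovers_charges(self, small_structure, simple_site):
        p1 = apply_charge_state(small_structure, simple_site, "protonated")
        d = apply_charge_state(p1, simple_site, "deprotonated")
        p2 = apply_charge_state(d, simple_site, "protonated")
        assert np.allclose(p1.charges, p2.charges, atol=1e-12)
        assert np.allclose(d.charges, small_structure.charges, atol=1e-12)

    def test_out_of_range_index_rejected(self, small_structure):
        site = TitratableSite(label="bad", atom_indices=[99], delta_q=[1.0])
        with pytest.raises(IndexError):
            apply_charge_state(small_structure, site, "protonated")

    def test_delta_q_must_sum_to_one(self):
        with pytest.raises(ValueError, match="delta_q"):
            TitratableSite(label="x", atom_indices=[0, 1], delta_q=[0.4, 0.4])


class TestDistanceSeries:
    def test_euclidean_distance(self):
        fs = FrameSet(n_atoms=2, frames=[np.array([[0.0, 0, 0], [3.0, 4.0, 0]])])
        assert distance_series(fs, 0, 1)[0] == pytest.approx(5.0)

    def test_same_atom_rejected(self, two_frame_set):
        with pytest.raises(ValueError):
            distance_series(two_frame_set, 1, 1)

    def test_invalid_index_rejected(self, two_frame_set):
        with pytest.raises(IndexError):
            distance_series(two_frame_set, 0, 17)

    def test_identical_frames_give_equal_values(self, small_structure):
        base = small_structure.positions
        fs = FrameSet(n_atoms=5, frames=[base, base])
        d = distance_series(fs, 0, 3)
        assert d[0] == pytest.approx(d[1])

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        frames = [rng.normal(size=(4, 3)) for _ in range(3)]
        fs = FrameSet(n_atoms=4, frames=frames)
        # random rotation via QR, plus translation, applied to every frame
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3)
        moved = FrameSet(n_atoms=4, frames=[f @ q.T + t for f in frames])
        assert np.allclose(
            distance_series(fs, 0, 2), distance_series(moved, 0, 2), atol=1e-10
        )


class TestInvariants:
    def test_atom_radius_validation(self):
        with pytest.raises(ValueError):
            make_atom(0, [0, 0, 0], r=-0.5)

    def test_non_contiguous_indices_rejected(self):
        atoms = [make_atom(0, [0, 0, 0]), make_atom(2, [1, 0, 0])]
        with pytest.raises(ValueError, match="contiguous"):
            Structure(atoms=atoms)

    def test_frameset_requires_frames(self):
        with pytest.raises(ValueError):
            FrameSet(n_atoms=3, frames=[])
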