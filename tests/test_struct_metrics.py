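"""Structure-model geometry: superposition, dihedrals, SASA, burial, wheels."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from killerkit import struct_metrics, synthetic
from killerkit.struct_metrics import (
    ATOM_COLUMNS,
    EISENBERG,
    StructureModel,
    backbone_dihedrals,
    confidence_summary,
    detect_disulfides,
    helix_burial,
    hydrophobic_moment,
    kabsch_superpose,
    ramachandran_summary,
    read_pdb_model,
    shrake_rupley_sasa,
    ss_fraction,
)


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent superposition oracle (Horn's quaternion method).

    The minimal RMSD over proper rotations follows from the largest
    eigenvalue of the 4x4 quaternion matrix built from the covariance of the
    centered point sets.
    """
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = len(x)
    msd = max(((x**2).sum() + (y**2).sum() - 2.0 * lam) / n, 0.0)
    return math.sqrt(msd)


def atoms_from_points(points, chain="A", element="C"):
    rows = [
        (chain, i + 1, "", "SPH", element, element, *map(float, p), 100.0, False)
        for i, p in enumerate(points)
    ]
    return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_identity_gives_zero_rmsd(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        assert kabsch_superpose(x, x).rmsd == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(12, 3))
        rot = random_rotation(rng)
        moved = x @ rot.T + rng.normal(size=3) * 10
        result = kabsch_superpose(moved, x)
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(result.rotation @ result.rotation.T, np.eye(3), atol=1e-8)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            quaternion_rmsd(a, b), abs=1e-6
        )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9
        )

    def test_reflection_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        mirrored = x * np.array([1.0, 1.0, -1.0])
        result = kabsch_superpose(mirrored, x)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-8)
        assert result.rmsd > 0.1  # a reflection cannot be undone by a rotation

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_too_few_points(self, n):
        pts = np.zeros((n, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestBackboneDihedrals:
    @settings(max_examples=20, derandomize=True)
    @given(
        phi=st.floats(min_value=-179.0, max_value=179.0),
        psi=st.floats(min_value=-179.0, max_value=179.0),
    )
    def test_recovery_on_ideal_backbones(self, phi, psi):
        model = synthetic.gen_ideal_backbone(8, phi, psi)
        d = backbone_dihedrals(model)
        assert np.nanmax(np.abs(d.phi.to_numpy()[1:] - phi)) < 1e-3
        assert np.nanmax(np.abs(d.psi.to_numpy()[:-1] - psi)) < 1e-3

    def test_terminal_angles_undefined(self):
        d = backbone_dihedrals(synthetic.gen_ideal_backbone(3, -57, -47))
        assert np.isnan(d.phi.iloc[0]) and np.isnan(d.psi.iloc[-1])
        assert not np.isnan(d.phi.iloc[1]) and not np.isnan(d.psi.iloc[1])

    def test_chain_break_yields_undefined_angles(self):
        model = synthetic.gen_ideal_backbone(8, -57, -47)
        atoms = model.atoms.copy()
        # translate residues 5-8 by 10 Angstrom: C(4)-N(5) becomes a break
        mask = atoms.resnum >= 5
        atoms.loc[mask, ["x", "y", "z"]] += 10.0
        broken = StructureModel(atoms)
        d = backbone_dihedrals(broken)
        assert np.isnan(d.psi.iloc[3]) and np.isnan(d.phi.iloc[4])
        assert not np.isnan(d.phi.iloc[3]) and not np.isnan(d.psi.iloc[4])


class TestRamachandran:
    def _frame(self, phi, psi, n=10, resname="ALA"):
        return pd.DataFrame(
            {
                "chain": "A", "resnum": range(1, n + 1), "icode": "",
                "resname": resname, "phi": [phi] * n, "psi": [psi] * n,
            }
        )

    def test_helical_angles_all_favored(self):
        summary = ramachandran_summary(self._frame(-60.0, -45.0))
        assert summary.fractions["favored"] == 1.0

    def test_forbidden_angles_all_outlier_for_non_glycine(self):
        summary = ramachandran_summary(self._frame(60.0, -170.0))
        assert summary.fractions["outlier"] == 1.0

    def test_glycine_tolerates_left_handed_region(self):
        summary = ramachandran_summary(self._frame(70.0, 30.0, resname="GLY"))
        assert summary.fractions["outlier"] == 0.0

    def test_fractions_match_brute_force_recount(self):
        rng = np.random.default_rng(2)
        n = 200
        frame = pd.DataFrame(
            {
                "chain": "A", "resnum": range(1, n + 1), "icode": "",
                "resname": rng.choice(["ALA", "GLY", "PRO", "SER"], n),
                "phi": rng.uniform(-180, 180, n),
                "psi": rng.uniform(-180, 180, n),
            }
        )
        summary = ramachandran_summary(frame)
        region_map = struct_metrics.load_rama_map()
        recount = {"favored": 0, "allowed": 0, "outlier": 0}
        resnames = frame.resname.tolist()
        for i, row in frame.iterrows():
            nxt = resnames[i + 1] if i + 1 < n else None
            sub = region_map[struct_metrics._submap_for(row.resname, nxt)]
            if struct_metrics._in_rects(row.phi, row.psi, sub["favored"]):
                recount["favored"] += 1
            elif struct_metrics._in_rects(row.phi, row.psi, sub["allowed"]):
                recount["allowed"] += 1
            else:
                recount["outlier"] += 1
        assert summary.counts == recount
        assert sum(summary.fractions.values()) == pytest.approx(1.0)


class TestSsFraction:
    def test_ideal_helix(self, ideal_helix):
        fracs = ss_fraction(backbone_dihedrals(ideal_helix))
        assert fracs["helix"] >= 0.9

    def test_ideal_strand(self):
        model = synthetic.gen_ideal_backbone(10, -120.0, 130.0)
        fracs = ss_fraction(backbone_dihedrals(model))
        assert fracs["strand"] >= 0.9

    def test_empty_input_warns_and_returns_zero(self):
        empty = pd.DataFrame(
            {"chain": [], "resnum": [], "icode": [], "resname": [],
             "phi": [], "psi": []}
        )
        with pytest.warns(UserWarning):
            fracs = ss_fraction(empty)
        assert fracs == {"helix": 0.0, "strand": 0.0, "other": 0.0}


class TestSasa:
    def test_single_atom_analytic(self):
        result = shrake_rupley_sasa(synthetic.gen_single_atom())
        analytic = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(analytic, rel=0.01)

    def test_disjoint_pair_additive(self):
        single = shrake_rupley_sasa(synthetic.gen_single_atom()).total
        pair = shrake_rupley_sasa(synthetic.gen_atom_pair(100.0)).total
        assert pair == pytest.approx(2 * single, rel=1e-9)

    @pytest.mark.parametrize("separation", [1.0, 2.0, 4.0])
    def test_overlapping_pair_matches_spherical_cap_formula(self, separation):
        result = shrake_rupley_sasa(synthetic.gen_atom_pair(separation))
        assert result.total == pytest.approx(
            synthetic.two_sphere_sasa_analytic(separation), rel=0.02
        )

    def test_per_atom_within_sphere_bound(self, ideal_helix):
        result = shrake_rupley_sasa(ideal_helix)
        radii = ideal_helix.atoms.element.map(struct_metrics.DEFAULT_RADII)
        bounds = 4 * math.pi * (radii.to_numpy(float) + 1.4) ** 2
        assert (result.per_atom >= 0).all()
        assert (result.per_atom <= bounds + 1e-9).all()
        assert result.total == pytest.approx(result.per_atom.sum(), abs=1e-6)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=3.0, size=(15, 3))
        base = shrake_rupley_sasa(atoms_from_points(pts)).total
        moved = pts @ random_rotation(rng).T + rng.normal(size=3) * 20
        after = shrake_rupley_sasa(atoms_from_points(moved)).total
        assert after == pytest.approx(base, rel=0.005)

    def test_matches_independent_implementation(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=3.0, size=(30, 3))
        arr = biotite_struc.AtomArray(30)
        arr.coord = pts.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 31)
        arr.res_name[:] = "SPH"
        arr.atom_name[:] = "C"
        arr.element[:] = "C"
        reference = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii="Single"
        ).sum()
        ours = shrake_rupley_sasa(atoms_from_points(pts)).total
        assert ours == pytest.approx(reference, rel=0.01)

    def test_unknown_element_rejected(self):
        model = atoms_from_points(np.zeros((1, 3)), element="ZZ")
        with pytest.raises(ValueError, match="ZZ"):
            shrake_rupley_sasa(model)


class TestHelixBurial:
    def test_span_alone_not_buried(self, ideal_helix):
        result = helix_burial(ideal_helix, (1, 20))
        assert result.buried_area == pytest.approx(0.0, abs=1e-6)
        assert result.percent_buried == pytest.approx(0.0, abs=1e-6)

    def test_enclosing_shell_buries_nearly_everything(self):
        scene = synthetic.gen_occlusion_scene()
        result = helix_burial(scene, (1, 5), chain="A")
        assert result.percent_buried >= 95.0
        assert result.percent_buried <= 100.0

    def test_burial_monotone_as_occluders_added(self):
        scene = synthetic.gen_occlusion_scene(shell_spacing=2.5)
        shell = scene.atoms[scene.atoms.chain == "B"]
        previous = -1.0
        for keep in (0, len(shell) // 3, len(shell)):
            atoms = pd.concat([scene.atoms[scene.atoms.chain == "A"], shell.iloc[:keep]])
            partial = StructureModel(atoms.reset_index(drop=True))
            result = helix_burial(partial, (1, 5), chain="A")
            assert 0.0 <= result.percent_buried <= 100.0
            assert result.percent_buried >= previous - 1e-9
            previous = result.percent_buried

    def test_empty_span_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            helix_burial(ideal_helix, (100, 120))


class TestDisulfides:
    def _sg_model(self, positions):
        rows = [
            ("A", i + 1, "", "CYS", "SG", "S", *map(float, p), 100.0, False)
            for i, p in enumerate(positions)
        ]
        return StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))

    def test_bonded_pair(self):
        bonds = detect_disulfides(self._sg_model([(0, 0, 0), (0, 0, 2.05)]))
        assert len(bonds) == 1 and bonds[0].kind == "bonded"
        assert bonds[0].distance == pytest.approx(2.05)

    def test_long_pair_ignored_at_defaults(self):
        assert detect_disulfides(self._sg_model([(0, 0, 0), (0, 0, 3.5)])) == []

    def test_near_class(self):
        bonds = detect_disulfides(self._sg_model([(0, 0, 0), (0, 0, 2.8)]))
        assert len(bonds) == 1 and bonds[0].kind == "near"

    def test_greedy_matching_each_sg_once(self):
        # triangle: 2.05 / 2.05 / ~2.9; only the closest pair bonds, the
        # third SG may pair "near" with a leftover but never twice
        positions = [(0, 0, 0), (2.05, 0, 0), (1.025, 2.53, 0)]
        bonds = detect_disulfides(self._sg_model(positions))
        bonded = [b for b in bonds if b.kind == "bonded"]
        assert len(bonded) == 1
        assert bonded[0].distance == pytest.approx(2.05, abs=0.01)
        seen = [b.residue_a for b in bonds] + [b.residue_b for b in bonds]
        assert len(seen) == len(set(seen))

    def test_no_cysteines_empty(self, ideal_helix):
        assert detect_disulfides(ideal_helix) == []


class TestHydrophobicMoment:
    def test_homopolymer_18mer_vanishes(self):
        # 18 residues x 100 degrees = five full turns: the unit vectors sum
        # to zero exactly, so a homopolymer has zero moment
        geometry = hydrophobic_moment("L" * 18)
        assert geometry.hydrophobic_moment == pytest.approx(0.0, abs=1e-9)

    def test_single_residue(self):
        geometry = hydrophobic_moment("F")
        assert geometry.hydrophobic_moment == pytest.approx(abs(EISENBERG["F"]))

    def test_matches_complex_exponential_oracle(self):
        seq = "LKLKLKLKLKLKLKLKLK"
        z = sum(
            EISENBERG[c] * np.exp(1j * math.radians(100.0 * n))
            for n, c in enumerate(seq)
        )
        geometry = hydrophobic_moment(seq)
        assert geometry.hydrophobic_moment == pytest.approx(abs(z), abs=1e-9)
        assert geometry.mean_hydrophobicity == pytest.approx(
            np.mean([EISENBERG[c] for c in seq])
        )

    @settings(max_examples=30, derandomize=True)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_reversal_with_negated_delta_invariance(self, seq):
        forward = hydrophobic_moment(seq, delta=100.0).hydrophobic_moment
        backward = hydrophobic_moment(seq[::-1], delta=-100.0).hydrophobic_moment
        assert forward == pytest.approx(backward, abs=1e-9)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_moment("LX")

    def test_wheel_angles_modulo_360(self):
        geometry = hydrophobic_moment("A" * 10)
        assert all(0 <= a < 360 for a in geometry.wheel_angles)
        assert geometry.wheel_angles[4] == pytest.approx(40.0)  # 400 mod 360


class TestConfidenceAndIO:
    def test_constant_confidence(self, ideal_helix):
        summary = confidence_summary(ideal_helix)
        assert summary.mean == summary.min == summary.max == 100.0

    def test_two_residue_mean(self):
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0.0, 0.0, 0.0, 50.0, False),
            ("A", 2, "", "ALA", "CA", "C", 4.0, 0.0, 0.0, 100.0, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))
        assert confidence_summary(model).mean == pytest.approx(75.0)

    def test_sampled_confidence_recount(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(30, 90, 25)
        rows = [
            ("A", i + 1, "", "ALA", "CA", "C", float(i) * 4, 0.0, 0.0, float(v), False)
            for i, v in enumerate(values)
        ]
        model = StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))
        assert confidence_summary(model).mean == pytest.approx(values.mean())

    def test_no_ca_atoms_rejected(self):
        rows = [("A", 1, "", "SPH", "C", "C", 0.0, 0.0, 0.0, 1.0, False)]
        model = StructureModel(pd.DataFrame(rows, columns=ATOM_COLUMNS))
        with pytest.raises(ValueError):
            confidence_summary(model)

    def test_pdb_roundtrip(self, tmp_path, ideal_helix):
        path = tmp_path / "helix.pdb"
        ideal_helix.write_pdb(path)
        back = read_pdb_model(path)
        assert len(back) == len(ideal_helix)
        assert np.abs(back.coords() - ideal_helix.coords()).max() < 1e-3
        assert (back.atoms.confidence == 100.0).all()

    def test_missing_atoms_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER only\nEND\n")
        with pytest.raises(struct_metrics.PDBParseError):
            read_pdb_model(path)

    def test_altloc_first_kept(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50 90.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50 80.00           C\n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(text)
        model = read_pdb_model(path)
        assert len(model) == 1
        assert model.atoms.iloc[0].x == pytest.approx(0.0)
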