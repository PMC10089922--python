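import numpy as np
import pandas as pd
import pytest

from fretkit.structure import (AVCloud, DyeParameters, compare_model_experiment,
                               compute_acv, compute_av, find_attachment,
                               model_distances, parse_structure)

COLS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z", "vdw"]
TOY_PARAMS = DyeParameters(linker_length=10.0, linker_width=2.0,
                           dye_radii=(1.0, 1.0, 1.0), grid_spacing=0.5)


def wall_atoms(z=-2.2, vdw=1.2, half=14.0):
    xs = np.arange(-half, half + 0.1, 1.0)
    rows = [("A", 1, "ALA", "X", "C", x, y, z, vdw) for x in xs for y in xs]
    return pd.DataFrame(rows, columns=COLS)


SYNTHETIC_PDB = """\
MODEL        1
ATOM      1  N   ALA A  29      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A  29      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  CB  ALA A  29      12.100  11.200  10.500  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A  29      20.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A  29      21.400  10.000  10.000  1.00  0.00           C
ATOM      3  CB  ALA A  29      22.100  11.200  10.500  1.00  0.00           C
ENDMDL
END
"""


class TestParse:
    @pytest.fixture()
    def pdb_file(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(SYNTHETIC_PDB)
        return p

    def test_three_atoms_with_coordinates(self, pdb_file):
        atoms = parse_structure(pdb_file)
        assert len(atoms) == 3
        assert atoms.iloc[0].x == pytest.approx(10.0)
        assert set(atoms.element) == {"N", "C"}

    def test_model_selection(self, pdb_file):
        first = parse_structure(pdb_file, model_index=0)
        second = parse_structure(pdb_file, model_index=1)
        assert first.iloc[0].x == pytest.approx(10.0)
        assert second.iloc[0].x == pytest.approx(20.0)

    def test_attachment_by_residue_number(self, pdb_file):
        atoms = parse_structure(pdb_file)
        cb = find_attachment(atoms, 29, "CB")
        np.testing.assert_allclose(cb, [12.1, 11.2, 10.5])
        with pytest.raises(KeyError, match="residue 99"):
            find_attachment(atoms, 99, "CB")


class TestAV:
    def test_free_space_ball(self):
        cloud = compute_av(pd.DataFrame(columns=COLS), np.zeros(3), TOY_PARAMS,
                           model="AV1")
        radii = np.linalg.norm(cloud.points, axis=1)
        assert radii.max() <= 10.0 + 1e-9
        np.testing.assert_allclose(cloud.mean_position, [0, 0, 0], atol=0.05)
        # volume close to the analytic ball (grid-limited)
        vol = cloud.points.shape[0] * 0.5**3
        # the lattice geodesic metric trims the rim by ~2% in radius
        assert vol == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.08)
        assert radii.max() >= 9.9

    def test_hemisphere_centroid(self):
        """A plane wall leaves a half-ball; its centroid sits at 3L/8 along
        the free axis (closed form), reproduced to grid accuracy."""
        cloud = compute_av(wall_atoms(), np.zeros(3), TOY_PARAMS, model="AV1")
        assert cloud.points[:, 2].min() >= 0.0
        assert cloud.mean_position[2] == pytest.approx(3 * 10.0 / 8, rel=0.10)

    def test_buried_attachment_error(self):
        # attachment fully enclosed by a box of atoms
        g = np.arange(-4, 4.1, 1.5)
        rows = [("A", 1, "ALA", "X", "C", x, y, z, 1.7)
                for x in g for y in g for z in g if max(abs(x), abs(y), abs(z)) > 1.9]
        atoms = pd.DataFrame(rows, columns=COLS)
        with pytest.raises(RuntimeError, match="buried"):
            compute_av(atoms, np.zeros(3), TOY_PARAMS, model="AV1")

    def test_av3_unions_three_radii(self):
        params = DyeParameters(linker_length=8.0, linker_width=2.0,
                               dye_radii=(3.0, 2.0, 1.0), grid_spacing=0.5)
        cloud = compute_av(wall_atoms(), np.zeros(3), params, model="AV3")
        # near-wall points are allowed only for the small radius: weight 1/3
        assert set(np.round(np.unique(cloud.weights / cloud.weights.min()), 6)) \
            <= {1.0, 2.0, 3.0}

    def test_rigid_body_invariance(self):
        """Rotating + translating the structure transports the cloud: the
        inter-cloud distances to a fixed partner are preserved."""
        from scipy.spatial.transform import Rotation

        atoms = wall_atoms()
        c1 = compute_av(atoms, np.zeros(3), TOY_PARAMS, model="AV1")
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        shift = np.array([5.0, -3.0, 8.0])
        atoms2 = atoms.copy()
        atoms2[["x", "y", "z"]] = rot.apply(atoms[["x", "y", "z"]].to_numpy()) + shift
        c2 = compute_av(atoms2, shift, TOY_PARAMS, model="AV1")
        # same point count to within grid-sampling tolerance, same mean height
        # grid re-discretization under rotation costs a few percent of points
        assert c2.points.shape[0] == pytest.approx(c1.points.shape[0], rel=0.05)
        h1 = c1.mean_position[2]
        h2 = (rot.inv().apply(c2.mean_position - shift))[2]
        assert h2 == pytest.approx(h1, abs=0.25)


class TestACV:
    def test_zero_contact_identical_to_av(self):
        cloud = compute_av(wall_atoms(), np.zeros(3), TOY_PARAMS, model="AV1")
        acv = compute_acv(cloud, wall_atoms(), contact_fraction=0.0)
        free = ~acv.contact_mask
        np.testing.assert_allclose(acv.weights[free] / acv.weights[free].sum(),
                                   cloud.weights[free] / cloud.weights[free].sum())
        assert acv.weights[acv.contact_mask].sum() == pytest.approx(0.0)

    def test_full_contact_moves_mean_to_surface(self):
        cloud = compute_av(wall_atoms(), np.zeros(3), TOY_PARAMS, model="AV1")
        acv = compute_acv(cloud, wall_atoms(), contact_fraction=1.0)
        assert acv.mean_position[2] < cloud.mean_position[2]

    def test_half_contact_centroid_quadrature(self):
        """Weighted mean equals the hand-computed two-set centroid."""
        cloud = compute_av(wall_atoms(), np.zeros(3), TOY_PARAMS, model="AV1")
        acv = compute_acv(cloud, wall_atoms(), contact_fraction=0.5)
        contact = acv.contact_mask
        manual = 0.5 * cloud.points[contact].mean(axis=0) \
            + 0.5 * cloud.points[~contact].mean(axis=0)
        np.testing.assert_allclose(acv.mean_position, manual, atol=1e-6)

    def test_contact_fraction_validated(self):
        cloud = compute_av(wall_atoms(), np.zeros(3), TOY_PARAMS, model="AV1")
        with pytest.raises(ValueError):
            compute_acv(cloud, wall_atoms(), contact_fraction=1.5)


class TestModelDistances:
    def test_point_clouds_all_distances_equal(self):
        c1 = AVCloud(points=np.array([[0.0, 0, 0]]), weights=np.array([1.0]),
                     attachment=np.zeros(3))
        c2 = AVCloud(points=np.array([[65.0, 0, 0]]), weights=np.array([1.0]),
                     attachment=np.array([65.0, 0, 0]))
        md = model_distances(c1, c2, r0=65.0)
        assert md.e_model == pytest.approx(0.5, abs=1e-12)
        assert md.r_e_model == pytest.approx(65.0, rel=1e-9)
        assert md.r_mp == pytest.approx(65.0)
        assert md.r_da_mean == pytest.approx(65.0)

    def test_two_point_masses(self):
        """Equal-weight points at 50/80 A: <E> is the plain average of the
        two Forster efficiencies and R<E> its inversion."""
        c1 = AVCloud(points=np.array([[0.0, 0, 0]]), weights=np.array([1.0]),
                     attachment=np.zeros(3))
        c2 = AVCloud(points=np.array([[50.0, 0, 0], [80.0, 0, 0]]),
                     weights=np.array([0.5, 0.5]), attachment=np.array([65.0, 0, 0]))
        md = model_distances(c1, c2, r0=65.0)
        e_expect = 0.5 * (1 / (1 + (50 / 65) ** 6) + 1 / (1 + (80 / 65) ** 6))
        assert md.e_model == pytest.approx(e_expect, rel=1e-12)
        assert md.r_e_model == pytest.approx(65.0 * (1 / e_expect - 1) ** (1 / 6), rel=1e-9)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        p1 = rng.normal(0, 3, (300, 3))
        w1 = rng.uniform(0.5, 1, 300)
        p2 = rng.normal([40, 0, 0], 3, (250, 3))
        w2 = rng.uniform(0.5, 1, 250)
        md = model_distances(AVCloud(points=p1, weights=w1, attachment=np.zeros(3)),
                             AVCloud(points=p2, weights=w2, attachment=np.zeros(3)),
                             r0=50.0)
        wn1, wn2 = w1 / w1.sum(), w2 / w2.sum()
        e = r = 0.0
        for i in range(300):
            d = np.linalg.norm(p1[i] - p2, axis=1)
            e += np.sum(wn1[i] * wn2 / (1 + (d / 50.0) ** 6))
            r += np.sum(wn1[i] * wn2 * d)
        assert abs(md.e_model - e) < 1e-9 * abs(e)
        assert abs(md.r_da_mean - r) < 1e-9 * abs(r)

    def test_grid_convergence(self):
        """Refining the grid from 1.0 to 0.5 A changes <R_DA> by < 0.5 A."""
        res = {}
        for ds in (1.0, 0.5):
            params = DyeParameters(linker_length=8.0, linker_width=2.0,
                                   dye_radii=(1.5, 1.5, 1.5), grid_spacing=ds)
            c1 = compute_av(wall_atoms(), np.zeros(3), params, model="AV1")
            c2 = compute_av(wall_atoms(z=-2.2), np.array([30.0, 0.0, 0.0]), params,
                            model="AV1")
            res[ds] = model_distances(c1, c2, r0=50.0).r_da_mean
        assert abs(res[1.0] - res[0.5]) < 0.5


class TestComparison:
    def test_identical_zero_rmsd(self):
        df = compare_model_experiment([{"label": "a", "r_exp": 60.0, "r_av": 60.0}])
        assert df.attrs["summary"]["dev_av"] == 0.0

    def test_rmsd_arithmetic(self):
        df = compare_model_experiment([
            {"label": "a", "r_exp": 65.0, "r_av": 66.0},
            {"label": "b", "r_exp": 80.0, "r_av": 78.0},
        ])
        assert df.attrs["summary"]["dev_av"] == pytest.approx(np.sqrt(2.5), abs=1e-9)
        assert df["within_band_av"].all()

    def test_acv_beats_av_for_sticky_dyes(self):
        """When the true dye density sticks to the surface, ACV-based
        distances deviate less than AV-based ones."""
        atoms = wall_atoms()
        cloud_d = compute_av(atoms, np.zeros(3), TOY_PARAMS, model="AV1")
        acv_d = compute_acv(cloud_d, atoms, contact_fraction=0.6)
        far = AVCloud(points=np.array([[40.0, 0, 6.0]]), weights=np.array([1.0]),
                      attachment=np.array([40.0, 0, 0]))
        # "experiment": sticky dye (ACV geometry is the truth)
        r_exp = model_distances(acv_d, far, r0=50.0).r_e_model
        r_av = model_distances(cloud_d, far, r0=50.0).r_e_model
        r_acv = model_distances(acv_d, far, r0=50.0).r_e_model
        df = compare_model_experiment([{"label": "w", "r_exp": r_exp,
                                        "r_av": r_av, "r_acv": r_acv}])
        assert abs(df.iloc[0].dev_acv) <= abs(df.iloc[0].dev_av)
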