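import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevopair.coevolution import ContactPrediction
from coevopair.structures import (
    Atom,
    ContactMap,
    StructureCoords,
    cofactor_distance,
    contact_map_from_structure,
    contact_map_to_grid,
    interdomain_contacts,
    kabsch_superpose,
    model_fit_rc,
    place_cofactor,
    precision_at,
    read_contact_map_tsv,
    read_structure,
    template_coverage,
    write_contact_map_tsv,
)

from conftest import make_pdb_text


def ca_only_structure(points, chain="A", resname="ALA"):
    return StructureCoords(
        [
            Atom(chain, i + 1, resname, "CB", tuple(p))
            for i, p in enumerate(points)
        ]
    )


def random_rotation(rng):
    M = rng.normal(size=(3, 3))
    Qm, R = np.linalg.qr(M)
    Qm *= np.sign(np.diag(R))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] *= -1
    return Qm


def helix_coords(n, rise=1.5, radius=2.3, turn=100.0):
    ang = np.radians(turn) * np.arange(n)
    return np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * np.arange(n)], axis=1
    )


class TestContactMapType:
    def test_pair_bounds(self):
        with pytest.raises(ValueError):
            ContactMap(npos=5, pairs=frozenset({(1, 5)}))

    def test_membership_unordered(self):
        cm = ContactMap(npos=5, pairs=frozenset({(1, 4)}), min_sep=1)
        assert (4, 1) in cm
        assert (1, 3) not in cm


class TestContactMapFromStructure:
    def test_close_pair(self):
        pts = [(0, 0, 0)] * 1 + [(100 * i, 0, 0) for i in range(1, 10)]
        pts.append((5.0, 0, 0))  # residue 11, 5 Å from residue 1
        cm = contact_map_from_structure(ca_only_structure(pts), cutoff=8.0, min_sep=6)
        assert (0, 10) in cm.pairs

    def test_far_pair(self):
        pts = [(100 * i, 0, 0) for i in range(10)] + [(9.0 + 900, 0, 0)]
        cm = contact_map_from_structure(ca_only_structure(pts), cutoff=8.0, min_sep=6)
        assert cm.pairs == frozenset()

    def test_min_sep_excludes_neighbours(self):
        pts = helix_coords(10)
        cm = contact_map_from_structure(ca_only_structure(pts), cutoff=8.0, min_sep=6)
        for i, j in cm.pairs:
            assert j - i >= 6

    def test_matches_brute_force_on_helix(self):
        pts = helix_coords(30)
        structure = ca_only_structure(pts)
        cm = contact_map_from_structure(structure, cutoff=8.0, min_sep=6)
        brute = set()
        for i in range(30):
            for j in range(i + 6, 30):
                if np.linalg.norm(pts[i] - pts[j]) < 8.0:
                    brute.add((i, j))
        assert cm.pairs == frozenset(brute)

    def test_cross_chain_exempt_from_separation(self):
        atoms = [Atom("A", 1, "ALA", "CB", (0.0, 0.0, 0.0)),
                 Atom("B", 1, "ALA", "CB", (3.0, 0.0, 0.0))]
        cm = contact_map_from_structure(StructureCoords(atoms), min_sep=6)
        assert (0, 1) in cm.pairs

    def test_glycine_uses_ca(self):
        atoms = [
            Atom("A", 1, "GLY", "CA", (0.0, 0.0, 0.0)),
            Atom("A", 1, "GLY", "C", (50.0, 0.0, 0.0)),
            Atom("B", 1, "ALA", "CB", (4.0, 0.0, 0.0)),
            Atom("B", 1, "ALA", "CA", (40.0, 0.0, 0.0)),
        ]
        cm = contact_map_from_structure(StructureCoords(atoms))
        assert (0, 1) in cm.pairs

    def test_rigid_motion_invariance(self, rng):
        pts = helix_coords(25)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 30
        cm1 = contact_map_from_structure(ca_only_structure(pts))
        cm2 = contact_map_from_structure(ca_only_structure(pts @ R.T + t))
        assert cm1.pairs == cm2.pairs


class TestPrecisionAt:
    def preds(self, pairs, probs=None):
        probs = probs or np.linspace(1.0, 0.5, len(pairs))
        return [
            ContactPrediction(i, j, p, p, p) for (i, j), p in zip(pairs, probs)
        ]

    def test_all_hits(self):
        cm = ContactMap(npos=10, pairs=frozenset({(0, 7), (1, 8)}), min_sep=1)
        assert precision_at(self.preds([(0, 7), (1, 8)]), cm, 2) == 1.0

    def test_disjoint(self):
        cm = ContactMap(npos=10, pairs=frozenset({(0, 7)}), min_sep=1)
        assert precision_at(self.preds([(1, 8), (2, 9)]), cm, 2) == 0.0

    def test_matches_brute_force(self, rng):
        npos = 15
        all_pairs = [(i, j) for i in range(npos) for j in range(i + 1, npos)]
        obs = frozenset(
            tuple(all_pairs[k]) for k in rng.choice(len(all_pairs), 30, replace=False)
        )
        cm = ContactMap(npos=npos, pairs=obs, min_sep=1)
        probs = rng.random(len(all_pairs))
        preds = self.preds(all_pairs, probs=list(probs))
        k = 12
        ranked = [p for _, p in sorted(zip(-probs, preds), key=lambda t: t[0])][:k]
        brute = sum(1 for p in ranked if (p.i, p.j) in obs) / k
        assert precision_at(preds, cm, k) == pytest.approx(brute)

    def test_k_overflow_flagged(self, caplog):
        cm = ContactMap(npos=5, pairs=frozenset({(0, 4)}), min_sep=1)
        with caplog.at_level("WARNING"):
            val = precision_at(self.preds([(0, 4)]), cm, 10)
        assert val == 1.0
        assert "exceeds" in caplog.text

    def test_non_increasing_in_k(self, rng):
        npos = 12
        all_pairs = [(i, j) for i in range(npos) for j in range(i + 1, npos)]
        obs = frozenset(
            tuple(all_pairs[k]) for k in rng.choice(len(all_pairs), 10, replace=False)
        )
        cm = ContactMap(npos=npos, pairs=obs, min_sep=1)
        # predictions sorted so that hits come first: precision@k then
        # cannot increase with k
        hits = [p for p in all_pairs if p in obs]
        misses = [p for p in all_pairs if p not in obs]
        ordered = hits + misses
        preds = self.preds(ordered, probs=list(np.linspace(1, 0.01, len(ordered))))
        vals = [precision_at(preds, cm, k) for k in range(1, len(ordered) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestInterdomainContacts:
    def test_within_one_region_empty(self):
        preds = [ContactPrediction(1, 3, 1, 1, 0.9)]
        out = interdomain_contacts(preds, {"CBD": (0, 10), "TMD": (10, 20)})
        assert out == []

    def test_straddling_pairs_returned(self):
        preds = [
            ContactPrediction(2, 12, 1, 1, 0.9),
            ContactPrediction(3, 5, 1, 1, 0.9),
            ContactPrediction(11, 25, 1, 1, 0.8),
            ContactPrediction(4, 22, 1, 1, 0.3),
        ]
        regions = {"CBD": (0, 10), "TMD": (10, 20), "B": (20, 30)}
        out = interdomain_contacts(preds, regions, threshold=0.5)
        assert [(label, p.i, p.j) for label, p in out] == [
            ("CBD-TMD", 2, 12),
            ("TMD-B", 11, 25),
        ]

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            interdomain_contacts([], {"a": (0, 5), "b": (4, 8)})


class TestModelFitRc:
    def test_all_satisfied_probability_one(self):
        cm = ContactMap(npos=10, pairs=frozenset({(0, 8), (1, 9)}), min_sep=1)
        preds = [ContactPrediction(0, 8, 1, 1, 1.0), ContactPrediction(1, 9, 1, 1, 1.0)]
        assert model_fit_rc(preds, cm, 2) == pytest.approx(1.0)

    def test_none_satisfied(self):
        cm = ContactMap(npos=10, pairs=frozenset(), min_sep=1)
        preds = [ContactPrediction(0, 8, 1, 1, 0.9)]
        assert model_fit_rc(preds, cm, 1) == 0.0

    def test_hand_computed_ratio(self):
        cm = ContactMap(npos=10, pairs=frozenset({(0, 8)}), min_sep=1)
        preds = [
            ContactPrediction(0, 8, 1, 1, 0.9),
            ContactPrediction(1, 9, 1, 1, 0.6),
        ]
        # satisfied = 1, probability mass = 1.5
        assert model_fit_rc(preds, cm, 2) == pytest.approx(1 / 1.5)

    def test_zero_mass(self):
        cm = ContactMap(npos=10, pairs=frozenset(), min_sep=1)
        with pytest.raises(ValueError, match="probability mass"):
            model_fit_rc([ContactPrediction(0, 8, 1, 1, 0.0)], cm, 1)


class TestCofactorDistance:
    def structure(self):
        return StructureCoords(
            [
                Atom("B", 101, "SF4", "FE1", (0.0, 0.0, 0.0)),
                Atom("B", 101, "SF4", "FE2", (2.0, 0.0, 0.0)),
                Atom("A", 200, "B12", "CO", (3.0, 4.0, 0.0)),
            ]
        )

    def test_coincident(self):
        s = StructureCoords(
            [
                Atom("A", 1, "X", "P", (1.0, 1.0, 1.0)),
                Atom("B", 2, "Y", "Q", (1.0, 1.0, 1.0)),
            ]
        )
        assert cofactor_distance(s, "A:1:P", "B:2:Q") == 0.0

    def test_three_four_five(self):
        assert cofactor_distance(self.structure(), "B:101:FE1", "A:200:CO") == 5.0

    def test_minimum_over_sets(self):
        # FE2 at (2,0,0) is closer to CO than FE1
        d = cofactor_distance(self.structure(), "B:*:FE*", "A:*:CO")
        assert d == pytest.approx(np.sqrt(1 + 16))

    def test_empty_selection_named(self):
        with pytest.raises(ValueError, match="C:\\*:ZN"):
            cofactor_distance(self.structure(), "C:*:ZN", "A:*:CO")


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_recovers_random_transform(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        R0 = random_rotation(rng)
        t0 = rng.normal(size=3) * 10
        moved = pts @ R0.T + t0
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-8
        assert np.allclose(R, R0, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_noise_rmsd_band(self):
        # Monte-Carlo: with per-point Gaussian noise sigma, the rmsd stays
        # within a 3-sigma band of sigma*sqrt(3) over 100 seeds
        sigma = 0.3
        rmsds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(20, 3)) * 6
            R0 = random_rotation(rng)
            moved = pts @ R0.T + rng.normal(size=3) + rng.normal(
                scale=sigma, size=(20, 3)
            )
            _, _, rmsd = kabsch_superpose(pts, moved)
            rmsds.append(rmsd)
        expected = sigma * np.sqrt(3)
        assert abs(np.mean(rmsds) - expected) < 3 * sigma

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_but_solved(self, caplog):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with caplog.at_level("WARNING"):
            R, t, rmsd = kabsch_superpose(pts, pts + 1.0)
        assert "degenerate" in caplog.text
        assert rmsd < 1e-8

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_property_transform_recovery(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3)) * 4
        R0 = random_rotation(rng)
        t0 = rng.normal(size=3)
        _, _, rmsd = kabsch_superpose(pts, pts @ R0.T + t0)
        assert rmsd < 1e-8


class TestPlaceCofactor:
    def anchors(self):
        return np.array(
            [[0, 0, 0], [6.4, 0, 0], [3.2, 5.5, 0], [3.2, 1.8, 5.2]], dtype=float
        )

    def cofactor(self, anchor_pts):
        atoms = [
            Atom("X", 0, "SF4", f"S{k+1}", tuple(p)) for k, p in enumerate(anchor_pts)
        ]
        atoms.append(Atom("X", 0, "SF4", "FE1", tuple(anchor_pts.mean(axis=0))))
        return StructureCoords(atoms)

    def model(self, anchor_pts):
        return StructureCoords(
            [
                Atom("B", 10 + k, "CYS", "SG", tuple(p))
                for k, p in enumerate(anchor_pts)
            ]
        )

    def test_coincident_identity(self):
        pts = self.anchors()
        cof = self.cofactor(pts)
        model = self.model(pts)
        pairs = [(f"B:{10+k}:SG", f"X:0:S{k+1}") for k in range(4)]
        placed, rmsd = place_cofactor(model, cof, pairs)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(placed.coords(), cof.coords(), atol=1e-12)

    def test_recovers_known_transform(self, rng):
        pts = self.anchors()
        R0 = random_rotation(rng)
        t0 = rng.normal(size=3) * 8
        cof = self.cofactor(pts)
        model = self.model(pts @ R0.T + t0)
        pairs = [(f"B:{10+k}:SG", f"X:0:S{k+1}") for k in range(4)]
        placed, rmsd = place_cofactor(model, cof, pairs)
        assert rmsd < 1e-8
        assert np.allclose(placed.coords(), cof.coords() @ R0.T + t0, atol=1e-8)

    def test_fe_lands_inside_anchor_bbox(self, rng):
        pts = self.anchors()
        R0 = random_rotation(rng)
        t0 = rng.normal(size=3) * 8
        model_pts = pts @ R0.T + t0
        placed, _ = place_cofactor(
            self.model(model_pts),
            self.cofactor(pts),
            [(f"B:{10+k}:SG", f"X:0:S{k+1}") for k in range(4)],
        )
        fe = placed.select_coords("X:0:FE1")[0]
        lo, hi = model_pts.min(axis=0) - 1e-6, model_pts.max(axis=0) + 1e-6
        assert np.all(fe >= lo) and np.all(fe <= hi)

    def test_too_few_anchors(self):
        pts = self.anchors()
        with pytest.raises(ValueError, match="3 anchor"):
            place_cofactor(
                self.model(pts), self.cofactor(pts), [("B:10:SG", "X:0:S1")]
            )


class TestTemplateCoverage:
    def preds(self):
        return [
            ContactPrediction(0, 8, 1, 1, 0.9),
            ContactPrediction(1, 9, 1, 1, 0.8),
            ContactPrediction(2, 12, 1, 1, 0.7),
        ]

    def test_full_mapping_identical_template(self):
        tmpl = ContactMap(npos=15, pairs=frozenset({(0, 8), (1, 9), (2, 12)}),
                          min_sep=1)
        mapping = {i: i for i in range(15)}
        cov, gap = template_coverage(self.preds(), tmpl, mapping, k=3)
        assert cov == 1.0
        assert gap == 0.0

    def test_partial_region_coverage(self):
        # template covers only columns 0..9: the interregion prediction
        # (2, 12) cannot be covered, so gap >= 1/3
        tmpl = ContactMap(npos=10, pairs=frozenset({(0, 8), (1, 9)}), min_sep=1)
        mapping = {i: i for i in range(10)}
        cov, gap = template_coverage(self.preds(), tmpl, mapping, k=3)
        assert gap >= 1 / 3
        assert cov == pytest.approx(2 / 3)

    def test_empty_predictions(self):
        tmpl = ContactMap(npos=5, pairs=frozenset(), min_sep=1)
        with pytest.raises(ValueError, match="empty prediction"):
            template_coverage([], tmpl, {0: 0})

    def test_empty_mapping(self):
        tmpl = ContactMap(npos=5, pairs=frozenset(), min_sep=1)
        with pytest.raises(ValueError, match="mapping"):
            template_coverage(self.preds(), tmpl, {})


class TestStructureIO:
    def test_read_pdb(self, tmp_path):
        text = make_pdb_text(
            [
                ("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
                ("ATOM", 2, "CB", "ALA", "A", 2, 1.0, 2.0, 3.0),
                ("HETATM", 3, "CO", "B12", "C", 1, 9.0, 9.0, 9.0),
            ]
        )
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert len(s.atoms) == 3
        co = s.select("C:1:CO")
        assert len(co) == 1
        assert co[0].xyz == (9.0, 9.0, 9.0)

    def test_read_mmcif(self, tmp_path):
        import biotite.structure as struc
        import biotite.structure.io.pdbx as pdbx

        arr = struc.AtomArray(2)
        arr.coord = np.array([[0, 0, 0], [1.5, 0, 0]], dtype=np.float32)
        arr.chain_id = np.array(["A", "A"])
        arr.res_id = np.array([1, 2])
        arr.res_name = np.array(["ALA", "GLY"])
        arr.atom_name = np.array(["CB", "CA"])
        arr.element = np.array(["C", "C"])
        f = pdbx.CIFFile()
        pdbx.set_structure(f, arr)
        p = tmp_path / "mini.cif"
        f.write(str(p))
        s = read_structure(p)
        assert [a.name for a in s.atoms] == ["CB", "CA"]

    def test_contact_map_tsv_round_trip(self, tmp_path):
        cm = ContactMap(npos=9, pairs=frozenset({(0, 7), (1, 8)}), cutoff=7.5,
                        min_sep=3)
        p = tmp_path / "map.tsv"
        write_contact_map_tsv(cm, p)
        back = read_contact_map_tsv(p)
        assert back == cm

    def test_grid_rendering(self):
        cm = ContactMap(npos=3, pairs=frozenset({(0, 2)}), min_sep=1)
        grid = contact_map_to_grid(cm)
        assert grid.splitlines() == ["..X", "...", "X.."]
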