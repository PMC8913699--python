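"""Core assembly, pose enumeration, clash detection, linker building."""

import numpy as np
import pytest

from contrast_screen.ensemble_builder import (CandidateModel, PoseGrid,
                                              build_complex1, build_complex2,
                                              build_linker, clash_check,
                                              enumerate_candidates,
                                              linker_feasible)
from contrast_screen.structures_io import (BeadModel, ComplexFrame, Transform,
                                           apply_transform, com)

from conftest import make_beads


# ---------------------------------------------------------------------------
# assembly fixtures derived from the toy complex

@pytest.fixture(scope="module")
def assembly_parts(toy):
    """(hexamer, ternary, a2_full) carved out of the toy ground truth."""
    truth, core, _ = toy
    hexamer = core.select(component="C")
    ci = core.subset((core.domain == "CI")
                     & (core.chain == "C0")).with_labels(chain="C")
    b = core.subset((core.domain == "B")
                    & (core.chain == "B0")).with_labels(chain="B")
    ca = core.subset(np.isin(core.domain, ["C1A", "C2A"])
                     & (core.chain == "A0")).with_labels(chain="A")
    ternary = BeadModel.concat([ci, b, ca])
    n1 = apply_transform(truth.n1a_template,
                         truth.pose_n1a).with_labels(chain="A")
    n2 = apply_transform(truth.n2a_template,
                         truth.pose_n2a).with_labels(chain="A")
    a2_full = BeadModel.concat([ca.with_labels(chain="A"), n1, n2])
    return hexamer, ternary, a2_full


class TestBuildComplex1:
    def test_component_counts(self, assembly_parts):
        hexamer, ternary, _ = assembly_parts
        c1 = build_complex1(hexamer, ternary)
        assert int((c1.domain == "B").sum()) == 6 * 15
        assert int(np.isin(c1.domain, ["C1A", "C2A"]).sum()) == 6 * 24
        assert not np.isin(c1.domain, ["N1A", "N2A"]).any()

    def test_deterministic(self, assembly_parts):
        hexamer, ternary, _ = assembly_parts
        a = build_complex1(hexamer, ternary)
        b = build_complex1(hexamer, ternary)
        assert np.array_equal(a.xyz, b.xyz)

    def test_reproduces_reference_core_geometry(self, assembly_parts, toy):
        """Re-assembly from parts lands on the original core positions."""
        _, core, _ = toy
        hexamer, ternary, _ = assembly_parts
        c1 = build_complex1(hexamer, ternary)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(core.xyz).query(c1.xyz)
        assert d.max() < 1e-9

    def test_missing_anchor_raises(self, assembly_parts):
        hexamer, ternary, _ = assembly_parts
        with pytest.raises(ValueError):
            build_complex1(hexamer, ternary.select(domain="B"))


class TestBuildComplex2:
    def test_adds_exactly_twelve_n_domains(self, assembly_parts):
        hexamer, ternary, a2 = assembly_parts
        c1 = build_complex1(hexamer, ternary)
        c2 = build_complex2(c1, a2)
        n_beads_per_domain = int((a2.domain == "N1A").sum())
        assert int(np.isin(c2.domain, ["N1A", "N2A"]).sum()) == \
            12 * n_beads_per_domain

    def test_collar_unchanged(self, assembly_parts):
        hexamer, ternary, a2 = assembly_parts
        c1 = build_complex1(hexamer, ternary)
        c2 = build_complex2(c1, a2)
        m1 = np.isin(c1.domain, ["C1A", "C2A"])
        assert np.allclose(c2.xyz[:c1.n_beads][m1], c1.xyz[m1], atol=1e-9)

    def test_crystal_arrangement_overlap_is_reported(self, assembly_parts,
                                                     toy):
        """A dimer whose N2A sits on the B ring produces clashes, which
        build_complex2 deliberately does not resolve."""
        truth, core, _ = toy
        hexamer, ternary, _ = assembly_parts
        c1 = build_complex1(hexamer, ternary)
        ca = core.subset(np.isin(core.domain, ["C1A", "C2A"])
                         & (core.chain == "A0")).with_labels(chain="A")
        b_com = com(core.select(domain="B", chain="B0"))
        n2_bad = truth.n2a_template.copy()
        n2_bad.xyz = n2_bad.xyz + b_com  # centre N2A on a B domain
        n2_bad = n2_bad.with_labels(chain="A")
        n1 = apply_transform(truth.n1a_template,
                             truth.pose_n1a).with_labels(chain="A")
        a2_bad = BeadModel.concat([ca, n1, n2_bad])
        c2 = build_complex2(c1, a2_bad)
        bodies = np.where(np.isin(c2.domain, ["N1A", "N2A"]),
                          c2.chain.astype(str), "core")
        clashing, n = clash_check(c2.xyz, 3.5, bodies=bodies)
        assert clashing and n > 0


# ---------------------------------------------------------------------------
# clash detection

class TestClashCheck:
    def test_cutoff_boundary(self):
        for eps, expected in ((+0.01, (False, 0)), (-0.01, (True, 1))):
            m = make_beads([[0, 0, 0], [3.5 + eps, 0, 0]])
            m.chain = np.array(["A", "B"], object)
            assert clash_check(m, 3.5) == expected

    def test_intra_body_ignored(self):
        m = make_beads([[0, 0, 0], [1.0, 0, 0]])  # same chain
        assert clash_check(m, 3.5) == (False, 0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        xyz = rng.uniform(0, 60, size=(1000, 3))
        bodies = rng.integers(0, 4, 1000)
        _, fast = clash_check(xyz, 3.5, bodies=bodies)
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        inter = bodies[:, None] != bodies[None, :]
        brute = int((np.triu(d < 3.5, k=1) & np.triu(inter)).sum())
        assert fast == brute

    def test_invalid_cutoff_raises(self):
        with pytest.raises(ValueError):
            clash_check(make_beads([[0, 0, 0]]), 0.0)


# ---------------------------------------------------------------------------
# enumeration

class TestEnumerate:
    def small_grid(self):
        return PoseGrid(r_values=(60.0, 70.0), theta_values=(0.0, 30.0),
                        z_values=(30.0,), n_orientations=2)

    def test_far_pose_survives(self, small_toy):
        truth, core, templates = small_toy
        grid1 = PoseGrid(r_values=(150.0,), theta_values=(0.0,),
                         z_values=(80.0,), n_orientations=1)
        grid2 = PoseGrid(r_values=(150.0,), theta_values=(180.0,),
                         z_values=(-80.0,), n_orientations=1)
        cands = list(enumerate_candidates(core, templates["N1A"],
                                          templates["N2A"], grid1,
                                          frame=truth.frame,
                                          grid_n2a=grid2))
        assert len(cands) == 1

    def test_pose_at_core_domain_rejected(self, small_toy):
        truth, core, templates = small_toy
        b_com = com(core.select(domain="B", chain="B0"))
        from contrast_screen.structures_io import cylindrical
        r, th, z = cylindrical(b_com, truth.frame)
        grid = PoseGrid(r_values=(r,), theta_values=(th,), z_values=(z,),
                        n_orientations=1)
        assert list(enumerate_candidates(core, templates["N1A"],
                                         templates["N2A"], grid,
                                         frame=truth.frame)) == []

    def test_count_matches_brute_force(self, small_toy):
        """Yield count equals an independent re-enumeration with explicit
        clash tests on expanded models."""
        truth, core, templates = small_toy
        grid = self.small_grid()
        fast = list(enumerate_candidates(core, templates["N1A"],
                                         templates["N2A"], grid,
                                         frame=truth.frame))
        # brute force: expand every pose pair and test all bead pairs
        poses = grid.poses(truth.frame)
        n_ok = 0
        from contrast_screen.ensemble_builder import _centered
        t1 = _centered(templates["N1A"], "N1A")
        t2 = _centered(templates["N2A"], "N2A")
        for p1 in poses:
            for p2 in poses:
                cand = CandidateModel(core, t1, t2, p1, p2, truth.frame)
                xyz, bodies = cand.bodies()
                d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
                inter = bodies[:, None] != bodies[None, :]
                if not (np.triu(d < 3.5, 1) & np.triu(inter)).any():
                    n_ok += 1
        assert len(fast) == n_ok

    def test_count_monotone_in_cutoff(self, small_toy):
        truth, core, templates = small_toy
        grid = self.small_grid()
        counts = [len(list(enumerate_candidates(core, templates["N1A"],
                                                templates["N2A"], grid,
                                                frame=truth.frame,
                                                cutoff=c)))
                  for c in (2.0, 3.5, 6.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_expanded_candidate_is_c6_symmetric(self, small_toy):
        truth, _, _ = small_toy
        full = truth.expand()
        rot = apply_transform(full, Transform.about_axis(
            truth.frame.z_axis, 60.0, truth.frame.origin))
        from scipy.spatial import cKDTree
        d, _ = cKDTree(full.xyz).query(rot.xyz)
        assert d.max() < 1e-9


# ---------------------------------------------------------------------------
# linkers

class TestLinker:
    def test_feasibility_boundary(self):
        assert linker_feasible([0, 0, 0], [5, 0, 0], 20, 3.8)
        assert not linker_feasible([0, 0, 0], [80, 0, 0], 20, 3.8)
        assert linker_feasible([0, 0, 0], [76.0, 0, 0], 20, 3.8)  # inclusive

    def test_single_residue_geometry(self):
        empty = make_beads(np.array([[500.0, 500, 500]]))  # far away
        a, b = np.array([0.0, 0, 0]), np.array([3.8, 0, 0])
        lk = build_linker(empty, a, b, n_res=1, seed=1, k_conformers=5)
        assert np.linalg.norm(lk.xyz[0] - a) == pytest.approx(3.8, abs=1e-9)
        assert 3.0 <= np.linalg.norm(lk.xyz[0] - b) <= 4.5

    def test_steps_within_bond_bounds(self, toy):
        truth, _, _ = toy
        model = truth.expand()
        a = truth.domain_com("N1A")
        b = model.xyz[(model.domain == "C1A") & (model.chain == "A0")][0]
        lk = build_linker(model, a, b, n_res=20, seed=3, k_conformers=10)
        pts = np.vstack([a, lk.xyz])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all((steps >= 3.0) & (steps <= 4.5))
        assert 3.0 <= np.linalg.norm(lk.xyz[-1] - b) <= 4.5

    def test_same_seed_identical(self, toy):
        truth, _, _ = toy
        model = truth.expand()
        a = truth.domain_com("N1A")
        b = model.xyz[(model.domain == "C1A") & (model.chain == "A0")][0]
        lk1 = build_linker(model, a, b, seed=5, k_conformers=8)
        lk2 = build_linker(model, a, b, seed=5, k_conformers=8)
        assert np.array_equal(lk1.xyz, lk2.xyz)

    def test_infeasible_anchors_raise(self):
        empty = make_beads(np.array([[500.0, 500, 500]]))
        with pytest.raises(ValueError):
            build_linker(empty, [0, 0, 0], [100.0, 0, 0], n_res=20, seed=0)
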