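"""Rigid-body candidate generation for the C6-symmetric complex.

Builds the core assemblies by domain superposition (Complex 1: ternary
subcomplexes placed on the hexamer; Complex 2: full-length dimers added in
their crystal arrangement), enumerates poses of the two mobile N-domains of
one asymmetric unit on a configurable grid, replicates them under C6
symmetry, rejects steric clashes, and tests/builds the 20-residue linkers
that tether the mobile domains to the core.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures_io import (BeadModel, ComplexFrame, Transform,
                            apply_transform, com, from_cylindrical,
                            pair_by_domain_resid, superpose, symmetry_mates)

__all__ = [
    "PoseGrid", "CandidateModel", "build_complex1", "build_complex2",
    "enumerate_candidates", "clash_check", "linker_feasible", "build_linker",
    "CLASH_CUTOFF", "PER_RES_MAX",
]

#: default inter-body clash cutoff between residue-COM beads, Å
CLASH_CUTOFF = 3.5
#: maximum Cα–Cα virtual bond per linker residue, Å
PER_RES_MAX = 3.8
#: linker bead step length, Å
LINKER_STEP = 3.8


# ---------------------------------------------------------------------------
# core assembly by superposition

def build_complex1(hexamer: BeadModel, ternary: BeadModel,
                   anchor_domain: str = "CI") -> BeadModel:
    """Place six copies of the ternary subcomplex onto the hexamer.

    Each copy is superposed via its ``anchor_domain`` beads onto one of the
    six corresponding domains of the hexamer (paired by residue index);
    duplicated anchor beads are resolved in favour of the hexamer copy.
    The result carries no N-domains.
    """
    chains = list(dict.fromkeys(
        hexamer.chain[hexamer.domain == anchor_domain]))
    if len(chains) == 0:
        raise ValueError(f"hexamer has no {anchor_domain!r} domains")
    tern_anchor_mask = ternary.domain == anchor_domain
    if not tern_anchor_mask.any():
        raise ValueError(f"ternary model has no {anchor_domain!r} domain")
    placed = [hexamer]
    tern_mobile = ternary.subset(~ternary.mask(domain=anchor_domain))
    drop_n = ~np.isin(tern_mobile.domain, ["N1A", "N2A"])
    tern_mobile = tern_mobile.subset(drop_n)
    for k, ch in enumerate(chains):
        target = hexamer.select(domain=anchor_domain, chain=ch)
        source = ternary.subset(tern_anchor_mask)
        pairing = _pair_by_resid(source, target)
        if len(pairing[0]) < 3:
            raise ValueError(f"cannot map {anchor_domain!r} onto chain {ch}")
        t, _ = superpose(source.xyz, target.xyz, pairing)
        copy = apply_transform(tern_mobile, t)
        copy.chain = np.array([f"{c}{k}" for c in copy.chain], object)
        placed.append(copy)
    return BeadModel.concat(placed)


def build_complex2(complex1: BeadModel, a2_full: BeadModel) -> BeadModel:
    """Add full-length dimers to Complex 1 in their crystal arrangement.

    Each dimer is superposed through its C1A/C2A domains onto the collar
    domains already present; the N-domains come along untouched, so steric
    overlap with the B ring is *not* resolved here — detecting that overlap
    is the point of the downstream pose search.
    """
    ca_mask = np.isin(a2_full.domain, ["C1A", "C2A"])
    if not ca_mask.any():
        raise ValueError("dimer model lacks C1A/C2A domains")
    chains = list(dict.fromkeys(
        complex1.chain[np.isin(complex1.domain, ["C1A", "C2A"])]))
    groups: dict[str, list[str]] = {}
    for ch in chains:
        groups.setdefault(str(ch), []).append(ch)
    placed = [complex1]
    n_src = a2_full.subset(np.isin(a2_full.domain, ["N1A", "N2A"]))
    src = a2_full.subset(ca_mask)
    for k, ch in enumerate(groups):
        target = complex1.subset(
            np.isin(complex1.domain, ["C1A", "C2A"]) & (complex1.chain == ch))
        pairing = pair_by_domain_resid(src, target)
        if len(pairing[0]) < 3:
            raise ValueError(f"cannot map C1A/C2A onto chain {ch}")
        t, _ = superpose(src.xyz, target.xyz, pairing)
        copy = apply_transform(n_src, t)
        copy.chain = np.array([f"{c}{k}" for c in copy.chain], object)
        placed.append(copy)
    return BeadModel.concat(placed)


def _pair_by_resid(a: BeadModel, b: BeadModel):
    key = {r: i for i, r in enumerate(a.resid)}
    ia, ib = [], []
    for j, r in enumerate(b.resid):
        if r in key:
            ia.append(key[r])
            ib.append(j)
    return np.array(ia, int), np.array(ib, int)


# ---------------------------------------------------------------------------
# pose grid and candidates

@dataclass(frozen=True)
class PoseGrid:
    """Cylindrical translation grid x quasi-uniform orientations.

    Translations place the domain COM at (r, theta, z) around the core
    (frame coordinates, theta in degrees); ``n_orientations`` rotations per
    placement are drawn quasi-uniformly (seeded, deterministic).
    """

    r_values: tuple = (45.0, 55.0, 65.0)
    theta_values: tuple = (0.0, 20.0, 40.0)
    z_values: tuple = (-40.0, -15.0, 10.0, 35.0)
    n_orientations: int = 4
    orientation_seed: int = 20

    def __post_init__(self):
        if not (self.r_values and self.theta_values and self.z_values):
            raise ValueError("empty grid axis")
        if self.n_orientations < 1:
            raise ValueError("need at least 1 orientation")

    @property
    def size(self) -> int:
        return (len(self.r_values) * len(self.theta_values)
                * len(self.z_values) * self.n_orientations)

    def orientations(self) -> np.ndarray:
        rots = [np.eye(3)]
        if self.n_orientations > 1:
            rng = np.random.default_rng(self.orientation_seed)
            rots.extend(Rotation.random(self.n_orientations - 1,
                                        random_state=rng).as_matrix())
        return np.array(rots)

    def poses(self, frame: ComplexFrame) -> list[Transform]:
        out = []
        rots = self.orientations()
        for r, th, z in itertools.product(self.r_values, self.theta_values,
                                          self.z_values):
            pos = from_cylindrical(r, th, z, frame)
            for R in rots:
                # template is COM-centred, so x -> Rx + pos lands its COM at pos
                out.append(Transform(R, pos))
        return out


@dataclass
class CandidateModel:
    """One rigid-body candidate: core + C6-replicated mobile-domain poses."""

    core: BeadModel
    n1a_template: BeadModel      # centred at its own COM origin
    n2a_template: BeadModel
    pose_n1a: Transform
    pose_n2a: Transform
    frame: ComplexFrame
    symmetry: int = 6
    scores: dict = field(default_factory=dict)
    linker_status: str = "absent"   # absent | feasible | built
    linker: BeadModel | None = None
    meta: dict = field(default_factory=dict)
    _expanded: BeadModel | None = field(default=None, repr=False)

    def placed_domains(self) -> list[BeadModel]:
        """The 12 mobile-domain copies (2 per dimer x C6)."""
        out = []
        for name, tmpl, pose in (("N1A", self.n1a_template, self.pose_n1a),
                                 ("N2A", self.n2a_template, self.pose_n2a)):
            first = apply_transform(tmpl, pose)
            for k, mate in enumerate(symmetry_mates(first, self.symmetry,
                                                    self.frame)):
                mate.chain = np.array([f"{name}.{k}"] * mate.n_beads, object)
                out.append(mate)
        return out

    def expand(self) -> BeadModel:
        """Full bead model (core + mobile domains + any built linker)."""
        if self._expanded is None:
            parts = [self.core] + self.placed_domains()
            if self.linker is not None:
                parts.append(self.linker)
            self._expanded = BeadModel.concat(parts)
        return self._expanded

    def invalidate(self) -> None:
        self._expanded = None

    def domain_com(self, domain: str, copy: int = 0) -> np.ndarray:
        tmpl, pose = ((self.n1a_template, self.pose_n1a) if domain == "N1A"
                      else (self.n2a_template, self.pose_n2a))
        first = apply_transform(tmpl, pose)
        mate = symmetry_mates(first, self.symmetry, self.frame)[copy]
        return com(mate)

    def bodies(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions, body labels) of core + placed domains for clash tests."""
        parts = [self.core] + self.placed_domains()
        xyz = np.concatenate([p.xyz for p in parts])
        labels = np.concatenate(
            [np.full(p.n_beads, i) for i, p in enumerate(parts)])
        return xyz, labels


# ---------------------------------------------------------------------------
# clash detection

def clash_check(model, cutoff: float = CLASH_CUTOFF,
                bodies: np.ndarray | None = None) -> tuple[bool, int]:
    """Count inter-body bead pairs closer than ``cutoff``.

    ``model`` is a BeadModel (bodies then default to its chain labels) or a
    coordinate array with explicit ``bodies`` labels.  Intra-body pairs are
    ignored.  Returns (clashing?, number of violating pairs); a KD-tree
    keeps the cost near-linear in the number of beads.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(model, BeadModel):
        xyz = model.xyz
        if bodies is None:
            bodies = model.chain
    else:
        xyz = np.asarray(model, float)
        if bodies is None:
            raise ValueError("body labels required for raw coordinates")
    bodies = np.asarray(bodies)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return False, 0
    inter = bodies[pairs[:, 0]] != bodies[pairs[:, 1]]
    n = int(inter.sum())
    return n > 0, n


# ---------------------------------------------------------------------------
# enumeration

def enumerate_candidates(core: BeadModel, n1a_domain: BeadModel,
                         n2a_domain: BeadModel, grid: PoseGrid,
                         frame: ComplexFrame | None = None,
                         cutoff: float = CLASH_CUTOFF,
                         grid_n2a: PoseGrid | None = None) -> Iterator[CandidateModel]:
    """Yield clash-free candidates over the full (pose_N1A x pose_N2A) grid.

    Both mobile domains get the identical asymmetric-unit treatment: the
    chosen pair of poses is replicated to all six dimers by C6 symmetry
    before the clash test, so the yield order is deterministic and the
    count is monotone non-increasing in the clash cutoff.  ``grid_n2a``
    gives the second domain its own bounds (default: share ``grid``).
    """
    if frame is None:
        frame = ComplexFrame.from_core(core)
    t1 = _centered(n1a_domain, "N1A")
    t2 = _centered(n2a_domain, "N2A")
    poses = grid.poses(frame)
    poses2 = poses if grid_n2a is None else grid_n2a.poses(frame)
    for p1 in poses:
        for p2 in poses2:
            cand = CandidateModel(core, t1, t2, p1, p2, frame)
            xyz, labels = cand.bodies()
            clashing, _ = clash_check(xyz, cutoff, bodies=labels)
            if not clashing:
                yield cand


def _centered(domain: BeadModel, name: str) -> BeadModel:
    out = domain.copy()
    out.xyz = out.xyz - com(out)
    out.domain[:] = name
    out.component[:] = "A"
    return out


# ---------------------------------------------------------------------------
# linkers

def linker_feasible(anchor_a: np.ndarray, anchor_b: np.ndarray,
                    n_res: int = 20, per_res_max: float = PER_RES_MAX) -> bool:
    """True iff the anchors are within the fully stretched linker length.

    The bound is inclusive: a gap of exactly n_res * per_res_max passes.
    """
    d = float(np.linalg.norm(np.asarray(anchor_a, float)
                             - np.asarray(anchor_b, float)))
    return d <= n_res * per_res_max + 1e-12


def build_linker(model: BeadModel, anchor_a, anchor_b, n_res: int = 20,
                 seed: int = 0, k_conformers: int = 100,
                 exp_profile=None, cutoff: float = CLASH_CUTOFF,
                 max_attempts: int = 2000, chain: str = "L",
                 component: str = "linker") -> BeadModel:
    """Bead linker between two anchors by a guided self-avoiding random walk.

    Generates up to ``k_conformers`` clash-free conformers (step length
    3.8 Å, final closure within [3.0, 4.5] Å of the far anchor, beads kept
    ``cutoff`` away from the model) and returns the conformer whose
    SAXS chi^2 against ``exp_profile`` is smallest — or the first one if no
    profile is supplied.  Fully reproducible for a given seed.
    """
    a = np.asarray(anchor_a, float)
    b = np.asarray(anchor_b, float)
    if not linker_feasible(a, b, n_res):
        raise ValueError("anchors farther apart than the stretched linker")
    rng = np.random.default_rng(seed)
    tree = cKDTree(model.xyz)
    conformers = []
    attempts = 0
    while len(conformers) < k_conformers and attempts < max_attempts:
        attempts += 1
        path = _walk(rng, a, b, n_res, tree, cutoff)
        if path is not None:
            conformers.append(path)
    if not conformers:
        raise RuntimeError("no clash-free linker conformer found "
                           f"in {max_attempts} attempts")
    best = conformers[0]
    if exp_profile is not None and len(conformers) > 1:
        from .scattering import chi2_score, debye_profile
        best_chi2 = np.inf
        for path in conformers:
            trial = BeadModel.concat([model, _linker_beads(path, chain,
                                                           component)])
            calc = debye_profile(trial, exp_profile.q, channel="xray")
            c2 = chi2_score(calc, exp_profile).chi2
            if c2 < best_chi2:
                best_chi2, best = c2, path
    return _linker_beads(best, chain, component)


def _walk(rng, a, b, n_res, tree, cutoff):
    """One guided SAW attempt; returns (n_res, 3) positions or None.

    Each bead sits exactly one virtual bond (3.8 Å) from its predecessor;
    the distance-to-target after each step is cone-sampled inside the band
    still reachable by the remaining beads, which guarantees closure
    geometry (final bead within [3.0, 4.5] Å of the far anchor) whenever
    the anchors are feasible at all.
    """
    pos = a.copy()
    path: list[np.ndarray] = []
    for i in range(n_res):
        left = n_res - 1 - i  # beads still to place after this one
        placed = False
        for _ in range(40):
            to_b = b - pos
            dist_b = float(np.linalg.norm(to_b))
            if dist_b < 1e-9:
                return None
            t_hi = min(dist_b + LINKER_STEP, left * LINKER_STEP + 4.2)
            t_lo = max(abs(dist_b - LINKER_STEP),
                       3.3 if left == 0 else 0.0,
                       t_hi - 2.0 * LINKER_STEP)
            if t_lo > t_hi:
                return None  # cannot reach the far anchor any more
            target_d = rng.uniform(t_lo, t_hi)
            cos_a = np.clip((dist_b ** 2 + LINKER_STEP ** 2 - target_d ** 2)
                            / (2.0 * dist_b * LINKER_STEP), -1.0, 1.0)
            e_b = to_b / dist_b
            perp = np.cross(e_b, rng.standard_normal(3))
            norm = np.linalg.norm(perp)
            if norm < 1e-9:
                continue
            perp /= norm
            sin_a = float(np.sqrt(1.0 - cos_a ** 2))
            direction = cos_a * e_b + sin_a * perp
            nxt = pos + LINKER_STEP * direction
            if len(tree.query_ball_point(nxt, cutoff)) > 0:
                continue
            if path and np.min(np.linalg.norm(np.array(path) - nxt,
                                              axis=1)) < 3.0:
                continue
            placed = True
            break
        if not placed:
            return None
        path.append(nxt)
        pos = nxt
    if not (3.0 - 1e-9 <= np.linalg.norm(b - path[-1]) <= 4.5 + 1e-9):
        return None
    return np.array(path)


def _linker_beads(path: np.ndarray, chain: str, component: str) -> BeadModel:
    n = len(path)
    return BeadModel(path, np.full(n, "GLY", object), np.arange(1, n + 1),
                     np.full(n, chain, object), np.full(n, 57.05),
                     np.full(n, component, object),
                     np.full(n, "linker", object), np.zeros(n))
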