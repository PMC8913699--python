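"""Synthetic ground-truth complexes and simulated experiments.

The toy assembly mirrors the architecture the pipeline is built for: a
rigid core of two stacked hexameric rings (the double-doughnut hexamer),
a hexameric ring of small domains on top of it (the B ring, whose top
surface defines the reference plane), a twelve-domain collar (C1A/C2A),
and twelve mobile N-domains — two per dimer, tethered by a 20-residue
linker — whose poses are the ground truth the screening stage must
recover.  Pseudo-domains are deterministic spherical bead clusters with a
residue mix drawn (seeded) from typical amino-acid abundances, so X-ray
and neutron contrasts behave like protein.

Every generator is reproducible: identical spec + seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble_builder import CandidateModel, clash_check
from .scattering import ContrastSpec, ScatteringProfile, debye_profile
from .structures_io import (BeadModel, ComplexFrame, Transform,
                            apply_transform, com, from_cylindrical,
                            symmetry_mates)
from .tables import AA_FREQUENCIES, RESIDUES

__all__ = ["ToySpec", "NoiseSpec", "make_toy_complex", "simulate_experiment",
           "make_decoys", "make_jiggle_trajectory", "sphere_cluster",
           "DEFAULT_CONTRAST"]

#: the iCM condition of the study: hydrogenated A, 75%-deuterated B and C
#: in pure D2O buffer
DEFAULT_CONTRAST = ContrastSpec(d2o_fraction=1.0,
                                deuteration={"A": 0.0, "B": 0.75, "C": 0.75,
                                             "linker": 0.0})


# ---------------------------------------------------------------------------
# geometry helpers

def sphere_cluster(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform bead fill of a ball (Fibonacci shells)."""
    if n == 1:
        return np.zeros((1, 3))
    # allocate beads to shells so density is roughly uniform
    idx = np.arange(n)
    r = radius * ((idx + 0.5) / n) ** (1.0 / 3.0)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (idx + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    th = golden * idx
    return np.stack([r * rho * np.cos(th), r * rho * np.sin(th), r * z],
                    axis=1)


def _domain(n: int, radius: float, center, resnames, chain: str,
            component: str, domain: str, resid0: int = 1) -> BeadModel:
    xyz = sphere_cluster(n, radius) + np.asarray(center, float)
    masses = np.array([RESIDUES[r].mass for r in resnames])
    return BeadModel(xyz, np.array(resnames, object),
                     np.arange(resid0, resid0 + n),
                     np.full(n, chain, object), masses,
                     np.full(n, component, object),
                     np.full(n, domain, object), np.zeros(n))


def _residue_mix(rng: np.random.Generator, n: int) -> np.ndarray:
    names = list(AA_FREQUENCIES)
    p = np.array([AA_FREQUENCIES[k] for k in names])
    return rng.choice(names, size=n, p=p / p.sum())


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class ToySpec:
    """Geometry of the synthetic C6 assembly (all lengths Å).

    Defaults give a clash-free complex roughly 180 Å across whose rigid
    core carries ~600 residue beads and whose 12 mobile domains add 240.
    """

    ring_radius: float = 40.0          # hexamer ring radius
    core_domain_radius: float = 13.0
    core_beads: int = 30               # beads per core domain
    ring_z: tuple = (-70.0, -44.0)     # CII and CI ring heights
    b_ring_radius: float = 34.0
    b_domain_radius: float = 9.0
    b_beads: int = 15
    b_z: float = -20.0
    collar_radius: float = 28.0
    ca_domain_radius: float = 8.5
    ca_beads: int = 12
    ca_z: float = 0.0
    ca_theta: tuple = (10.0, 30.0)     # C1A, C2A azimuths within a sector
    n_domain_radius: float = 11.0
    n_beads: int = 20
    # ground-truth mobile poses (r, theta deg, z *relative to the reference
    # plane z0*): one domain above the plane (U ring), one below (L ring)
    truth_n1a: tuple = (50.0, 15.0, 12.0)
    truth_n2a: tuple = (58.0, 45.0, -18.0)
    linker_length: int = 20
    deuteration: dict = field(default_factory=lambda: {"B": 0.75, "C": 0.75})
    seed: int = 7

    def __post_init__(self):
        lengths = (self.ring_radius, self.core_domain_radius,
                   self.b_ring_radius, self.b_domain_radius,
                   self.collar_radius, self.ca_domain_radius,
                   self.n_domain_radius)
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Relative Gaussian noise growing linearly in Q.

    sigma(Q) = I(Q) * (rel_low + (rel_high - rel_low) * (Q - Qmin)/(Qmax - Qmin)),
    the shape of typical SEC-SAXS counting statistics (good at low Q,
    a few times worse near the high-Q end).
    """

    rel_low: float = 0.02
    rel_high: float = 0.10
    n_points: int = 60
    q_range: tuple = (0.006, 0.12)
    seed: int = 0

    def __post_init__(self):
        if self.rel_low <= 0 or self.rel_high <= 0:
            raise ValueError("noise levels must be positive")

    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_range[0], self.q_range[1], self.n_points)

    def rel_sigma(self, q: np.ndarray) -> np.ndarray:
        lo, hi = self.q_range
        f = (np.asarray(q, float) - lo) / (hi - lo)
        return self.rel_low + (self.rel_high - self.rel_low) * np.clip(f, 0, 1)


# ---------------------------------------------------------------------------
# generators

def make_toy_complex(spec: ToySpec = ToySpec()):
    """Ground-truth candidate, rigid core and mobile-domain templates.

    Returns ``(truth, core, templates)`` where ``templates`` maps
    ``{"N1A": BeadModel, "N2A": BeadModel}`` (COM-centred).  The truth
    candidate is C6-symmetric by construction and clash-free at the default
    cutoff; a geometrically impossible spec raises.
    """
    rng = np.random.default_rng(spec.seed)
    # one asymmetric unit, replicated by exact 60-degree rotations so the
    # core is C6-symmetric to machine precision (identical protomers share
    # one residue sequence, as in a real homohexamer)
    unit_parts = []
    for z, dom in zip(spec.ring_z, ("CII", "CI")):
        unit_parts.append(_domain(spec.core_beads, spec.core_domain_radius,
                                  _cyl(spec.ring_radius, 0.0, z),
                                  _residue_mix(rng, spec.core_beads),
                                  "C", "C", dom))
    unit_parts.append(_domain(spec.b_beads, spec.b_domain_radius,
                              _cyl(spec.b_ring_radius, 0.0, spec.b_z),
                              _residue_mix(rng, spec.b_beads), "B", "B", "B"))
    for th_off, dom in zip(spec.ca_theta, ("C1A", "C2A")):
        unit_parts.append(_domain(spec.ca_beads, spec.ca_domain_radius,
                                  _cyl(spec.collar_radius, th_off, spec.ca_z),
                                  _residue_mix(rng, spec.ca_beads),
                                  "A", "A", dom))
    unit = BeadModel.concat(unit_parts)
    copies = []
    for k in range(6):
        t = Transform.about_axis((0.0, 0.0, 1.0), 60.0 * k)
        c = apply_transform(unit, t)
        c.chain = np.array([f"{ch}{k}" for ch in c.chain], object)
        copies.append(c)
    core = BeadModel.concat(copies)
    for comp, frac in spec.deuteration.items():
        core.deuteration[core.component == comp] = frac
    frame = ComplexFrame.from_core(core)

    templates = {}
    for dom in ("N1A", "N2A"):
        t = _domain(spec.n_beads, spec.n_domain_radius, (0.0, 0.0, 0.0),
                    _residue_mix(rng, spec.n_beads), dom, "A", dom)
        templates[dom] = t
    pose1 = _pose_at(spec.truth_n1a, frame, rng)  # z measured from z0
    pose2 = _pose_at(spec.truth_n2a, frame, rng)
    truth = CandidateModel(core, templates["N1A"], templates["N2A"],
                           pose1, pose2, frame, meta={"is_truth": True})
    xyz, labels = truth.bodies()
    clashing, n_bad = clash_check(xyz, bodies=labels)
    if clashing:
        raise ValueError(f"toy spec is geometrically impossible: "
                         f"{n_bad} clashing bead pairs")
    return truth, core, templates


def _cyl(r, theta_deg, z):
    th = np.deg2rad(theta_deg)
    return np.array([r * np.cos(th), r * np.sin(th), z])


def _pose_at(cyl_pos, frame: ComplexFrame, rng) -> Transform:
    r, theta, z_rel = cyl_pos
    pos = from_cylindrical(r, theta, frame.z0 + z_rel, frame)
    R = Rotation.random(random_state=rng).as_matrix()
    return Transform(R, pos)


def simulate_experiment(model, channel: str = "xray",
                        contrast: ContrastSpec | None = None,
                        noise: NoiseSpec = NoiseSpec()) -> ScatteringProfile:
    """Noisy simulated profile of a model (or candidate).

    I_obs(Q) = I_true(Q) * (1 + eps), eps ~ N(0, rel sigma(Q)); the reported
    sigma is the true generating width.  ``noise.rel_low == 0`` is not
    allowed, but a separate noiseless curve is just ``debye_profile``.
    """
    beads = model.expand() if isinstance(model, CandidateModel) else model
    q = noise.q_grid()
    true = debye_profile(beads, q, channel="neutron" if channel != "xray"
                         else "xray", spec=contrast)
    rel = noise.rel_sigma(q)
    rng = np.random.default_rng(noise.seed)
    sigma = rel * np.abs(true.i)
    obs = true.i * (1.0 + rel * rng.standard_normal(len(q)))
    return ScatteringProfile(q, obs, sigma, label=f"simulated {channel}")


def make_decoys(truth: CandidateModel, k: int, seed: int = 0,
                dr: float = 20.0, dtheta: float = 50.0, dz: float = 30.0,
                min_shift: float = 8.0, cutoff: float = 3.5,
                max_attempts_per_decoy: int = 200) -> list[CandidateModel]:
    """Truth + k clash-free decoy candidates with perturbed mobile poses.

    Each decoy displaces both N-domain COMs by at least ``min_shift`` Å
    (uniform cylindrical perturbations up to ``dr``/``dtheta``/``dz``) and
    randomizes orientations.  The true pose appears exactly once, at a
    seeded random position in the list; decoys carry ``meta['is_truth'] =
    False``.  Deterministic per seed.
    """
    if k < 1:
        raise ValueError("need k >= 1 decoys")
    rng = np.random.default_rng(seed)
    frame = truth.frame
    base = {}
    for dom, pose in (("N1A", truth.pose_n1a), ("N2A", truth.pose_n2a)):
        from .structures_io import cylindrical
        base[dom] = cylindrical(pose.translation, frame)
    decoys: list[CandidateModel] = []
    attempts = 0
    while len(decoys) < k:
        attempts += 1
        if attempts > k * max_attempts_per_decoy:
            raise RuntimeError("could not place the requested number of "
                               "clash-free decoys")
        poses = {}
        ok = True
        for dom in ("N1A", "N2A"):
            r0, th0, z0 = base[dom]
            r = max(r0 + rng.uniform(-dr, dr), 15.0)
            th = th0 + rng.uniform(-dtheta, dtheta)
            z = z0 + rng.uniform(-dz, dz)
            pos = from_cylindrical(r, th % 360.0, z, frame)
            ref = (truth.pose_n1a if dom == "N1A" else truth.pose_n2a)
            if np.linalg.norm(pos - ref.translation) < min_shift:
                ok = False
                break
            poses[dom] = Transform(
                Rotation.random(random_state=rng).as_matrix(), pos)
        if not ok:
            continue
        cand = replace_poses(truth, poses["N1A"], poses["N2A"])
        xyz, labels = cand.bodies()
        clashing, _ = clash_check(xyz, cutoff, bodies=labels)
        if clashing:
            continue
        cand.meta = {"is_truth": False}
        decoys.append(cand)
    out = list(decoys)
    pos = int(rng.integers(0, k + 1))
    out.insert(pos, truth)
    return out


def replace_poses(cand: CandidateModel, pose_n1a: Transform,
                  pose_n2a: Transform) -> CandidateModel:
    return CandidateModel(cand.core, cand.n1a_template, cand.n2a_template,
                          pose_n1a, pose_n2a, cand.frame, cand.symmetry)


def make_jiggle_trajectory(model, amplitudes: dict, n_frames: int = 200,
                           seed: int = 0, phi: float = 0.9,
                           rot_sigma_deg: float = 2.0, dt_ps: float = 20.0):
    """Trajectory with mobile domains jiggling about their mean poses.

    ``amplitudes`` maps domain labels to the target 3-D RMS amplitude (Å)
    of the domain-COM fluctuation; the core (all unlisted domains) is held
    fixed.  COM offsets follow a stationary AR(1) process per axis (decay
    ``phi``) started from its stationary distribution, plus small random
    rigid re-orientations about the instantaneous COM.  Topology is frame
    invariant, so the result plugs straight into the trajectory metrics.
    """
    from .trajectory_analysis import Trajectory

    beads = model.expand() if isinstance(model, CandidateModel) else model
    if any(a < 0 for a in amplitudes.values()):
        raise ValueError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    coords = np.repeat(beads.xyz[None, :, :], n_frames, axis=0)
    units = []  # (mask, amplitude) rigid units: one per (domain, chain)
    for dom, amp in amplitudes.items():
        dmask = beads.domain == dom
        for ch in dict.fromkeys(beads.chain[dmask]):
            units.append((dmask & (beads.chain == ch), float(amp)))
    for mask, amp in units:
        if amp == 0 or not mask.any():
            continue
        s = amp / np.sqrt(3.0)  # per-axis stationary std
        sw = s * np.sqrt(1.0 - phi ** 2)
        x = rng.normal(0.0, s, 3)
        center = beads.xyz[mask].mean(axis=0)
        local = beads.xyz[mask] - center
        for f in range(n_frames):
            if f > 0:
                x = phi * x + rng.normal(0.0, sw, 3)
            if rot_sigma_deg > 0:
                R = Rotation.from_rotvec(np.deg2rad(
                    rng.normal(0.0, rot_sigma_deg, 3))).as_matrix()
            else:
                R = np.eye(3)
            coords[f, mask] = local @ R.T + center + x
    return Trajectory(beads, coords, dt_ps=dt_ps)
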