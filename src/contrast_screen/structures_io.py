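"""Structure I/O, residue-level coarse-graining and rigid-body geometry.

Defines the coordinate machinery the whole pipeline rests on: atomic models
read with gemmi, one-bead-per-residue coarse-grained models, proper-rotation
superposition, C6 symmetry replication, and the cylindrical complex frame
(symmetry axis + reference plane) in which mobile domains are classified.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .tables import ATOMIC_MASSES, RESIDUES

__all__ = [
    "AtomModel", "BeadModel", "Transform", "ComplexFrame",
    "read_structure", "coarse_grain", "superpose", "apply_transform",
    "symmetry_mates", "com", "cylindrical", "from_cylindrical",
    "write_multimodel_pdb", "pair_by_domain_resid",
]


# ---------------------------------------------------------------------------
# types

@dataclass
class AtomModel:
    """Flat arrays of one atomic model (all Å)."""

    element: np.ndarray    # str
    name: np.ndarray       # atom name
    resname: np.ndarray
    resid: np.ndarray      # int
    chain: np.ndarray      # str
    xyz: np.ndarray        # (N, 3) float
    occupancy: np.ndarray  # float
    source: str = ""
    model_number: int = 1

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)


@dataclass
class BeadModel:
    """One bead per residue, with component/domain labels and deuteration.

    ``component`` is the molecular species a bead belongs to (e.g. A, B, C
    or linker); ``domain`` is the finer structural unit (N1A, N2A, C1A,
    C2A, B, CI, CII, linker).  ``body`` labels rigid bodies for clash
    checking and may be shared across components.
    """

    xyz: np.ndarray          # (N, 3) Å
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    mass: np.ndarray         # Da
    component: np.ndarray
    domain: np.ndarray
    deuteration: np.ndarray  # fraction of non-exchangeable H that is D

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        self.resname = np.asarray(self.resname, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        self.component = np.asarray(self.component, dtype=object)
        self.domain = np.asarray(self.domain, dtype=object)
        self.deuteration = np.asarray(self.deuteration, dtype=float)
        for arr in (self.resname, self.resid, self.chain, self.mass,
                    self.component, self.domain, self.deuteration):
            if len(arr) != n:
                raise ValueError("BeadModel field lengths differ")
        if n and (self.deuteration.min() < 0 or self.deuteration.max() > 1):
            raise ValueError("deuteration fractions must lie in [0, 1]")

    @property
    def n_beads(self) -> int:
        return len(self.xyz)

    def copy(self) -> "BeadModel":
        return BeadModel(*(np.array(getattr(self, f), copy=True) for f in
                           ("xyz", "resname", "resid", "chain", "mass",
                            "component", "domain", "deuteration")))

    def subset(self, mask: np.ndarray) -> "BeadModel":
        mask = np.asarray(mask)
        return BeadModel(self.xyz[mask], self.resname[mask], self.resid[mask],
                         self.chain[mask], self.mass[mask], self.component[mask],
                         self.domain[mask], self.deuteration[mask])

    def mask(self, component=None, domain=None, chain=None) -> np.ndarray:
        m = np.ones(self.n_beads, dtype=bool)
        for arr, want in ((self.component, component), (self.domain, domain),
                          (self.chain, chain)):
            if want is None:
                continue
            want = {want} if isinstance(want, str) else set(want)
            m &= np.isin(arr, list(want))
        return m

    def select(self, **kw) -> "BeadModel":
        return self.subset(self.mask(**kw))

    @staticmethod
    def concat(models: Sequence["BeadModel"]) -> "BeadModel":
        return BeadModel(*(np.concatenate([getattr(m, f) for m in models])
                           for f in ("xyz", "resname", "resid", "chain", "mass",
                                     "component", "domain", "deuteration")))

    def with_labels(self, component=None, domain=None, chain=None) -> "BeadModel":
        out = self.copy()
        if component is not None:
            out.component[:] = component
        if domain is not None:
            out.domain[:] = domain
        if chain is not None:
            out.chain[:] = chain
        return out

    # --- tabular round trip -------------------------------------------------
    _COLUMNS = ("chain", "resid", "resname", "x", "y", "z",
                "mass", "component", "domain", "deuteration")

    def to_table(self, path) -> None:
        """Write the documented whitespace table (one row per bead)."""
        df = pd.DataFrame({
            "chain": self.chain, "resid": self.resid, "resname": self.resname,
            "x": self.xyz[:, 0], "y": self.xyz[:, 1], "z": self.xyz[:, 2],
            "mass": self.mass, "component": self.component,
            "domain": self.domain, "deuteration": self.deuteration,
        })
        with open(path, "w") as fh:
            fh.write("# " + " ".join(self._COLUMNS) + "\n")
            df.to_csv(fh, sep=" ", header=False, index=False,
                      float_format="%.6f")

    @classmethod
    def from_table(cls, path) -> "BeadModel":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=list(cls._COLUMNS))
        return cls(df[["x", "y", "z"]].to_numpy(), df["resname"].to_numpy(),
                   df["resid"].to_numpy(), df["chain"].astype(str).to_numpy(),
                   df["mass"].to_numpy(), df["component"].to_numpy(),
                   df["domain"].to_numpy(), df["deuteration"].to_numpy())


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det = -1) not allowed")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, axis, angle_deg: float, origin=(0.0, 0.0, 0.0)) -> "Transform":
        """Rotation by ``angle_deg`` about a line through ``origin``."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        origin = np.asarray(origin, float)
        return cls(R, origin - R @ origin)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class ComplexFrame:
    """Cylindrical coordinate frame of the assembly.

    ``origin`` is the rigid-core center of mass, ``z_axis`` the C6 symmetry
    axis (pointing from the CII side toward the KaiB ring), ``x_axis`` the
    azimuth origin, and ``z0`` the reference plane (top plane of the KaiB
    ring) expressed in frame coordinates.
    """

    origin: np.ndarray
    z_axis: np.ndarray
    x_axis: np.ndarray
    z0: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        z = np.asarray(self.z_axis, float)
        z = z / np.linalg.norm(z)
        x = np.asarray(self.x_axis, float)
        x = x - (x @ z) * z
        nx = np.linalg.norm(x)
        if nx < 1e-12:
            raise ValueError("x_axis parallel to z_axis")
        self.z_axis, self.x_axis = z, x / nx

    @property
    def y_axis(self) -> np.ndarray:
        return np.cross(self.z_axis, self.x_axis)

    def to_frame(self, xyz: np.ndarray) -> np.ndarray:
        """Cartesian coordinates in the frame basis."""
        d = np.asarray(xyz, float) - self.origin
        return np.stack([d @ self.x_axis, d @ self.y_axis, d @ self.z_axis],
                        axis=-1)

    def from_frame(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, float)
        return (self.origin + np.outer(xyz[..., 0].ravel(), self.x_axis)
                + np.outer(xyz[..., 1].ravel(), self.y_axis)
                + np.outer(xyz[..., 2].ravel(), self.z_axis)).reshape(xyz.shape)

    @classmethod
    def from_core(cls, core: BeadModel, b_component: str = "B",
                  theta_origin_chain=None) -> "ComplexFrame":
        """Frame derived from a rigid core.

        For an n-fold symmetric assembly the gyration tensor has two
        degenerate (radial) eigenvalues; the symmetry axis is the
        eigenvector of the remaining, unique one.  The axis is oriented so
        the KaiB component lies on the +z side; the azimuth origin is the
        direction of the first KaiB bead group (chain order); the reference
        plane is the highest z of KaiB beads.
        """
        w = core.mass / core.mass.sum()
        c = w @ core.xyz
        d = core.xyz - c
        gyr = (d * w[:, None]).T @ d
        evals, evecs = np.linalg.eigh(gyr)
        # unique eigenvalue = the one whose two partners are closest together
        gaps = [abs(evals[1] - evals[2]), abs(evals[0] - evals[2]),
                abs(evals[0] - evals[1])]
        z = evecs[:, int(np.argmin(gaps))]
        bmask = core.component == b_component
        if not bmask.any():
            raise ValueError(f"core has no component {b_component!r}")
        b_com = core.mass[bmask] @ core.xyz[bmask] / core.mass[bmask].sum()
        if (b_com - c) @ z < 0:
            z = -z
        chains = core.chain[bmask]
        first = chains[0] if theta_origin_chain is None else theta_origin_chain
        fmask = bmask & (core.chain == first)
        ref = core.xyz[fmask].mean(axis=0)
        x = ref - c - ((ref - c) @ z) * z
        if np.linalg.norm(x) < 1e-9:
            x = np.array([1.0, 0.0, 0.0]) - z[0] * z
        frame = cls(c, z, x, 0.0)
        frame.z0 = float(frame.to_frame(core.xyz[bmask])[:, 2].max())
        return frame


# ---------------------------------------------------------------------------
# reading structures

def read_structure(source, fmt: str | None = None, model: int | None = None,
                   chains: Iterable[str] | None = None) -> AtomModel:
    """Read a PDB or mmCIF structure into an :class:`AtomModel`.

    ``source`` may be a path or the file content as text.  By default all
    chains of the first model are returned.
    """
    import gemmi

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        st = gemmi.read_structure(str(source))
        label = os.path.basename(str(source))
    else:
        text = str(source)
        if fmt == "cif" or text.lstrip().startswith("data_"):
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_pdb_string(text)
        label = "<text>"
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{label}: structure contains no models")
    want_model = 1 if model is None else model
    try:
        mdl = st[want_model - 1]
    except IndexError:
        raise ValueError(f"{label}: no model {want_model}") from None

    chains = None if chains is None else set(chains)
    rows = []
    for ch in mdl:
        if chains is not None and ch.name not in chains:
            continue
        for res in ch:
            for at in res:
                rows.append((at.element.name.upper(), at.name, res.name,
                             res.seqid.num, ch.name,
                             (at.pos.x, at.pos.y, at.pos.z), at.occ))
    if not rows:
        raise ValueError(f"{label}: empty atom selection")
    el, nm, rn, ri, cn, xyz, occ = zip(*rows)
    return AtomModel(np.array(el, object), np.array(nm, object),
                     np.array(rn, object), np.array(ri, int),
                     np.array(cn, object), np.array(xyz, float),
                     np.array(occ, float), source=label,
                     model_number=want_model)


def coarse_grain(model: AtomModel, placement: str = "com") -> BeadModel:
    """Collapse an atomic model to one bead per residue.

    ``placement='com'`` puts each bead at the mass-weighted centroid of the
    residue's atoms; ``placement='ca'`` at the Cα.  Bead mass is the
    standard residue mass where the residue is known, otherwise the sum of
    its atom masses.  Deuteration defaults to 0.
    """
    if placement not in ("com", "ca"):
        raise ValueError("placement must be 'com' or 'ca'")
    keys = pd.DataFrame({"chain": model.chain, "resid": model.resid})
    _, first_idx = np.unique(keys.apply(tuple, axis=1), return_index=True)
    order = np.sort(first_idx)  # preserve file order
    beads = []
    for start in order:
        ch, ri = model.chain[start], model.resid[start]
        sel = (model.chain == ch) & (model.resid == ri)
        rn = model.resname[start]
        masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in model.element[sel]])
        if placement == "ca":
            ca = sel & (model.name == "CA")
            if not ca.any():
                raise ValueError(f"residue {ch}/{ri} has no CA atom")
            pos = model.xyz[ca][0]
        else:
            pos = masses @ model.xyz[sel] / masses.sum()
        res = RESIDUES.get(str(rn).upper())
        mass = res.mass if res is not None else float(masses.sum())
        beads.append((pos, rn, ri, ch, mass))
    xyz, rn, ri, ch, ms = zip(*beads)
    n = len(xyz)
    return BeadModel(np.array(xyz), np.array(rn, object), np.array(ri, int),
                     np.array(ch, object), np.array(ms, float),
                     np.full(n, "", object), np.full(n, "", object),
                     np.zeros(n))


# ---------------------------------------------------------------------------
# rigid-body geometry

def _coords(model) -> np.ndarray:
    return model if isinstance(model, np.ndarray) else model.xyz


def superpose(mobile, reference, pairing=None) -> tuple[Transform, float]:
    """Least-squares proper-rotation superposition (Kabsch).

    ``pairing`` is a pair of index arrays (mobile_idx, reference_idx);
    by default points are paired in order.  Returns the transform that maps
    the mobile onto the reference and the minimized RMSD (Å).
    """
    xm, xr = _coords(mobile), _coords(reference)
    if pairing is not None:
        im, ir = pairing
        xm, xr = xm[np.asarray(im)], xr[np.asarray(ir)]
    if len(xm) != len(xr):
        raise ValueError("paired point sets differ in length")
    if len(xm) < 3:
        raise ValueError("need at least 3 paired points")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    a, b = xr - cr, xm - cm
    if np.linalg.matrix_rank(b - b.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(a, b)  # proper rotation by construction
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((xm @ R.T + t - xr) ** 2, axis=1))))
    return Transform(R, t), rmsd


def pair_by_domain_resid(mobile: BeadModel, reference: BeadModel):
    """Index pairing by (domain, resid); unmatched residues are dropped."""
    key_m = {(d, r): i for i, (d, r) in
             enumerate(zip(mobile.domain, mobile.resid))}
    im, ir = [], []
    for j, (d, r) in enumerate(zip(reference.domain, reference.resid)):
        i = key_m.get((d, r))
        if i is not None:
            im.append(i)
            ir.append(j)
    return np.array(im, int), np.array(ir, int)


def apply_transform(model, t: Transform):
    """Return a copy of ``model`` with all positions mapped x -> Rx + t."""
    if isinstance(model, np.ndarray):
        return t.apply(model)
    out = model.copy() if hasattr(model, "copy") else replace(model)
    out.xyz = t.apply(model.xyz)
    return out


def symmetry_mates(model, n: int, frame: ComplexFrame) -> list:
    """n copies rotated by k*360/n degrees about the frame z-axis."""
    if n < 1:
        raise ValueError("symmetry order must be >= 1")
    return [apply_transform(model, Transform.about_axis(
        frame.z_axis, 360.0 * k / n, frame.origin)) for k in range(n)]


def com(model, selection=None) -> np.ndarray:
    """Mass-weighted centroid; ``selection`` is a boolean mask."""
    xyz, m = model.xyz, model.mass
    if selection is not None:
        xyz, m = xyz[selection], m[selection]
    if len(xyz) == 0:
        raise ValueError("empty selection")
    return m @ xyz / m.sum()


def cylindrical(point, frame: ComplexFrame):
    """(r, theta_deg in [0, 360), z) of a point in the complex frame.

    theta is measured from the frame azimuth origin, counterclockwise when
    viewed from +z; points on the axis get theta = 0 by convention.
    """
    p = frame.to_frame(np.asarray(point, float))
    single = p.ndim == 1
    p = np.atleast_2d(p)
    r = np.hypot(p[:, 0], p[:, 1])
    theta = np.degrees(np.arctan2(p[:, 1], p[:, 0])) % 360.0
    theta[r < 1e-12] = 0.0
    out = (r, theta, p[:, 2])
    return tuple(float(v[0]) for v in out) if single else out


def from_cylindrical(r, theta_deg, z, frame: ComplexFrame) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    return frame.from_frame(np.array([r * np.cos(th), r * np.sin(th), z]))


# ---------------------------------------------------------------------------
# writing

def write_multimodel_pdb(models: Sequence[BeadModel], path) -> None:
    """Write bead models as a multi-model PDB (one CA pseudo-atom per bead)."""
    def chain_id(c):
        s = str(c)
        return s[0] if s else "A"

    with open(path, "w") as fh:
        for k, m in enumerate(models, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            for i in range(m.n_beads):
                x, y, z = m.xyz[i]
                rn = str(m.resname[i])[:3].upper() or "ALA"
                fh.write(
                    f"ATOM  {(i + 1) % 100000:5d}  CA  {rn:<3s} {chain_id(m.chain[i])}"
                    f"{int(m.resid[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"           C\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
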