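"""Residue-level physical constants used throughout the scattering code.

All quantities refer to a residue *within* a polypeptide chain, i.e. the
amino acid minus one water (the convention of residue-level scattering
calculations).  Compositions are for the neutral protonation state.

Sources compiled here:
  * coherent neutron scattering lengths: standard neutron data tables
    (Sears compilation), in fm;
  * residue volumes: Jacrot's solution residue volumes (Å³), the standard
    set for neutron contrast-variation calculations (B. Jacrot, Rep. Prog.
    Phys. 39, 911 (1976));
  * residue masses: monoisotopic-free average residue masses (Da);
  * exchangeable hydrogens: backbone amide H (absent in proline) plus
    side-chain O-H / N-H / S-H hydrogens of the neutral form.
"""

from __future__ import annotations

from dataclasses import dataclass

# coherent scattering lengths, fm
B_H = -3.7406
B_D = 6.6710
B_C = 6.6511
B_N = 9.3700
B_O = 5.8030
B_S = 2.8470

#: volume of one water molecule, Å³
V_WATER = 29.9

#: electron density of water, e/Å³ (X-ray solvent contrast reference)
ELECTRON_DENSITY_WATER = 0.334

#: atomic masses for residue-COM coarse-graining, Da
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "MG": 24.305,
    "ZN": 65.38, "CA": 40.078, "NA": 22.990, "K": 39.098, "CL": 35.45,
}


@dataclass(frozen=True)
class Residue:
    """Physical data for one residue type (in-chain composition)."""

    name: str          # three-letter code
    mass: float        # Da
    n_c: int
    n_h: int           # total hydrogens
    n_n: int
    n_o: int
    n_s: int
    n_exch_h: int      # exchangeable subset of n_h
    volume: float      # Å³

    @property
    def electrons(self) -> int:
        return 6 * self.n_c + self.n_h + 7 * self.n_n + 8 * self.n_o + 16 * self.n_s

    @property
    def radius(self) -> float:
        """Radius (Å) of a sphere with this residue's volume."""
        return (3.0 * self.volume / (4.0 * 3.141592653589793)) ** (1.0 / 3.0)

    def neutron_b(self, deuteration: float, d2o_fraction: float,
                  exchange_fraction: float = 1.0) -> float:
        """Coherent scattering length (fm) of the residue.

        Non-exchangeable hydrogens carry the biosynthetic deuteration
        fraction ``deuteration``; exchangeable hydrogens equilibrate with the
        solvent: a fraction ``exchange_fraction * d2o_fraction`` of them is D.
        """
        b_heavy = self.n_c * B_C + self.n_n * B_N + self.n_o * B_O + self.n_s * B_S
        n_nonexch = self.n_h - self.n_exch_h
        b_nonexch = n_nonexch * ((1.0 - deuteration) * B_H + deuteration * B_D)
        f_d = exchange_fraction * d2o_fraction
        b_exch = self.n_exch_h * ((1.0 - f_d) * B_H + f_d * B_D)
        return b_heavy + b_nonexch + b_exch


def _r(name, mass, c, h, n, o, s, exch, vol):
    return Residue(name, mass, c, h, n, o, s, exch, vol)


RESIDUES: dict[str, Residue] = {
    r.name: r
    for r in [
        _r("GLY", 57.05, 2, 3, 1, 1, 0, 1, 66.4),
        _r("ALA", 71.08, 3, 5, 1, 1, 0, 1, 91.5),
        _r("SER", 87.08, 3, 5, 1, 2, 0, 2, 99.1),
        _r("PRO", 97.12, 5, 7, 1, 1, 0, 0, 129.3),
        _r("VAL", 99.13, 5, 9, 1, 1, 0, 1, 141.7),
        _r("THR", 101.10, 4, 7, 1, 2, 0, 2, 122.1),
        _r("CYS", 103.14, 3, 5, 1, 1, 1, 2, 105.6),
        _r("LEU", 113.16, 6, 11, 1, 1, 0, 1, 167.9),
        _r("ILE", 113.16, 6, 11, 1, 1, 0, 1, 168.8),
        _r("ASN", 114.10, 4, 6, 2, 2, 0, 3, 135.2),
        _r("ASP", 115.09, 4, 5, 1, 3, 0, 2, 113.6),
        _r("GLN", 128.13, 5, 8, 2, 2, 0, 3, 161.1),
        _r("LYS", 128.17, 6, 12, 2, 1, 0, 3, 176.2),
        _r("GLU", 129.12, 5, 7, 1, 3, 0, 2, 140.6),
        _r("MET", 131.19, 5, 9, 1, 1, 1, 1, 170.8),
        _r("HIS", 137.14, 6, 7, 3, 1, 0, 2, 167.3),
        _r("PHE", 147.18, 9, 9, 1, 1, 0, 1, 203.4),
        _r("ARG", 156.19, 6, 12, 4, 1, 0, 5, 180.8),
        _r("TYR", 163.18, 9, 9, 1, 2, 0, 2, 203.6),
        _r("TRP", 186.21, 11, 10, 2, 1, 0, 2, 237.6),
    ]
}

#: typical amino-acid abundances in globular proteins (UniProt frequencies, %)
AA_FREQUENCIES: dict[str, float] = {
    "ALA": 8.25, "ARG": 5.53, "ASN": 4.06, "ASP": 5.45, "CYS": 1.37,
    "GLN": 3.93, "GLU": 6.75, "GLY": 7.07, "HIS": 2.27, "ILE": 5.96,
    "LEU": 9.66, "LYS": 5.84, "MET": 2.42, "PHE": 3.86, "PRO": 4.70,
    "SER": 6.56, "THR": 5.34, "TRP": 1.08, "TYR": 2.92, "VAL": 6.87,
}


def solvent_neutron_sld(d2o_fraction: float) -> float:
    """Neutron scattering-length density of the solvent, fm/Å³."""
    b_water = 2.0 * ((1.0 - d2o_fraction) * B_H + d2o_fraction * B_D) + B_O
    return b_water / V_WATER


def residue(name: str) -> Residue:
    try:
        return RESIDUES[name.upper()]
    except KeyError:
        raise KeyError(f"unknown residue {name!r}: not in the residue table") from None
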