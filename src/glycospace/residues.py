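"""Idealised internal-coordinate templates for the monosaccharides and the
asparagine anchor.

Rings are rigid 4C1-chair pyranoses (the package does not sample ring
pucker); substituents are placed axially or equatorially from a per-residue
orientation table. Geometry is idealised (uniform ring bond length, exact
tetrahedral branching): the analysis operates on ring-atom RMSD and
glycosidic torsions, for which these templates are sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import nerf

RING_BOND = 1.48  # A, uniform ring bond (C-C ~1.52, C-O ~1.43)
CO_BOND = 1.43  # A, C-O exocyclic
CC_BOND = 1.52
CN_BOND = 1.45
GLYCOSIDIC_ANGLE = 117.0  # C1-O-Cx
ASN_GLYCOSIDIC_ANGLE = 124.0  # C1-ND2-CG
_TET_HALF = 54.7356  # half the tetrahedral angle


@dataclass
class ResidueTemplate:
    name: str
    coords: dict  # atom name -> np.ndarray(3)
    bonds: list  # (name, name)
    ring_order: tuple = ("C1", "C2", "C3", "C4", "C5", "O5")

    @property
    def heavy_atoms(self):
        return list(self.coords)


def _chair_ring():
    """4C1-chair ring coordinates, C1..C5 then O5."""
    r = np.sqrt(RING_BOND**2 - 4 * 0.25**2)  # so adjacent atoms sit RING_BOND apart
    pts = {}
    names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    for i, nm in enumerate(names):
        ang = np.radians(60.0 * i)
        z = 0.25 if i % 2 == 0 else -0.25
        pts[nm] = np.array([r * np.cos(ang), r * np.sin(ang), z])
    return pts


def _substituent_dirs(pts, i):
    """The two free tetrahedral directions at ring position i; returns
    (axial, equatorial) unit vectors."""
    names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    p = pts[names[i]]
    u = pts[names[(i - 1) % 6]] - p
    v = pts[names[(i + 1) % 6]] - p
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    s = -(u + v)
    s /= np.linalg.norm(s)
    n = np.cross(u, v)
    n /= np.linalg.norm(n)
    c, sn = np.cos(np.radians(_TET_HALF)), np.sin(np.radians(_TET_HALF))
    d1 = s * c + n * sn
    d2 = s * c - n * sn
    if abs(d1[2]) >= abs(d2[2]):
        return d1, d2
    return d2, d1


# per-sugar substituent orientation overrides (default: all equatorial)
_AXIAL = {
    "Man": {"O2"},
    "Gal": {"O4"},
}

# which substituents each sugar carries (besides O1 at C1)
_SUBSTITUENTS = {
    "Glc": {"C2": "O2", "C3": "O3", "C4": "O4", "C5": "C6"},
    "Man": {"C2": "O2", "C3": "O3", "C4": "O4", "C5": "C6"},
    "Gal": {"C2": "O2", "C3": "O3", "C4": "O4", "C5": "C6"},
    "GlcNAc": {"C2": "N2", "C3": "O3", "C4": "O4", "C5": "C6"},
    "Fuc": {"C2": "O2", "C3": "O3", "C4": "O4", "C5": "C6"},  # 6-deoxy: no O6
    "Xyl": {"C2": "O2", "C3": "O3", "C4": "O4"},  # pentose: no C6
}

SUPPORTED_RESIDUES = tuple(_SUBSTITUENTS)


class UnsupportedResidueError(ValueError):
    pass


def build_residue(name: str, config: str = "b") -> ResidueTemplate:
    """Build an idealised pyranose template.

    `config` sets the anomeric configuration: 'a' places O1 axial, 'b'
    equatorial (D-sugar, 4C1-chair convention).
    """
    if name not in _SUBSTITUENTS:
        raise UnsupportedResidueError(
            f"unsupported residue {name!r}; supported: {SUPPORTED_RESIDUES}"
        )
    pts = _chair_ring()
    bonds = [
        ("C1", "C2"),
        ("C2", "C3"),
        ("C3", "C4"),
        ("C4", "C5"),
        ("C5", "O5"),
        ("O5", "C1"),
    ]
    axial_set = _AXIAL.get(name, set())
    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]

    ax, eq = _substituent_dirs(pts, 0)
    o1_dir = ax if config == "a" else eq
    pts["O1"] = pts["C1"] + CO_BOND * o1_dir
    bonds.append(("C1", "O1"))

    for carbon, sub in _SUBSTITUENTS[name].items():
        i = ring_names.index(carbon)
        ax, eq = _substituent_dirs(pts, i)
        d = ax if sub in axial_set else eq
        bond = CC_BOND if sub.startswith("C") else (CN_BOND if sub.startswith("N") else CO_BOND)
        pts[sub] = pts[carbon] + bond * d
        bonds.append((carbon, sub))

    if "C6" in pts:
        if name != "Fuc":
            # omega default -60 deg (gg rotamer): dihedral(O6, C6, C5, O5)
            pts["O6"] = nerf(pts["O5"], pts["C5"], pts["C6"], CO_BOND, 110.0, -60.0)
            bonds.append(("C6", "O6"))
    if name == "GlcNAc":
        pts["C7"] = nerf(pts["C1"], pts["C2"], pts["N2"], 1.33, 122.0, 120.0)
        pts["O7"] = nerf(pts["C2"], pts["N2"], pts["C7"], 1.23, 122.0, 0.0)
        pts["C8"] = nerf(pts["C2"], pts["N2"], pts["C7"], 1.50, 115.0, 180.0)
        bonds += [("N2", "C7"), ("C7", "O7"), ("C7", "C8")]
    return ResidueTemplate(name=name, coords=pts, bonds=bonds)


def build_asn() -> ResidueTemplate:
    """Idealised asparagine residue (heavy atoms, trans backbone stub)."""
    n = np.zeros(3)
    ca = np.array([1.46, 0.0, 0.0])
    c = ca + CC_BOND * np.array([np.cos(np.radians(69.0)), np.sin(np.radians(69.0)), 0.0])
    o = nerf(n, ca, c, 1.23, 121.0, 150.0)
    cb = nerf(c, n, ca, 1.53, 110.5, -122.0)
    cg = nerf(n, ca, cb, 1.52, 113.0, -60.0)
    od1 = nerf(ca, cb, cg, 1.23, 121.0, -58.0)
    nd2 = nerf(ca, cb, cg, 1.33, 116.5, 122.0)
    coords = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "CG": cg, "OD1": od1, "ND2": nd2}
    bonds = [
        ("N", "CA"),
        ("CA", "C"),
        ("C", "O"),
        ("CA", "CB"),
        ("CB", "CG"),
        ("CG", "OD1"),
        ("CG", "ND2"),
    ]
    return ResidueTemplate(name="ASN", coords=coords, bonds=bonds, ring_order=())


# ---------------------------------------------------------------------------
# Non-bonded parameter tables (12-6 Lennard-Jones + partial charges)
# ---------------------------------------------------------------------------

#: element -> (rmin/2 in A, epsilon in kcal/mol)
LJ_PARAMS = {
    "C": (2.00, 0.055),
    "O": (1.70, 0.120),
    "N": (1.85, 0.200),
}


def partial_charge(atom_name: str) -> float:
    """Coarse partial charge (e) by atom role, for the screened-Coulomb term
    of the default torsion-map energy."""
    if atom_name == "C1":
        return 0.30
    if atom_name == "C7":
        return 0.55
    if atom_name == "O7":
        return -0.50
    if atom_name.startswith("O"):
        return -0.40
    if atom_name.startswith("N"):
        return -0.45
    return 0.15


def lj_parameters(element: str):
    try:
        return LJ_PARAMS[element]
    except KeyError:
        raise UnsupportedResidueError(f"no Lennard-Jones parameters for element {element!r}")
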