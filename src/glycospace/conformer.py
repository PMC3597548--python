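"""Random conformer pools for N-glycan sequences.

The pipeline here mirrors the standard treatment of glycosidic flexibility:
for every distinct linkage type an adiabatic (phi, psi[, omega]) energy map
is evaluated on a regular grid over the rigid disaccharide, converted into a
Boltzmann probability map, and thresholded into an "accessible" torsion set.
Conformer pools are then grown by a rejection-sampled Markov chain: each
accepted conformation is the previous one with one randomly chosen linkage
resampled from its accessible set; conformations with steric bad contacts
(van der Waals energy above a cutoff, default 10 kcal/mol) are rejected.

The 1->6 linkage carries three rotatable torsions (phi, psi, omega) and is
scanned on a 72x72x72 grid at the default 5 degree spacing (373,248 points);
all other linkages have two torsions (5,184 points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from . import residues as res
from .geometry import dihedral, nerf, nerf_batch, frames_from_points, wrap_angle
from .glycan_io import (
    AtomRecord,
    AsnAnchor,
    GlycanTree,
    GlycanTopology,
    GlycosidicLinkage,
    MonosaccharideRing,
    PDB_CODE_TABLE,
    parse_topology,
)

logger = logging.getLogger(__name__)

KB = 0.0019872041  # kcal/mol/K
COULOMB = 332.0636  # kcal*A/mol/e^2
DEFAULT_TEMPERATURE = 300.0  # K
DEFAULT_THRESHOLD = 1e-4
DEFAULT_SPACING = 5.0  # degrees
DEFAULT_CLASH_CUTOFF = 10.0  # kcal/mol

# default torsions used by the internal-coordinate builder (degrees),
# keyed by (anomeric config, parent position); clash-free for the templates
_DEFAULT_TORSIONS = {
    ("b", 0): (-97.0, 178.0),  # GlcNAc-beta-Asn
    ("b", 2): (-20.0, -120.0),
    ("b", 3): (-20.0, -100.0),
    ("b", 4): (-80.0, 120.0),
    ("b", 6): (-20.0, 120.0, -80.0),
    ("a", 2): (80.0, -140.0),
    ("a", 3): (80.0, -100.0),
    ("a", 4): (120.0, 120.0),
    ("a", 6): (100.0, -100.0, -20.0),
}


class UnknownLinkageError(ValueError):
    pass


class AccessibleSetError(ValueError):
    pass


@dataclass(frozen=True)
class LinkageType:
    """One glycosidic linkage type: anomeric configuration of the child and
    the substitution position on the parent (0 denotes the Asn linkage)."""

    anomeric_config: str
    parent_position: int

    @property
    def dims(self) -> int:
        return 3 if self.parent_position == 6 else 2

    @property
    def key(self) -> tuple:
        return (self.anomeric_config, self.parent_position)

    def __str__(self):
        pos = "Asn" if self.parent_position == 0 else str(self.parent_position)
        return f"{self.anomeric_config}1-{pos}"


#: linkage types with a built-in disaccharide template: alpha/beta at
#: positions 2, 3, 4, 6 plus the beta GlcNAc-Asn anchor (the generic pyranose
#: template covers the Xyl/Fuc variants of these positions as well).
SUPPORTED_LINKAGE_TYPES = tuple(
    [LinkageType(c, p) for c in "ab" for p in (2, 3, 4, 6)] + [LinkageType("b", 0)]
)


def default_energy(r, rmin, eps, qq):
    """Per-pair 12-6 Lennard-Jones plus distance-dependent-dielectric
    Coulomb (epsilon = 4r) energy in kcal/mol."""
    x = (rmin / r) ** 6
    return eps * (x * x - 2.0 * x) + COULOMB * qq / (4.0 * r * r)


def lj_energy(r, rmin, eps, qq=None):
    """Pure van der Waals 12-6 term (the bad-contact criterion)."""
    x = (rmin / r) ** 6
    return eps * (x * x - 2.0 * x)


@dataclass
class TorsionGrid:
    """Per-linkage-type torsion grid: energies, Boltzmann probabilities and
    the accessible mask.

    Axis order is (phi, psi[, omega]); cell centers run -180, -180+spacing,
    ... in each dimension.
    """

    linkage_type: LinkageType
    spacing: float
    energies: np.ndarray  # (n,)*dims, kcal/mol, min shifted to 0
    probabilities: np.ndarray | None = None
    accessible: np.ndarray | None = None
    temperature: float | None = None
    threshold: float | None = None

    @property
    def dims(self) -> int:
        return self.energies.ndim

    @property
    def n_per_axis(self) -> int:
        return self.energies.shape[0]

    @property
    def n_points(self) -> int:
        return self.energies.size

    @property
    def centers(self) -> np.ndarray:
        return -180.0 + self.spacing * np.arange(self.n_per_axis)

    def cell_index(self, angles) -> tuple:
        """Nearest grid cell (with wrap-around) for a torsion tuple."""
        idx = np.rint((np.asarray(angles, dtype=float) + 180.0) / self.spacing).astype(int)
        return tuple(idx % self.n_per_axis)

    def is_accessible(self, angles) -> bool:
        if self.accessible is None:
            raise ValueError("accessible set not computed")
        return bool(self.accessible[self.cell_index(angles)])

    def accessible_marginal(self, dim: int = 0) -> np.ndarray:
        """Accessible-cell counts along one torsion axis (the expected
        marginal of uniform-over-accessible sampling)."""
        axes = tuple(i for i in range(self.dims) if i != dim)
        return self.accessible.sum(axis=axes)

    def sample(self, rng, size=None, temperature=None) -> np.ndarray:
        """Draw torsion tuples from the accessible set.

        With ``temperature=None`` cells are drawn uniformly over the
        accessible set; otherwise with Boltzmann weights exp(-E/kT)
        restricted to accessible cells. Values are jittered uniformly within
        the chosen cell (+- spacing/2).
        """
        if self.accessible is None:
            raise ValueError("accessible set not computed")
        flat_idx = np.flatnonzero(self.accessible.ravel())
        if temperature is None:
            p = None
        else:
            e = self.energies.ravel()[flat_idx]
            w = np.exp(-(e - e.min()) / (KB * temperature))
            p = w / w.sum()
        n = 1 if size is None else int(size)
        chosen = rng.choice(flat_idx, size=n, p=p)
        idx = np.stack(np.unravel_index(chosen, self.energies.shape), axis=-1)
        angles = -180.0 + self.spacing * idx + rng.uniform(
            -self.spacing / 2, self.spacing / 2, size=idx.shape
        )
        angles = wrap_angle(angles)
        return angles[0] if size is None else angles


# ---------------------------------------------------------------------------
# Internal-coordinate builder
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates atoms/bonds/nodes while residues are attached."""

    def __init__(self):
        self.names = []  # (residue_index, atom_name)
        self.coords = []
        self.bonds = []
        self.residues = []  # (template_name, config, pdb_code)
        self.index = {}  # (residue_index, atom_name) -> global index

    def add_residue(self, template, config, pdb_code, placed_coords):
        ri = len(self.residues)
        self.residues.append((template.name, config, pdb_code))
        for name, xyz in placed_coords.items():
            self.index[(ri, name)] = len(self.coords)
            self.names.append((ri, name))
            self.coords.append(np.asarray(xyz, dtype=float))
        for a, b in template.bonds:
            if a in placed_coords and b in placed_coords:
                self.bonds.append((self.index[(ri, a)], self.index[(ri, b)]))
        return ri


def _attach_child(builder, bridge_idx, cx_idx, cprev_idx, template, config,
                  pdb_code, phi, psi, c1_bond, c1_angle):
    """Place a child residue template through its anomeric carbon onto an
    existing bridge atom with the requested phi/psi, dropping the child O1
    (the bridge atom takes its place)."""
    coords = builder.coords
    b_pos = coords[bridge_idx]
    cx_pos = coords[cx_idx]
    cprev_pos = coords[cprev_idx]
    tpl = template.coords
    c1_t = nerf(cprev_pos, cx_pos, b_pos, c1_bond, c1_angle, psi)
    d_c1o5 = np.linalg.norm(tpl["C1"] - tpl["O5"])
    ang_o5 = np.degrees(
        np.arccos(
            np.dot(tpl["O5"] - tpl["C1"], tpl["O1"] - tpl["C1"])
            / (d_c1o5 * np.linalg.norm(tpl["O1"] - tpl["C1"]))
        )
    )
    o5_t = nerf(cx_pos, b_pos, c1_t, d_c1o5, ang_o5, phi)
    f_target = frames_from_points(c1_t, b_pos, o5_t)
    f_tpl = frames_from_points(tpl["C1"], tpl["O1"], tpl["O5"])
    rot = f_target @ f_tpl.T
    placed = {
        name: c1_t + rot @ (xyz - tpl["C1"])
        for name, xyz in tpl.items()
        if name != "O1"
    }
    ri = builder.add_residue(template, config, pdb_code, placed)
    c1_idx = builder.index[(ri, "C1")]
    builder.bonds.append((bridge_idx, c1_idx))
    return ri


def build_initial_structure(topology) -> GlycanTree:
    """Build an idealised 3D structure (attached to an Asn anchor) for a
    glycan topology string, with template default torsions.

    Deterministic; all bond lengths and angles at template values, chair
    ring geometry throughout.
    """
    if isinstance(topology, GlycanTopology):
        topology = topology.canonical_string
    if isinstance(topology, GlycanTree):
        topology = topology.canonical_string
    spec = parse_topology(topology)

    builder = _Builder()
    asn_tpl = res.build_asn()
    builder.add_residue(asn_tpl, "", "ASN", asn_tpl.coords)

    edges_spec = []  # (child_ri, parent_ri, position, config, bridge_idx)

    def attach(node_spec, parent_ri, config, position):
        name, children = node_spec
        template = res.build_residue(name, config)
        pdb_code = PDB_CODE_TABLE.get((name, config))
        if pdb_code is None:
            raise res.UnsupportedResidueError(f"no PDB code for {name} ({config})")
        if position == 0:
            bridge = builder.index[(0, "ND2")]
            cx = builder.index[(0, "CG")]
            cprev = builder.index[(0, "CB")]
            phi, psi = _DEFAULT_TORSIONS[("b", 0)]
            ri = _attach_child(
                builder, bridge, cx, cprev, template, config, pdb_code,
                phi, psi, res.CN_BOND, res.ASN_GLYCOSIDIC_ANGLE,
            )
        else:
            defaults = _DEFAULT_TORSIONS[(config, position)]
            phi, psi = defaults[0], defaults[1]
            if position == 6:
                omega = defaults[2]
                if (parent_ri, "O6") not in builder.index:
                    raise UnknownLinkageError(
                        f"parent residue has no O6 for a 1->6 linkage in {topology!r}"
                    )
                o5p = builder.coords[builder.index[(parent_ri, "O5")]]
                c5p = builder.coords[builder.index[(parent_ri, "C5")]]
                c6p = builder.coords[builder.index[(parent_ri, "C6")]]
                builder.coords[builder.index[(parent_ri, "O6")]] = nerf(
                    o5p, c5p, c6p, res.CO_BOND, 110.0, omega
                )
                bridge = builder.index[(parent_ri, "O6")]
                cx = builder.index[(parent_ri, "C6")]
                cprev = builder.index[(parent_ri, "C5")]
            else:
                oname = f"O{position}"
                if (parent_ri, oname) not in builder.index:
                    raise UnknownLinkageError(
                        f"parent residue has no {oname} for a 1->{position} linkage"
                    )
                bridge = builder.index[(parent_ri, oname)]
                cx = builder.index[(parent_ri, f"C{position}")]
                cprev = builder.index[(parent_ri, f"C{position - 1}")]
            ri = _attach_child(
                builder, bridge, cx, cprev, template, config, pdb_code,
                phi, psi, res.CO_BOND, res.GLYCOSIDIC_ANGLE,
            )
        edges_spec.append((ri, parent_ri, position, config,
                           builder.index[(0, "ND2")] if position == 0 else bridge))
        for cfg, pos, sub in children:
            attach(sub, ri, cfg, pos)
        return ri

    attach(spec, 0, "b", 0)

    # assemble the GlycanTree
    atoms = []
    for gi, (ri, name) in enumerate(builder.names):
        tname, config, pdb_code = builder.residues[ri]
        atoms.append(
            AtomRecord(
                serial=gi + 1,
                name=name,
                element=name[0],
                residue_name=pdb_code,
                residue_id=("A", ri + 1, ""),
                coordinates=builder.coords[gi],
                is_hetatm=(ri != 0),
            )
        )
    coords = np.array(builder.coords)

    nodes = []
    node_of_ri = {}
    for ri, (tname, config, pdb_code) in enumerate(builder.residues):
        if ri == 0:
            continue
        ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
        ring_atoms = [builder.index[(ri, nm)] for nm in ring_names]
        node_of_ri[ri] = len(nodes)
        nodes.append(
            MonosaccharideRing(
                ring_atoms=ring_atoms,
                ring_oxygen=ring_atoms[-1],
                anomeric_carbon=ring_atoms[0],
                residue_name=pdb_code,
                assigned_name=tname,
                residue_id=("A", ri + 1, ""),
                anomeric_config=config,
                atom_indices=[
                    g for g, (r2, _) in enumerate(builder.names) if r2 == ri
                ],
            )
        )

    edges = []
    asn_linkage = None
    for child_ri, parent_ri, position, config, bridge in edges_spec:
        c1 = builder.index[(child_ri, "C1")]
        o5c = builder.index[(child_ri, "O5")]
        if position == 0:
            nd2 = builder.index[(0, "ND2")]
            cg = builder.index[(0, "CG")]
            cb = builder.index[(0, "CB")]
            asn_linkage = GlycosidicLinkage(
                child=node_of_ri[child_ri],
                parent=-1,
                parent_position=0,
                anomeric_config=config,
                bridge_atom=nd2,
                phi_atoms=(o5c, c1, nd2, cg),
                psi_atoms=(c1, nd2, cg, cb),
            )
            continue
        if position == 6:
            cx = builder.index[(parent_ri, "C6")]
            c5p = builder.index[(parent_ri, "C5")]
            o5p = builder.index[(parent_ri, "O5")]
            psi_atoms = (c1, bridge, cx, c5p)
            omega_atoms = (bridge, cx, c5p, o5p)
        else:
            cx = builder.index[(parent_ri, f"C{position}")]
            cprev = builder.index[(parent_ri, f"C{position - 1}")]
            psi_atoms = (c1, bridge, cx, cprev)
            omega_atoms = None
        edges.append(
            GlycosidicLinkage(
                child=node_of_ri[child_ri],
                parent=node_of_ri[parent_ri],
                parent_position=position,
                anomeric_config=config,
                bridge_atom=bridge,
                phi_atoms=(o5c, c1, bridge, cx),
                psi_atoms=psi_atoms,
                omega_atoms=omega_atoms,
            )
        )

    asn_atoms = {
        name: builder.index[(0, name)]
        for name in ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2")
    }
    tree = GlycanTree(
        atoms=atoms,
        coords=coords,
        bonds=sorted(tuple(sorted(b)) for b in builder.bonds),
        nodes=nodes,
        edges=edges,
        root=0,
        asn=AsnAnchor(residue_id=("A", 1, ""), atom_indices=asn_atoms),
        asn_linkage=asn_linkage,
    )
    return tree


# ---------------------------------------------------------------------------
# Torsion manipulation
# ---------------------------------------------------------------------------


class TorsionMachine:
    """Precomputed subtree rotations for every torsion of a glycan tree.

    For a dihedral (a, b, c, d) the moved set is the connected component of
    the bond graph, with the central bond (b, c) removed, that contains b;
    rotating it about the b-c axis changes exactly that one internal
    coordinate.
    """

    def __init__(self, tree: GlycanTree):
        self.tree = tree
        g = nx.Graph()
        g.add_nodes_from(range(len(tree.atoms)))
        g.add_edges_from(tree.bonds)
        self.linkages = tree.all_linkages()
        self.specs = []  # per linkage: list of (atom_tuple, moved_idx, sign)
        coords = tree.coords.copy()
        for lk in self.linkages:
            per_torsion = []
            for tup in lk.torsion_atom_tuples:
                a, b, c, d = tup
                g.remove_edge(b, c)
                moved = np.array(sorted(nx.node_connected_component(g, b)))
                g.add_edge(b, c)
                sign = self._calibrate_sign(coords, tup, moved)
                per_torsion.append((tup, moved, sign))
            self.specs.append(per_torsion)

    @staticmethod
    def _rotate(coords, tup, moved, delta_deg):
        a, b, c, d = tup
        axis = coords[b] - coords[c]
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(delta_deg) * axis)
        coords[moved] = rot.apply(coords[moved] - coords[c]) + coords[c]

    @classmethod
    def _calibrate_sign(cls, coords, tup, moved):
        a, b, c, d = tup
        before = dihedral(coords[a], coords[b], coords[c], coords[d])
        test = coords.copy()
        cls._rotate(test, tup, moved, 10.0)
        after = dihedral(test[a], test[b], test[c], test[d])
        return 1.0 if abs(wrap_angle(after - before - 10.0)) < 1e-6 else -1.0

    def set_torsions(self, coords, linkage_index, angles):
        """Set all torsions of one linkage, in place."""
        spec = self.specs[linkage_index]
        angles = np.atleast_1d(angles)
        if len(angles) != len(spec):
            raise ValueError(
                f"expected {len(spec)} torsion values, got {len(angles)}"
            )
        for (tup, moved, sign), target in zip(spec, angles):
            a, b, c, d = tup
            current = dihedral(coords[a], coords[b], coords[c], coords[d])
            self._rotate(coords, tup, moved, sign * wrap_angle(target - current))

    def get_torsions(self, coords, linkage_index):
        return tuple(
            dihedral(coords[a], coords[b], coords[c], coords[d])
            for (a, b, c, d), _, _ in self.specs[linkage_index]
        )


def set_torsion(coordinates, tree: GlycanTree, linkage, angles) -> np.ndarray:
    """Return a copy of `coordinates` with one linkage's torsions set to
    `angles` (degrees); all atoms distal to the rotated bonds move rigidly,
    bond lengths and angles are untouched."""
    machine = TorsionMachine(tree)
    linkages = machine.linkages
    idx = next(i for i, lk in enumerate(linkages) if lk is linkage or lk == linkage)
    out = np.array(coordinates, dtype=float)
    machine.set_torsions(out, idx, angles)
    return out


# ---------------------------------------------------------------------------
# Non-bonded energies
# ---------------------------------------------------------------------------


def _nonbonded_pairs(tree: GlycanTree):
    """Index arrays (i, j, rmin, eps) of heavy-atom pairs four or more bonds
    apart; cached on the tree instance."""
    cached = getattr(tree, "_nb_pairs", None)
    if cached is not None:
        return cached
    g = nx.Graph()
    n = len(tree.atoms)
    g.add_nodes_from(range(n))
    g.add_edges_from(tree.bonds)
    near = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    ii, jj = [], []
    for i in range(n):
        excl = near.get(i, {i: 0})
        for j in range(i + 1, n):
            if j not in excl:
                ii.append(i)
                jj.append(j)
    ii = np.array(ii, dtype=int)
    jj = np.array(jj, dtype=int)
    half = {e: (p[0], np.sqrt(p[1])) for e, p in res.LJ_PARAMS.items()}
    ri = np.array([half[tree.atoms[i].element][0] for i in ii])
    rj = np.array([half[tree.atoms[j].element][0] for j in jj])
    ei = np.array([half[tree.atoms[i].element][1] for i in ii])
    ej = np.array([half[tree.atoms[j].element][1] for j in jj])
    pairs = (ii, jj, ri + rj, ei * ej)
    tree._nb_pairs = pairs
    return pairs


def clash_energy(coordinates, tree: GlycanTree) -> float:
    """Total 12-6 van der Waals energy (kcal/mol) over heavy-atom pairs at
    least four bonds apart; the bad-contact criterion of the sampler."""
    ii, jj, rmin, eps = _nonbonded_pairs(tree)
    if len(ii) == 0:
        return 0.0
    d = np.linalg.norm(coordinates[ii] - coordinates[jj], axis=1)
    return float(lj_energy(d, rmin, eps).sum())


# ---------------------------------------------------------------------------
# Adiabatic torsion maps
# ---------------------------------------------------------------------------


def _linkage_template(linkage_type: LinkageType):
    """Disaccharide (or GlcNAc-Asn) template for a linkage type: returns
    (static_atoms, bridge info, child template, bond graph metadata)."""
    cfg, pos = linkage_type.anomeric_config, linkage_type.parent_position
    if pos == 0:
        parent = res.build_asn()
        child = res.build_residue("GlcNAc", "b")
        bridge_name, cx, cprev = "ND2", "CG", "CB"
        c1_bond, c1_angle = res.CN_BOND, res.ASN_GLYCOSIDIC_ANGLE
    else:
        parent = res.build_residue("Glc", "b")
        child = res.build_residue("Glc", cfg)
        c1_bond, c1_angle = res.CO_BOND, res.GLYCOSIDIC_ANGLE
        if pos == 6:
            bridge_name, cx, cprev = "O6", "C6", "C5"
        else:
            bridge_name, cx, cprev = f"O{pos}", f"C{pos}", f"C{pos - 1}"
        if bridge_name not in parent.coords:
            raise UnknownLinkageError(f"unsupported linkage type {linkage_type}")
    return parent, child, bridge_name, cx, cprev, c1_bond, c1_angle


def scan_linkage_energy(
    linkage_type,
    energy_fn=None,
    spacing: float = DEFAULT_SPACING,
) -> TorsionGrid:
    """Evaluate the rigid-disaccharide energy over the full torsion grid of
    a linkage type (no per-point minimisation); energies are shifted so the
    minimum is zero.

    `energy_fn(r, rmin, eps, qq)` maps per-pair distances to per-pair
    energies; the default is 12-6 Lennard-Jones plus screened Coulomb.
    """
    if isinstance(linkage_type, tuple):
        linkage_type = LinkageType(*linkage_type)
    if linkage_type.key not in {lt.key for lt in SUPPORTED_LINKAGE_TYPES}:
        raise UnknownLinkageError(
            f"unknown linkage type {linkage_type}; supported: "
            + ", ".join(str(t) for t in SUPPORTED_LINKAGE_TYPES)
        )
    if energy_fn is None:
        energy_fn = default_energy
    parent, child, bridge_name, cx_name, cprev_name, c1_bond, c1_angle = (
        _linkage_template(linkage_type)
    )
    dims = linkage_type.dims
    n = int(round(360.0 / spacing))
    centers = -180.0 + spacing * np.arange(n)

    # bond graph of the linked disaccharide, on ("p"/"c", atom name) nodes
    g = nx.Graph()
    for a, b in parent.bonds:
        g.add_edge(("p", a), ("p", b))
    for a, b in child.bonds:
        if a != "O1" and b != "O1":
            g.add_edge(("c", a), ("c", b))
    g.add_edge(("p", bridge_name), ("c", "C1"))

    child_names = [nm for nm in child.coords if nm != "O1"]
    moving = [("c", nm) for nm in child_names]
    static_names = [nm for nm in parent.coords]
    if dims == 3:
        static_names = [nm for nm in static_names if nm != bridge_name]
        moving = moving + [("p", bridge_name)]
    static = [("p", nm) for nm in static_names]

    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    pair_m, pair_s = [], []
    for mi, m in enumerate(moving):
        near = dist.get(m, {})
        for si, s in enumerate(static):
            if s not in near:
                pair_m.append(mi)
                pair_s.append(si)
    pair_m = np.array(pair_m, dtype=int)
    pair_s = np.array(pair_s, dtype=int)

    def params(atom_key):
        side, nm = atom_key
        element = nm[0]
        half_r, e = res.LJ_PARAMS[element]
        return half_r, np.sqrt(e), res.partial_charge(nm)

    mp = [params(m) for m in moving]
    sp = [params(s) for s in static]
    rmin = np.array([mp[i][0] + sp[j][0] for i, j in zip(pair_m, pair_s)])
    eps = np.array([mp[i][1] * sp[j][1] for i, j in zip(pair_m, pair_s)])
    qq = np.array([mp[i][2] * sp[j][2] for i, j in zip(pair_m, pair_s)])

    static_xyz = np.array([parent.coords[nm] for _, nm in static])

    # local child coordinates in the (C1, O1, O5) anchor frame
    tpl = child.coords
    f_tpl = frames_from_points(tpl["C1"], tpl["O1"], tpl["O5"])
    local = np.array([(tpl[nm] - tpl["C1"]) @ f_tpl for nm in child_names])
    d_c1o5 = np.linalg.norm(tpl["C1"] - tpl["O5"])
    v1 = tpl["O5"] - tpl["C1"]
    v2 = tpl["O1"] - tpl["C1"]
    ang_o5 = np.degrees(
        np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    )

    cx = parent.coords[cx_name]
    cprev = parent.coords[cprev_name]

    if dims == 2:
        phi_g, psi_g = np.meshgrid(centers, centers, indexing="ij")
        grids = [phi_g.ravel(), psi_g.ravel()]
        bridge_fixed = parent.coords[bridge_name]
    else:
        phi_g, psi_g, omega_g = np.meshgrid(centers, centers, centers, indexing="ij")
        grids = [phi_g.ravel(), psi_g.ravel(), omega_g.ravel()]
        o5p = parent.coords["O5"]
        c5p = parent.coords["C5"]

    total = grids[0].size
    energies = np.empty(total)
    chunk = 20000
    for start in range(0, total, chunk):
        sl = slice(start, min(start + chunk, total))
        phi = grids[0][sl]
        psi = grids[1][sl]
        if dims == 3:
            omega = grids[2][sl]
            bridge = nerf_batch(o5p, c5p, cx, res.CO_BOND, 110.0, omega)
        else:
            bridge = np.broadcast_to(bridge_fixed, phi.shape + (3,))
        c1 = nerf_batch(cprev, cx, bridge, c1_bond, c1_angle, psi)
        o5 = nerf_batch(
            np.broadcast_to(cx, c1.shape), bridge, c1, d_c1o5, ang_o5, phi
        )
        frames = frames_from_points(c1, bridge, o5)
        child_xyz = c1[:, None, :] + np.einsum("pij,aj->pai", frames, local)
        if dims == 3:
            moving_xyz = np.concatenate([child_xyz, bridge[:, None, :]], axis=1)
        else:
            moving_xyz = child_xyz
        diff = moving_xyz[:, pair_m, :] - static_xyz[pair_s][None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        energies[sl] = energy_fn(r, rmin, eps, qq).sum(axis=-1)

    energies = energies.reshape((n,) * dims)
    finite = np.isfinite(energies)
    if finite.any():
        energies = energies - energies[finite].min()
    return TorsionGrid(linkage_type=linkage_type, spacing=spacing, energies=energies)


def boltzmann_probabilities(grid: TorsionGrid, temperature: float = DEFAULT_TEMPERATURE) -> TorsionGrid:
    """Convert the energy grid to a normalised Boltzmann probability map
    (p_i proportional to exp(-E_i / kT)); non-finite energies get p = 0."""
    e = grid.energies
    with np.errstate(over="ignore", invalid="ignore"):
        w = np.exp(-np.where(np.isfinite(e), e, np.inf) / (KB * temperature))
    w[~np.isfinite(w)] = 0.0
    z = w.sum()
    if z <= 0:
        raise ValueError("all grid energies non-finite; cannot normalise")
    grid.probabilities = w / z
    grid.temperature = temperature
    return grid


def accessible_set(grid: TorsionGrid, threshold: float = DEFAULT_THRESHOLD) -> TorsionGrid:
    """Mark grid cells with probability above `threshold` as accessible."""
    if grid.probabilities is None:
        raise ValueError("probabilities not computed; call boltzmann_probabilities")
    mask = grid.probabilities > threshold
    if not mask.any():
        raise AccessibleSetError(
            f"no grid cell has probability above {threshold}; lower the threshold"
        )
    grid.accessible = mask
    grid.threshold = threshold
    return grid


_MAP_CACHE = {}


def build_torsion_map(
    linkage_type,
    spacing: float = DEFAULT_SPACING,
    temperature: float = DEFAULT_TEMPERATURE,
    threshold: float = DEFAULT_THRESHOLD,
    energy_fn=None,
) -> TorsionGrid:
    """Scan + Boltzmann + accessibility for one linkage type, cached.

    The accessibility threshold is interpreted on the torsion-angle-pair
    scale: for three-torsion (1->6) grids the per-cell threshold is divided
    by the number of cells of the extra omega axis, so the same numerical
    value carries the same meaning for 2-D and 3-D maps. Without this the
    omega dimension would dilute per-cell probabilities 72-fold and
    artificially freeze the 1->6 rotamers.
    """
    if isinstance(linkage_type, tuple):
        linkage_type = LinkageType(*linkage_type)
    key = (linkage_type.key, spacing, temperature, threshold, energy_fn)
    if key not in _MAP_CACHE:
        grid = scan_linkage_energy(linkage_type, energy_fn=energy_fn, spacing=spacing)
        boltzmann_probabilities(grid, temperature)
        accessible_set(grid, threshold / grid.n_per_axis ** (grid.dims - 2))
        _MAP_CACHE[key] = grid
    return _MAP_CACHE[key]


def torsion_maps_for(tree: GlycanTree, spacing=DEFAULT_SPACING,
                     temperature=DEFAULT_TEMPERATURE, threshold=DEFAULT_THRESHOLD,
                     energy_fn=None) -> dict:
    """Torsion maps for every linkage type occurring in a tree, keyed by
    (anomeric_config, parent_position)."""
    out = {}
    for lk in tree.all_linkages():
        if lk.linkage_key not in out:
            out[lk.linkage_key] = build_torsion_map(
                LinkageType(*lk.linkage_key), spacing, temperature, threshold, energy_fn
            )
    return out


# ---------------------------------------------------------------------------
# Pool generation
# ---------------------------------------------------------------------------


@dataclass
class ConformerPool:
    """Random conformer pool for one glycan sequence."""

    topology: str
    tree: GlycanTree
    conformers: np.ndarray  # (n_conformers, n_atoms, 3)
    seed: int
    attempts: int
    rejections: int
    maps: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.conformers)

    @property
    def acceptance_stats(self):
        return {"attempts": self.attempts, "rejections": self.rejections}

    def validate(self, clash_cutoff: float = DEFAULT_CLASH_CUTOFF) -> dict:
        """Fraction of conformers passing the clash cutoff and whose
        recomputed torsions fall on accessible cells (nearest-cell
        assignment)."""
        machine = TorsionMachine(self.tree)
        clash_ok = 0
        access_ok = 0
        for coords in self.conformers:
            if clash_energy(coords, self.tree) <= clash_cutoff:
                clash_ok += 1
            ok = True
            for li, lk in enumerate(machine.linkages):
                grid = self.maps[lk.linkage_key]
                if not grid.is_accessible(machine.get_torsions(coords, li)):
                    ok = False
                    break
            access_ok += ok
        n = len(self.conformers)
        return {"clash_pass": clash_ok / n, "accessible_pass": access_ok / n}


def generate_pool(
    topology,
    n_conformers: int = 10000,
    torsion_maps: dict | None = None,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    seed: int = 0,
    spacing: float = DEFAULT_SPACING,
    temperature: float = DEFAULT_TEMPERATURE,
    threshold: float = DEFAULT_THRESHOLD,
    sample_temperature: float | None = None,
) -> ConformerPool:
    """Grow a clash-rejected conformer pool for one glycan sequence.

    Starting from an accessible, clash-free initial conformation, each
    iteration picks one glycosidic linkage uniformly at random, redraws its
    torsions from the accessible map (uniformly unless
    `sample_temperature` requests Boltzmann weighting) and accepts the move
    if the van der Waals energy stays at or below `clash_cutoff`.
    Reproducible given `seed`.
    """
    tree = build_initial_structure(topology)
    if torsion_maps is None:
        torsion_maps = torsion_maps_for(tree, spacing, temperature, threshold)
    machine = TorsionMachine(tree)
    linkages = machine.linkages
    rng = np.random.default_rng(seed)

    coords = tree.coords.copy()
    n_atoms = coords.shape[0]
    out = np.empty((n_conformers, n_atoms, 3))

    if not linkages:
        out[:] = coords
        return ConformerPool(
            topology=tree.canonical_string, tree=tree, conformers=out, seed=seed,
            attempts=n_conformers, rejections=0, maps=torsion_maps,
        )

    grids = [torsion_maps[lk.linkage_key] for lk in linkages]

    # burn-in: land every linkage on the accessible set, clash-free
    for attempt in range(500):
        for li, grid in enumerate(grids):
            machine.set_torsions(coords, li, grid.sample(rng, temperature=sample_temperature))
        if clash_energy(coords, tree) <= clash_cutoff:
            break
    else:
        raise RuntimeError(
            "could not find a clash-free starting conformation in 500 attempts"
        )

    attempts = 0
    accepted = 0
    backup = coords.copy()
    while accepted < n_conformers:
        li = int(rng.integers(len(linkages)))
        angles = grids[li].sample(rng, temperature=sample_temperature)
        np.copyto(backup, coords)
        machine.set_torsions(coords, li, angles)
        attempts += 1
        if clash_energy(coords, tree) <= clash_cutoff:
            out[accepted] = coords
            accepted += 1
        else:
            np.copyto(coords, backup)
        if attempts >= 1_000_000 and accepted / attempts < 1e-4:
            raise RuntimeError(
                f"acceptance rate {accepted / attempts:.2e} below 1e-4 after "
                f"{attempts} attempts; check clash cutoff and torsion maps"
            )
    return ConformerPool(
        topology=tree.canonical_string,
        tree=tree,
        conformers=out,
        seed=seed,
        attempts=attempts,
        rejections=attempts - accepted,
        maps=torsion_maps,
    )


def background_rmsd_distribution(
    pool: ConformerPool,
    subsample: int = 500,
    seed: int | None = None,
    anchoring: str = "ring",
    substructure=None,
) -> np.ndarray:
    """Pairwise structural distances over a seeded random subsample of the
    pool: the null distribution that the significance model is fitted to.

    For `subsample` conformers all subsample*(subsample-1)/2 unordered pairs
    are measured (500 -> 124,750). `anchoring` selects the ring-atom RMSD
    (default), the Asn-anchored or the two-residue-stub-anchored distance;
    `substructure` optionally restricts to an internal substructure (a
    SubstructureSpec).
    """
    from . import similarity  # deferred: similarity imports glycan_io only

    if subsample < 2:
        raise ValueError("subsample must be at least 2")
    if subsample > len(pool):
        raise ValueError(f"subsample {subsample} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(pool.seed + 1 if seed is None else seed)
    chosen = rng.choice(len(pool), size=subsample, replace=False)
    ii, jj = np.triu_indices(subsample, k=1)
    pairs = np.stack([chosen[ii], chosen[jj]], axis=1)
    return similarity.batch_pair_distances(
        pool.conformers, pairs, pool.tree, anchoring=anchoring, substructure=substructure
    )
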