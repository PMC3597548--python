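"""Read glycoprotein structure files, recognise carbohydrate rings, assemble
N-glycan trees and emit canonical glycan sequence strings.

Carbohydrate recognition follows the classic ring-membership rule: a pyranose
is a six-membered and a furanose a five-membered cycle made of carbon atoms
and exactly one oxygen. Glycan chains are then assembled by walking the
glycosidic bonds between recognised rings, rooted at the ring whose anomeric
carbon is bonded to an asparagine side-chain nitrogen (ND2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral

logger = logging.getLogger(__name__)

#: Asparagine heavy atoms used for Asn-anchored superposition.
ASN_HEAVY_ATOMS = ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2")

# PDB residue code -> (assigned name, anomeric configuration)
RESIDUE_NAME_TABLE = {
    "NAG": ("GlcNAc", "b"),
    "NDG": ("GlcNAc", "a"),
    "BMA": ("Man", "b"),
    "MAN": ("Man", "a"),
    "FUC": ("Fuc", "a"),
    "FUL": ("Fuc", "b"),
    "XYP": ("Xyl", "b"),
    "XYS": ("Xyl", "a"),
    "GLC": ("Glc", "a"),
    "BGC": ("Glc", "b"),
    "GAL": ("Gal", "b"),
    "GLA": ("Gal", "a"),
}

# assigned name -> PDB residue code, per anomeric configuration
PDB_CODE_TABLE = {
    ("GlcNAc", "b"): "NAG",
    ("GlcNAc", "a"): "NDG",
    ("Man", "b"): "BMA",
    ("Man", "a"): "MAN",
    ("Fuc", "a"): "FUC",
    ("Fuc", "b"): "FUL",
    ("Xyl", "b"): "XYP",
    ("Xyl", "a"): "XYS",
    ("Glc", "a"): "GLC",
    ("Glc", "b"): "BGC",
    ("Gal", "b"): "GAL",
    ("Gal", "a"): "GLA",
}

BOND_INFERENCE_CUTOFF = 1.8  # Angstrom, heavy-atom bond inference


class GlycanParseError(ValueError):
    pass


class SequenceMismatchError(ValueError):
    """Comparison requested between glycans of different sequence."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: tuple  # (chain, number, insertion code)
    coordinates: np.ndarray
    is_hetatm: bool
    occupancy: float = 1.0


@dataclass
class ProteinResidue:
    name: str
    one_letter: str
    residue_id: tuple
    atom_indices: dict  # atom name -> index into the structure atom list


@dataclass
class ProteinChain:
    chain_id: str
    residues: list

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coordinates(self, atoms) -> np.ndarray:
        idx = [r.atom_indices["CA"] for r in self.residues if "CA" in r.atom_indices]
        return np.array([atoms[i].coordinates for i in idx])


@dataclass
class MonosaccharideRing:
    """One detected sugar ring.

    ``ring_atoms`` are atom indices ordered anomeric carbon first and ring
    oxygen last (C1, C2, ..., O5 for a pyranose); ``atom_indices`` covers all
    heavy atoms of the residue.
    """

    ring_atoms: list
    ring_oxygen: int
    anomeric_carbon: int
    residue_name: str
    assigned_name: str
    residue_id: tuple
    anomeric_config: str = "b"
    atom_indices: list = field(default_factory=list)


@dataclass
class GlycosidicLinkage:
    """A glycosidic bond child-C1 -> bridging O -> parent-Cx.

    Torsion atom tuples are ordered child-to-parent so that the central bond
    of each dihedral is (atoms[1], atoms[2]):
    phi = O5-C1-O-C'x, psi = C1-O-C'x-C'x-1 and, for 1->6 linkages,
    omega = O-C'6-C'5-O'5.
    """

    child: int  # node index
    parent: int  # node index; -1 for the Asn anchor
    parent_position: int  # x in 1->x; 0 for the Asn linkage
    anomeric_config: str
    bridge_atom: int
    phi_atoms: tuple
    psi_atoms: tuple
    omega_atoms: tuple | None = None

    @property
    def is_one_six(self) -> bool:
        return self.parent_position == 6

    @property
    def n_torsions(self) -> int:
        return 3 if self.omega_atoms is not None else 2

    @property
    def torsion_atom_tuples(self) -> list:
        tup = [self.phi_atoms, self.psi_atoms]
        if self.omega_atoms is not None:
            tup.append(self.omega_atoms)
        return tup

    @property
    def linkage_key(self) -> tuple:
        """(anomeric configuration, parent position); the unit the torsion
        maps are indexed by. The Asn linkage is ('b', 0)."""
        return (self.anomeric_config, self.parent_position)


@dataclass
class AsnAnchor:
    residue_id: tuple
    atom_indices: dict  # heavy-atom name -> atom index


@dataclass
class GlycanTopology:
    canonical_string: str

    def __eq__(self, other):
        return self.canonical_string == getattr(other, "canonical_string", other)

    def __hash__(self):
        return hash(self.canonical_string)


@dataclass
class GlycanTree:
    """Rooted tree of monosaccharides plus the attachment Asn.

    Atom indices everywhere refer to ``atoms``/``coords`` of this tree.
    ``coords`` is the authoritative coordinate array; ``atoms`` carries
    identity metadata.
    """

    atoms: list
    coords: np.ndarray
    bonds: list
    nodes: list  # MonosaccharideRing
    edges: list  # GlycosidicLinkage between rings
    root: int = 0
    asn: AsnAnchor | None = None
    asn_linkage: GlycosidicLinkage | None = None
    non_n_linked: bool = False
    resolution: float | None = None
    source_id: str | None = None
    _canonical: str | None = None

    # -- topology ----------------------------------------------------------

    def children_of(self, node: int) -> list:
        out = [e for e in self.edges if e.parent == node]
        out.sort(key=lambda e: (-e.parent_position, self._subtree_string(e.child)))
        return out

    def parent_edge(self, node: int):
        for e in self.edges:
            if e.child == node:
                return e
        return None

    def canonical_order(self) -> list:
        """Node indices in canonical depth-first order (branches at a node
        ordered by descending parent position, i.e. the 1->6 arm first)."""
        order = []

        def visit(n):
            order.append(n)
            for e in self.children_of(n):
                visit(e.child)

        visit(self.root)
        return order

    def chart_order(self) -> list:
        """Depth-first order with 1->6 branches last (for GDT charts)."""
        order = []

        def visit(n):
            order.append(n)
            for e in sorted(
                (e for e in self.edges if e.parent == n),
                key=lambda e: (e.parent_position, self._subtree_string(e.child)),
            ):
                visit(e.child)

        visit(self.root)
        return order

    def _subtree_string(self, node: int) -> str:
        ring = self.nodes[node]
        kids = [e for e in self.edges if e.parent == node]
        kids.sort(key=lambda e: (-e.parent_position, self._subtree_string(e.child)))
        if not kids:
            return ring.assigned_name
        inner = ",".join(
            f"{e.anomeric_config}1-{e.parent_position}:{self._subtree_string(e.child)}"
            for e in kids
        )
        return f"{ring.assigned_name}[{inner}]"

    @property
    def canonical_string(self) -> str:
        if self._canonical is None:
            self._canonical = self._subtree_string(self.root)
        return self._canonical

    def __len__(self):
        return len(self.nodes)

    def residue_distance(self, node: int) -> int:
        """Number of glycosidic linkages from Asn, counting the linkage to
        Asn itself (the root residue is at distance 1)."""
        d = 1
        n = node
        while n != self.root:
            n = self.parent_edge(n).parent
            d += 1
        return d

    def crosses_one_six(self, node: int) -> bool:
        """True if the path from `node` to the root crosses a 1->6 edge."""
        n = node
        while n != self.root:
            e = self.parent_edge(n)
            if e.is_one_six:
                return True
            n = e.parent
        return False

    def all_linkages(self) -> list:
        """Glycosidic linkages including the Asn linkage, if present."""
        out = list(self.edges)
        if self.asn_linkage is not None:
            out.append(self.asn_linkage)
        return out

    # -- geometry ----------------------------------------------------------

    def ring_atom_indices(self, node_order=None) -> list:
        """Flat list of ring heavy-atom indices (C1..C5, O5 per residue)
        following `node_order` (canonical order by default)."""
        if node_order is None:
            node_order = self.canonical_order()
        idx = []
        for n in node_order:
            idx.extend(self.nodes[n].ring_atoms)
        return idx

    def ring_coords(self, coords=None, node_order=None) -> np.ndarray:
        c = self.coords if coords is None else coords
        return c[self.ring_atom_indices(node_order)]

    def asn_anchor_coords(self, coords=None) -> np.ndarray:
        if self.asn is None:
            raise ValueError("glycan tree carries no Asn anchor")
        missing = [a for a in ASN_HEAVY_ATOMS if a not in self.asn.atom_indices]
        if missing:
            raise ValueError(f"missing Asn side-chain atoms: {missing}")
        c = self.coords if coords is None else coords
        return c[[self.asn.atom_indices[a] for a in ASN_HEAVY_ATOMS]]

    def torsions(self, linkage: GlycosidicLinkage, coords=None) -> tuple:
        """(phi, psi[, omega]) of one linkage, in degrees."""
        c = self.coords if coords is None else coords
        return tuple(dihedral(*(c[i] for i in t)) for t in linkage.torsion_atom_tuples)

    def all_torsions(self, coords=None) -> dict:
        return {
            (lk.parent, lk.child): self.torsions(lk, coords)
            for lk in self.all_linkages()
        }

    def copy(self) -> "GlycanTree":
        return replace(self, coords=self.coords.copy(), _canonical=self._canonical)


def canonical_topology(tree: GlycanTree) -> GlycanTopology:
    """Deterministic sequence string of a glycan tree; invariant to atom and
    residue input order."""
    return GlycanTopology(tree.canonical_string)


def parse_topology(s: str):
    """Parse a canonical topology string into nested
    ``(name, [(config, position, subtree), ...])`` tuples."""
    pos = 0

    def parse_node():
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "[],:":
            pos += 1
        name = s[start:pos]
        if not name:
            raise GlycanParseError(f"empty residue name at offset {start} in {s!r}")
        children = []
        if pos < len(s) and s[pos] == "[":
            pos += 1
            while True:
                cfg = s[pos]
                if cfg not in "ab":
                    raise GlycanParseError(f"bad anomeric config {cfg!r} in {s!r}")
                if s[pos + 1 : pos + 3] != "1-":
                    raise GlycanParseError(f"bad linkage syntax at {pos} in {s!r}")
                pos += 3
                dstart = pos
                while s[pos].isdigit():
                    pos += 1
                position = int(s[dstart:pos])
                if s[pos] != ":":
                    raise GlycanParseError(f"expected ':' at {pos} in {s!r}")
                pos += 1
                children.append((cfg, position, parse_node()))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == "]":
                    pos += 1
                    break
        return (name, children)

    node = parse_node()
    if pos != len(s):
        raise GlycanParseError(f"trailing characters at offset {pos} in {s!r}")
    return node


def topology_length(s: str) -> int:
    """Number of monosaccharide residues in a topology string."""

    def count(node):
        return 1 + sum(count(c[2]) for c in node[1])

    return count(parse_topology(s))


# ---------------------------------------------------------------------------
# Structure parsing
# ---------------------------------------------------------------------------


def parse_structure(path):
    """Parse a PDB-format file.

    Returns ``(atoms, bonds, protein_chains, resolution)``. The first model
    is used; alternate locations keep the highest-occupancy conformer. Bonds
    combine CONECT records, LINK-derived connections, and distance-inferred
    bonds (< 1.8 A between heavy atoms) for HETATM residues that carry no
    CONECT records at all.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise GlycanParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise GlycanParseError(f"{path}: no models present")
    resolution = st.resolution if st.resolution > 0 else None
    model = st[0]

    atoms = []
    serial_to_index = {}
    protein_chains = {}
    for chain in model:
        residues = []
        for res in chain:
            rid = (chain.name, res.seqid.num, res.seqid.icode.strip())
            is_het = res.het_flag == "H"
            # highest-occupancy conformer per atom name
            best = {}
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atom_idx = {}
            for at in best.values():
                idx = len(atoms)
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_id=rid,
                        coordinates=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hetatm=is_het,
                        occupancy=at.occ,
                    )
                )
                serial_to_index[at.serial] = idx
                atom_idx[at.name] = idx
            if not is_het:
                info = gemmi.find_tabulated_residue(res.name)
                one = info.one_letter_code.upper() if info else "X"
                residues.append(
                    ProteinResidue(
                        name=res.name,
                        one_letter=one if one.isalpha() else "X",
                        residue_id=rid,
                        atom_indices=atom_idx,
                    )
                )
        if residues:
            protein_chains[chain.name] = ProteinChain(chain.name, residues)

    bonds = set()
    residues_with_conect = set()
    for serial, partners in st.conect_map.items():
        i = serial_to_index.get(serial)
        if i is None:
            continue
        residues_with_conect.add(atoms[i].residue_id)
        for p in partners:
            j = serial_to_index.get(p)
            if j is not None and i != j:
                bonds.add((min(i, j), max(i, j)))
    for con in st.connections:
        cra1 = model.find_cra(con.partner1)
        cra2 = model.find_cra(con.partner2)
        if cra1.atom is None or cra2.atom is None:
            continue
        i = serial_to_index.get(cra1.atom.serial)
        j = serial_to_index.get(cra2.atom.serial)
        if i is not None and j is not None and i != j:
            bonds.add((min(i, j), max(i, j)))

    # distance-based inference for HETATM residues lacking CONECT
    het_idx = [i for i, a in enumerate(atoms) if a.is_hetatm and a.residue_name != "HOH"]
    need = [i for i in het_idx if atoms[i].residue_id not in residues_with_conect]
    if need:
        # candidate partners: all HETATM atoms plus Asn side-chain nitrogens
        cand = list(het_idx)
        cand += [
            i
            for i, a in enumerate(atoms)
            if not a.is_hetatm and a.residue_name == "ASN" and a.name == "ND2"
        ]
        cand = sorted(set(cand))
        coords = np.array([atoms[i].coordinates for i in cand])
        tree = cKDTree(coords)
        pos = {i: k for k, i in enumerate(cand)}
        for i in need:
            for k in tree.query_ball_point(atoms[i].coordinates, BOND_INFERENCE_CUTOFF):
                j = cand[k]
                if j != i:
                    bonds.add((min(i, j), max(i, j)))
    if not any(atoms[i].is_hetatm or atoms[j].is_hetatm for i, j in bonds) and het_idx:
        logger.warning("%s: no bonds found or inferable for HETATM records", path)

    return atoms, sorted(bonds), protein_chains, resolution


# ---------------------------------------------------------------------------
# Ring detection and naming
# ---------------------------------------------------------------------------


def detect_rings(atoms, bonds) -> list:
    """Identify candidate monosaccharide rings: 5- or 6-membered cycles of
    carbons with exactly one oxygen, among HETATM atoms.

    The anomeric carbon is the ring carbon bonded to the ring oxygen and to
    an exocyclic oxygen (or, for an N-linked residue, nitrogen).
    """
    g = nx.Graph()
    het = [i for i, a in enumerate(atoms) if a.is_hetatm]
    g.add_nodes_from(het)
    hetset = set(het)
    g.add_edges_from((i, j) for i, j in bonds if i in hetset and j in hetset)
    full = nx.Graph()
    full.add_edges_from(bonds)

    rings = []
    seen = set()
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) not in (5, 6):
            continue
        key = frozenset(cycle)
        if key in seen:
            continue
        seen.add(key)
        elements = [atoms[i].element for i in cycle]
        if elements.count("O") != 1 or elements.count("C") != len(cycle) - 1:
            continue
        ring_o = cycle[elements.index("O")]
        # rotate cycle so the ring oxygen is last
        k = cycle.index(ring_o)
        cycle = cycle[k + 1 :] + cycle[: k + 1]
        # anomeric carbon: ring-oxygen neighbour with an exocyclic O/N
        candidates = []
        for c in (cycle[0], cycle[-2]):
            exo = [
                n
                for n in full.neighbors(c)
                if n not in key and atoms[n].element in ("O", "N")
            ]
            if exo:
                candidates.append((c, exo))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (not any(atoms[n].element == "O" for n in t[1]), atoms[t[0]].serial))
        anomeric = candidates[0][0]
        if anomeric == cycle[-2]:
            cycle = [cycle[-2]] + cycle[-3::-1] + [ring_o]
        ring = MonosaccharideRing(
            ring_atoms=list(cycle),
            ring_oxygen=ring_o,
            anomeric_carbon=anomeric,
            residue_name=atoms[anomeric].residue_name,
            assigned_name="",
            residue_id=atoms[anomeric].residue_id,
        )
        ring.atom_indices = [
            i for i, a in enumerate(atoms) if a.residue_id == ring.residue_id and a.is_hetatm
        ]
        rings.append(ring)
    rings.sort(key=lambda r: atoms[r.anomeric_carbon].serial)
    return rings


def identify_monosaccharide(ring: MonosaccharideRing, atoms, bonds) -> str:
    """Assign a monosaccharide name from the chemistry of the ring
    substituents, falling back to the PDB residue-name table.

    The chemical decision distinguishes N-acetyl hexosamines (nitrogen at
    C2), pentoses (no exocyclic carbon at C5), and 6-deoxy hexoses (C6
    without oxygen); stereochemical discrimination among Man/Glc/Gal relies
    on the residue-name table.
    """
    g = nx.Graph()
    g.add_edges_from(bonds)
    in_ring = set(ring.ring_atoms)
    name, config = RESIDUE_NAME_TABLE.get(ring.residue_name, (None, "b"))
    # chemical-group classification; decisive for the classes that do not
    # require stereochemistry (N at C2, missing C6, 6-deoxy C6)
    chem = None
    if len(ring.ring_atoms) == 6:
        c2 = ring.ring_atoms[1]
        c5 = ring.ring_atoms[4]
        if any(atoms[n].element == "N" for n in g.neighbors(c2) if n not in in_ring):
            chem = "GlcNAc"
        else:
            exo_c = [
                n for n in g.neighbors(c5) if n not in in_ring and atoms[n].element == "C"
            ]
            if not exo_c:
                chem = "Xyl"
            else:
                c6 = exo_c[0]
                if not any(atoms[n].element == "O" for n in g.neighbors(c6) if n != c5):
                    chem = "Fuc"
    assigned = name if name is not None else (chem if chem is not None else "UNK-sugar")
    ring.assigned_name = assigned
    ring.anomeric_config = config
    return assigned


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def _find_parent(atoms, g, rings, ring_of_atom, child_ring):
    """Locate the glycosidic attachment of `child_ring`: returns
    (parent_ring_index, parent_position, bridge_oxygen) or an Asn anchor
    marker ('asn', asn_nitrogen_index) or None for a free reducing end."""
    anomeric = child_ring.anomeric_carbon
    in_ring = set(child_ring.ring_atoms)
    for nbr in g.neighbors(anomeric):
        if nbr in in_ring:
            continue
        a = atoms[nbr]
        if a.element == "N" and a.residue_name == "ASN":
            return ("asn", nbr)
        if a.element != "O":
            continue
        for nn in g.neighbors(nbr):
            if nn == anomeric:
                continue
            if atoms[nn].element != "C":
                continue
            parent_idx = ring_of_atom.get(nn)
            if parent_idx is not None and rings[parent_idx] is not child_ring:
                pr = rings[parent_idx]
                position = pr.ring_atoms.index(nn) + 1
                return (parent_idx, position, nbr)
            # exocyclic C6 of a parent ring (1->6 linkage)
            for nnn in g.neighbors(nn):
                p2 = ring_of_atom.get(nnn)
                if (
                    p2 is not None
                    and rings[p2] is not child_ring
                    and nnn == rings[p2].ring_atoms[4]
                ):
                    return (p2, 6, nbr)
    return None


def build_glycan_trees(atoms, bonds, rings, protein_chains=None) -> list:
    """Assemble one :class:`GlycanTree` per connected carbohydrate
    component.

    The root is the ring whose anomeric carbon is bonded to an Asn
    side-chain nitrogen; components with no Asn attachment are returned
    flagged ``non_n_linked``. Components whose ring-linkage graph contains a
    cycle are rejected with a logged diagnostic.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from(bonds)
    ring_of_atom = {}
    for k, r in enumerate(rings):
        for i in r.ring_atoms:
            ring_of_atom[i] = k
    for r in rings:
        if not r.assigned_name:
            identify_monosaccharide(r, atoms, bonds)

    links = {}
    asn_of_ring = {}
    for k, r in enumerate(rings):
        hit = _find_parent(atoms, g, rings, ring_of_atom, r)
        if hit is None:
            continue
        if hit[0] == "asn":
            asn_of_ring[k] = hit[1]
        else:
            links[k] = hit

    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(range(len(rings)))
    comp_graph.add_edges_from((k, parent) for k, (parent, _, _) in links.items())

    trees = []
    for comp in sorted(nx.connected_components(comp_graph), key=min):
        comp = sorted(comp)
        n_edges = sum(1 for k in comp if k in links)
        if n_edges >= len(comp):
            logger.warning(
                "carbohydrate component %s contains a bond cycle; rejected", comp
            )
            continue
        roots = [k for k in comp if k not in links]
        root = next((k for k in roots if k in asn_of_ring), roots[0])
        asn_nitrogen = asn_of_ring.get(root)

        # collect atoms: all residue atoms of member rings (+ Asn heavy atoms)
        atom_ids = []
        for k in comp:
            atom_ids.extend(rings[k].atom_indices)
        asn_anchor = None
        if asn_nitrogen is not None:
            asn_rid = atoms[asn_nitrogen].residue_id
            asn_atoms = {
                a.name: i
                for i, a in enumerate(atoms)
                if a.residue_id == asn_rid and a.name in ASN_HEAVY_ATOMS
            }
            atom_ids.extend(sorted(asn_atoms.values()))
        atom_ids = sorted(set(atom_ids))
        remap = {old: new for new, old in enumerate(atom_ids)}
        tree_atoms = [atoms[i] for i in atom_ids]
        coords = np.array([a.coordinates for a in tree_atoms])
        tree_bonds = sorted(
            (remap[i], remap[j]) for i, j in bonds if i in remap and j in remap
        )

        node_of = {k: n for n, k in enumerate(comp)}
        nodes = []
        for k in comp:
            r = rings[k]
            nodes.append(
                MonosaccharideRing(
                    ring_atoms=[remap[i] for i in r.ring_atoms],
                    ring_oxygen=remap[r.ring_oxygen],
                    anomeric_carbon=remap[r.anomeric_carbon],
                    residue_name=r.residue_name,
                    assigned_name=r.assigned_name,
                    residue_id=r.residue_id,
                    anomeric_config=r.anomeric_config,
                    atom_indices=[remap[i] for i in r.atom_indices],
                )
            )

        edges = []
        for k in comp:
            if k not in links:
                continue
            parent_k, position, bridge = links[k]
            child_ring = rings[k]
            parent_ring = rings[parent_k]
            c1 = remap[child_ring.anomeric_carbon]
            o5c = remap[child_ring.ring_oxygen]
            obr = remap[bridge]
            if position == 6:
                gb = g
                c6 = next(
                    n
                    for n in gb.neighbors(bridge)
                    if n != child_ring.anomeric_carbon and atoms[n].element == "C"
                )
                cx = remap[c6]
                c5p = remap[parent_ring.ring_atoms[4]]
                o5p = remap[parent_ring.ring_oxygen]
                psi = (c1, obr, cx, c5p)
                omega = (obr, cx, c5p, o5p)
            else:
                cx = remap[parent_ring.ring_atoms[position - 1]]
                prev = remap[parent_ring.ring_atoms[position - 2]]
                psi = (c1, obr, cx, prev)
                omega = None
            edges.append(
                GlycosidicLinkage(
                    child=node_of[k],
                    parent=node_of[parent_k],
                    parent_position=position,
                    anomeric_config=child_ring.anomeric_config,
                    bridge_atom=obr,
                    phi_atoms=(o5c, c1, obr, cx),
                    psi_atoms=psi,
                    omega_atoms=omega,
                )
            )

        asn_linkage = None
        anchor = None
        if asn_nitrogen is not None:
            asn_rid = atoms[asn_nitrogen].residue_id
            asn_atoms = {
                a.name: remap[i]
                for i, a in enumerate(atoms)
                if a.residue_id == asn_rid and a.name in ASN_HEAVY_ATOMS and i in remap
            }
            anchor = AsnAnchor(residue_id=asn_rid, atom_indices=asn_atoms)
            rroot = nodes[node_of[root]]
            if "CG" in asn_atoms and "CB" in asn_atoms:
                asn_linkage = GlycosidicLinkage(
                    child=node_of[root],
                    parent=-1,
                    parent_position=0,
                    anomeric_config=rroot.anomeric_config,
                    bridge_atom=asn_atoms["ND2"],
                    phi_atoms=(
                        rroot.ring_oxygen,
                        rroot.anomeric_carbon,
                        asn_atoms["ND2"],
                        asn_atoms["CG"],
                    ),
                    psi_atoms=(
                        rroot.anomeric_carbon,
                        asn_atoms["ND2"],
                        asn_atoms["CG"],
                        asn_atoms["CB"],
                    ),
                )

        trees.append(
            GlycanTree(
                atoms=tree_atoms,
                coords=coords,
                bonds=tree_bonds,
                nodes=nodes,
                edges=edges,
                root=node_of[root],
                asn=anchor,
                asn_linkage=asn_linkage,
                non_n_linked=asn_nitrogen is None,
            )
        )
    return trees


def extract_glycans(path, min_length: int = 1) -> list:
    """Parse a structure file and return its N-glycan trees (convenience
    wrapper: parse, detect rings, name them, build trees)."""
    atoms, bonds, chains, resolution = parse_structure(path)
    rings = detect_rings(atoms, bonds)
    for r in rings:
        identify_monosaccharide(r, atoms, bonds)
    trees = build_glycan_trees(atoms, bonds, rings, chains)
    for t in trees:
        t.resolution = resolution
        t.source_id = str(path)
    return [t for t in trees if len(t) >= min_length]


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def tree_to_json(tree: GlycanTree) -> dict:
    d = {
        "canonical_string": tree.canonical_string,
        "source_id": tree.source_id,
        "resolution": tree.resolution,
        "non_n_linked": tree.non_n_linked,
        "nodes": [
            {
                "name": n.assigned_name,
                "residue_name": n.residue_name,
                "residue_id": list(n.residue_id),
            }
            for n in tree.nodes
        ],
        "edges": [
            {
                "child": e.child,
                "parent": e.parent,
                "parent_position": e.parent_position,
                "anomeric_config": e.anomeric_config,
                "torsions": list(tree.torsions(e)),
            }
            for e in tree.edges
        ],
    }
    if tree.asn_linkage is not None:
        d["asn_torsions"] = list(tree.torsions(tree.asn_linkage))
    return d


def save_trees_json(trees, path):
    with open(path, "w") as fh:
        json.dump([tree_to_json(t) for t in trees], fh, indent=1)


def write_glycan_pdb(tree: GlycanTree, path):
    """Write the glycan (and its Asn anchor, if any) as a PDB fragment."""
    from .pdbwriter import format_pdb  # local import; avoids cycle

    with open(path, "w") as fh:
        fh.write(format_pdb(tree.atoms, tree.coords, tree.bonds, tree.resolution))
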