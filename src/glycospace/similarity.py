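"""Pairwise structural similarity of N-glycans.

Three anchorings are supported, mirroring the three questions one can ask of
a glycan pair of identical sequence:

* ``glycan_rmsd`` — superpose on (and score over) all carbohydrate ring
  heavy atoms (C1..C5, O5 per residue): similarity of the glycan
  conformation itself.
* ``asn_anchored_distance`` — superpose on the glycosylated Asn heavy atoms
  only, then measure the ring-atom deviation with no further alignment:
  similarity of the glycan's orientation relative to the protein.
* ``stub_anchored_distance`` — superpose on the ring atoms of the first two
  residues, score the remaining residues: how well a partial (stub) glycan
  structure predicts the rest.

GDT-TS and per-atom GDT deviation charts quantify which parts of the chain
superpose well, and internal substructures are extracted by residue distance
from the Asn attachment point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    kabsch_rmsd_many,
    superpose,
)
from .glycan_io import GlycanTree, SequenceMismatchError

GDT_TS_CUTOFFS = (0.5, 1.0, 2.0)  # Angstrom
GDT_CHART_BINS = (1.0, 2.0, 3.0, 4.0)  # Angstrom; fifth bin is >= 4


@dataclass
class AtomCorrespondence:
    """Matched atom index lists between two trees of identical sequence."""

    pairs: list  # list of (index in A, index in B)
    anchor_set: list  # subset of `pairs` used for superposition
    scored_set: list  # subset of `pairs` used for distance computation


@dataclass
class SubstructureSpec:
    """Internal substructure: residues within `max_residue_distance`
    glycosidic linkages of Asn (counting the Asn linkage), optionally
    dropping residues whose path to the root crosses a 1->6 linkage."""

    max_residue_distance: int
    exclude_one_six: bool = False

    def __post_init__(self):
        if self.max_residue_distance < 1:
            raise ValueError("max_residue_distance must be >= 1")


def _check_same_topology(a: GlycanTree, b: GlycanTree):
    if a.canonical_string != b.canonical_string:
        raise SequenceMismatchError(
            f"sequence mismatch: {a.canonical_string} vs {b.canonical_string}"
        )


def ring_correspondence(a: GlycanTree, b: GlycanTree) -> AtomCorrespondence:
    """Ring heavy-atom correspondence in canonical node order."""
    _check_same_topology(a, b)
    ia = a.ring_atom_indices()
    ib = b.ring_atom_indices()
    pairs = list(zip(ia, ib))
    return AtomCorrespondence(pairs=pairs, anchor_set=pairs, scored_set=pairs)


def glycan_rmsd(a: GlycanTree, b: GlycanTree) -> float:
    """Ring-heavy-atom RMSD after least-squares superposition of the two
    glycan structures; defined only for identical sequences."""
    _check_same_topology(a, b)
    return superpose(a.ring_coords(), b.ring_coords()).rmsd


def asn_anchored_distance(a: GlycanTree, b: GlycanTree) -> float:
    """Root-mean-square ring-atom deviation after superposing only the
    glycosylated Asn heavy atoms (no further alignment): measures the
    glycan's orientation with respect to the protein."""
    _check_same_topology(a, b)
    sp = superpose(a.asn_anchor_coords(), b.asn_anchor_coords())
    moved = sp.transform(a.ring_coords())
    return float(np.sqrt(np.mean(np.sum((moved - b.ring_coords()) ** 2, axis=1))))


def _stub_indices(tree: GlycanTree):
    order = tree.canonical_order()
    if len(order) < 3:
        raise ValueError("stub anchoring needs at least 3 residues")
    anchor = tree.ring_atom_indices(order[:2])
    scored = tree.ring_atom_indices(order[2:])
    return anchor, scored


def stub_anchored_distance(a: GlycanTree, b: GlycanTree) -> float:
    """Root-mean-square deviation of the distal residues after superposing
    the ring atoms of the first two residues from the root (the partial
    glycan "stub" frequently resolved in crystal structures)."""
    _check_same_topology(a, b)
    anchor_a, scored_a = _stub_indices(a)
    anchor_b, scored_b = _stub_indices(b)
    sp = superpose(a.coords[anchor_a], b.coords[anchor_b])
    moved = sp.transform(a.coords[scored_a])
    return float(
        np.sqrt(np.mean(np.sum((moved - b.coords[scored_b]) ** 2, axis=1)))
    )


# ---------------------------------------------------------------------------
# GDT
# ---------------------------------------------------------------------------


def _gdt_fraction(xa: np.ndarray, xb: np.ndarray, seeds, cutoff: float) -> float:
    """Largest fraction of corresponded atoms superposable within `cutoff`,
    by deterministic seed-and-extend iteration."""
    n = len(xa)
    best = 0
    for seed in seeds:
        current = np.asarray(seed)
        for _ in range(10):
            if len(current) < 3:
                break
            try:
                sp = superpose(xa[current], xb[current])
            except DegenerateGeometryError:
                break
            d = np.linalg.norm(sp.transform(xa) - xb, axis=1)
            within = np.flatnonzero(d <= cutoff)
            if len(within) == len(current) and np.array_equal(within, current):
                break
            if len(within) < 3:
                break
            current = within
        else:
            current = np.asarray(seed)
        if len(current) >= 3:
            sp = superpose(xa[current], xb[current])
            d = np.linalg.norm(sp.transform(xa) - xb, axis=1)
            best = max(best, int((d <= cutoff).sum()))
    return best / n


def _gdt_seeds(tree: GlycanTree):
    """Seed atom sets: the global set plus every contiguous run of one, two
    or three residues along a root-to-leaf path (a single residue's six
    ring atoms already define a superposition, and short runs are needed to
    discover small well-fitting regions)."""
    order = tree.canonical_order()
    pos_in_flat = {n: k for k, n in enumerate(order)}
    seeds = [np.arange(6 * len(order))]
    paths = []

    def walk(n, path):
        path = path + [n]
        kids = [e.child for e in tree.edges if e.parent == n]
        if not kids:
            paths.append(path)
        for c in kids:
            walk(c, path)

    walk(tree.root, [])
    seen = set()
    for path in paths:
        for run_len in (1, 2, 3):
            for k in range(len(path) - run_len + 1):
                run = tuple(path[k : k + run_len])
                if run in seen:
                    continue
                seen.add(run)
                seeds.append(
                    np.concatenate([6 * pos_in_flat[n] + np.arange(6) for n in run])
                )
    return seeds


def gdt_ts(a: GlycanTree, b: GlycanTree, cutoffs=GDT_TS_CUTOFFS) -> float:
    """Global distance test (total score): mean over distance cutoffs of the
    maximal fraction of ring atoms superposable within each cutoff."""
    _check_same_topology(a, b)
    xa, xb = a.ring_coords(), b.ring_coords()
    seeds = _gdt_seeds(a)
    return float(np.mean([_gdt_fraction(xa, xb, seeds, c) for c in cutoffs]))


def gdt_chart(pairs) -> dict:
    """Per-atom deviation categories for a list of same-sequence tree pairs.

    For each pair, the ring atoms (depth-first order with 1->6 branches
    last) are binned by deviation after whole-glycan superposition:
    bins 0..4 for <1, <2, <3, <4 and >= 4 Angstrom. Returns the bin matrix
    (n_pairs x n_atoms), the atom order and a mask of 1->6-branch atoms.
    """
    first = pairs[0][0]
    order = first.chart_order()
    one_six_atom = np.repeat(
        [first.crosses_one_six(n) for n in order], 6
    )
    bins = np.empty((len(pairs), 6 * len(order)), dtype=int)
    for k, (a, b) in enumerate(pairs):
        _check_same_topology(a, b)
        xa = a.ring_coords(node_order=a.chart_order())
        xb = b.ring_coords(node_order=b.chart_order())
        sp = superpose(xa, xb)
        d = np.linalg.norm(sp.transform(xa) - xb, axis=1)
        bins[k] = np.digitize(d, GDT_CHART_BINS)
    return {
        "bins": bins,
        "node_order": order,
        "one_six_mask": one_six_atom,
    }


# ---------------------------------------------------------------------------
# Substructures
# ---------------------------------------------------------------------------


def substructure_by_distance(tree: GlycanTree, spec: SubstructureSpec) -> GlycanTree:
    """Induced subtree of the residues within `spec.max_residue_distance`
    linkages of Asn (inclusive of the Asn linkage); with
    ``exclude_one_six``, residues whose path to the root crosses a 1->6
    linkage are dropped."""
    keep = [
        n
        for n in range(len(tree.nodes))
        if tree.residue_distance(n) <= spec.max_residue_distance
        and not (spec.exclude_one_six and tree.crosses_one_six(n))
    ]
    if not keep:
        raise ValueError("substructure specification leaves no residues")
    keep_set = set(keep)
    remap = {n: i for i, n in enumerate(keep)}
    nodes = [tree.nodes[n] for n in keep]
    edges = [
        _remap_linkage(e, remap)
        for e in tree.edges
        if e.parent in keep_set and e.child in keep_set
    ]
    asn_linkage = tree.asn_linkage
    if asn_linkage is not None:
        from dataclasses import replace

        asn_linkage = replace(asn_linkage, child=remap[tree.root])
    sub = GlycanTree(
        atoms=tree.atoms,
        coords=tree.coords,
        bonds=tree.bonds,
        nodes=nodes,
        edges=edges,
        root=remap[tree.root],
        asn=tree.asn,
        asn_linkage=asn_linkage,
        non_n_linked=tree.non_n_linked,
        resolution=tree.resolution,
        source_id=tree.source_id,
    )
    return sub


def _remap_linkage(e, remap):
    from dataclasses import replace

    return replace(e, child=remap[e.child], parent=remap[e.parent])


def _subset_tree(tree: GlycanTree, keep: list) -> GlycanTree:
    from dataclasses import replace

    keep_set = set(keep)
    remap = {n: i for i, n in enumerate(keep)}
    asn_linkage = tree.asn_linkage
    if asn_linkage is not None:
        asn_linkage = replace(asn_linkage, child=remap[tree.root])
    return GlycanTree(
        atoms=tree.atoms,
        coords=tree.coords,
        bonds=tree.bonds,
        nodes=[tree.nodes[n] for n in keep],
        edges=[
            _remap_linkage(e, remap)
            for e in tree.edges
            if e.parent in keep_set and e.child in keep_set
        ],
        root=remap[tree.root],
        asn=tree.asn,
        asn_linkage=asn_linkage,
        non_n_linked=tree.non_n_linked,
        resolution=tree.resolution,
        source_id=tree.source_id,
    )


def common_rooted_subtree(a: GlycanTree, b: GlycanTree):
    """Trim two N-glycans to their maximal common rooted fragment.

    Nodes are matched from the root down by residue name and by the
    (anomeric configuration, parent position) of each linkage; the returned
    pair of trees has identical canonical topology and can be compared with
    any of the pairwise measures. Useful when two deposited structures
    resolve different portions of the same glycan.
    """
    keep_a, keep_b = [], []

    def walk(na, nb):
        if a.nodes[na].assigned_name != b.nodes[nb].assigned_name:
            return
        keep_a.append(na)
        keep_b.append(nb)
        kids_b = {
            (e.anomeric_config, e.parent_position): e.child
            for e in b.edges
            if e.parent == nb
        }
        for e in (e for e in a.edges if e.parent == na):
            match = kids_b.get((e.anomeric_config, e.parent_position))
            if match is not None:
                walk(e.child, match)

    walk(a.root, b.root)
    if not keep_a:
        raise SequenceMismatchError("glycans share no common rooted fragment")
    return _subset_tree(a, keep_a), _subset_tree(b, keep_b)


# ---------------------------------------------------------------------------
# Batched pair distances (pool backgrounds and pair tables)
# ---------------------------------------------------------------------------


def batch_pair_distances(
    conformers: np.ndarray,
    pairs: np.ndarray,
    tree: GlycanTree,
    anchoring: str = "ring",
    substructure: SubstructureSpec | None = None,
) -> np.ndarray:
    """Vectorised pair distances over conformers of one tree.

    `conformers` is (n_conformers, n_atoms, 3); `pairs` an (n_pairs, 2)
    index array. Anchoring 'ring' gives the superposed ring-atom RMSD,
    'asn' the Asn-anchored and 'stub' the two-residue-stub-anchored
    distance, matching the single-pair functions.
    """
    target = tree if substructure is None else substructure_by_distance(tree, substructure)
    ring_idx = np.asarray(target.ring_atom_indices())
    ia, ib = pairs[:, 0], pairs[:, 1]
    if anchoring == "ring":
        return kabsch_rmsd_many(conformers[ia][:, ring_idx], conformers[ib][:, ring_idx])
    if anchoring == "asn":
        from .glycan_io import ASN_HEAVY_ATOMS

        anchor_idx = np.asarray([tree.asn.atom_indices[a] for a in ASN_HEAVY_ATOMS])
        scored_idx = ring_idx
    elif anchoring == "stub":
        anchor, scored = _stub_indices(target)
        anchor_idx = np.asarray(anchor)
        scored_idx = np.asarray(scored)
    else:
        raise ValueError(f"unknown anchoring {anchoring!r}")
    return _batch_anchored(conformers, ia, ib, anchor_idx, scored_idx)


def _batch_anchored(conformers, ia, ib, anchor_idx, scored_idx):
    """Superpose each pair on the anchor atoms, score RMS deviation over the
    scored atoms (batched Kabsch with explicit rotations)."""
    a = conformers[ia][:, anchor_idx]
    b = conformers[ib][:, anchor_idx]
    ca = a.mean(axis=1, keepdims=True)
    cb = b.mean(axis=1, keepdims=True)
    cov = np.einsum("pij,pik->pjk", a - ca, b - cb)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(np.einsum("pij,pjk->pik", u, vt))
    d = np.ones_like(s)
    d[:, -1] = np.sign(det)
    # rot maps centered A onto centered B: R = V diag(d) U^T
    rot = np.einsum("pki,pk,pjk->pij", vt, d, u)
    sa = conformers[ia][:, scored_idx]
    sb = conformers[ib][:, scored_idx]
    moved = np.einsum("pij,paj->pai", rot, sa - ca) + cb
    return np.sqrt(np.mean(np.sum((moved - sb) ** 2, axis=-1), axis=-1))
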