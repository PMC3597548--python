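"""Synthetic glycoprotein fixtures with controlled glycan conformational
structure.

The generator emulates the statistical structure of a curated N-glycan
dataset: families of glycoproteins that share a glycan sequence, where
"homologous" family members carry tightly clustered glycan conformations
(small Gaussian torsional noise around a family reference) on similar
protein scaffolds, while "non-homologous" instances are independent draws
from the accessible torsion space on unrelated scaffolds.

Non-homologous torsions are drawn, per linkage, from a mixture of a
protein-restrained component (a cold Boltzmann draw over the accessible
cells, 50 K by default, emulating the extra contact energy a protein
surface adds on top of the free disaccharide map) and the free
uniform-over-accessible background, with the background weight growing with
residue distance from the Asn attachment and strongly inflated for 1->6
linkages (a depth-4 1->6 arm is fully free). This emulates the physics attributed to real crystal structures:
contacts with the protein restrict the proximal residues most, so deposited
conformations are more concentrated than the free random background, the
more so the closer a residue sits to the protein, while the 1->6 arms are
essentially free. The pure uniform draw is reserved for the random
background pool itself.

Everything is emitted as plain PDB files (HETATM + CONECT + REMARK 2
resolution) plus a JSON ground-truth manifest, so every pipeline stage is
testable without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import conformer, residues
from .geometry import nerf, superpose
from .glycan_io import AtomRecord, GlycanTree
from .pdbwriter import format_pdb

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

#: default benchmark topologies: the pentasaccharide core (with its 1->6
#: branch) and a linear tetrasaccharide.
DEFAULT_TOPOLOGIES = (
    "GlcNAc[b1-4:GlcNAc[b1-4:Man[a1-6:Man,a1-3:Man]]]",
    "GlcNAc[b1-4:GlcNAc[b1-4:Man[a1-3:Man]]]",
)


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    ``torsion_noise_sd`` is the per-torsion Gaussian noise (degrees) of
    homologous family members around their family reference;
    ``one_six_noise_multiplier`` inflates it on 1->6 linkages.
    ``restrained_temperature`` (K) sets the protein-restrained Boltzmann
    component of the deposited-conformation draw;
    ``background_weight0``/``background_weight_growth`` set the probability
    (at residue distance 1, and its per-linkage growth) that a linkage
    escapes the restraint and is drawn from the free background instead,
    multiplied (and capped at 1) for 1->6 linkages by
    ``one_six_background_multiplier``: with the defaults a depth-4 1->6
    arm is drawn entirely from the free background.
    """

    topologies: tuple = DEFAULT_TOPOLOGIES
    n_homologous_families: int = 2
    family_size: int = 5
    n_nonhomologous: int = 12
    torsion_noise_sd: float = 10.0
    one_six_noise_multiplier: float = 2.0
    restrained_temperature: float = 50.0
    background_weight0: float = 0.05
    background_weight_growth: float = 1.8
    one_six_background_multiplier: float = 4.0
    protein_scaffold_size: int = 200
    family_divergence: float = 0.25
    resolution_range: tuple = (1.5, 2.9)
    include_decoys: bool = True
    clash_cutoff: float = conformer.DEFAULT_CLASH_CUTOFF
    spacing: float = conformer.DEFAULT_SPACING
    temperature: float = conformer.DEFAULT_TEMPERATURE
    threshold: float = conformer.DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self):
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        if self.torsion_noise_sd < 0:
            raise ValueError("torsion_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Protein scaffold
# ---------------------------------------------------------------------------


@dataclass
class Scaffold:
    sequence: str
    asn_site: int  # 0-based residue index of the glycosylated Asn
    atoms: list  # AtomRecord (protein)
    coords: np.ndarray
    family_id: int


def _helix_backbone(n_res, axis_offset=np.zeros(3), reverse=False):
    """Idealised alpha-helix backbone (N, CA, C, O, CB per residue)."""
    radius, twist, rise = 2.3, np.radians(100.0), 1.5
    out = []
    for i in range(n_res):
        t = twist * i
        z = rise * i
        if reverse:
            z = -z
        ca = np.array([radius * np.cos(t), radius * np.sin(t), z]) + axis_offset
        # local frame: radial out, tangential, axial
        radial = np.array([np.cos(t), np.sin(t), 0.0])
        tang = np.array([-np.sin(t), np.cos(t), 0.0])
        axial = np.array([0.0, 0.0, -1.0 if reverse else 1.0])
        n = ca - 0.9 * tang - 1.1 * axial + 0.4 * radial
        c = ca + 0.9 * tang + 1.0 * axial + 0.4 * radial
        o = c + 1.1 * radial + 0.4 * tang
        cb = ca + 1.3 * radial + 0.6 * tang
        out.append({"N": n, "CA": ca, "C": c, "O": o, "CB": cb})
    return out


def make_scaffold(size, family_id, divergence, rng, reference_sequence=None,
                  asn_site=None) -> Scaffold:
    """Generate a synthetic two-helix protein scaffold with one N-X-T
    sequon whose Asn carries a full side chain.

    Within a family, pass the family's `reference_sequence` and `asn_site`:
    the emitted sequence differs from the reference by `divergence` random
    substitutions. Across families sequences are independent draws.
    """
    if size < 20:
        raise ValueError("scaffold must have at least 20 residues")
    half = size // 2
    if reference_sequence is None:
        seq = rng.choice(list(AMINO_ACIDS), size=size)
        if asn_site is None:
            asn_site = int(rng.integers(half // 4, half - half // 4))
    else:
        if asn_site is None:
            raise ValueError("asn_site required with a reference sequence")
        seq = np.array(list(reference_sequence))
        n_sub = int(round(divergence * size))
        protected = {asn_site, asn_site + 1, asn_site + 2}
        positions = [i for i in range(size) if i not in protected]
        chosen = rng.choice(positions, size=min(n_sub, len(positions)), replace=False)
        for i in chosen:
            seq[i] = rng.choice(list(AMINO_ACIDS))
    # force the sequon at the glycosylation site (also when the requested
    # site differs from the reference scaffold's)
    seq[asn_site] = "N"
    if seq[asn_site + 1] == "P":
        seq[asn_site + 1] = rng.choice(list(AMINO_ACIDS.replace("P", "")))
    seq[asn_site + 2] = "T"
    sequence = "".join(seq)

    bb1 = _helix_backbone(half)
    bb2 = _helix_backbone(size - half, axis_offset=np.array([9.0, 0.0, (half - 1) * 1.5]),
                          reverse=True)
    backbone = bb1 + bb2

    atoms = []
    coords = []
    for i, (one, res) in enumerate(zip(sequence, backbone)):
        resname = THREE_LETTER[one]
        names = ["N", "CA", "C", "O"] + (["CB"] if one != "G" else [])
        pts = dict(res)
        if i == asn_site:
            # full Asn side chain, idealised geometry pointing outward
            pts["CG"] = nerf(pts["N"], pts["CA"], pts["CB"], 1.52, 113.0, -60.0)
            pts["OD1"] = nerf(pts["CA"], pts["CB"], pts["CG"], 1.23, 121.0, -58.0)
            pts["ND2"] = nerf(pts["CA"], pts["CB"], pts["CG"], 1.33, 116.5, 122.0)
            names += ["CG", "OD1", "ND2"]
        for nm in names:
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1,
                    name=nm,
                    element=nm[0],
                    residue_name=resname,
                    residue_id=("A", i + 1, ""),
                    coordinates=pts[nm],
                    is_hetatm=False,
                )
            )
            coords.append(pts[nm])
    return Scaffold(
        sequence=sequence,
        asn_site=asn_site,
        atoms=atoms,
        coords=np.array(coords),
        family_id=family_id,
    )


# ---------------------------------------------------------------------------
# Glycan conformations
# ---------------------------------------------------------------------------


def _linkage_depth(tree: GlycanTree, linkage) -> int:
    return tree.residue_distance(linkage.child)


def sample_reference_torsions(tree, maps, config, rng) -> list:
    """One 'deposited-conformation' draw per linkage (a non-homologous
    instance or a family reference): restrained Boltzmann draw, escaping to
    the free uniform-over-accessible background with a probability that
    grows with residue distance from Asn (doubled for 1->6 linkages)."""
    out = []
    for lk in tree.all_linkages():
        grid = maps[lk.linkage_key]
        w = config.background_weight0 * config.background_weight_growth ** (
            _linkage_depth(tree, lk) - 1
        )
        if lk.is_one_six:
            w *= config.one_six_background_multiplier
        if rng.uniform() < min(1.0, w):
            angles = grid.sample(rng)  # free background
        else:
            angles = grid.sample(rng, temperature=config.restrained_temperature)
        out.append(np.atleast_1d(angles))
    return out


def sample_family_reference(tree, machine, maps, config, rng, max_retries=100):
    """Clash-checked family reference conformation (torsion list)."""
    _, torsions = make_glycan_conformation(
        tree, machine, maps, config, rng, "random", max_retries=max_retries
    )
    return torsions


def _apply_torsions(tree, machine, torsion_list):
    coords = tree.coords.copy()
    for li, angles in enumerate(torsion_list):
        machine.set_torsions(coords, li, angles)
    return coords


def make_glycan_conformation(tree, machine, maps, config, rng, mode,
                             reference=None, max_retries: int = 100):
    """Clash-checked torsion assignment.

    mode 'random': fresh depth-tempered Boltzmann draw; mode 'homologous':
    `reference` plus Gaussian noise of sd `torsion_noise_sd` (doubled on
    1->6 linkages by default). Returns (coords, torsions)."""
    for _ in range(max_retries):
        if mode == "random":
            torsions = sample_reference_torsions(tree, maps, config, rng)
        elif mode == "homologous":
            torsions = []
            for lk, ref in zip(machine.linkages, reference):
                sd = config.torsion_noise_sd
                if lk.is_one_six:
                    sd *= config.one_six_noise_multiplier
                torsions.append(np.asarray(ref) + rng.normal(0.0, sd, size=len(ref)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        coords = _apply_torsions(tree, machine, torsions)
        if conformer.clash_energy(coords, tree) <= config.clash_cutoff:
            return coords, torsions
    raise RuntimeError(
        f"no clash-free {mode} conformation found in {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Instance emission
# ---------------------------------------------------------------------------


def make_glycan_instance(topology, scaffold, config, rng, mode="random",
                         reference=None, resolution=None, maps=None):
    """Assemble one glycoprotein fixture: the scaffold plus a glycan in the
    requested conformational mode attached at the scaffold's Asn.

    Returns (pdb_text, ground_truth_record).
    """
    tree = conformer.build_initial_structure(topology)
    if maps is None:
        maps = conformer.torsion_maps_for(
            tree, config.spacing, config.temperature, config.threshold
        )
    machine = conformer.TorsionMachine(tree)
    coords, torsions = make_glycan_conformation(
        tree, machine, maps, config, rng, mode, reference
    )

    # graft onto the scaffold by superposing on the (CB, CG, ND2) triangle:
    # its internal geometry is identical in builder and scaffold (same
    # template constants), so the map is exactly rigid and the recorded
    # glycosidic torsions survive the graft unchanged
    asn_rid = ("A", scaffold.asn_site + 1, "")
    scaffold_asn = {
        a.name: a.coordinates for a in scaffold.atoms if a.residue_id == asn_rid
    }
    anchor_names = ["CB", "CG", "ND2"]
    tree_anchor = np.array(
        [coords[tree.asn.atom_indices[n]] for n in anchor_names]
    )
    target = np.array([scaffold_asn[n] for n in anchor_names])
    sp = superpose(tree_anchor, target)
    glycan_atom_idx = [i for i, a in enumerate(tree.atoms) if a.is_hetatm]
    glycan_xyz = sp.transform(coords[glycan_atom_idx])

    if resolution is None:
        resolution = float(rng.uniform(*config.resolution_range))

    atoms = list(scaffold.atoms)
    out_coords = [a.coordinates for a in scaffold.atoms]
    serial_of_tree_atom = {}
    next_resnum = len(scaffold.sequence)
    # renumber sugar residues after the protein
    resmap = {}
    for k, i in enumerate(glycan_atom_idx):
        a = tree.atoms[i]
        if a.residue_id not in resmap:
            next_resnum += 1
            resmap[a.residue_id] = next_resnum
        serial_of_tree_atom[i] = len(atoms)
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                residue_id=("A", resmap[a.residue_id], ""),
                coordinates=glycan_xyz[k],
                is_hetatm=True,
            )
        )
        out_coords.append(glycan_xyz[k])

    # bonds among glycan atoms + the Asn ND2 link
    nd2_global = next(
        k for k, a in enumerate(atoms)
        if a.residue_id == asn_rid and a.name == "ND2"
    )
    bonds = []
    for i, j in tree.bonds:
        gi = serial_of_tree_atom.get(i)
        gj = serial_of_tree_atom.get(j)
        if gi is not None and gj is not None:
            bonds.append((gi, gj))
        elif gi is not None and tree.atoms[j].name == "ND2":
            bonds.append((min(gi, nd2_global), max(gi, nd2_global)))
        elif gj is not None and tree.atoms[i].name == "ND2":
            bonds.append((min(gj, nd2_global), max(gj, nd2_global)))

    text = format_pdb(atoms, np.array(out_coords), sorted(bonds), resolution)
    record = {
        "topology": topology,
        "mode": mode,
        "scaffold_family": scaffold.family_id,
        "asn_site": scaffold.asn_site + 1,
        "resolution": resolution,
        "torsions": [list(np.round(t, 6)) for t in torsions],
        "reference_torsions": (
            [list(np.round(np.asarray(r), 6)) for r in reference]
            if reference is not None
            else None
        ),
    }
    return text, record


def _free_disaccharide_pdb(rng) -> str:
    """Decoy: a sugar chain with no Asn attachment (non-N-linked)."""
    tree = conformer.build_initial_structure("GlcNAc[b1-4:GlcNAc]")
    glycan_idx = [i for i, a in enumerate(tree.atoms) if a.is_hetatm]
    remap = {i: k for k, i in enumerate(glycan_idx)}
    atoms = []
    for i in glycan_idx:
        a = tree.atoms[i]
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                residue_id=("A", a.residue_id[1], ""),
                coordinates=tree.coords[i],
                is_hetatm=True,
            )
        )
    bonds = sorted(
        (remap[i], remap[j]) for i, j in tree.bonds if i in remap and j in remap
    )
    return format_pdb(atoms, tree.coords[glycan_idx], bonds,
                      float(rng.uniform(1.5, 2.9)))


def make_benchmark(config: SyntheticConfig, out_dir) -> dict:
    """Emit the full benchmark: per topology, `n_homologous_families`
    families of `family_size` instances plus `n_nonhomologous` independent
    instances, with filter decoys; returns (and writes) the ground-truth
    manifest. Deterministic under ``config.seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {"config": asdict(config), "instances": {}}
    family_counter = 0

    for ti, topology in enumerate(config.topologies):
        tree = conformer.build_initial_structure(topology)
        maps = conformer.torsion_maps_for(
            tree, config.spacing, config.temperature, config.threshold
        )
        machine = conformer.TorsionMachine(tree)
        for fi in range(config.n_homologous_families):
            family_counter += 1
            ref_scaffold = make_scaffold(
                config.protein_scaffold_size, family_counter, 0.0, rng
            )
            reference = sample_family_reference(tree, machine, maps, config, rng)
            for k in range(config.family_size):
                scaffold = make_scaffold(
                    config.protein_scaffold_size,
                    family_counter,
                    config.family_divergence,
                    rng,
                    reference_sequence=ref_scaffold.sequence,
                    asn_site=ref_scaffold.asn_site,
                )
                name = f"t{ti}_hom_f{family_counter:02d}_{k:02d}"
                text, rec = make_glycan_instance(
                    topology, scaffold, config, rng,
                    mode="homologous", reference=reference, maps=maps,
                )
                rec["family"] = family_counter
                (out / f"{name}.pdb").write_text(text)
                manifest["instances"][name] = rec
        for k in range(config.n_nonhomologous):
            family_counter += 1
            scaffold = make_scaffold(
                config.protein_scaffold_size, family_counter, 0.0, rng
            )
            name = f"t{ti}_rnd_{k:02d}"
            text, rec = make_glycan_instance(
                topology, scaffold, config, rng, mode="random", maps=maps
            )
            rec["family"] = None
            (out / f"{name}.pdb").write_text(text)
            manifest["instances"][name] = rec

    if config.include_decoys:
        short_topo = "GlcNAc[b1-4:GlcNAc[b1-4:Man]]"
        scaffold = make_scaffold(config.protein_scaffold_size, 9001, 0.0, rng)
        text, rec = make_glycan_instance(short_topo, scaffold, config, rng)
        rec["decoy"] = "short_glycan"
        (out / "decoy_short.pdb").write_text(text)
        manifest["instances"]["decoy_short"] = rec

        scaffold = make_scaffold(config.protein_scaffold_size, 9002, 0.0, rng)
        text, rec = make_glycan_instance(
            config.topologies[0], scaffold, config, rng, resolution=3.5
        )
        rec["decoy"] = "bad_resolution"
        (out / "decoy_badres.pdb").write_text(text)
        manifest["instances"]["decoy_badres"] = rec

        (out / "decoy_free.pdb").write_text(_free_disaccharide_pdb(rng))
        manifest["instances"]["decoy_free"] = {"decoy": "non_n_linked"}

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def true_pair_label(manifest, name_a: str, name_b: str) -> str:
    """Ground-truth pair label from the manifest: homologous iff the two
    instances belong to the same family."""
    ra = manifest["instances"][name_a]
    rb = manifest["instances"][name_b]
    fa, fb = ra.get("family"), rb.get("family")
    if fa is not None and fa == fb:
        return "homologous"
    return "non_homologous"
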