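"""Shared fixtures: programmatically generated PDB fixtures and session-wide
conformer pools (no binary assets; everything is built at test time)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from glycospace import conformer, residues

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from glycospace.glycan_io import AtomRecord
from glycospace.pdbwriter import format_pdb
from glycospace.synthetic_data import SyntheticConfig, make_benchmark

MAN3 = "GlcNAc[b1-4:GlcNAc[b1-4:Man[a1-6:Man,a1-3:Man]]]"
CHITOBIOSE = "GlcNAc[b1-4:GlcNAc]"


def free_sugar_pdb(name="GlcNAc", config="b"):
    """PDB text of one free monosaccharide (O1 retained) with full CONECT."""
    tpl = residues.build_residue(name, config)
    names = list(tpl.coords)
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=nm,
            element=nm[0],
            residue_name="NAG" if name == "GlcNAc" else name.upper()[:3],
            residue_id=("A", 1, ""),
            coordinates=tpl.coords[nm],
            is_hetatm=True,
        )
        for i, nm in enumerate(names)
    ]
    idx = {nm: i for i, nm in enumerate(names)}
    bonds = [(idx[a], idx[b]) for a, b in tpl.bonds]
    coords = np.array([tpl.coords[nm] for nm in names])
    return format_pdb(atoms, coords, bonds, resolution=1.8)


def tree_pdb(topology, resolution=1.8):
    """PDB text of a builder glycan (with its Asn anchor) at default
    torsions."""
    tree = conformer.build_initial_structure(topology)
    return format_pdb(tree.atoms, tree.coords, tree.bonds, resolution), tree


@pytest.fixture(scope="session")
def man3_tree():
    return conformer.build_initial_structure(MAN3)


@pytest.fixture(scope="session")
def man3_pool():
    """Small conformer pool of the pentasaccharide core, shared across
    tests."""
    return conformer.generate_pool(MAN3, n_conformers=600, seed=42)


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """Compact synthetic benchmark (one pass of the generator)."""
    out = tmp_path_factory.mktemp("bench")
    cfg = SyntheticConfig(family_size=3, n_nonhomologous=5, seed=3)
    manifest = make_benchmark(cfg, out)
    return out, manifest, cfg
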