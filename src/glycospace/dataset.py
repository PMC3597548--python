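"""Dataset assembly and the full analysis pipeline.

Given a directory of glycoprotein structure files, this module extracts the
N-glycan instances, groups them by identical glycan sequence, filters by
resolution / glycan length / group size, classifies pairs as homologous or
non-homologous from parent-protein sequence similarity (30% cutoff; >= 90%
excluded as highly homologous; glycosylation sites farther than 10 A apart
after chain superposition are non-homologous), and measures pairwise glycan
similarity under three anchorings together with its statistical significance
against each sequence's random conformer background.
"""

from __future__ import annotations

import json
import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import conformer, significance, similarity
from .geometry import superpose
from .glycan_io import (
    GlycanTree,
    build_glycan_trees,
    detect_rings,
    identify_monosaccharide,
    parse_structure,
)
from .similarity import SubstructureSpec

logger = logging.getLogger(__name__)

HOMOLOGY_CUTOFF = 30.0  # percent sequence similarity
HIGH_HOMOLOGY_CUTOFF = 90.0
ASN_CA_CUTOFF = 10.0  # Angstrom
LOCAL_SHELL = 6.0  # Angstrom
MIN_LOCAL_RESIDUES = 5
SUBSTRUCTURE_SPECS = {
    "d3": SubstructureSpec(3),
    "d4": SubstructureSpec(4),
    "d4no16": SubstructureSpec(4, exclude_one_six=True),
}


@dataclass
class GlycanInstance:
    source_id: str
    tree: GlycanTree
    protein_sequence: str
    asn_site: int
    resolution: float | None
    chain: object = None  # ProteinChain of the parent chain
    atoms: list = field(default_factory=list)  # full-structure atoms

    @property
    def topology(self) -> str:
        return self.tree.canonical_string


@dataclass
class PairClassification:
    label: str  # homologous | non_homologous | excluded_high_homology | excluded_redundant
    sequence_similarity: float
    asn_ca_distance: float | None = None


@dataclass
class LocalStructure:
    residues: list  # ProteinResidue
    ca_coordinates: np.ndarray
    excluded: bool


def load_instances(paths) -> list:
    """Extract all N-linked glycan instances from structure files."""
    out = []
    for path in sorted(Path(p) for p in paths):
        try:
            atoms, bonds, chains, resolution = parse_structure(path)
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        rings = detect_rings(atoms, bonds)
        for r in rings:
            identify_monosaccharide(r, atoms, bonds)
        for tree in build_glycan_trees(atoms, bonds, rings, chains):
            if tree.non_n_linked:
                continue
            tree.resolution = resolution
            tree.source_id = path.stem
            chain_id, asn_num, _ = tree.asn.residue_id
            chain = chains.get(chain_id)
            out.append(
                GlycanInstance(
                    source_id=path.stem,
                    tree=tree,
                    protein_sequence=chain.sequence if chain else "",
                    asn_site=asn_num,
                    resolution=resolution,
                    chain=chain,
                    atoms=atoms,
                )
            )
    return out


def load_directory(directory) -> list:
    return load_instances(sorted(Path(directory).glob("*.pdb")))


def filter_instances(
    instances,
    min_length: int = 4,
    max_resolution: float = 3.0,
    min_group_size: int = 20,
) -> dict:
    """Group instances by canonical glycan sequence, dropping instances with
    resolution above `max_resolution` or fewer than `min_length` residues,
    then dropping groups below `min_group_size`."""
    groups = {}
    for inst in instances:
        if inst.resolution is None or inst.resolution > max_resolution:
            continue
        if len(inst.tree) < min_length:
            continue
        groups.setdefault(inst.topology, []).append(inst)
    dropped = [t for t, g in groups.items() if len(g) < min_group_size]
    for t in dropped:
        logger.info("dropping group %s with %d instances", t, len(groups[t]))
        del groups[t]
    return groups


# ---------------------------------------------------------------------------
# Homology classification
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner() -> Align.PairwiseAligner:
    # conservative gap penalties: the classifier must not let unrelated
    # sequences drift above the 30% cutoff through gap-assisted alignments
    a = Align.PairwiseAligner()
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -25.0
    a.extend_gap_score = -3.0
    a.mode = "global"
    return a


def _align(seq_a: str, seq_b: str):
    if not seq_a or not seq_b:
        raise ValueError("empty protein sequence")
    return _aligner().align(seq_a, seq_b)[0]


def _aligned_positions(alignment):
    """(i, j) index pairs of aligned residues."""
    out = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        out.extend(zip(range(a0, a1), range(b0, b1)))
    return out


def sequence_similarity(seq_a: str, seq_b: str) -> float:
    """Percent sequence similarity: globally aligned residue pairs with a
    positive substitution score, over the shorter sequence length."""
    alignment = _align(seq_a, seq_b)
    positives = sum(
        1
        for i, j in _aligned_positions(alignment)
        if _BLOSUM62[seq_a[i], seq_b[j]] > 0
    )
    return 100.0 * positives / min(len(seq_a), len(seq_b))


def classify_pair(a: GlycanInstance, b: GlycanInstance) -> PairClassification:
    """Homology classification of a same-sequence glycan structure pair.

    Order of the rules: identical source structures are redundant;
    similarity below 30% is non-homologous regardless of geometry; 90% and
    above is excluded as highly homologous; otherwise the parent chains are
    superposed on sequence-aligned Calpha atoms and the pair is homologous
    only if the glycosylated Asn Calpha atoms land within 10 A.
    """
    if a.source_id == b.source_id:
        return PairClassification("excluded_redundant", 100.0)
    sim = sequence_similarity(a.protein_sequence, b.protein_sequence)
    if sim < HOMOLOGY_CUTOFF:
        return PairClassification("non_homologous", sim)
    if sim >= HIGH_HOMOLOGY_CUTOFF:
        return PairClassification("excluded_high_homology", sim)
    dist = _asn_ca_distance(a, b)
    if dist is None:
        logger.warning(
            "missing Calpha atoms for %s/%s; falling back to the sequence rule",
            a.source_id,
            b.source_id,
        )
        return PairClassification("homologous", sim)
    label = "non_homologous" if dist > ASN_CA_CUTOFF else "homologous"
    return PairClassification(label, sim, asn_ca_distance=dist)


def _asn_ca_distance(a: GlycanInstance, b: GlycanInstance):
    if a.chain is None or b.chain is None:
        return None
    alignment = _align(a.protein_sequence, b.protein_sequence)
    pairs = _aligned_positions(alignment)
    ca_a, ca_b = [], []
    for i, j in pairs:
        ra = a.chain.residues[i].atom_indices.get("CA")
        rb = b.chain.residues[j].atom_indices.get("CA")
        if ra is not None and rb is not None:
            ca_a.append(a.atoms[ra].coordinates)
            ca_b.append(b.atoms[rb].coordinates)
    if len(ca_a) < 3:
        return None

    def asn_ca(inst):
        for r in inst.chain.residues:
            if r.residue_id == inst.tree.asn.residue_id and "CA" in r.atom_indices:
                return inst.atoms[r.atom_indices["CA"]].coordinates
        return None

    pa, pb = asn_ca(a), asn_ca(b)
    if pa is None or pb is None:
        return None
    sp = superpose(np.array(ca_a), np.array(ca_b))
    return float(np.linalg.norm(sp.transform(pa) - pb))


# ---------------------------------------------------------------------------
# Local protein structure
# ---------------------------------------------------------------------------


def extract_local_structure(instance: GlycanInstance) -> LocalStructure:
    """Protein residues with any heavy atom within 6 A (closed interval) of
    any glycan heavy atom; instances with fewer than 5 such residues are
    flagged excluded from the local-structure analysis."""
    glycan_xyz = np.array(
        [a.coordinates for a in instance.tree.atoms if a.is_hetatm]
    )
    residues = []
    cas = []
    chains = [instance.chain] if instance.chain is not None else []
    for chain in chains:
        for r in chain.residues:
            xyz = np.array([instance.atoms[i].coordinates for i in r.atom_indices.values()])
            d = np.linalg.norm(xyz[:, None, :] - glycan_xyz[None, :, :], axis=-1)
            if d.min() <= LOCAL_SHELL:
                residues.append(r)
                ca = r.atom_indices.get("CA")
                cas.append(
                    instance.atoms[ca].coordinates if ca is not None else xyz.mean(axis=0)
                )
    return LocalStructure(
        residues=residues,
        ca_coordinates=np.array(cas) if cas else np.empty((0, 3)),
        excluded=len(residues) < MIN_LOCAL_RESIDUES,
    )


def tm_d0(length: int) -> float:
    """TM-score distance scale for a structure of `length` residues (floored
    at 0.5 A for the very short local structures handled here)."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def local_similarity(a: LocalStructure, b: LocalStructure, correspondence) -> float:
    """TM-score of two local structures over a given residue correspondence
    (index pairs into a.residues / b.residues), normalised by the smaller
    structure's length; superposition is least-squares on the corresponded
    Calpha atoms."""
    if len(correspondence) < 3:
        raise ValueError("correspondence must contain at least 3 residue pairs")
    xa = np.array([a.ca_coordinates[i] for i, _ in correspondence])
    xb = np.array([b.ca_coordinates[j] for _, j in correspondence])
    l_min = min(len(a.residues), len(b.residues))
    d0 = tm_d0(l_min)
    sp = superpose(xa, xb)
    d = np.linalg.norm(sp.transform(xa) - xb, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_min)


def fetch_pdb(pdb_id: str, directory=".") -> Path:
    """Download one RCSB entry (convenience; no analysis depends on it)."""
    dest = Path(directory) / f"{pdb_id.lower()}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=30) as resp:
        dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    input_dir: str | None = None
    min_length: int = 4
    max_resolution: float = 3.0
    min_group_size: int = 20
    pool_size: int = 2000
    subsample: int = 500
    clash_cutoff: float = conformer.DEFAULT_CLASH_CUTOFF
    spacing: float = conformer.DEFAULT_SPACING
    temperature: float = conformer.DEFAULT_TEMPERATURE
    threshold: float = conformer.DEFAULT_THRESHOLD
    seed: int = 0
    make_plots: bool = False


@dataclass
class TopologyResult:
    topology: str
    instances: list
    pair_table: pd.DataFrame
    gev_params: dict  # measure name -> GEVParams
    backgrounds: dict  # measure name -> np.ndarray
    gdt_chart: dict | None


@dataclass
class PipelineReport:
    """Results of one full pipeline run: per-sequence pair tables with
    p-values under every anchoring and substructure, the fitted null
    parameters, and aggregate statistics."""

    config: PipelineConfig
    topologies: dict  # topology string -> TopologyResult

    def pair_table(self) -> pd.DataFrame:
        return pd.concat(
            [t.pair_table for t in self.topologies.values()], ignore_index=True
        )

    def summary(self) -> pd.DataFrame:
        """Aggregate per-class statistics across all glycan sequences."""
        table = self.pair_table()
        rows = []
        for label, sub in table.groupby("label"):
            row = {"label": label, "n_pairs": len(sub)}
            for col in ("rmsd", "asn_dist", "stub_dist", "gdt_ts"):
                row[f"mean_{col}"] = sub[col].mean()
            for col in table.columns:
                if col.startswith("p_"):
                    row[f"frac_sig_{col[2:]}"] = float((sub[col] < 0.05).mean())
                    row[f"mean_{col}"] = sub[col].mean()
            rows.append(row)
        return pd.DataFrame(rows).set_index("label")

    def background_means(self) -> dict:
        return {
            topo: float(np.mean(t.backgrounds["rmsd"]))
            for topo, t in self.topologies.items()
        }

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_table().to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
        self.summary().to_csv(out / "summary.tsv", sep="\t", float_format="%.6g")
        gev = {
            topo: {
                measure: {
                    "location": p.location,
                    "scale": p.scale,
                    "shape": p.shape,
                    "fit_quality": p.fit_quality,
                }
                for measure, p in t.gev_params.items()
            }
            for topo, t in self.topologies.items()
        }
        with open(out / "gev_params.json", "w") as fh:
            json.dump(gev, fh, indent=1, sort_keys=True)
        if self.config.make_plots:
            from . import plotting

            plotting.save_report_figures(self, out)


_MEASURES = ("rmsd", "asn_dist", "stub_dist")


def run_pipeline(config: PipelineConfig, instances=None) -> PipelineReport:
    """Run the full analysis: filter and group instances, build per-sequence
    random backgrounds, fit the GEV nulls, and measure + classify every
    same-sequence structure pair. Every random stage is seeded from
    ``config.seed``."""
    if instances is None:
        if config.input_dir is None:
            raise ValueError("config.input_dir or an instance list is required")
        instances = load_directory(config.input_dir)
    groups = filter_instances(
        instances, config.min_length, config.max_resolution, config.min_group_size
    )
    if not groups:
        census = {}
        for inst in instances:
            census[inst.topology] = census.get(inst.topology, 0) + 1
        raise ValueError(
            f"no glycan sequence passes the filters; census of parsed input: {census}"
        )

    results = {}
    for gi, (topo, members) in enumerate(sorted(groups.items())):
        results[topo] = _analyse_group(topo, members, config, seed=config.seed + 1000 * gi)
    return PipelineReport(config=config, topologies=results)


def _substructure_specs_for(tree: GlycanTree) -> dict:
    """The applicable named substructure specs for one topology (a spec that
    leaves no residues is skipped)."""
    specs = {}
    for name, spec in SUBSTRUCTURE_SPECS.items():
        try:
            similarity.substructure_by_distance(tree, spec)
        except ValueError:
            continue
        specs[name] = spec
    return specs


def _analyse_group(topo, members, config, seed) -> TopologyResult:
    pool = conformer.generate_pool(
        topo,
        n_conformers=config.pool_size,
        clash_cutoff=config.clash_cutoff,
        seed=seed,
        spacing=config.spacing,
        temperature=config.temperature,
        threshold=config.threshold,
    )
    specs = _substructure_specs_for(pool.tree)

    backgrounds = {}
    gev_params = {}
    for name, anchoring in (("rmsd", "ring"), ("asn_dist", "asn"), ("stub_dist", "stub")):
        backgrounds[name] = conformer.background_rmsd_distribution(
            pool, subsample=config.subsample, anchoring=anchoring
        )
        gev_params[name] = significance.fit_gev(backgrounds[name])
    for name, spec in specs.items():
        backgrounds[f"sub_{name}"] = conformer.background_rmsd_distribution(
            pool, subsample=config.subsample, substructure=spec
        )
        gev_params[f"sub_{name}"] = significance.fit_gev(backgrounds[f"sub_{name}"])

    rows = []
    chart_pairs = []
    n = len(members)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = members[i], members[j]
            cls = classify_pair(a, b)
            row = {
                "id_a": a.source_id,
                "id_b": b.source_id,
                "topology": topo,
                "label": cls.label,
                "sequence_similarity": cls.sequence_similarity,
                "asn_ca_distance": cls.asn_ca_distance,
                "rmsd": similarity.glycan_rmsd(a.tree, b.tree),
                "asn_dist": similarity.asn_anchored_distance(a.tree, b.tree),
                "stub_dist": similarity.stub_anchored_distance(a.tree, b.tree),
                "gdt_ts": similarity.gdt_ts(a.tree, b.tree),
            }
            for name, spec in specs.items():
                sa = similarity.substructure_by_distance(a.tree, spec)
                sb = similarity.substructure_by_distance(b.tree, spec)
                row[f"sub_{name}_rmsd"] = similarity.glycan_rmsd(sa, sb)
            rows.append(row)
            if cls.label in ("homologous", "non_homologous"):
                chart_pairs.append((a.tree, b.tree))
    table = pd.DataFrame(rows)
    for name in _MEASURES:
        table[f"p_{name}"] = significance.p_values(table[name].to_numpy(), gev_params[name])
    for name in specs:
        table[f"p_sub_{name}"] = significance.p_values(
            table[f"sub_{name}_rmsd"].to_numpy(), gev_params[f"sub_{name}"]
        )

    chart = None
    if chart_pairs and any(e.is_one_six for e in members[0].tree.edges):
        chart = similarity.gdt_chart(chart_pairs)
    return TopologyResult(
        topology=topo,
        instances=members,
        pair_table=table,
        gev_params=gev_params,
        backgrounds=backgrounds,
        gdt_chart=chart,
    )
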