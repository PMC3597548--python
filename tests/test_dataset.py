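"""Dataset assembly: filters, homology classification, local structures,
TM-scores and pipeline orchestration."""

import numpy as np
import pytest

from glycospace import dataset
from glycospace.dataset import (
    LocalStructure,
    PipelineConfig,
    classify_pair,
    extract_local_structure,
    filter_instances,
    local_similarity,
    run_pipeline,
    sequence_similarity,
    tm_d0,
)
from glycospace.glycan_io import AtomRecord, ProteinChain, ProteinResidue
from glycospace.synthetic_data import SyntheticConfig, make_glycan_instance, make_scaffold

from conftest import MAN3


@pytest.fixture(scope="module")
def instances(benchmark_dir):
    out, manifest, cfg = benchmark_dir
    return dataset.load_directory(out), manifest, cfg


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def test_filter_drops_bad_resolution_and_short_glycans(instances):
    insts, manifest, cfg = instances
    by_id = {i.source_id: i for i in insts}
    assert "decoy_badres" in by_id  # parsed fine...
    assert by_id["decoy_badres"].resolution == pytest.approx(3.5)
    groups = filter_instances(insts, min_group_size=2)
    kept = {i.source_id for g in groups.values() for i in g}
    assert "decoy_badres" not in kept  # ...but dropped by the 3 A filter
    assert "decoy_short" not in kept  # 3-residue glycan dropped
    assert "decoy_free" not in kept  # non-N-linked never loaded


def test_filter_resolution_threshold_closed():
    class FakeTree(list):
        canonical_string = "T"

    insts = []
    for res in (2.9, 3.0, 3.2):
        t = FakeTree([None] * 4)
        inst = dataset.GlycanInstance(f"r{res}", t, "", 1, res)
        inst.tree = t
        insts.append(inst)
    groups = filter_instances(insts, min_group_size=1)
    kept = {i.source_id for g in groups.values() for i in g}
    assert kept == {"r2.9", "r3.0"}  # 3.0 kept (closed threshold), 3.2 dropped


def test_filter_group_size_threshold():
    class FakeTree(list):
        canonical_string = "T"

    def build(n):
        return [
            dataset.GlycanInstance(f"i{k}", FakeTree([None] * 4), "", 1, 2.0)
            for k in range(n)
        ]

    assert filter_instances(build(19), min_group_size=20) == {}
    assert len(filter_instances(build(20), min_group_size=20)["T"]) == 20


def test_filter_length_threshold():
    class FakeTree(list):
        def __init__(self, n, s):
            super().__init__([None] * n)
            self.canonical_string = s

    three = dataset.GlycanInstance("three", FakeTree(3, "S3"), "", 1, 2.0)
    four = dataset.GlycanInstance("four", FakeTree(4, "S4"), "", 1, 2.0)
    groups = filter_instances([three, four], min_group_size=1)
    assert set(groups) == {"S4"}


# ---------------------------------------------------------------------------
# Sequence similarity
# ---------------------------------------------------------------------------


def test_sequence_similarity_identity():
    assert sequence_similarity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0


def test_sequence_similarity_single_negative_substitution():
    # G -> W scores negative in BLOSUM62: 5 positive pairs over 6 positions
    assert sequence_similarity("ACDEFG", "ACDEFW") == pytest.approx(100 * 5 / 6)


def test_sequence_similarity_shuffled_below_cutoff():
    """A 200-residue sequence vs composition-preserving shuffles stays
    below the 30% homology cutoff (checked over 20 seeds)."""
    rng = np.random.default_rng(0)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aa, size=200))
    for seed in range(20):
        shuffled = "".join(
            np.random.default_rng(seed).permutation(list(base))
        )
        assert sequence_similarity(base, shuffled) < 30.0


def test_sequence_similarity_rejects_empty():
    with pytest.raises(ValueError):
        sequence_similarity("", "ACD")


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------


def test_classify_low_similarity_is_non_homologous(instances):
    insts, manifest, cfg = instances
    a = next(i for i in insts if i.source_id == "t0_hom_f01_00")
    b = next(i for i in insts if i.source_id == "t0_rnd_00")
    cls = classify_pair(a, b)
    assert cls.label == "non_homologous"
    assert cls.sequence_similarity < 30.0


def test_classify_family_pair_is_homologous(instances):
    insts, manifest, cfg = instances
    a = next(i for i in insts if i.source_id == "t0_hom_f01_00")
    b = next(i for i in insts if i.source_id == "t0_hom_f01_01")
    cls = classify_pair(a, b)
    assert cls.label == "homologous"
    assert 30.0 <= cls.sequence_similarity < 90.0
    assert cls.asn_ca_distance < 10.0


def test_classify_identical_source_redundant(instances):
    insts, _, _ = instances
    a = insts[0]
    assert classify_pair(a, a).label == "excluded_redundant"


def test_classify_high_homology_excluded(tmp_path):
    """Nearly identical parent sequences (>= 90% similarity) are excluded."""
    rng = np.random.default_rng(5)
    cfg = SyntheticConfig(seed=5)
    ref = make_scaffold(120, 1, 0.0, rng)
    close = make_scaffold(120, 1, 0.02, rng, reference_sequence=ref.sequence,
                          asn_site=ref.asn_site)
    insts = []
    for k, scaf in enumerate((ref, close)):
        text, _ = make_glycan_instance(MAN3, scaf, cfg, rng)
        p = tmp_path / f"h{k}.pdb"
        p.write_text(text)
        insts += dataset.load_instances([p])
    cls = classify_pair(*insts)
    assert cls.sequence_similarity >= 90.0
    assert cls.label == "excluded_high_homology"


def test_classify_distant_sites_non_homologous(tmp_path):
    """Similar sequences whose glycosylation sites sit > 10 A apart after
    chain superposition are non-homologous."""
    rng = np.random.default_rng(6)
    cfg = SyntheticConfig(seed=6)
    ref = make_scaffold(120, 1, 0.0, rng)
    shifted = make_scaffold(
        120, 1, 0.2, rng, reference_sequence=ref.sequence, asn_site=ref.asn_site + 12
    )
    insts = []
    for k, scaf in enumerate((ref, shifted)):
        text, _ = make_glycan_instance(MAN3, scaf, cfg, rng)
        p = tmp_path / f"s{k}.pdb"
        p.write_text(text)
        insts += dataset.load_instances([p])
    cls = classify_pair(*insts)
    assert 30.0 <= cls.sequence_similarity < 90.0
    assert cls.asn_ca_distance > 10.0
    assert cls.label == "non_homologous"


def test_classify_symmetric(instances):
    insts, _, _ = instances
    a, b = insts[0], insts[3]
    ca = classify_pair(a, b)
    cb = classify_pair(b, a)
    assert ca.label == cb.label
    assert ca.sequence_similarity == pytest.approx(cb.sequence_similarity)


# ---------------------------------------------------------------------------
# Local structure and TM-score
# ---------------------------------------------------------------------------


def test_local_structure_shell(instances):
    insts, _, _ = instances
    ls = extract_local_structure(insts[0])
    assert len(ls.residues) >= 5
    assert not ls.excluded


def test_local_structure_far_glycan_excluded(instances):
    insts, _, _ = instances
    inst = insts[1]
    import copy

    far = copy.deepcopy(inst)
    for a in far.tree.atoms:
        if a.is_hetatm:
            a.coordinates = a.coordinates + 500.0
    ls = extract_local_structure(far)
    assert len(ls.residues) == 0
    assert ls.excluded


def _chain_of_cas(positions):
    atoms = []
    residues = []
    for k, p in enumerate(positions):
        atoms.append(
            AtomRecord(k + 1, "CA", "C", "GLY", ("A", k + 1, ""), np.array(p, float), False)
        )
        residues.append(
            ProteinResidue("GLY", "G", ("A", k + 1, ""), {"CA": k})
        )
    return atoms, ProteinChain("A", residues)


def test_local_structure_boundary_inclusive():
    """A residue whose only atom sits at exactly 6.0 A is included (closed
    interval)."""
    glycan_atom = AtomRecord(99, "C1", "C", "NAG", ("A", 99, ""), np.zeros(3), True)

    class T:
        atoms = [glycan_atom]

    positions = [(6.0, 0, 0), (0, 6.000001, 0), (3, 0, 0), (0, 0, 5), (4, 0, 0), (0, 4, 0)]
    atoms, chain = _chain_of_cas(positions)
    inst = dataset.GlycanInstance("x", T(), "G" * 6, 99, 2.0, chain=chain, atoms=atoms)
    ls = extract_local_structure(inst)
    ids = {r.residue_id[1] for r in ls.residues}
    assert 1 in ids  # exactly 6.0 -> included
    assert 2 not in ids  # just beyond
    assert len(ls.residues) == 5
    assert not ls.excluded


def test_tm_score_identity_symmetry_and_bound():
    rng = np.random.default_rng(7)
    pos = rng.normal(scale=5, size=(20, 3))
    _, chain = _chain_of_cas(pos)
    a = LocalStructure(chain.residues, pos.copy(), False)
    b = LocalStructure(chain.residues, pos.copy(), False)
    corr = [(i, i) for i in range(20)]
    assert local_similarity(a, b, corr) == pytest.approx(1.0)
    # scrambled far structure scores low
    far = LocalStructure(chain.residues, pos + rng.normal(scale=40, size=pos.shape), False)
    assert local_similarity(a, far, corr) < 0.1
    # normalisation by the smaller structure: symmetric under swap
    short = LocalStructure(chain.residues[:12], pos[:12].copy(), False)
    corr2 = [(i, i) for i in range(12)]
    s1 = local_similarity(short, LocalStructure(chain.residues, pos.copy(), False), corr2)
    s2 = local_similarity(LocalStructure(chain.residues, pos.copy(), False), short, corr2)
    assert s1 == pytest.approx(s2)
    with pytest.raises(ValueError):
        local_similarity(a, b, corr[:2])


def test_tm_d0_floor():
    assert tm_d0(5) == 0.5
    assert tm_d0(100) > 2.0


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def test_pipeline_empty_input_raises(tmp_path):
    with pytest.raises(ValueError, match="census"):
        run_pipeline(PipelineConfig(input_dir=str(tmp_path)))


def test_pair_enumeration_count(instances):
    insts, manifest, cfg = instances
    groups = filter_instances(insts, min_group_size=2)
    cfgp = PipelineConfig(pool_size=250, subsample=80, min_group_size=2, seed=1)
    rep = run_pipeline(cfgp, instances=insts)
    for topo, tr in rep.topologies.items():
        n = len(groups[topo])
        assert len(tr.pair_table) == n * (n - 1) // 2


def test_pipeline_deterministic_rerun(tmp_path, instances):
    insts, _, _ = instances
    cfgp = PipelineConfig(pool_size=200, subsample=60, min_group_size=2, seed=9)
    for d in ("one", "two"):
        rep = run_pipeline(cfgp, instances=insts)
        rep.save(tmp_path / d)
    for name in ("pairs.tsv", "summary.tsv", "gev_params.json"):
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


def test_ground_truth_agreement(instances):
    """classify_pair reproduces the generator's labels exactly for all
    non-excluded pairs."""
    from glycospace.synthetic_data import true_pair_label

    insts, manifest, cfg = instances
    groups = filter_instances(insts, min_group_size=2)
    for topo, members in groups.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                cls = classify_pair(a, b)
                if cls.label.startswith("excluded"):
                    continue
                assert cls.label == true_pair_label(manifest, a.source_id, b.source_id)
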