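"""Torsion maps, the internal-coordinate builder, steric energies and the
rejection-sampled conformer pool."""

import numpy as np
import pytest
from scipy import stats

from glycospace import conformer
from glycospace.conformer import (
    KB,
    AccessibleSetError,
    LinkageType,
    TorsionGrid,
    TorsionMachine,
    UnknownLinkageError,
    accessible_set,
    background_rmsd_distribution,
    boltzmann_probabilities,
    build_initial_structure,
    build_torsion_map,
    clash_energy,
    generate_pool,
    lj_energy,
    scan_linkage_energy,
)
from glycospace.residues import LJ_PARAMS, UnsupportedResidueError

from conftest import CHITOBIOSE, MAN3


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------


def test_grid_point_counts():
    """5 degree spacing: 72^2 = 5,184 points for two-torsion linkages and
    72^3 = 373,248 for the three-torsion 1->6 linkage."""
    g2 = scan_linkage_energy(LinkageType("b", 4), energy_fn=lambda r, *p: np.zeros_like(r))
    assert g2.n_points == 5184
    g3 = scan_linkage_energy(LinkageType("a", 6), energy_fn=lambda r, *p: np.zeros_like(r))
    assert g3.n_points == 373248
    for spacing, dims, expect in ((10.0, 2, 36**2), (15.0, 2, 24**2)):
        g = scan_linkage_energy(
            LinkageType("b", 4), energy_fn=lambda r, *p: np.zeros_like(r), spacing=spacing
        )
        assert g.n_points == expect == (360 / spacing) ** dims


def test_constant_energy_fn_gives_zero_grid():
    g = scan_linkage_energy(
        LinkageType("b", 2), energy_fn=lambda r, *p: np.zeros_like(r), spacing=30.0
    )
    assert np.allclose(g.energies, 0.0)


def test_unknown_linkage_type_rejected():
    with pytest.raises(UnknownLinkageError):
        scan_linkage_energy(LinkageType("b", 5))


def test_boltzmann_uniform_and_two_point():
    g = TorsionGrid(LinkageType("b", 4), 30.0, energies=np.zeros((12, 12)))
    boltzmann_probabilities(g, 300.0)
    assert np.allclose(g.probabilities, 1.0 / 144)
    assert g.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
    # two-point grid with an energy gap of kT ln 2 -> probabilities 2/3, 1/3
    e = np.array([[0.0, 300.0 * KB * np.log(2.0)]])
    g2 = TorsionGrid(LinkageType("b", 4), 180.0, energies=e)
    boltzmann_probabilities(g2, 300.0)
    assert np.allclose(g2.probabilities, [[2.0 / 3.0, 1.0 / 3.0]])


def test_boltzmann_nonfinite_energies_get_zero_probability():
    e = np.array([[0.0, np.inf], [1.0, np.nan]])
    g = TorsionGrid(LinkageType("b", 4), 180.0, energies=e)
    boltzmann_probabilities(g, 300.0)
    assert g.probabilities[0, 1] == 0.0
    assert g.probabilities[1, 1] == 0.0
    assert g.probabilities.sum() == pytest.approx(1.0)


def test_accessible_set_arithmetic():
    # uniform 5,184-point grid: p ~ 1.93e-4 each, all above 1e-4
    g = TorsionGrid(LinkageType("b", 4), 5.0, energies=np.zeros((72, 72)))
    boltzmann_probabilities(g)
    accessible_set(g, 1e-4)
    assert g.accessible.all()
    # uniform 373,248-point grid: p ~ 2.7e-6 each, empty set -> error
    g3 = TorsionGrid(LinkageType("a", 6), 5.0, energies=np.zeros((72, 72, 72)))
    boltzmann_probabilities(g3)
    with pytest.raises(AccessibleSetError):
        accessible_set(g3, 1e-4)
    # delta-function probability map -> exactly one accessible cell
    e = np.full((72, 72), 1e6)
    e[10, 20] = 0.0
    gd = TorsionGrid(LinkageType("b", 4), 5.0, energies=e)
    boltzmann_probabilities(gd)
    accessible_set(gd, 1e-4)
    assert gd.accessible.sum() == 1
    assert gd.accessible[10, 20]


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------


def test_build_single_glcnac():
    tree = build_initial_structure("GlcNAc")
    sugar_atoms = [a for a in tree.atoms if a.is_hetatm]
    # 15 heavy atoms for the free residue; linked to Asn, O1 is replaced by
    # the side-chain nitrogen, leaving 14 sugar atoms (the free-residue count
    # is covered by the parser fixture test)
    assert len(sugar_atoms) == 14
    ring = tree.nodes[0].ring_atoms
    closure = np.linalg.norm(tree.coords[ring[0]] - tree.coords[ring[-1]])
    assert closure == pytest.approx(1.48, abs=0.01)


def test_build_chitobiose_default_torsions_roundtrip():
    tree = build_initial_structure(CHITOBIOSE)
    lk = tree.edges[0]
    phi, psi = tree.torsions(lk)
    assert phi == pytest.approx(-80.0, abs=1e-6)
    assert psi == pytest.approx(120.0, abs=1e-6)


def test_build_man3_canonical_roundtrip():
    tree = build_initial_structure(MAN3)
    assert tree.canonical_string == MAN3
    assert len(tree.nodes) == 5
    assert sum(e.is_one_six for e in tree.edges) == 1


def test_build_rejects_unsupported_residue():
    with pytest.raises(UnsupportedResidueError):
        build_initial_structure("Frob")


def test_build_rejects_impossible_one_six():
    # xylose has no C6: a 1->6 child cannot attach
    with pytest.raises(UnknownLinkageError):
        build_initial_structure("Xyl[a1-6:Man]")


# ---------------------------------------------------------------------------
# set_torsion
# ---------------------------------------------------------------------------


def test_set_torsion_roundtrip_and_locality(man3_tree):
    tree = man3_tree
    machine = TorsionMachine(tree)
    li = next(i for i, lk in enumerate(machine.linkages) if lk.parent != -1)
    lk = machine.linkages[li]
    coords = tree.coords.copy()
    machine.set_torsions(coords, li, np.array([60.0, -120.0, 45.0])[: lk.n_torsions])
    got = machine.get_torsions(coords, li)
    assert got[0] == pytest.approx(60.0, abs=1e-6)
    assert got[1] == pytest.approx(-120.0, abs=1e-6)
    # parent-side atoms unmoved
    moved_sets = [set(m) for _, m, _ in machine.specs[li]]
    moved = set().union(*moved_sets)
    fixed = [i for i in range(len(tree.atoms)) if i not in moved]
    assert np.allclose(coords[fixed], tree.coords[fixed])
    # bond lengths unchanged
    for i, j in tree.bonds:
        before = np.linalg.norm(tree.coords[i] - tree.coords[j])
        after = np.linalg.norm(coords[i] - coords[j])
        assert after == pytest.approx(before, abs=1e-9)


def test_set_torsion_360_is_identity(man3_tree):
    tree = man3_tree
    machine = TorsionMachine(tree)
    coords = tree.coords.copy()
    start = machine.get_torsions(coords, 0)
    machine.set_torsions(coords, 0, np.asarray(start) + 360.0)
    assert np.allclose(coords, tree.coords, atol=1e-9)


def test_set_torsion_preserves_other_linkages(man3_tree):
    tree = man3_tree
    machine = TorsionMachine(tree)
    coords = tree.coords.copy()
    before = [machine.get_torsions(coords, i) for i in range(len(machine.linkages))]
    machine.set_torsions(coords, 2, np.array([77.0, -33.0, 150.0])[: machine.linkages[2].n_torsions])
    for i in range(len(machine.linkages)):
        if i == 2:
            continue
        assert np.allclose(machine.get_torsions(coords, i), before[i], atol=1e-6)


# ---------------------------------------------------------------------------
# Clash energy
# ---------------------------------------------------------------------------


def test_lj_pair_term_at_minimum():
    rmin, eps = 3.4, 0.12
    assert lj_energy(np.array([rmin]), rmin, eps)[0] == pytest.approx(-eps)


def test_extended_disaccharide_below_cutoff():
    tree = build_initial_structure(CHITOBIOSE)
    assert clash_energy(tree.coords, tree) < 10.0


def test_overlapping_atoms_blow_up():
    tree = build_initial_structure(MAN3)
    machine = TorsionMachine(tree)
    coords = tree.coords.copy()
    # drive the 1->3 and 1->6 arms into each other by brute-force search
    worst = 0.0
    rng = np.random.default_rng(0)
    for _ in range(60):
        for li, lk in enumerate(machine.linkages):
            machine.set_torsions(
                coords, li, rng.uniform(-180, 180, size=lk.n_torsions)
            )
        worst = max(worst, clash_energy(coords, tree))
    assert worst > 1e4  # random torsions quickly produce < 1 A contacts


def test_clash_pair_term_scale_at_overlap():
    r_half, eps = LJ_PARAMS["O"]
    e = lj_energy(np.array([0.5]), 2 * r_half, np.sqrt(eps * eps))
    assert e[0] > 1e6  # repulsive wall dominates at 0.5 A


# ---------------------------------------------------------------------------
# Pools
# ---------------------------------------------------------------------------


def test_single_residue_pool_is_degenerate_modulo_asn():
    """The only linkage of a single-residue glycan is the Asn anchor; ring
    atoms move rigidly, so all pairwise ring RMSDs are zero."""
    pool = generate_pool("GlcNAc", n_conformers=30, seed=1)
    d = background_rmsd_distribution(pool, subsample=10)
    assert d.shape == (45,)
    assert np.allclose(d, 0.0, atol=1e-7)


def test_background_pair_counts(man3_pool):
    assert len(background_rmsd_distribution(man3_pool, subsample=500)) == 124750
    assert len(background_rmsd_distribution(man3_pool, subsample=2)) == 1
    with pytest.raises(ValueError):
        background_rmsd_distribution(man3_pool, subsample=1)


def test_pool_reproducible(man3_pool):
    again = generate_pool(MAN3, n_conformers=10, seed=42)
    assert np.allclose(again.conformers, man3_pool.conformers[:10])


def test_pool_validates_clash_and_accessibility(man3_pool):
    """Every accepted conformer passes the clash cutoff and sits on
    accessible torsion cells (nearest-cell assignment)."""
    v = man3_pool.validate()
    assert v["clash_pass"] == 1.0
    assert v["accessible_pass"] == 1.0


def test_sampled_marginal_matches_accessible_map():
    """The torsion sampler's phi marginal matches the accessible-map
    marginal (chi-squared, p > 0.01, n = 10,000)."""
    grid = build_torsion_map(LinkageType("b", 4))
    rng = np.random.default_rng(123)
    draws = grid.sample(rng, 10000)
    cells = np.rint((draws[:, 0] + 180.0) / grid.spacing).astype(int) % grid.n_per_axis
    counts = np.bincount(cells, minlength=grid.n_per_axis).astype(float)
    expected = grid.accessible_marginal(0).astype(float)
    expected = expected / expected.sum() * counts.sum()
    keep = expected > 0
    # group cells with small expectation to keep the chi-squared test valid
    obs, exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(counts[keep], expected[keep]):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        obs[-1] += acc_o
        exp[-1] += acc_e
    res = stats.chisquare(obs, exp)
    assert res.pvalue > 0.01
    # nothing sampled off the accessible set
    assert counts[~keep].sum() == 0


def test_mean_background_rmsd_grows_with_length():
    """Random-background RMSD is length dependent: longer glycans have
    larger mean pairwise RMSD."""
    topos = [
        "GlcNAc[b1-4:GlcNAc[b1-4:Man[a1-3:Man]]]",
        MAN3,
        "GlcNAc[b1-4:GlcNAc[b1-4:Man[a1-6:Man[a1-2:Man],a1-3:Man[a1-2:Man]]]]",
    ]
    means = []
    for k, topo in enumerate(topos):
        pool = generate_pool(topo, n_conformers=250, seed=100 + k)
        means.append(background_rmsd_distribution(pool, subsample=120).mean())
    assert means[0] < means[1] < means[2]
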