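# Methods

This note records the models, numerical choices and limits behind
`glycospace`, in the order the pipeline uses them.

## Glycan recognition and canonical sequences

Carbohydrate candidates are cycles of length 5 or 6 with exactly one oxygen
and otherwise carbon members, detected on the HETATM bond graph (CONECT
records plus LINK-derived connections; for HETATM residues carrying no
CONECT at all, bonds are inferred between heavy atoms closer than 1.8 Å).
The anomeric carbon is the ring-oxygen-adjacent carbon with an exocyclic
oxygen (or, when N-linked, nitrogen) substituent. Monosaccharide naming
uses decisive chemical features where they exist — nitrogen at C2
(GlcNAc-type), a missing exocyclic C6 (pentoses), a C6 without oxygen
(6-deoxy sugars) — and otherwise the PDB residue-code table
(NAG/NDG/MAN/BMA/FUC/FUL/XYP/XYS/GLC/BGC/GAL/GLA); stereo-isomer
discrimination from substituent orientations is deliberately not attempted
beyond this, since the analysis only needs sequence identity. Unknown,
ambiguous rings are retained as `UNK-sugar`. Anomeric configuration is
taken from the residue-code table (reference geometry), not validated
against deposited hydrogens.

Canonical strings are built root-down with branches ordered by descending
parent position (the 1→6 arm first), e.g.
`GlcNAc[b1-4:GlcNAc[b1-4:Man[a1-6:Man,a1-3:Man]]]`; the string is invariant
to atom and residue input order, and all pairwise comparisons are
restricted to identical strings. Structures with multiple models use the
first model; alternate locations keep the highest-occupancy conformer.

## Torsion conventions

φ = O5–C1–O–C′x, ψ = C1–O–C′x–C′x−1 and, for 1→6 linkages,
ω = O–C′6–C′5–O′5; the linkage to Asn is treated as a regular two-torsion
linkage with φ = O5–C1–ND2–CG, ψ = C1–ND2–CG–CB, and counts as one linkage
in residue distances (the root residue is at distance 1). Angles are
degrees in [−180, 180). Setting a torsion rotates the connected component
behind the central bond; this leaves all other internal coordinates exactly
unchanged, and round-trips to 10⁻⁶ degrees.

## Similarity measures

Superposition is the closed-form proper-rotation least-squares optimum
(reflections excluded; `scipy.spatial.transform.Rotation.align_vectors`,
with a batched 3×3-SVD Kabsch for bulk pair tables). The three anchorings
(ring, Asn, stub) are defined in the README; the Asn-anchored and
stub-anchored measures are root-mean-square deviations over the scored
atoms (an RMS, not a mean distance — the choice is ours; the two are
monotonically related on these ensembles). Asn anchoring uses the eight Asn
heavy atoms N, Cα, C, O, Cβ, Cγ, Oδ1, Nδ2.

GDT P_X is found by deterministic seed-and-extend: seed superpositions from
the global set and every contiguous run of 1–3 residues along root-to-leaf
paths, iterating inclusion of atoms within X Å to a fixed point (3-atom
minimum; ≤ 10 iterations). One-residue seeds matter: a well-fitting region
smaller than three residues is otherwise undiscoverable. GDT-TS averages
X ∈ {0.5, 1, 2} Å; GDT charts bin per-atom deviations at 1/2/3/4 Å after
whole-glycan superposition, with atoms of 1→6 branches reported last.

Substructures keep residues within d glycosidic linkages of Asn
(d = 3, d = 4, and d = 4 excluding residues whose path crosses a 1→6
linkage); their backgrounds are the same pool conformers restricted to the
substructure atoms, so substructure p-values are always matched-null.

## Conformer pools

Per linkage type (anomeric configuration × parent position, plus the
GlcNAc–Asn anchor), a rigid generic-pyranose disaccharide template is
scanned over the full torsion grid at 5° spacing. The energy is 12-6
Lennard-Jones plus distance-dependent-dielectric Coulomb (ε(r) = 4r) over
pairs ≥ 4 bonds apart, with a small built-in element table
(C: rmin/2 = 2.0 Å, ε = 0.055; O: 1.7/0.12; N: 1.85/0.20 kcal/mol) and
coarse role-based partial charges; any user-supplied `energy_fn(r, rmin,
eps, qq)` can replace it. There is no per-grid-point minimisation: the
accessibility threshold absorbs most of the difference, at the cost of
somewhat sharper basins than a relaxed map would give.

Energies become Boltzmann probabilities at T = 300 K (the conversion
temperature is a package choice; nothing in the analysis is sensitive to it
at the reported precision, since accessibility is a threshold on the same
exponential family). Cells with p > 10⁻⁴ are *accessible*. For
three-torsion (1→6) grids the threshold is applied on the torsion-pair
scale — per-cell threshold divided by the 72 cells of the extra ω axis —
because the raw per-cell reading would dilute probabilities 72-fold and
freeze ω into a single rotamer, contradicting the well-documented gg/gt/tg
flexibility of 1→6 arms; with the pair scale the accessible set spans the
ω rotamers (~52k of 373k cells for α1-6).

Pools grow by a reproducible chain: start from an accessible, clash-free
conformation; each step resamples one uniformly chosen linkage uniformly
over its accessible cells (cell centre + uniform jitter of ±2.5°) and
accepts unless the total van der Waals energy exceeds 10 kcal/mol. Default
pool size is 10,000 conformers (pipeline runs use 2,000); backgrounds use
a seeded 500-conformer subsample, i.e. 124,750 pairs. Ring geometry is
rigid (ideal ⁴C₁ chairs); ring pucker, solvent and entropy are out of
scope.

## Significance

Backgrounds are fitted by maximum likelihood with `scipy.stats.genextreme`
(shape converted to the standard extreme-value sign convention ξ = −c),
initialised from the method-of-moments Gumbel fit; fit quality is the
Pearson correlation between empirical and model CDF on sorted samples
(typically > 0.999). p = F(observed) is the lower tail; score-type measures
(TM-score) use the upper tail 1 − F. The Gumbel limit is substituted for
|ξ| < 10⁻⁹. Parameter recovery on 124,750 simulated draws is within
±0.002/±0.001/±0.002 of (μ, σ, ξ) at seed 1, and self-p-values are uniform
to KS < 0.01.

## Dataset rules

Filters: glycans of more than 3 residues; resolution ≤ 3 Å (closed
thresholds everywhere); sequences with at least 20 structures. Sequence
similarity is 100 × (positively scoring aligned pairs) / (shorter length)
under global BLOSUM62 alignment with gap open/extend −25/−3 — deliberately
conservative penalties, chosen so that unrelated length-200 sequences stay
well below the 30% homology cutoff (they average 21 ± 3%; with lenient
blastp-style gaps they drift above 30%, which would corrupt the
classification). Classification order: same entry → redundant; < 30% →
non-homologous; ≥ 90% → excluded; otherwise chains are superposed on
sequence-aligned Cα pairs and the pair is homologous only if the
glycosylated Asn Cα atoms land within 10 Å. Local structures are protein
residues with any heavy atom within 6.0 Å (inclusive) of any glycan heavy
atom; fewer than 5 residues excludes the instance from local analysis.
Local similarity is a fixed-correspondence TM-score, d0 from the smaller
structure's length and floored at 0.5 Å — a simplification of a full
structural-alignment search, adequate because the correspondence comes from
the same sequence alignment that defined the pair.

## The synthetic benchmark

The generator emulates the statistical structure of a curated N-glycan
dataset, with full ground truth and no downloads:

* **Scaffolds** are idealised two-helix bundles (length 200 by default)
  with random sequences, one N-X-T sequon whose Asn carries a full side
  chain; family members share the reference's geometry and differ by 25%
  random substitutions (pairwise similarity ≈ 55–65%, safely inside the
  30–90% homologous window), while families and independent instances draw
  fresh sequences (≈ 21% pairwise, below the cutoff).
* **Homologous glycans** take a family reference conformation plus Gaussian
  torsion noise, sd 10° per torsion, doubled on 1→6 linkages.
* **Non-homologous glycans** draw each linkage from a mixture: with
  probability w = min(1, 0.05 · 1.8^(d−1)) (d the residue distance,
  multiplied by 4 for 1→6 linkages) the free uniform-over-accessible
  background, otherwise a cold (50 K) Boltzmann draw over the accessible
  cells. The cold component stands in for the conformational restriction a
  protein surface adds on top of the free-disaccharide map — at 300 K the
  within-accessible Boltzmann distribution is statistically
  indistinguishable from uniform, so it cannot express restraint at all —
  and the depth-growing escape weight encodes that restriction decays with
  distance from the protein while a depth-4 1→6 arm is essentially free.
  The resulting concentration ratio versus the background (≈ 0.55 in mean
  RMSD) matches the magnitude reported for real non-homologous pairs.
* **Decoys** exercise the filters: a 3-residue glycan, a 3.5 Å-resolution
  instance, a non-N-linked free disaccharide.

What passing the benchmark shows — and what it does not: the pipeline
recovers the qualitative structure the generator encodes (homologous <
non-homologous < background mean RMSD; higher significant fractions for
homologous pairs; substructure conservation growing toward the root and
improving when 1→6 residues are excluded; 1→6 branch atoms in larger GDT
bins). Because the generator *encodes* those patterns, the benchmark
validates the measurement machinery, not the biological claims; real
crystallographic effects (partial occupancy, lattice contacts, genuinely
heterogeneous protein folds) are not emulated. Fixture files quantise
coordinates to 0.001 Å, so torsions recomputed from emitted files match the
recorded ground truth to ~0.1°, not machine precision.

## Problem sizes and determinism

Default analysis sizes — 2,000-conformer pools, 500-conformer
(124,750-pair) backgrounds, two benchmark sequences with 22 instances each —
were chosen so a complete run finishes in a few minutes on one CPU while
every estimate reported (class means, significant fractions) carries
hundreds of pairs. Every random stage (map sampling, pool chains,
subsampling, benchmark emission) flows from explicit integer seeds;
rerunning any entry point with the same seed reproduces byte-identical
tables and fixture hashes.

## Known limitations

* The energy model is a coarse LJ+Coulomb surrogate: absolute map energies
  and basin shapes differ from force-field adiabatic maps; only the
  map → probability → accessibility → sampling pipeline is faithful.
* Monosaccharide naming trusts residue codes for stereo pairs (Man/Glc/Gal).
* The TM-score search is fixed-correspondence, not a full structural
  alignment; cross-sequence glycan alignment is out of scope by design.
* O-glycans, glycolipids and chemically modified sugars are not recognised.
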