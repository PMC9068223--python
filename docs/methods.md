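# Methods

`tmdkit` implements a desk-scale pipeline for designing and analyzing
single-span transmembrane (TM) helix oligomers: parametric bundle
generation, surrogate membrane scoring with the published filter criteria,
fuzzy-logic Monte Carlo sequence diversification, multi-symmetry
energy-landscape funnel analysis with negative design across oligomeric
states, and the conversion of dual-selection deep-mutational-scanning read
counts into apparent free energies of self-association.

## Bundle geometry

Backbones are idealized Cα traces placed by a Crick-style
parameterization: each chain is an ideal α-helix (minor radius 2.26 Å,
rise 1.51 Å/residue, 3.6 residues/turn), rotated about its own axis by the
*interface phase*, leaned tangentially by the *tilt* angle relative to the
membrane normal, placed with its axis at the *superhelical radius* from
the bundle axis and offset axially by *z-offset*; chains 2..n are exact
copies rotated by 360°/n about the bundle axis, so Cn symmetry holds to
machine precision. This is a deterministic surrogate for fragment-based
fold-and-dock sampling: it spans the same physically meaningful degrees of
freedom for a single-span bundle while remaining exactly reproducible.
Coordinates live in the membrane frame (z = membrane normal, midplane
z = 0, default slab half-thickness 15 Å). The default superhelical radius
of 5 Å puts dimer helix axes ~10 Å apart, the observed scale of packed TM
dimers. Antiparallel topologies are representable (`parallel=False` flips
alternate chains) but excluded from design campaigns: a receptor-style
type I orientation constrains designed chains to parallel bundles, and
exact Cn symmetry is only guaranteed for the parallel case.

Tilt is measured back from coordinates as the angle between a chain's
least-squares (principal-component) axis and z, which round-trips the
generator's tilt parameter to within 1° over [0°, 45°] (the small residual
comes from the helical winding of the Cα cloud).

The crossing-angle penalty is the published cubic, with θ in degrees:

    penalty(θ) = 1.51·10⁻⁴ θ³ − 8.925·10⁻³ θ² + 0.187 θ − 0.532

Degree units are the only reading under which the coefficient magnitudes
make sense (the penalty crosses zero near θ ≈ 3.1° and reaches ~2.3 at
θ = 40°). The per-helix tilt-versus-membrane-normal interpretation is
implemented; a pairwise interhelical-angle reading exists in the
literature but is not used here.

Symmetry- and comparison-RMSDs use Kabsch superposition; the symmetry
check compares the bundle to itself rotated by 360°/n (no refit), and
symmetry-aware comparisons minimize over cyclic chain relabelings only
(all-permutation matching is unnecessary for parallel Cn bundles).

## Surrogate membrane energy

The scorer reproduces the decision structure — packing plus depth-dependent
lipophilicity plus the crossing-angle bias — of an atomistic membrane
energy function without re-implementing one. Terms:

* **Packing**: a soft Lennard-Jones-style sum over cross-chain residue
  spheres (Cα-centered, radii 2.3–3.8 Å by residue size, well depth 1.0,
  10 Å cutoff). Counting only cross-chain pairs makes this an *interface*
  packing term, so the association energy ΔΔG_binding — complex energy
  minus the sum of isolated-chain energies at fixed internal coordinates —
  reduces exactly to it, and separated chains score 0. The well depth is
  calibrated once so that well-packed 24-residue dimers land in the
  −15…−30 range typical of atomistic TM association energies.
* **Lipophilicity**: per-residue insertion energy interpolated from a
  depth-dependent profile. The packaged default applies the biological
  (translocon) hydrophobicity scale weighted by a taper that is 1 in the
  slab core (|z| ≤ 9 Å) and falls to 0 at |z| = 22.5 Å; measured
  depth-dependent profiles load from TSV in the same format.
* **Crossing-angle penalty**: the cubic above, summed over chains.

Quantities feeding the filters: buried interface SASA is computed by
in-package Shrake–Rupley on the residue spheres (1.4 Å probe, 960
deterministic golden-spiral points per sphere), validated against the
closed-form two-sphere buried-area formula. Shape complementarity scores
the contact band of interface surface points: for each point, the signed
gap to the nearest opposing sphere surface and the normal there give
s = (−n_a·n_b)·exp(−w·gap²) with w = 0.5 Å⁻², and the statistic is the
mean of the two per-side medians over points with |gap| < 1 Å. "Helicality"
has no published definition; it is implemented as the mean squared
deviation of Cα pseudo-torsions from the ideal helical value (scaled by
10⁻³ per squared degree), which is 0 for generator output and far above
the 0.1 cutoff for extended chains. TM span is the minimum over chains of
|Δz| between terminal Cαs; topology match is the fraction of positions
whose z-compartment (cytosolic below the slab / membrane / external above)
matches the requested labels.

Filter thresholds default to the published numbers (design stage: buried
SASA > 700 Å², Sc > 0.6, ΔΔG_binding < −15, helicality < 0.1, best 1% by
system energy; prediction stage: SASA > 600 Å², energy < 0, span > 25 Å,
topology match > 0.1), evaluated as strict inequalities, with the energy
percentile applied at the ensemble level after the threshold filters.
**Calibration caveat**: the printed cutoffs are calibrated to atomistic
Rosetta energies and surfaces; on the coarse surrogate scale the SASA and
Sc of physical poses are systematically smaller (a packed Cα-sphere dimer
buries ~400–600 Å² at Sc ≈ 0.3–0.45), so campaigns on the surrogate scorer
should supply thresholds appropriate to it. All thresholds are plain
configuration fields; the defaults are not silently rescaled.

## Sequence diversification

De novo TM design gravitates toward Leu-rich sequences; the
countermeasure is 120 steps of Metropolis simulated annealing over single
point mutations restricted to {G, A, V, I, L, M, F, Y, W}. Each proposal
is evaluated on three criteria — association energy, system energy (both
relative to the starting model), and the composition RMSD

    RMSD_seq-comp = sqrt( Σ_aa (f_design(aa) − f_natural(aa))² / L )

against a natural single-span TM composition (packaged default; any
profile loads from TSV). Each criterion is squashed by
f(x) = 1/(1 + e^{(x−o)s}) with published parameters (o, s) = (3, 1) for
association energy, (20, 0.5) for system energy, (0.05, 50) for
composition RMSD, and combined conjunctively. The conjunction is the
product t-norm by default (smooth, differentiable-in-spirit; `minimum` is
available by configuration since the published operator is not specified).
The square root in the composition RMSD honors its name; the un-rooted
variant is a switch. Mutations are accepted by Metropolis on the maximized
objective under geometric cooling from T = 0.2 to T = 0.01 in objective
units (the schedule is not published; these values give ~50% early
acceptance of mildly worsening moves and near-greedy behavior at the end).
Structure relaxation after each mutation is replaced by re-scoring the
fixed backbone with the mutated sequence; the scorer argument accepts any
callable, so a relaxing scorer can be substituted. Traces record every
proposal (position, residues, raw and transformed criteria, objective,
temperature, acceptance) and runs are byte-reproducible for a fixed seed.

## Funnel analysis and state selection

For each candidate symmetry (C2, C3, C4) an ensemble of randomized
geometries (radius 4–10 Å, phase 0–360°, z-offset ±3 Å, tilt 0–35°) is
scored and compared to the reference model by symmetry-aware RMSD. The
funnel statistic is

    Z = (mean(E) − E_lowest) / std(E)

with E_lowest the lowest energy among models within 2 Å of the reference
and E the energies of models beyond 2 Å lying within 50 energy units above
E_lowest (population standard deviation over that windowed set). The sign
convention makes funneled landscapes positive so the published cutoff
Z > 2.5 applies directly. Degenerate inputs (no near-native model, a
comparison set smaller than 2 or with zero variance) raise a distinct
undefined-funnel error rather than returning 0. The negative-design rule
selects a sequence only if its target symmetry is funneled and neither
alternative is; the decision depends only on the funneled flags. Decoy
sets read and write as delimited text (`model_id, symmetry, rmsd,
energy`), so externally generated score tables analyze identically.

## Deep-mutational-scanning energetics

Counts from the dual selection (reference population: survival on
ampicillin = insertion; selected population: ampicillin +
chloramphenicol = insertion and self-association) convert per position i
and mutation j as p_ij = count_ij / count_wt (pseudo-count 1 when the
wild-type count is 0), s_ij = p_selected / p_reference, and
ΔΔG_measured = −RT·ln(s_ij / s_wt) with R = 1.9872·10⁻³ kcal·mol⁻¹K⁻¹ and
T = 310 K (RT ≈ 0.616 kcal/mol). Because chloramphenicol survival reflects
insertion twice over for a homodimer, the apparent association energy
subtracts the doubled depth-dependent insertion difference:
ΔΔG_assoc = ΔΔG_measured − 2·ΔΔG_ins. The published pseudo-count rule
covers only the wild type; zero *mutant* counts would make the log
undefined, so the default policy also floors mutant counts at 1, and a
strict mode instead reports such cells as missing. The shipped insertion
profile is flat zero (the correction is then an identity, logged as such);
measured profiles load from TSV. Mutations are classed detrimental iff the
energy change strictly exceeds 2.5 (configurable), matching the published
classifier boundary. Per-position sensitivity summaries aggregate
ΔΔG_assoc over mutations at each position, group by interface/exposed
labels (from the structural burial classifier: a position is interface if
complexation removes >25% of its isolated-chain SASA), and compare classes
with a two-sided Mann–Whitney U test.

## Synthetic data

The synthetic count generator is the exact sampling inverse of the
analysis: per position, reference fractions are uniform over wild type
plus the specified mutants, the selected population re-weights each
variant by exp(−ΔΔG/RT), and both populations draw multinomially at the
configured depth (default 10⁶ reads per position, T = 310 K). At that
depth the pipeline recovers a known ΔΔG table with |bias| < 0.05 and
RMSE < 0.1 kcal/mol over |ΔΔG| ≤ 3 — the parameter-recovery bar the test
suite enforces. What the generator does *not* emulate: sequencing error,
PCR jackpots, position-dependent coverage, epistasis, or the
chloramphenicol dose–response series; recovery tests therefore validate
the estimator's algebra and sampling noise behavior, not robustness to
those real-data artifacts.

Synthetic landscapes draw RMSDs uniformly on [0, 10] Å; funneled
ensembles set energy = base + 10·min(RMSD, 4 Å) + U(−3, 3), flat
ensembles draw energies U(base, base + 40) independently of RMSD. Bounded
uniform noise keeps the flat null's Z well below 2.5 (a Gaussian null's
minimum-statistic tail would sit uncomfortably close to the cutoff), while
funneled ensembles score Z ≈ 4–6. Across 50 seeds the funneled generator
exceeds Z = 2.5 in ≥ 90% and the flat generator in ≤ 10% of replicates.

The 19 packaged DNA sequences (twelve first-round designs, the symmetric
C1/C2.1/C3.1/C4.1 series, and the CLS / ErbB2 / QSOX2 assay controls) are
stored verbatim with a SHA-256 integrity check; four labels whose printed
headers read "roMP" are normalized to "proMP" with the raw label kept.
Two control sequences end in a partial codon as printed; translation drops
it. Peptides exclude the expression-construct flanks (N-terminal EPE,
C-terminal RRLC) used for recombinant production.

## Problem sizes and numerical choices

Default test-and-demo scales are deliberately small: design campaigns of
~10 bundles and 100 decoys per symmetry, 200-sample synthetic landscapes,
and 24-residue chains — large enough for every statistical contract in
the test suite, small enough to run interactively on one core. SASA uses
960 sphere points (~1% discretization error against the two-sphere
closed form); Sc uses 120 surface points per atom (stable to < 0.05
against 500). Ties and degenerate inputs fail loudly: zero-variance
comparison sets, missing wild-type rows, non-covering profiles and
monomer inputs to interface quantities all raise typed errors.

## Known limitations

* The surrogate scorer has no electrostatics, hydrogen bonding, rotamer
  packing or explicit lipids; its energies are on their own scale and the
  printed atomistic thresholds are not directly transferable (see the
  calibration caveat above).
* The parametric decoy generator cannot produce non-helical or kinked
  conformations, so landscape funnels measure discrimination among
  idealized bundle geometries only.
* Interface/exposed classification at 25% burial is a geometric proxy;
  lipid-facing versus interface assignment in real bundles also depends on
  sequence context the sphere model ignores.
* Per-chain asymmetric sequences and hetero-oligomers are out of scope;
  all design operations assume one shared sequence per bundle.
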