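# Methods

## Structure geometry

Coordinates are read from fixed-column PDB ATOM/HETATM records into a flat
atom table. Alternate locations are resolved to a single conformer per atom:
highest occupancy wins, ties prefer altloc `A`, then first appearance — the
convention is stated because deposited files differ and the choice can move
a borderline contact. Waters are retained but flagged (`HOH`/`WAT`/`DOD`)
and excluded from all protein-side geometry, as are hydrogens (invisible at
typical crystallographic resolution) and other hetero groups.

**Proximity site definition.** For each protein residue the distance to a
chosen ligand is the minimum over all heavy-atom pairs; the *k* smallest
residues (default k = 20) form the site, sorted ascending, with rank-k ties
broken lexicographically on (chain, residue number) so output is
deterministic. A 4 Å cutoff variant gives the contact shell. When the
asymmetric unit contains two protein copies, the site is computed on one
chain — by default the chain owning the protein atom nearest the ligand;
both the chain and the ligand pose are explicit parameters since deposited
structures do not dictate a unique choice. Residue numbering follows the
file (author numbering); no renumbering is attempted.

**Superposition.** Backbone superposition pairs residues across two models
and fits the rigid transform minimising the squared deviation over their
N/CA/C/O atoms (Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`,
which enforces det(R) = +1 so reflections can never masquerade as fits).
Residues missing any of the four atoms are dropped with a logged warning;
fewer than three complete pairs is an error; near-collinear sets are flagged
`degenerate` but still return the reflection-free optimum. RMSD is reported
after applying the fit.

## Conservation

Percent identity is reference-anchored: the denominator is the set of
selected columns where the reference is un-gapped, so site definitions —
which are reference residue numbers — always index well-defined columns.
An ortholog gap at a counted column scores as a mismatch by default; since
published analyses rarely state their gap rule, `skip_ortholog_gaps=True`
switches to dropping those columns from the denominator. Matching is
case-insensitive and strict (no substitution-matrix similarity); `X` matches
nothing, including itself. Zero countable columns raises rather than
returning 0, because "0% identical" and "nothing to compare" are different
claims. An explicit offset maps construct residue numbering to reference
positions for engineered proteins whose numbering starts mid-sequence.
Ortholog retrieval and alignment (BLASTP/MAFFT) are consumed as input, not
performed.

## CPMG hit calling

The observable is the attenuation ratio ρ = I(+protein)/I(protein-free
reference); a fragment is a binder iff ρ ≤ τ, boundary inclusive. τ is not
a measured constant but an operating point; the default τ = 0.8 (≥ 20%
attenuation over a 600 ms CPMG filter) is ordinary practice for
ligand-observed screens and every entry point takes τ explicitly. Cap-site
assignment compares the ratio re-measured after competitor addition:
recovery ρ_comp − ρ ≥ recovery_delta (default 0.15) classifies the binder
as competed at that site. Input tables carry one row per fragment,
pre-aggregated over resonances by the minimum-ratio convention; spectral
processing is out of scope. The summary reports the hit rate as
100·n_hits/n_library rounded to one decimal.

## ITC: one-set-of-sites model

For n identical independent sites with association constant Ka = 1/K_d and
molar enthalpy ΔH, the occupied-site fraction Θ at total macromolecule M_t
and total ligand X_t solves the binding quadratic:

    Θ = ½ [ 1 + X/(nM) + 1/(n·Ka·M) − √( (1 + X/(nM) + 1/(n·Ka·M))² − 4X/(nM) ) ]

and the cumulative heat is Q = n·Θ·M_t·ΔH·V₀. The discriminant is
analytically non-negative for valid inputs; it is clamped at zero with a
warning against floating-point excursions, and Θ is clipped to [0, 1].

**Injection bookkeeping.** Each injection of volume v displaces well-mixed
cell contents: concentrations scale by (1 − v/V₀) and the ligand gains
X_syr·v/V₀. The measured heat carries the half-volume displacement
correction q_i = Q_i − Q_{i−1} + (v_i/V₀)(Q_i + Q_{i−1})/2. Commercial
fitting software does not publish its exact convention; simulator and
fitter share this one, so parameter-recovery results are
convention-independent. The first injection can optionally be discarded
(syringe-tip dilution); default is to keep it.

**Fitting.** Nonlinear least squares over (n, log₁₀Ka, ΔH, q_dil) with
`scipy.optimize.least_squares` (TRF, tolerances 1e−15), residuals scaled by
the largest observed heat (with a floor at the full-saturation heat of
1 kcal/mol, which keeps all-zero thermograms finite — those are flagged
un-converged/degenerate rather than fitted). Fitting in log-Ka space keeps
the parameter well-scaled across the K_d range. The dilution offset q_dil
is floated by default or pinned to a buffer-control value. Initialisation:
n = 1, ΔH from the total heat budget, Ka at c = 50 (mid Wiseman window).
Standard errors come from the Jacobian at the optimum (delta method for
K_d); a warning is emitted when c = n·M₀/K_d leaves [1, 1000], the window
in which single-site titrations meaningfully constrain K_d. Non-convergence
is reported through `converged=False`, never silently. Derived quantities:
ΔG = RT·ln K_d (R = 1.9872×10⁻³ kcal/(mol·K), natural log, T default
298.15 K), −TΔS = ΔG − ΔH, LE = −ΔG/N_heavy. Heavy-atom counts are user
inputs — no structure perception is attempted. LE tables round to two
decimals for presentation; full precision is always available.

**Dose–response.** EC50s come from a 4-parameter logistic
y = bottom + (top − bottom)/(1 + (EC50/x)^hill), fitted in log-EC50 space;
≥ 5 points spanning ≥ 2 log units are required, flat data return an
EC50-undefined flag, and residuals above 20% of the response span attach a
poor-fit warning rather than failing.

## Synthetic data

Generators are pure functions of (spec, seed) — byte-identical re-runs —
and every generator emits a ground-truth sidecar so tests never re-derive
truth from generated data.

* **Ortholog families**: independent per-position substitutions at
  background rate p_global (default 0.2, giving ~80% mean identity, typical
  of a cross-species ortholog set) and site rate p_site (default 0.02,
  strong site conservation); replacements uniform over the 19 alternatives.
  Defaults: length 220 (the size of a small single-domain protein),
  30 orthologs. Optional per-position deletions leave the alignment
  columnar. No phylogeny, no substitution matrix, no insertions: the
  conservation stage tests identity arithmetic, not evolutionary realism,
  and passing tests say nothing about rate heterogeneity in real families.
* **Screen decks**: 1371 fragments in cocktails of four with 50 planted
  binders by default; binder ρ ~ U(0.2, 0.6) and non-binder ρ ~ U(0.9, 1.05)
  are each separated from τ = 0.8 by a 0.1 margin, enforced at spec
  validation (an `allow_overlap` flag exists for robustness experiments).
  20% of binders are cap-site-competable with ρ recovering to 0.9–1.0.
  Real screens have ambiguous mid-range ratios and cocktail overlap
  artefacts that this generator deliberately omits, so perfect
  sensitivity/specificity here only validates the calling arithmetic.
* **Toy structures**: line (single-CA residues at known spacings), helix
  (full N/CA/C/O backbone on an α-helical curve, for superposition
  fixtures) and random-sphere (residues scattered in a 2–12 Å shell around
  the ligand, minimum 0.5 Å atom separation) geometries, each with its
  exact residue–ligand minimum-distance table; rigid-copy pairs record the
  applied rotation and translation.

## Problem sizes and numerical checks

The simulation-based checks use 20 seeded titrations of 17 injections at
c ≈ 111 with 1% heat noise for ITC recovery, 100 random-sphere toys for the
brute-force site-definition comparison, and 20 seeded families for the
site-vs-global conservation property — sizes at which the medians and
comparisons involved are stable across seed choices while the whole suite
runs in seconds. Backbone-RMSD correctness is verified three ways: rigid
motions refit to zero, a numerical optimiser over rotations reproduces the
Kabsch minimum, and a deformation constructed orthogonal to all rigid
motions (translations and infinitesimal rotations projected out) and scaled
to 0.9 Å RMS is recovered at 1-decimal rounding.

## Limitations

mmCIF input, multi-site/sequential and competitive ITC models, raw-power
baseline integration, NMR spectral processing and cocktail deconvolution,
phylogenetically weighted conservation, and any cell-assay statistics are
out of scope. Two-letter elements are only recognised from an explicit PDB
element column. The 20-residue site definition and one-chain convention are
parameters, not discoveries: different deposited ligand poses or chain
choices yield different (equally defensible) site lists.
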