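# Methods

This note documents the models, numerical choices and limitations behind
`acidbridge`, in the order the pipeline runs them.

## Structures and ensembles

Structures are read and written through gemmi's PDB parser; coordinates
stay in Å, residue numbering is taken verbatim from the file, and
hydrogens are ignored by every geometry operation (the bridge criterion is
a heavy-atom criterion). HETATM records (waters, ligands, heme) are kept
but flagged non-protein and excluded from all geometry unless requested.
The default altloc policy keeps, per atom name, the alternate conformer
with the highest occupancy (ties broken alphabetically by altloc letter):
bridge detection wants a single deterministic conformer, and the
highest-occupancy state is the conventional representative. `keep-all` is
available when both states matter (side chains refined in two 0.5
occupancy states are common at high resolution).

Ensembles are ordered frame lists sharing an identical topology, read from
multi-model PDB files. They stand in for MD trajectory snapshots; the
package deliberately contains no MD engine.

The crystal-packing utility implements the Matthews relation: cell volume
V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosαcosβcosγ), V_M = V/(z·mass),
solvent fraction = 1 − 1.66·v̄/V_M with v̄ = 0.74 cm³/g by default (the
canonical protein partial specific volume; 1.66 converts Da·cm³/g to Å³).

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

* **Toy structures** are ideal poly-alanine α-helices (rise 1.5 Å/residue,
  twist 100°, Cα radius 2.3 Å). A planted pair occupies two consecutive
  residues; the basic partner's charged group points radially outward at
  its canonical Cα distance (Arg guanidinium N 4.1 Å, Lys NZ 4.7 Å, His
  ring N 3.6 Å; Asp carboxyl O 2.9 Å, Glu 3.9 Å; two-atom groups are split
  ±0.55 Å), and the acidic group is positioned by bisection along the
  inter-group line so the minimum N–O distance equals the requested target
  to ~1e-6 Å (the contract promises ±0.05 Å). Pairs are spaced eight
  residues apart so planted pairs do not interact across sites. Only
  charged-atom geometry matters to the criterion, so no rotamer sampling
  is attempted — which is also the main way these fixtures differ from
  real side chains.
* **Ensembles** add i.i.d. isotropic Gaussian displacements per atom with
  a per-residue σ. The closed form E‖d‖² = 3σ² anchors the RMSF tests.
  Real MD frames are temporally correlated and anisotropic; passing tests
  on jittered ensembles validates the estimators, not MD realism.
* **Kinetics tables** use multiplicative Gaussian noise (spectrophotometric
  error scales with signal). Default study conditions mirror the assay
  design they emulate: substrate 50–2000 µM at 0.02 µM enzyme with native
  constants K_M = 121 µM, k_cat = 10 s⁻¹; inactivation series over ~3
  half-lives with 5% relative noise for Monte-Carlo recovery checks.

All generators are pure functions of (spec, seed) with no hidden RNG
state.

## Titration and the Wyman integral

Per-site protonation follows Henderson–Hasselbalch,
θ = 1/(1 + 10^(pH − pKa)), acids carrying −(1 − θ) and bases +θ. Model
pKas: Asp 4.0, Glu 4.4, His 6.3, Lys 10.4, Arg 12.0, Tyr 9.6, free Cys
8.3, N-terminus 7.5, C-terminus 3.8. Disulfide-bonded cysteines (SG–SG
< 2.3 Å) are not titratable. The doubly protonated histidine (both ring
nitrogens, net +1) is the only His form eligible as a bridge donor, which
is what couples the bridge survey to pH.

Effective pKas come from a mean-field self-consistent scheme:

* burial b = clamp((N₉ − 15)/(40 − 15), 0, 1), where N₉ is the heavy-atom
  count within 9 Å of the site's charged-atom centroid; Born/desolvation
  shift = +1.5·b pKa units for acids, −1.5·b for bases (burial penalises
  the charged form);
* pairwise shift for site i = −Σ_j q_j·332/(ε_eff·r_ij)/(ln10·RT) with
  ε_eff = 20, r_ij the centroid distance, and q_j the other sites'
  fractional charges at the target pH (default 2.5, the design pH);
* synchronous iteration until the largest pKa change is below 0.01
  (≤ 50 iterations; non-convergence is flagged, not raised).

This is an openly documented stand-in with the interface and
pH-integration structure of continuum-electrostatics ionisation models,
not a numerical clone of any of them; all constants live in
`TitrationConfig` (YAML-serialisable). Its absolute energies are
indicative, which is why downstream decisions use only a coarse threshold
classification.

The unfolded-state reference uses unshifted model pKas (the standard null
model in pH-stability calculations). The pH-dependent stability change is
the Wyman linkage integral −RT ln10 ∫ [Q_U − Q_F] dpH, evaluated by the
composite trapezoid rule at a step ≤ 0.01 pH units; the integrand is a
smooth sum of logistics, and the quadrature agrees with the one-site
closed form to < 1e-4 kcal/mol (tested). Swapping limits flips the sign
exactly; the integral is additive over adjacent intervals.

## Bridge survey

"Within 4.0 Å" is read as a closed cutoff (≤ 4.0). Detection is
residue-pair deduplicated — a bidentate Arg–Glu contact is one bridge —
and annotated with the minimum qualifying atom-pair distance. On
ensembles, occupancy is the fraction of frames satisfying the criterion;
the default reporting threshold is 0.5 (majority persistence), and
threshold 0 gives a union-over-frames survey. Both modes are provided
because persistence conventions vary between studies. Detection is
invariant under rigid transforms and monotone in the cutoff (tested
against an exhaustive all-pairs scan).

## Homology mapping

Global Needleman–Wunsch alignment with affine gaps (BLOSUM62, open 10,
extend 0.5; a gap of length L costs 10 + 0.5(L−1)) via Biopython's
PairwiseAligner. Identity and similarity are reported over *all* alignment
columns, gaps included — the EMBOSS-needle convention — and are therefore
convention-sensitive numbers, not invariants.

Superposition is the Kabsch SVD solution with reflection correction
(det = +1), over Cα atoms of alignment columns where both residues are
present. It matches an independent quaternion (Horn) oracle to 1e-8 Å in
tests. Bridge projection uses the sequence alignment, not 3D proximity:
deterministic and testable; a proximity-based mapping would be a natural
extension for low-identity pairs.

## Mutant building and ΔΔG

Mutants are built by minimal side-chain grafting: rename, strip side-chain
atoms beyond Cβ, and place the new charged group along the Cα→Cβ direction
at its canonical distance (pseudo-Cβ direction from backbone N/C for
glycine). A new heavy atom within 2.5 Å of another residue raises a clash
flag for that position. No rotamer optimisation is attempted; the clash
penalty is the coarse steric backstop.

The score is

ΔΔG_mut = [ΔG_unfold^wt − ΔG_unfold^mut] (target vs reference pH)
          − 1.0 kcal/mol · (bridges gained − bridges lost at target pH)
          + 5.0 kcal/mol · (clashing mutated residues),

negative = stabilizing. The reference pH defaults to 7.0 (acid behaviour
is judged against neutral-pH behaviour). The bridge bonus and clash
penalty are round heuristic magnitudes — a formed salt bridge is worth of
order 1 kcal/mol, an unresolved heavy-atom overlap much more — and both
are configurable. Classification uses the ±0.5 kcal/mol rule: < −0.5
stabilizing, > +0.5 destabilizing, the closed band between them neutral.
Because the energy engine is a stand-in, published ΔΔG magnitudes are used
only to test the classifier, never as regression targets for the engine.

The pipeline grafts the donor pair's residue types at incompatible
positions (one candidate per donor bridge, single or double mutation as
required) rather than searching all 20×20 substitutions, mirroring the
homology-grafting rationale. All incompatible positions are reported;
selecting which candidates to take to the bench is left to the user.
Candidates that fail to build are logged in the report's stage log and
skipped, so one bad position cannot abort a survey.

## Ensemble metrics

Backbone RMSD uses N/CA/C/O atoms, each frame optionally Kabsch-fitted to
the reference first (default). RMSF uses Cα only (the conventional
per-residue granularity; the atom selection is configurable in the code)
after aligning every frame to the ensemble mean, with the mean/fit pair
iterated twice. Aligning removes six rigid degrees of freedom, so on an
N-residue ensemble the measured RMSF runs a factor ≈ √(1 − 2/N) below the
raw closed form; tests therefore use 60-residue fixtures where the
correction is under 2%. Absolute RMSD/RMSF values from real trajectories
depend on the sampling protocol and are not reproduced here; the module is
validated by synthetic closed forms.

## Kinetics

Inactivation: OLS of ln(activity) on time; kd = −slope,
t½ = ln 2/kd (identity holds to machine precision by construction), R²
reported; a non-negative slope returns a `no_decay` flag with t½ = +∞
rather than an error. Hanes–Woolf: unweighted OLS of S/v on S, slope
1/V_max, intercept K_M/V_max, k_cat = V_max/[E]. The linearisation is the
primary estimator because it is the classical method for this assay; a
nonlinear Michaelis–Menten fit is included as a cross-check (they agree
exactly on clean data). Note the unweighted linearisation amplifies noise
at high S — single noisy replicates scatter considerably more than the
nonlinear fit, which is why Monte-Carlo checks and the acceptance script
use medians over replicates. Catalytic efficiency is k_cat/K_M converted
to s⁻¹ mM⁻¹. Absorbance-to-rate conversion is Beer–Lambert with mM
extinction coefficients (e.g. ε₄₂₀ = 36.7 mM⁻¹cm⁻¹ for the ABTS assay,
ε₄₀₉ = 168 mM⁻¹cm⁻¹ for heme quantification via the Soret band).

## Problem sizes

Monte-Carlo checks use 100–500 replicates/frames and toy structures of
10–60 residues; the brute-force bridge cross-check runs 100 random
structures. These sizes put the statistical tolerances (5–10%) well above
sampling error while keeping the full suite and the acceptance script in
the seconds-to-a-minute range.

## Known limitations

* The titration scheme is mean-field with a uniform effective dielectric;
  it ignores conformational relaxation, explicit solvent and tautomer
  enumeration beyond the doubly/singly protonated His distinction.
* Side-chain grafting is direction-only (no rotamers); steric feasibility
  is judged solely by the 2.5 Å clash flag.
* Sequence-based bridge mapping can mispair structurally equivalent but
  sequence-shifted positions at low identity.
* Synthetic ensembles have no temporal correlation; occupancy statistics
  on them validate bookkeeping, not conformational kinetics.
* Identity/similarity percentages depend on alignment conventions (gap
  treatment, matrix) and should be compared only under matching
  conventions.
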