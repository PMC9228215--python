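# Methods

## Equilibrium model and speciation

The chemistry is a two-component equilibrium system: receptor L (a cyclic
pentapeptide presenting five amide N–H donors) and anion A, linked by
cumulative formation equilibria l·L + a·A ⇌ L_lA_a with constants
β_la = [L_lA_a]/([L]^l[A]^a) on the molar (mol dm⁻³) concentration scale.
The canonical species set is the 1:1 complex LA; for dihydrogen phosphate
in acetonitrile the anion dimer A₂ and, optionally, the dimer complex LA₂
are added. The free components are implicit with log β = 0. A 1:2 complex
can be parameterised either as L + 2A (β₁₂) or as L + A₂ (β₁₂/β₀₂); the two
are interconvertible and both are accepted.

Given total concentrations c_L and c_A, the solver finds free
concentrations satisfying both mass balances by Newton iteration on
x = ln([L], [A]) with the analytic Jacobian
∂(calc_i)/∂x_j = δ_ij·[free_i] + Σ_s ν_si·ν_sj·c_s. Working in log space
keeps iterates strictly positive; steps are capped at 3 log-e units to
avoid overflow for stiff β. Convergence demands a maximum relative
mass-balance residual below 1e-12 within 200 iterations (cheap at this
problem size); on stall the solver falls back to globally convergent
nested bisection (outer loop on free A, inner on free L — both residuals
are monotone in the respective free concentration). Compositions with one
component absent reduce exactly to the remaining one-component problem.
1:1 and dimer-only models also have closed-form quadratic solutions, kept
as independent oracles and used as the fast path in the ITC forward model.

The dihydrogen phosphate dimerization constant in acetonitrile is a
required user input (`Species(0, 2, log_beta02, fixed=True)`); the
generator's placeholder default of log β₀₂ = 2.0 is an assumption, not a
literature value, and fitted reports mark fixed constants as such.

## Titration schedules

Cuvette titrations use the dilution convention: each aliquot of anion
stock grows the total volume, so total_L(i) = c_L·V0/(V0+v_i) and
total_A(i) = c_A,titrant·v_i/(V0+v_i). NMR titrations use constant-ligand
mode, where the titrant also contains the receptor at the working
concentration and total_L stays fixed. Defaults mirror the instruments the
data shapes come from: cuvette V0 = 2.0 mL with receptor near 1e-4
mol dm⁻³, NMR-tube concentrations near 1e-3 mol dm⁻³, 298.15 K.

## Global multivariate fitting (variable projection)

A spectral titration is the bilinear model Yᵀ = C(log β)·S + E, with Y the
channels × points response matrix, C the concentrations of the responsive
species at each point (free L plus every receptor-containing complex; the
free anion is assumed silent unless requested) and S the per-species molar
responses. For any trial log β, S is the exact linear least-squares
minimiser; the outer search over the free log β is
`scipy.optimize.least_squares` (Levenberg–Marquardt) on the projected
residual, multistarted from 0 and ±1 log-unit offsets to guard against
local minima. Weighting is uniform across channels and points; molar
responses are unconstrained in sign by default (difference and CD spectra
can be negative) with an optional non-negativity switch for emission, and
an optional constant-offset channel (off by default). Fast-exchange NMR
titrations use the same engine with C replaced by receptor mole fractions
l·[s]/c_L, so the linear parameters become per-species limiting shifts.

Standard errors of log β come from the Jacobian at the optimum,
cov = (JᵀJ)⁻¹·SSR/dof with dof counting both the nonlinear and the
projected linear parameters; replicate-based SDs are reported alongside
when triplicate fits are supplied. Degenerate designs are refused: a
response with zero variance across points, or a concentration design
matrix with condition number above 1e12, raises an ill-conditioning error
rather than returning meaningless constants.

Background signals that scale with titrant concentration (e.g. emissive
iodide stocks) are removed by `blank_correct`, which interpolates a blank
titration's spectra to each sample point's total anion concentration.

## ITC model

The cell (volume V0 = 1.4 mL by default) is treated as a perfusion cell:
injecting v_i displaces v_i of premixed content, so moles evolve as
n(i) = n(i−1)·(1−v_i/V0) (+ c_syringe·v_i for the titrant). The heat of
injection i is Q_i = V0·ΔH·([LA]_i − [LA]_{i−1}·(1−v_i/V0)) + q_blank.
Fitted parameters are log K, ΔH and optionally a constant per-injection
blank; measured blanks can instead be subtracted injection-wise. The
entropy follows from ΔS = (ΔH + RT·ln10·log K)/T, and every emitted record
enforces ΔG = −RT·ln K = ΔH − TΔS to numerical precision. Fits warn when
the Wiseman c parameter K·c_L leaves [1, 1000] and when the fitted ΔH is
indistinguishable from zero (non-binding). Internally everything is J,
dm³, mol dm⁻³; reports use kJ mol⁻¹ and J mol⁻¹ K⁻¹; thermogram files use
µL and µcal with 1 cal = 4.184 J.

## Transfer cycles

All transfer energies are reported for the source → target direction
(positive = unfavourable); literature values quoted for the reverse
direction are negated on input and the orientation is recorded in the
cycle's provenance map. The complex leg closes the cycle
Δ_tG°(LA⁻) = Δ_tG°(A⁻) + Δ_tG°(L) + Δ_rG°(target) − Δ_rG°(source)
exactly by construction, and any single unknown leg can be solved from the
same linear identity. The ligand leg comes from saturation solubilities
via Δ_tG° = −RT·ln(s_target/s_source), valid for a neutral solute with the
same solid phase in both solvents and ideal-dilute behaviour. Anion legs
are per-anion configuration inputs (they depend on an extra-thermodynamic
single-ion assumption) rather than built-in constants. T defaults to
298.15 K.

## Ensemble analysis

Coordinate ensembles (multi-model PDB or XYZ; frames in Å) are
post-processed purely geometrically:

* **Coordination matrix** — for each (amide N–H, acceptor heavy atom) pair
  and frame: d(N⋯X), d(H⋯X) and the N–H⋯X angle at the hydrogen. For the
  free receptor the carbonyl oxygens stand in for the anion atoms.
* **H-bond census** — intramolecular N–H⋯O=C bonds counted per frame with
  the common MD criterion d(N⋯O) ≤ 3.5 Å and angle ≥ 150°, both
  configurable; same-residue pairs excluded. The exact criterion used by
  any given study is rarely stated, so these defaults are documented
  choices, not assertions about anyone else's protocol.
* **Coordination occupancy** — per amide, the fraction of frames with any
  acceptor atom within d(H⋯X) ≤ 2.8 Å (typical H⋯acceptor range; optional
  angle gate, per-anion override). A nearest-atom attribution reports
  which acceptor atom receives the contact per frame — this is how
  binding through, e.g., the thiocyanate nitrogen is verified as an output
  statistic rather than assumed.
* **Representative structure** — coordination-matrix columns are centred
  and scaled to unit variance (distances and angles are not commensurate),
  projected on the first 2–3 principal components, and k-means clustered
  with k ∈ 2..8 chosen by silhouette; if no split scores above 0.5 the
  ensemble is treated as one cluster. The representative frame minimises
  the distance to the centroid of the most populous cluster in PC space.
  k-means with a silhouette rule is a simple reproducible choice where the
  underlying clustering method is otherwise unspecified.
* **Ring–backbone distances** — per frame, the mass-weighted centre of each
  phenyl ring versus the unweighted centroid of the five Cα atoms.
* **Spectrum averaging** — externally computed per-frame spectra (e.g. CD)
  on a shared wavelength axis are averaged over a strided subsample
  (default every 50th frame), matching the usual practice of representative
  spectra from long trajectories.

All of these are invariant under global rotation and translation, which is
property-tested with random rigid transforms.

## Synthetic data

The generators produce every input with known truth. Spectral titrations
are Gaussian emission bands (free receptor peaked at 285 nm, 2 nm pitch)
in the exact column space of the speciation design, with quenching
(complex amplitude 0.35× free) or enhancement templates and homoscedastic
Gaussian noise parameterised by SNR (peak signal over σ). NMR titrations
are population-weighted fast-exchange shifts for three protons (amide N–H
shifting downfield by 0.5 ppm on binding, Cα–H by 0.15 ppm, an aromatic
proton nearly inert). Thermograms wrap the ITC forward model with a
constant dilution heat and 1 % noise, and come with a matching blank run.
Default demo constants span the qualitative range seen for this receptor
class — log K ≈ 6 for chloride in acetonitrile down to ≈ 1.5 in methanol —
and are illustrative, not reproductions of any measured table.

The recovery-study helpers (`spectral_recovery_config`,
`shift_recovery_config`) apply the standard design rule that the titrant
window must bracket 1/K: weak binders are titrated to larger excess
(capped at 1000 equivalents / ~0.1 mol dm⁻³ titrant) so that every
simulated constant in log K ∈ [2, 5] is identifiable in principle. This is
experimental design, not tuning: the rule is fixed a priori by the binding
isotherm's information content.

The coordinate generator builds a 5-fold pseudo-cyclopeptide (amide N–H
crown on a 3 Å ring, Cα ring, carbonyl oxygens, phenyl dummy hexagons) and
places the anion endo — above the ring on the sidechain face, where all
five amide hydrogens sit within the 2.8 Å coordination cutoff by
construction — or exo below the ring, mixing states with set weights and
adding per-atom Gaussian jitter (default 0.08 Å, small enough that the
endo contact geometry survives). Frames carry ground-truth state labels.
What the generators deliberately do **not** emulate: photophysics of
quenching (no Stern–Volmer model), heteroscedastic detector noise,
baseline drift, slow-exchange NMR lineshapes, force-field-quality
conformational sampling, or solvent structure. Passing recovery tests
therefore demonstrates correctness of the inference chain under its own
model assumptions, not robustness to every artefact of real instruments.

## Problem sizes and numerical choices

The test and reproduction runs use 15-point titrations, 25-injection
thermograms, ensembles of 100–1000 frames, recovery studies of 20–50
seeded fits and oracle sweeps of 1000 random compositions — sizes chosen
to exercise every code path while keeping a full run in seconds to a few
minutes. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); pipeline stages split one top-level seed
deterministically via CRC-keyed `SeedSequence`. Ties in representative-
frame selection fall to the lowest frame index via `argmin`; species are
always reported in lexicographic (l, a) order.

## Known limitations

Only two-component (L, A) equilibria are supported — no protonation or
activity-coefficient corrections, no ionic-strength dependence. The ITC
module fits a single-site model only. Slow-exchange NMR data (emerging new
signals at high anion excess) are outside the fast-exchange model and must
be excluded from fits. CD spectra are consumed as externally computed
per-frame inputs; the package averages them but does not compute them.
Transfer cycles inherit whatever extra-thermodynamic assumption underlies
the supplied single-ion transfer energies.
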