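# Methods

`hapabm` simulates the pharmacokinetics and pharmacodynamics (PKPD) of
hypoxia-activated prodrugs (HAPs) in three culture systems — monolayers,
multicellular layers (MCLs) and multicellular spheroids — with the goal of
quantifying *bystander effects*: killing of metabolically incompetent
"target" cells by cytotoxic metabolites that diffuse out of prodrug-
activating "activator" cells.  The activator/target system is modelled on
isogenic HCT116 lines with P450 oxidoreductase (POR) overexpressed
(POR-R, POR-G) or knocked out (PORko-R, PORko-G).

## The agent-based spheroid model

Cells occupy sites of a regular cubic lattice.  A site's volume is twice
the mean cell volume (default 2,500 µm³, giving an edge of 17.1 µm), so an
occupied site is half intracellular and half extracellular — a cell volume
fraction of 0.5.  The model covers the whole culture: the lattice box
containing the spheroid is embedded in an unstirred medium column with the
prescribed volume and depth (0.2 mL / 6.1 mm during growth, 80 µL during
drug exposure), with the gas-phase O₂ value imposed at the medium–air
interface.

### Growth

Each viable cell grows exponentially in volume at rate
`(ln 2 / T_d) · V · s(O₂)` where `T_d` is the line's doubling time (31 h;
38 h for the slower POR-G clone) and `s(O₂) = O₂/(O₂ + 1 µM)` is a
Michaelis–Menten oxygen scaling (the functional form and half-saturation
are model choices; only the existence of an O₂ dependence is prescribed by
the biology).  A cell divides on reaching twice its birth volume, so one
cycle equals one doubling time at full oxygenation.  The daughter occupies
a vacant site among the 26 surrounding sites; if none exists, the chain of
cells along an outward direction is displaced one site radially.  The
outward direction is *sampled* (seeded RNG) among the outward-pointing
lattice directions with weights proportional to the squared alignment with
the radial vector: a deterministic "most radial" choice funnels mass along
the 26 quantised rays and grows non-physical spikes, while the weighted
choice keeps spheroids round and remains exactly reproducible given the
seed.

Cells kept below the severe-hypoxia threshold (0.15 µM O₂) for longer than
24 h are tagged for death and become necrotic (their site reverting to
vacant) after a further lysis delay (24 h, assumed).  Oxygen during growth
is solved as a quasi-steady radial profile (consumption is line-independent,
so the O₂ field is close to spherically symmetric) with Michaelis–Menten
uptake (V_max = 6·10⁻¹⁷ mol cell⁻¹ s⁻¹, K_m = 1.3 µM, assumed values
typical of HCT116) coupled to a quasi-steady unstirred column with the
incubator value (200 µM) at the top.  Growing 1,000 seeded cells for 4 days
yields ≈ 8,600 cells and a 435 µm equivalent-sphere diameter, matching the
reported day-4 spheroid size; growth from 3,000 cells gives ≈ 24,000 cells
and 610 µm with a hypoxic (< 4 µM) fraction of ≈ 0.23.

### Transport

Every diffusible solute (prodrug, tracked metabolites, O₂) has an
extracellular concentration on each lattice site and an intracellular
concentration in each cell.  Extracellular diffusion uses the 6-neighbour
flux form with harmonic-mean face diffusivities (D_tissue within occupied
sites, D_medium elsewhere); membrane exchange is first-order
(`dC_i/dt = K_in·C_e − K_out·C_i`) and conserves moles by construction;
intracellular metabolism, chemical chain conversion and first-order losses
complete the reaction network.  The medium column is a stack of well-
defined slabs; all box-boundary sites couple to the bottom slab with a
common conductance, which reduces the coupling to a small
(boundary-mean, slabs) linear system solved exactly.

Numerics: the method of lines with an implicit diffusion step (backward
Euler, default Δt = 10 s).  Backward Euler was chosen over Crank–Nicolson
because the implicit operator is an M-matrix — the update preserves
positivity and conserves mass exactly (measured drift < 10⁻¹¹ per hour),
whereas trapezoidal ringing on sharp bolus fronts produced clipped
undershoots that injected ≈ 2·10⁻³ of the inventory per hour.  The linear
systems are solved by Jacobi-preconditioned conjugate gradients (the
volume-weighted form is symmetric positive definite) with warm starts;
Dirichlet-clamped oracle problems fall back to a sparse LU.  The per-cell
reaction network is linear with piecewise-constant coefficients, so the
reaction update over each step is an *exact* matrix exponential applied per
group of cells sharing a line and O₂ level; the kill hazard accumulates as
part of the same linear system and is therefore step-size independent.
Against the closed-form steady profile of a consuming sphere
(`C(r)/C_R = (R/r)·sinh(r/λ)/sinh(R/λ)`, R = 200 µm, λ = 100 µm) the
solver is accurate to 1.3 % (max relative error at 17.1 µm spacing, centre
ratio 0.549 vs 0.5515), improving under grid refinement.

During anoxic drug exposures O₂ is identically zero.  When the drug bolus
carries dissolved oxygen (2.5 µM initial, "O₂ contamination"), O₂ is
integrated as a transient radial field on a fine (5 µm) mesh extending
800 µm into the unstirred medium, with semi-implicit Michaelis–Menten
uptake; the early-time diffusion boundary layer this resolves is what sets
the initial spheroid-surface O₂ (≈ 0.17 µM for the day-4 spheroid; the
corresponding reported model value is 0.25 µM — the difference reflects
the assumed V_max/K_m and the lattice surface roughness).  The surface
readout is taken at the equivalent-sphere radius, since the rough outer
fringe of a lattice spheroid holds few cells.

### Monolayer and MCL models

Monolayers: concentrations depend only on depth.  The medium column (0.15
mL over 0.32 cm², i.e. 4.7 mm deep) is discretised in 1D with the cell
layer (default 10⁵ cells) as one intracellular compartment per lineage at
the bottom, and integrated with LSODA.  The unstirred column matters: over
a 1-h exposure only the bottom ~1.2 mm of medium exchanges drug with the
cells.  MCLs: a 150 µm slab (cell volume fraction 0.5, activator/target
mix per node) between two well-stirred 8.5 mL compartments with 0.3 cm²
exposed area; the support membrane is treated as transparent.  The
acellular steady flux matches Fick's law to 0.1 %.

## Pharmacology

Prodrug reduction is intracellular and oxygen-inhibited:
`K_met(O₂) = K_met,0 · K_O₂/(K_O₂ + O₂)`, with the metabolism rate
`M′ = K_met · C_i` feeding the metabolite chain
(Prodrug → Metabolite 1 → Metabolite 2 → untracked) stoichiometrically.
Cell kill accumulates as a hazard: survival = exp(−∫ hazard dt), the
Δt → 0 limit of the discrete per-step kill probabilities
(`P_kill = K_c·M′·Δt` or `K_c·C·Δt`), making survival independent of step
subdivision.  Simultaneous cytotoxins combine by independent action,
`P = 1 − (1−P₁)(1−P₂)`, which the hazard sum reproduces exactly.
Activators and targets have identical intrinsic sensitivity.  Both an
expectation mode (mean of per-cell survival probabilities — the default)
and a Bernoulli sampling mode (realised clonogen counts) are provided.

Three models:

* **SN30000, no bystander.**  Metabolite 1 is a DNA-reactive radical that
  never leaves the cell; it is treated as quasi-steady, the kill law uses
  `M′` directly (K_c = 1.0 mM⁻¹, a calibration placeholder) and the inert
  1-oxide/nor-oxide pool receives the stoichiometric flux (tracked so the
  MCL metabolite readout can be simulated).  K_met,0: 1.88 min⁻¹ (parental
  HCT116, published), 14 min⁻¹ (POR activators) and 1.3 min⁻¹ (PORko
  targets), the latter two being the published monolayer-fit values.
* **PR104A, H+M model.**  The hydroxylamine/amine metabolites (lumped
  Metabolite 1, K_c = 0.092 mM⁻¹s⁻¹, published) are the only cytotoxins:
  hydrophilic (K_in = K_out = 10⁻³ s⁻¹, assumed), reactive
  (intracellular loss 5·10⁻³ s⁻¹ total) and slow-diffusing
  (D_tissue = 40 µm²/s, assumed).  In spheroids this model predicts
  *decreasing* target kill with activator fraction — its documented
  failure, reproduced here.
* **PR104A, dichloro model.**  Metabolite 1 additionally converts to the
  lumped dichloro mustards (Metabolite 2, K_c = 0.05 mM⁻¹s⁻¹, published):
  fast intracellularly (4·10⁻³ s⁻¹, assumed; consistent with the dichloro
  pool dominating the observed extracellular metabolites) and slowly in
  medium (3.85·10⁻⁴ s⁻¹, half-life ≈ 30 min).  Metabolite 2 is stable
  (intracellular and medium reaction four-fold slower than the parent
  mustards), lipophilic (K_in/K_out = 2) and long-ranged
  (D_tissue = 150 µm²/s) — the bystander carrier.

PR104A's K_met,0 values are not published for these lines; they were
fitted once so that the 1-h monolayer forward model reproduces the
reported potencies (IC90 17 µM for targets, 1 µM for activators), giving
0.111 min⁻¹ (PORko) and 3.58 min⁻¹ (POR) — a 32-fold differential,
comparable to the reported 24-fold reductase (FSL61) differential for the
POR-G/PORko-R pair.  At those concentrations the monolayer kill decomposes
as ≈ 69% Metabolite 1 / 31% Metabolite 2 for both lineages, matching the
reported dominance of PR104H+M in monolayers.  The monolayer IC90s are
therefore calibrated quantities; the spheroid potencies, bystander
directions and the O₂-contamination effect are genuine predictions.  In
day-4 spheroid co-cultures (50% activators) the dichloro pool's share of
the kill rises to ≈ 43% for targets while staying ≈ 30% for activators —
removing it costs the targets more, the signature of a metabolite-mediated
bystander effect.

## Protocols

The drivers mirror the wet protocols: 1-h anoxic exposures; monolayers at
10⁵ cells/0.15 mL; spheroids exposed in 80 µL with prodrug depletion
modelled; four spheroids pooled (independent seeds, clonogen-weighted) per
concentration; selective plating idealised as perfect lineage separation;
IC90 by log-linear interpolation of SF vs concentration.  The metabolite-
contribution decomposition re-runs the dichloro model with each potency
zeroed (transport unchanged).  The seeding-heterogeneity experiment grows
spheroids from different seed numbers at 10% activators with equal 16-h
doubling times and hypoxic death disabled, to a common size, then treats
with 40 µM PR104A.  Every run is reproducible from (parameter set, seed)
and the run manifest records all parameters with their provenance
(published / assumed / fitted) plus the seeds.

## Synthetic data

The generator stands in for the wet experiments: clonogenic dose–response
tables with mean-corrected lognormal replicate scatter (default CV 0.15,
matching the inter-replicate spread of clonogenic assays) and a counting
floor (10⁻⁴·⁵); MCL time courses with additive Gaussian noise (SD 2 % of
the donor bolus) and the 100 µL-per-draw sampling depletion of compartment
volumes.  It emulates the *statistical structure* of the real data —
multiplicative SF scatter, censoring, measurement noise — but not
biological systematics (plating-efficiency drift, spheroid-to-spheroid
size variation, incomplete selection), so passing recovery tests show the
calibration machinery is sound, not that real data would be this benign.

## Problem sizes used in tests and the acceptance script

Whole-pipeline checks use day-4 spheroids grown from 400 seeded cells
(≈ 3,400 cells, 320 µm) for direction experiments and from 1,000 cells
(≈ 8,600 cells, 435 µm — the reported day-4 size) for the potency and
oxygen-contamination quantities; the heterogeneity experiment uses 20 vs
2,000 seeded cells grown to 2,000 cells.  These sizes preserve the
physical regimes that drive the results (prodrug penetration depth ≪
spheroid radius for SN30000 and for PR104A at high activator fractions;
Metabolite-2 range ≫ radius) while keeping runs to tens of seconds.

## Known limitations

* All metabolite transport/kinetic parameters are assumed (the measured
  values live in unpublished supplementary tables); the calibrated
  K_met,0 values absorb any mismatch, and the fitted activator/target
  ratio (31×) accordingly exceeds the measured FSL61 differential (24×).
* The day-4 diameter from 3,000 seeds (610 µm) overshoots the reported
  426 µm — the growth model lacks the contact inhibition and nutrient
  co-limitation of the original; growth from 1,000 seeds reproduces the
  reported size and is used where size matters.
* The initial surface O₂ under the 2.5 µM bolus (0.17 µM) is ~30 % below
  the reported model value (0.25 µM); it is sensitive to the assumed O₂
  consumption parameters and to the lattice's rough surface.
* The lumped Metabolite 2 has a tissue bystander range much larger than a
  spheroid radius.  This carries the (correct) increase of target kill
  with activator fraction, but it also floods the prodrug-depleted core of
  pure-activator spheroids, so the model under-predicts the activator
  spheroid IC90 (~1.6 µM vs the reported 5 µM), and it makes the bystander
  field spatially uniform, so the seeding-heterogeneity experiment shows
  the reported increase in between-seed variability (13-fold in SD) but
  not the small reported decrease in mean target kill.
* The medium column is 1D axial and the exposure O₂ field radial; full 3D
  medium gradients (e.g. wall effects) are not represented.
* No cell-cycle phases, no mechanics beyond radial displacement, no
  glucose dependence (deliberately disabled, as in the experiments the
  model mirrors), no aerobic cytotoxicity of the prodrugs.
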