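# Methods

This note documents the models, estimators and numerical choices behind
`quenchscan`, what the synthetic-data generators do and do not emulate, and
the known limitations of each stage.

## The quench assay and its forward model

Cells co-express cytosolic mCherry and a CFTR construct carrying the
halide-sensitive YFP(H148Q/I152L) on its N-terminus. The imaging protocol is:
a 20 s baseline (frames every 2 s, 100 µl of standard buffer, 140 mM Cl⁻);
addition of 50 µl activator buffer (forskolin to 10 µM final, or DMSO as
control); 230 s to reach gating steady state; then 50 µl of iodide buffer
(400 mM NaI, chloride-free), which mixes to 100 mM extracellular I⁻ and
105 mM Cl⁻; imaging continues for 40 s. Iodide entering through open anion
channels binds the sensor and quenches it; the quench time course encodes the
whole-cell anion conductance G (nS) and the membrane potential V_m (mV).

The model (`quench_model`):

- **Mixing.** Each addition instantaneously mixes: for every solute,
  concentration = (moles present + moles added)/(new volume). The bath is an
  infinite reservoir relative to the picoliter cell, so extracellular
  concentrations are piecewise constant.
- **Binding.** Sensor fluorescence follows instantaneous competitive
  single-site equilibrium, `f_unbound = 1/(1 + I/K_I + Cl/K_Cl)`; binding
  kinetics are orders of magnitude faster than transmembrane flux.
- **Steady state.** Up to the iodide addition the cell is treated as at an
  exact steady state: V_m at its fitted value, intracellular Cl⁻ at 140 mM
  (symmetrical), no iodide. With symmetrical chloride and no iodide the
  fluorescence carries no kinetic information, so nothing is lost by not
  integrating this phase; unmodeled homeostatic currents are assumed to hold
  the state.
- **Conductance.** From the iodide addition at `t_add`,
  `g(t) = G + G_trans·exp(−(t − t_add)/τ_trans)`. The transient term models
  an endogenous anion conductance elicited by the fluid addition itself.
  That is why it is measurable in DMSO controls, where CFTR stays closed —
  and why it must be anchored at the iodide addition: anchored at the
  activator addition 230 s earlier it would have decayed by e⁻²⁰ before any
  iodide was present and could never have been estimated from control
  quenching.
- **Flux.** Goldman–Hodgkin–Katz constant-field flux per anion, with the
  permeability scale calibrated so that the slope conductance under the
  pre-addition symmetrical-chloride condition equals g(t) exactly; iodide
  permeability is `p_ratio` times chloride's. An ohmic/Nernst law is
  available (`flux_law="ohmic"`) but the GHK form is the default because it
  handles asymmetric anion mixtures without a divergent reversal potential
  at zero intracellular iodide.
- **State update.** d[X]ᵢₙ/dt = I_X/(F·V_cell) per anion (outward-positive
  anion current = influx). Two membrane-potential modes exist:
  `vm_mode="dynamic"` integrates C_m·dV_m/dt = −(I_Cl + I_I + I_leak) with a
  background leak reversing at the fitted V_m (pinning the pre-addition
  steady state); `vm_mode="fixed"` holds V_m at the fitted value. **Fixed is
  the default**: in dynamic mode the large anion conductance collapses V_m
  onto a quasi-steady value within milliseconds (C_m/g ≈ 0.2–2 ms), which
  leaves the fitted V_m almost without influence on the trace — its
  objective ridge is shallower than the forward solver's tolerance, and
  (V_m, G) recovery becomes ill-posed. With V_m fixed the model is exactly
  identifiable from noiseless data.
- **Integration.** LSODA (via `scipy.integrate.odeint`) from the iodide
  addition on the frame grid, rtol 1e−6, atol 1e−9 on concentrations,
  maximum step one frame interval. The unit suite checks the solver against
  an independently coded fixed-step RK4 integrator on a fine grid.

### Calibration constants

The sensor affinities and cell parameters are calibration inputs, not fitted
and not asserted by the screen itself. Defaults: K_I = 1.9 mM and
K_Cl = 85 mM (halide affinities reported for YFP-H148Q/I152L), V_cell = 2 pl
and C_m = 20 pF (typical HEK293), p_ratio = P_I/P_Cl = 0.4 (CFTR conducts
iodide less well than chloride), temperature 301.15 K (28 °C), background
leak g_bg = 2 nS. All live in `QuenchModelParams.constants` and can be
overridden per analysis.

## Fitting (trace_fit)

Observed traces are baseline-normalized (mean over the pre-first-addition
window = 1), making them commensurate with the model's baseline-normalized
anion-free fraction. The objective is the sum of squared residuals over the
informative window (20 s before the iodide addition through the end); the
flat earlier baseline adds no information about the anion fluxes.

`fit_trace` uses bounded trust-region least squares
(V_m ∈ [−100, +10] mV, G ∈ [0, 500] nS) with three starts spanning the
plausible range ((−60, 1), (−30, 20), (−10, 100)); the best residual wins
and non-convergence is flagged, not raised. `constrained` mode fixes
G_trans = 9 nS and τ_trans = 11.4 s (the control averages) and fits (V_m, G);
`four_free` also frees the transient pair.

**Identifiability.** The sensor's strong iodide binding (K_I ≈ 1.9 mM) makes
the post-iodide trace rate-dominated: V_m and G trade off along a narrow
ridge (Fisher analysis at V_m = −40 mV, G = 20 nS, 1 % baseline noise:
corr(V̂_m, Ĝ) ≈ −0.9996, sd(Ĝ) ≈ 48 % — versus 1.3 % if V_m were known). The
least-squares estimator is median-unbiased for G but individual-well
estimates carry that ridge variance; interpret per-well G through group
medians, as the screen does. This is a property of the assay under this
model, not of the optimizer.

`estimate_transient_params` recovers the control-average (G_trans, τ_trans)
by a joint fit across all DMSO wells: one shared transient pair plus
per-trace basal conductances. Per-trace four-parameter fits are unusable
here — the optimizer routinely finds residuals below the truth's at wildly
wrong parameter combinations — and the membrane potential multiplies every
conductance through the driving force, so the transient amplitude is only
defined relative to an assumed control V_m (free-V_m Fisher uncertainty of
G_trans exceeds 10× its value even when pooling 20 controls). The estimator
therefore fixes the control resting potential at −40 mV (a typical HEK293
value, `control_vm` argument); the amplitude estimate scales with the
driving force at that potential, a documented limitation. τ_trans is robust
to this choice.

`normalize_G` divides fitted conductance by mean cellular mCherry to cancel
transfection-efficiency differences (G and expression both scale with
plasmid dose).

## Image quantification (image_quant)

Segmentation runs on the mCherry channel: 3×3 median filter → Otsu threshold
→ hole filling → distance transform → watershed seeded at distance-map peaks
(≥ 5 px apart). A contrast guard rejects fields whose foreground/background
separation is under 5 background standard deviations, so blank fields yield
zero labels instead of Otsu-split noise. Background is the median intensity
outside the cell mask.

Per-cell QC removes cells with area outside [108, 5400] µm², major axis
above 32.4 µm, area/perimeter ratio outside [ap_min, 300] µm, border
contact, or a negative mean normalized intensity in either channel (applied
per channel, conservatively). **The lower area/perimeter default is
2.5 µm**, not the screen's stated 25 µm: the isoperimetric inequality gives
A/P ≤ √(A/4π) for any planar shape, which is at most 20.7 µm at the 5400 µm²
area cap and at most 8.1 µm under the 32.4 µm axis cap — a 25 µm lower bound
is unsatisfiable jointly with the other rules in any consistent unit system
and would empty every dataset. 2.5 µm removes sub-cellular debris
(equivalent-disk diameter below ~10 µm) while remaining coherent; all
thresholds are explicit `QCRules` parameters, so the literal 25 µm can be
applied when wanted (the test suite verifies exact boundary behaviour at
both values).

The membrane-proximal zone is a 1.08 µm band inside the cell border,
computed as the mask minus its erosion by a Euclidean disk of
round(1.08/pixel size) pixels via the distance transform (iterated
cross-shaped erosion distorts band thickness along diagonals). Intensities
are normalized per plate and channel to the median over WT-expressing cells,
and `ρ = ⟨normalized YFP in band⟩ / ⟨normalized mCherry in cell⟩`. ρ is
invariant to common per-plate gain by construction. The default pixel size
(0.656 µm/px, a generic 20× widefield figure) is a required calibration
input for real data.

## Screen statistics (plate_stats, screen)

- One-tailed Wilcoxon rank-sum tests compare per-well G (or V_m) between
  groups; the exact null distribution is used for min(n) ≤ 10 without ties,
  otherwise the tie-corrected, continuity-corrected normal approximation
  (group wells are independent, hence rank-sum rather than signed-rank).
- ρ measurements are approximately lognormal, so per-plate means of log₁₀ρ
  are compared by paired t-tests, paired by plate.
- The family of planned variant-versus-reference comparisons is adjusted by
  Benjamini–Hochberg at a 10 % FDR (via statsmodels).
- Since G = N·P_o·γ, a least-squares line through the origin fitted to WT
  (ρ, G) points (slope = Σρ·G / Σρ²) predicts the conductance a variant
  would have with WT single-channel behaviour at its measured membrane
  proximity; variants below the line are gating/conduction-defective beyond
  their trafficking defect.
- An expression QC flags a variant whose normalized mCherry is significantly
  lower than the rest (two-sided rank-sum, α = 0.05) with a median ratio
  below 0.5 (configurable); such variants are not comparable and are
  excluded.

## MD interface metrics (md_metrics)

All coordinates are handled in nm; multi-model PDB I/O goes through biotite.
The interface selection is ICL4 residues 1050–1080 plus the NBD1 loop
495–512 (human numbering; a numbering map supports orthologue offsets).

- RMSD uses Kabsch superposition on the backbone (N, Cα, C) atoms of the
  selection, with the RMSD over the same atoms.
- Daura clustering: pairwise fit-RMSDs at a 0.1 nm cutoff (boundary
  inclusive) define a neighbor graph; iteratively the frame with the most
  unassigned neighbors becomes a center (ties broken by lowest frame index),
  its neighborhood is removed, and clusters are reported ranked by
  population. The implementation is verified against an independently coded
  brute-force version on random trajectories.
- χ1 is the N-Cα-Cβ-γ dihedral (γ = CG, or OG/OG1/SG/CG1 by residue type),
  reported in [0°, 360°) under the standard sign convention (checked against
  biotite); densities use periodic 5° bins and integrate to 1.
- A hydrogen bond is present when donor–acceptor distance ≤ 0.35 nm AND the
  hydrogen–donor–acceptor angle ≤ 30°, boundaries inclusive. Missing amide
  hydrogens can be placed geometrically (bisector of N→Cα and N→C(prev),
  0.101 nm); reconstructed-hydrogen mode is flagged in the output.
- Trajectories are assumed unwrapped; `validate_unwrapped` rejects frames
  whose intra-residue backbone bonds exceed 0.25 nm as likely crossing a
  periodic boundary.
- `ca_superpose_rmsd` superposes Cα atoms of two structure files matched by
  residue id (with a residue range and exclusions, e.g. position 508 when
  one partner carries the deletion). It reproduces the published 0.8 Å
  NBD1-on-NBD1 alignment when local copies of the two experimental
  structures are placed under `data/structures/` (2pzf.pdb, 6msm.pdb); no
  structure files ship with the package and nothing is downloaded.

## Synthetic data (synthetic_data)

Generators produce every input format the pipeline consumes, with complete
ground-truth manifests; recovery tests compare pipeline output to the
manifest and nothing else. A master seed spawns per-object streams through a
CRC-32-keyed scheme that is stable across platforms; identical (spec, seed)
give identical bytes.

- **Images**: non-overlapping elliptical cells (equivalent radius 7–12 µm,
  passing the default geometry QC) with uniform mCherry; YFP split between
  the same 1.08 µm Euclidean band the analysis uses and the interior to
  realize each cell's planted ρ; Poisson shot noise, Gaussian read noise
  (sd 2), constant background (100 counts). Not emulated: illumination
  gradients, focus drift, overlapping or touching cells, cytoplasmic
  texture; passing recovery tests therefore demonstrates correctness of the
  measurement chain, not robustness to those real-data effects.
- **Traces**: the forward model scaled to a raw baseline (default 3000
  counts) plus i.i.d. Gaussian noise of sd `noise_sd`·baseline (default 1 %,
  matching a well-averaged fluorescence read). No photobleaching, drift or
  addition artifacts.
- **Plates/screens**: per spec'd variant, true median forskolin/DMSO
  conductances, per-well lognormal spread of G (cv 0.3) and Gaussian V_m
  jitter (sd 4 mV), and per-cell log₁₀ρ draws (sd 0.12 within plate).
  Default headline values mirror the screen: WT 117.7 nS (forskolin) /
  2.35 nS (DMSO), F508del 5.7/0.86 nS, and an R1070W-like revertant at
  49.76 nS where planted. WT and F508del are required on every plate
  (normalization and pairing).
- **Trajectories**: a toy poly-residue chain (backbone N, Cα, C, O, amide H;
  side-chain Cβ, Cγ) whose conformers are fixed random deformations
  (per-atom sd 0.08 nm → inter-conformer RMSD well above the 0.1 nm cutoff)
  with per-frame jitter (sd 0.004 nm, well below it); exact conformer counts
  by largest remainder, then a seeded shuffle. χ1 schedules place Cγ exactly
  at the planted dihedral; hydrogen-bond schedules put the acceptor O at
  0.29 nm (present) or 0.50 nm (absent) along the donor's N–H direction.

## Problem sizes in the acceptance computations

The acceptance script (`scripts/acceptance.py`) works at sizes chosen to
make each check statistically meaningful at desk scale: 100 noisy-fit
replicates for the conductance recovery study; 3 noiseless controls for
transient estimation; 20 random trajectories (≤ 50 frames), the full
≤ 6 × ≤ 6 group-size sweep and 1000 random geometries for the oracle
agreement checks; one 12-cell field for image recovery; and 200 simulated
null screens (5 variants, 5 plates, 1 well per variant-condition per plate,
30 ρ-cells per variant-plate) plus one planted-revertant screen for FDR
calibration. Image rendering is exercised in the dedicated image checks but
not inside the 200-screen loop, where the generator supplies per-cell ρ
summaries directly.

## Known limitations

- Per-well Ĝ carries the (V_m, G) ridge variance described above; group
  medians are the meaningful screen readout.
- G_trans is estimated relative to an assumed control resting potential.
- The model omits pH, cell-volume changes, photobleaching and stochastic
  gating; G is a deterministic macroscopic conductance.
- Segmentation assumes well-separated, roughly convex cells on a flat
  background; no temporal tracking or 3-D support.
- The hydrogen-bond module evaluates explicit donor/acceptor pair lists; it
  does not discover all possible pairs automatically.
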