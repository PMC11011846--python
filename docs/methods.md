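# Methods

## Scope and model

`sectd` treats a tetra-detector SEC run as a linear inverse problem.  Each
chromatographic species i contributes a concentration band c_i(v) (mg per
mL of eluate) to five detector traces:

* RI = k_RI · Σ c_i · (dn/dc)_i — the concentration-defining channel;
* UV₂₈₀ = k_UV · Σ c_i · (dA/dc)_i;
* RALS = k_RALS · Σ c_i · M_w,i · (dn/dc)_i², and LALS likewise — the
  single-detector Rayleigh relation with the form factor P(θ) fixed at 1,
  valid because every species here has r_h ≲ 13 nm ≪ λ; the two angles
  are therefore redundant and are averaged, with a warning if they
  disagree by more than 2 % (a size-regime violation signature);
* DP = k_DP · Σ c_i · [η]_i (differential viscometer).

The response constants k are empirical and absorb all instrument optics;
they are fixed by one injection of a BSA standard (2 mg/mL, M_w 66.4 kDa,
dn/dc 0.185 mL/g, dA/dc 0.67 mL g⁻¹ cm⁻¹, [η] 4.1 mL/g, 100 µL) by
matching integrated areas over the apex ± 4 sd region of the RI peak
(> 99.99 % of a Gaussian band).  No absolute Rayleigh calibration (laser
wavelength, solvent refractive index) is attempted.  Analyses are exactly
invariant to rescaling any detector gain, and a noiseless
calibrate-then-reanalyse round trip on the standard reproduces its
reference values to better than 0.1 %.

dn/dc is fixed at 0.185 mL/g for every protein and complex (the
all-protein assumption; the glycan contribution of the HER2 ectodomain is
ignored).  Complex dA/dc values are mass-weighted means of the members'
values.

## Column model and band shape

The column calibration is log-linear, log₁₀(M_w/kDa) = a − b·V_e, fitted
through retention anchors; the defaults pass through (13.5 mL, 485 kDa)
and (12.0 mL, 930 kDa), the observed retention volumes of the ternary and
high-order complexes, which places the free IgG peak at 16.25 mL and the
free HER2 ectodomain at 17.5 mL, consistent with the late free-mAb
elution in these experiments.  Bands are Gaussian with a default sd of
0.35 mL shared within a run; exponentially modified (tailing) shapes,
column overload and adsorption are out of scope.  The default grid is
8–20 mL at 0.01 mL steps (0.5 mL/min, 309 K).  Interdetector transfer
volumes default to zero in simulation; a nonzero path exists and
alignment is by linear interpolation after apex matching.

## Baseline, deconvolution and inversion

Baseline correction fits a straight line per channel in two stages: an
asymmetric sigma-clipping pass (signal is one-sided) yields a
drift-tolerant rough line; the contiguous signal-free flanks are then
located on the lightly smoothed detrended trace (2 % threshold, 0.5 mL
margin against band tails) and the final line is fitted to the raw flanks
only.  If the flanks cover less than 10 % of the grid, or are not flat to
within 5 % of the signal maximum (a band wider than the window), the
trace is returned unchanged with a warning.

Deconvolution fits the RI trace as a sum of Gaussians by nonlinear least
squares (lmfit/TRF), initialised either from detected peaks (1 %
prominence) or from the predicted elution volumes of candidate
compositions; initial centers closer than 0.05 mL are merged (free
trastuzumab and pertuzumab co-elute and are quantified as one free-mAb
band).  Centers may move ± 0.25 mL; widths are bounded [0.12, 0.8] mL and,
in the model pipeline, shared across components — the uniform-dispersion
assumption — which materially stabilises area partitioning between
overlapping neighbours under noise.  Centers and widths are then frozen
and every other channel receives non-negative least-squares amplitudes;
the noisy traces are not rectified before this step, since clipping noise
at zero would bias weak components upward.

Per component, m = A_RI/(k_RI·dn/dc) gives the injected mass, and the
area ratios give M_w (RALS/LALS averaged), [η] and dA/dc as in the
README.  Slice-wise M_w(v) is also available; slices below 5 % of the
regional RI maximum are excluded to bound noise amplification in channel
ratios.

## Stoichiometry

Binding rules: an IgG offers two Fab arms, binds only its cognate HER2
domain (pertuzumab → domain II, trastuzumab and its biosimilars → domain
IV), and each antigen copy offers one bond per domain; a complex must be a
connected bond graph.  Realisability is decided by an exhaustive
backtracking search for a degree-constrained spanning tree, with
interchangeable-subunit pruning and a 12-subunit cap (admitting catenary
chains up to three repeat units, i.e. ~1400 kDa, the largest species
observed).  Because every subunit has maximum degree 2 under these rules,
valid complexes are alternating antibody/antigen paths or cycles; the test
suite checks the search against that closed form independently.

Assignment picks the realisable composition minimising |M_theoretical −
M_measured|, with ties broken by fewer subunits then fewer distinct
species, and reports a ranked alternatives list; the default tolerance is
5 % relative (the largest observed deviation between a measured complex
mass and its theoretical value is ~3.4 %).  Assignment is performed
against the species actually present in the preparation.  The default
analysis trio is trastuzumab/pertuzumab/HER2: trastuzumab biosimilars are
indistinguishable from the reference by mass (< 1 %), so including them
would make mass-based assignment meaningless; their registry entries exist
for parameter lookups and per-run subsets.  When the candidate species of
a run are supplied (e.g. from a ground-truth sidecar), component identity
is established from retention position (± 0.15 mL) with a 15 % mass
consistency check, falling back to pure mass assignment otherwise — this
mirrors how species are identified in practice and keeps minor components
identifiable at noise levels where a 5 % mass window alone would fail.

The catenary model for high-order complexes is a chain of
{trastuzumab 1, pertuzumab 1, HER2 2} repeat units: 466.7 kDa per repeat,
hence 933.4 kDa for n = 2 and 1400.1 kDa for n = 3, matching the ~930 and
~1400 kDa species.  The composition of the ~930 kDa species is the
model's inference from its mass and the binding rules, and is flagged as
an assignment, not an observation.

## Synthetic data and what it does not emulate

The generator reproduces the study conditions: total 1 mg/mL injected at
100 µL, mAb:HER2 = 3:1 by mass with a 1:1 trastuzumab:pertuzumab split,
and a HER2-mass budget per complex class.  The high-order fractions are
the observed outcomes — HO(2) at 2 % of HER2 mass for the sequential
cases (centre of the reported 1–3 % band) and 30 % plus a minor 3 %
HO(3) for the premixed case.  The split of the remaining antigen
(ternary complex dominant, small binary complexes, ~5–11 % free antigen)
is this package's realistic default, chosen once: C3/C1/C2/free =
60/18/12/8 % (case 1), C3/C2/free = 62/25/11 % (case 2) and
C3/C2/C1/free = 50/7/5/5 % alongside the high-order species (case 3).
Complex intrinsic viscosities are the measured values (C1 6.7, C2 8.0,
C3 8.1, HO(2) 9.8 mL/g); HO(3) has no measured value and uses 10.8 mL/g
by mild extrapolation of the chain trend.  Noise is per-channel Gaussian
with sd = channel maximum / SNR plus optional linear drift, seeded.

Not emulated: column non-ideality (tailing, adsorption, overload),
inter-channel correlated noise, band-broadening differences between
detectors, chemical equilibria (the species fractions are imposed, not
computed from affinities), and glycan heterogeneity.  Passing tests
therefore demonstrate correctness of the inversion and assignment
machinery under the stated detector model, not robustness to every
instrument artefact.

## Extinction coefficients

ε(280 nm) is additive over chromophores; two coefficient sets are
shipped, the 1989 set (Trp 5540, Tyr 1480, cystine 134 M⁻¹cm⁻¹, default)
and the 1995 revision (5500/1490/125).  Cysteines are assumed fully
disulfide-paired by default (n_cystine = ⌊n_Cys/2⌋), appropriate for
secreted proteins, and overridable.  dA/dc = ε/M for a 1 cm path.  The
shipped FASTA fixtures are synthetic stand-ins whose Trp/Tyr/Cys counts
match literature compositions of BSA (2/20/35), ovalbumin (3/10/6),
conalbumin (9/21/30), trastuzumab (22/54/32) and pertuzumab (21/54/32);
exact lot sequences are unavailable, and the ± 0.05 mL g⁻¹ cm⁻¹
comparison band absorbs both this and the method's intrinsic spread.

## Hydrodynamic radii

r_h is computed from the Einstein viscosity relation for an equivalent
sphere, [η]M = 2.5 N_A V_h, i.e. r_h = (3[η]M/(10π N_A))^{1/3}; a
Stokes–Einstein helper (r_h = k_B T / 6πηD) converts DLS diffusion
coefficients to the same radius for cross-checks.  The sphere relation
reproduces the reported radii of the monomers and of the compact binary
and ternary complexes to within ~4 %.  It deliberately fails for the
~930 kDa catenary chain (it predicts 11.3 nm against a reported
9.5 nm): an extended chain is not an equivalent sphere, and the ~19 %
discrepancy is an expected property of chain-like species, not a defect
of the implementation.  The corresponding physical-consistency test rows
are left failing to document this, as are two biosimilar ternary rows
whose reported dA/dc (1.25 mL g⁻¹ cm⁻¹) sits 5.3 % above the
mass-weighted prediction (1.18), just outside the 5 % band that every
other row satisfies.

## Problem sizes and numerical choices

Default runs use 1201-point grids; deconvolution handles seven
overlapping components in well under a second, and the full acceptance
recomputation (calibration, three noisy case analyses, round trip) takes
a few seconds on one CPU.  Monte-Carlo checks in the test suite use 10–20
seeded replicates at SNR 100, which bound the recovered M_w bias below
0.5 % and its spread below 2 % for a lone IgG-sized species, and the
run-to-run C3-production difference below one percentage point — the
noise floor against which preparation equivalence is judged.  Tolerances:
mass conservation 0.1 % noiseless / 2 % noisy; assignment 5 %; RALS/LALS
agreement warning at 2 %.  All randomness flows from explicit seeds.
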