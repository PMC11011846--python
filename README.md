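# sectd — size-exclusion chromatography with tetra-detection

`sectd` analyses four-detector size-exclusion chromatography (SEC-TD) runs
of antibody–antigen mixtures: it recovers, per chromatographic species, the
absolute molecular weight M_w, the concentration c, the intrinsic viscosity
[η], the hydrodynamic radius r_h and the specific absorbance increment
dA/dc, and then identifies each species as a valence-consistent
antibody–antigen complex.  It was built around mixtures of the anti-HER2
IgG antibodies trastuzumab (and its biosimilars) and pertuzumab with the
glycosylated HER2 extracellular domain, where the method resolves
heterodimers (C1, 1 mAb + 1 HER2), heterotrimers (C2, 1 mAb + 2 HER2), the
two-antibody ternary complex (C3) and chain-like high-order catenary
complexes HO(n) of alternating bivalent antibodies and two-epitope
antigens.

Because raw instrument data for such experiments are rarely shared, the
package also contains a forward simulator that generates four-channel
chromatograms (RI, UV₂₈₀, RALS, LALS, differential viscometer) with known
ground truth, including presets for the three order-of-addition
experiments (HER2 added to trastuzumab first, to pertuzumab first, or to a
premixed 1:1 antibody solution, always at a 3:1 mAb:HER2 mass ratio).

## The model

A SEC column separates by size; detector responses for a species eluting
at concentration c(v) are

    RI(v)    ∝ c · (dn/dc)                 (defines concentration)
    UV280(v) ∝ c · (dA/dc)
    RALS(v), LALS(v) ∝ c · M_w · (dn/dc)²  (small-particle Rayleigh regime)
    DP(v)    ∝ c · [η]

All five response constants are fixed by a single injection of a bovine
serum albumin standard of known M_w, c, dn/dc, dA/dc and [η].  Overlapping
species are separated by nonlinear least-squares deconvolution of the RI
trace into Gaussian components; per-channel component areas then give

    M_w  = (A_LS/k_LS) / (m · (dn/dc)²),   m = A_RI/(k_RI · dn/dc)
    [η]  = (A_DP/k_DP) / m
    dA/dc = (A_UV/k_UV) / m
    r_h  = (3 [η] M / (10 π N_A))^{1/3}    (Einstein equivalent sphere)

Stoichiometry assignment enumerates all complexes realisable under the
binding rules — two Fab arms per IgG, one bond per antigen domain (HER2
domain II binds pertuzumab, domain IV trastuzumab), connected bond graph —
and picks the composition whose theoretical mass is closest to the
measured M_w.  Sequence-based extinction coefficients use the 280 nm
aromatic-residue additivity method (ε = n_Trp·5540 + n_Tyr·1480 +
n_cystine·134 M⁻¹cm⁻¹ by default).

## Worked example

Simulate the premixed-antibody experiment (case 3) with realistic detector
noise, calibrate on the BSA standard, and invert:

```python
import sectd as sd

registry = sd.default_registry()
trio = registry.subset(sd.DEFAULT_ANALYSIS_SPECIES)
column = sd.default_column_calibration()

standard, reference = sd.make_bsa_standard(column=column)
calibration = sd.calibrate_detectors(standard, reference, column=column)

scenario = sd.scenario_case(3)
chrom, truth = sd.simulate_scenario(scenario, registry,
                                    noise=sd.NoiseSpec(snr=100, seed=7))
model = sd.SECTDModel(chrom, calibration, trio,
                      expected_compositions=[c.composition
                                             for c in scenario.components])
results = model.fit(total_antigen_mass_mg=scenario.antigen_mass_mg(registry))
print(results.summary())
```

```
SEC tetra-detection analysis
======================================================================
case: 3    components: 7    relative residual: 2.77e-02
total detected mass: 0.0997 mg    unassigned: 1
----------------------------------------------------------------------
 peak  center_mL  mw_kda  ...  label                       composition  her2_mass_fraction
    0     11.064  1368.3  ...  HO(3) her2:6+pertuzumab:3+trastuzumab:3              0.0306
    1     11.991   934.5  ...  HO(2) her2:4+pertuzumab:2+trastuzumab:2              0.2991
    2     13.590   467.9  ...     C3 her2:2+pertuzumab:1+trastuzumab:1              0.4985
    3     14.467   302.2  ...     C2               her2:2+pertuzumab:1              0.0710
    4     15.194   238.6  ...     C1              her2:1+trastuzumab:1              0.0494
    5     16.250   147.5  ...   free                     trastuzumab:1              0.0000
    6     17.453    69.9  ...   unassigned                           -                 NaN
----------------------------------------------------------------------
C3 production (HER2-mass %): 49.85    high-order production: 32.97
```

The 930 kDa species eluting at 12 mL is identified as the two-repeat
catenary chain HO(2) (theoretical 933.4 kDa), and the generated 30 %
high-order HER2-mass fraction is recovered at 29.9 %.  Assigning a single
measured mass directly:

```python
>>> print(sd.assign_stoichiometry(932.0, trio))
932.0 kDa -> HO(2) [her2:4+pertuzumab:2+trastuzumab:2] theoretical 933.4 kDa (rel. error 0.15%)
```

A `sectd` command-line tool wraps the same pipeline
(`sectd simulate / calibrate / analyze / assign / report`); see
`sectd --help`.

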