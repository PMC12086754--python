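# Methods

This note documents the models, the data they run on, the numerical
choices, and the limits of what the shipped synthetic data can show.

## Photon model

CT numbers are *theoretical*: no reconstruction, beam hardening or scatter.
For a mixture with mass fractions `w_i` and density `ρ`,

    μ̄ = ρ · Σ_E W(E) · Σ_i w_i (μ/ρ)_i(E),      HU = 1000 (μ̄ − μ̄_w)/μ̄_w ,

with elemental mass attenuation coefficients (total, with coherent
scattering) from a transcribed XCOM-style table on a 10–150 keV grid,
interpolated log-log linearly.  Photon cross sections are near power laws in
energy away from edges, so the log-log interpolant is smooth and exact at
nodes; iodine and tin carry extra grid points bracketing their K edges.
Water (H 0.1119 / O 0.8881, 1 g/cm³) is the normalization material
everywhere, so `HU(water) = 0` holds structurally.

Spectral weights `W(E)` default to **energy fluence** (`fluence · E`),
emulating an energy-integrating detector; plain photon-fluence weighting is
available (`weighting="photon"`) for sensitivity checks.  At 140 kVp the two
differ by a few HU in bone.

### Tube spectra

Five fixture spectra ship with the package (80/100/120/140 kVp, plus
Sn-filtered 140 kVp for the DECT high channel), generated once by a simple
tungsten-anode model: Kramers bremsstrahlung `(E0 − E)/E` on a 1 keV grid,
tungsten characteristic K lines above 69.5 kVp, and Beer–Lambert filtration.
Total filtration is **8 mm Al-equivalent** for all tubes — a typical CT
value once inherent filtration and the bowtie center are counted — giving a
mean energy of 65.5 keV (energy-fluence effective energy ≈ 74 keV) at
140 kVp; the DECT high channel adds 0.4 mm Sn.  The analysis is only weakly
sensitive to the fine spectral shape because every CT number is normalized
to water computed with the same spectrum; the filtration choice was frozen
after verifying that all four tube voltages populate every calibration
segment of the conventional curve.

### Stoichiometric parameterization

    μ/μ_w = ρ_e,rel · (K_ph Z̃^3.62 + K_coh Ẑ^1.86 + K_KN),

with `Z̃^3.62 = Σ λ_i Z_i^3.62`, `Ẑ^1.86 = Σ λ_i Z_i^1.86` over electron
fractions `λ_i`.  The fit to the 13 Gammex RMI 467 insert CT numbers is
linear least squares subject to the water-normalization constraint
(the bracket evaluates to exactly 1 for water), solved by null-space
elimination — so water predicts 0 HU to machine precision and the overall
scale of the K's is fixed.  RMS residual on the insert set is ≈ 0.9 HU at
140 kVp; soft-tissue transfer to spectrum-exact HUs is within ~6 HU.
Iodine-bearing tissues (thyroid) are a known failure mode: the `Z^3.62`
photoelectric term is valid to Z ≈ 20 and mispredicts the 0.1% iodine
content by tens of HU.  This is a property of the stoichiometric model
itself, not of the implementation.

## Proton model

RSP is computed at a single beam energy (100 MeV; `β²` relativistic from
CODATA constants) with the uncorrected Bethe stopping number

    L(I) = ln(2 m_e c² β² / (I (1 − β²))) − β²,      RSP = ρ_e,rel · L(I)/L(I_w).

Mixture I-values follow Bragg additivity on the electron scale
(`ln I = Σ λ_i ln I_i`) with ICRU-37 elemental I-values.  The water I-value
(≈ 69.0 eV) is computed from the same elemental table and mixture rule —
not hard-coded — so `RSP(water) = 1` is structural and the choice of
elemental I-value set cancels to first order in all RSP *ratios*.  No
shell, density or Barkas corrections; no energy dependence beyond the fixed
beam energy.

## SECT calibration curves

Tissues are binned into segments by their **predicted** (parameterized) CT
number, matching how a clinical calibration transfers a phantom fit to
tabulated tissues.  Segment membership is half-open `[lo, hi)` with the top
segment closed; each segment is an unweighted OLS line of reference RSP on
predicted HU; joins are not continuity-constrained and the jump sizes are
reported in the curve metadata.  Boundaries:

* conventional (adult-70): −1000 / −150 / b / 200 / 3100 HU with the
  adipose–soft boundary b = −85/−75/−75/−95 HU at 80/100/120/140 kVp;
* age-specific (pediatric-53, one curve per age and sex, 12 in all):
  −1000 / −100 / 200 / 4100 HU.

The lung segment is anchored at the air endpoint (−1000 HU, RSP 0) because
tissue tables contain at most one inflated-lung entry.  Above the top
boundary the bone line extrapolates; below −1000 HU inputs clamp; outputs
floor at 0.  Note that water is *not* a calibration tissue: the fitted soft
segment passes ≈ 2% above the water point (curve(0 HU) ≈ 1.02), a real
property of stoichiometric curves fitted to protein-rich organ clusters.

Error statistics are reported in percent per tissue group
(`ΔRSP = (RSP_est − RSP_ref)/RSP_ref`), mean/sd (sample sd, ddof = 1)/
min/max, always excluding teeth and in-body air; an optional exclusion list
removes the medullary-cavity tissues (ids 22, 23, 25) for the sensitivity
variant.

## DECT calibration

Effective-atomic-number route with reduced CT numbers `u = HU/1000 + 1`:

1. `Γ = u_L/u_H`; the **Z_eff scale** is defined self-consistently: the
   spectrum-averaged electron cross section of each element (relative to
   water) is fitted as a degree-4 polynomial in Z, and a mixture's
   theoretical Z_eff is the root of the elemental ratio curve at the
   mixture's Γ.  A cubic polynomial `Z_eff(Γ)` is then fitted on the insert
   set and checked for strict monotonicity.
2. **Electron density**: `ρ_e = u / F_spec(Z_eff)`, averaged over the two
   channels with equal weights.  The degree-4 `F_spec(Z)` polynomials are
   fitted on the inserts *together with* the adult reference tissues: the
   epoxy surrogates alone leave a coverage gap at Z_eff 8–10 and have a
   slightly different mixture geometry than body tissues, which costs ~1%
   electron-density bias exactly where spongiosa live.  The polynomials are
   rescaled so that `ρ_e(water) = 1` exactly (water anchoring).
3. **I-value**: `ln I` as a cubic polynomial in Z_eff, fitted on the adult
   reference tissues so calibration and (pediatric) evaluation tissues stay
   disjoint.
4. RSP through the same Bethe ratio.

Z_eff estimates are clamped to the fitted validity range with a flag;
air-like voxels (`u_H ≤ 0`) raise for scalar inputs and are flagged and set
to RSP 0 in vectorized use.  Polynomial orders (3/4/3) are configurable.
With theoretical (noiseless) CT numbers the per-group pediatric errors are
|mean| ≤ 0.45%, sd ≤ 0.36%; with 12/8 HU channel noise the water-voxel bias
stays below 0.5% over 10⁴ draws.

## Tissue data

* **Adult-70** and **Gammex RMI 467**: transcribed CSV fixtures with a
  provenance note per row; mass fractions validated to Σw = 1 ± 10⁻³.
* **Pediatric-53 (synthetic)**: generated deterministically per age/sex,
  not transcribed.  Numbering follows the reference convention (1 teeth,
  2–21 spongiosa sites, 22–25 medullary cavities — soft group, 26–52 soft
  organs, 53 in-body air; sex differences only in gonads, uterus/prostate
  and breast glandular tissue).  Construction rules:
  * soft organs: adult organ blended with water (hydration fraction 0.22 /
    0.18 / 0.11 / 0.06 / 0.025 / 0 from newborn to adult; adipose 2.5×),
    densities mixed harmonically — younger tissue has more O, less C;
  * spongiosa: mass mixture of cortical bone, unmineralized osteoid matrix,
    cartilage and red/yellow marrow; the mineralized fraction scales with
    age (0.32 → 1.0), displaced mineral becomes osteoid, and marrow
    converts red → yellow with age, peripheral sites first;
  * medullary cavities: marrow plus a hydroxyapatite admixture; the
    admixture of the 1-year-old humeral cavity is solved (bisection) so its
    theoretical 140 kVp CT number equals the one published per-tissue anchor
    available for this family, 309 HU; other sites and ages scale from it.

  **What passing tests show, and what they do not**: the synthetic database
  reproduces the *structure* of the pediatric problem — watery soft tissues
  sitting below the adult curve (systematic overestimation), mineral-poor
  dense young spongiosa above it (systematic underestimation, monotone with
  age), marrow-like medullary tissues inside the bone fit region, and a
  roughly tenfold DECT improvement.  It does **not** reproduce the
  published per-group statistics to printed precision, and its extreme
  per-tissue errors (≈ −5%/+4%) are milder than the published extremes
  (−18.65%/+17.80%), which arise from specific reference compositions that
  are not public.  Tests asserting those printed values are expected to
  fail against the stand-in and are kept as an honest record of the gap.

## Phantoms and range evaluation

Phantoms are voxelized geometric primitives (ellipsoid/box/cylinder,
priority-ordered, 0-based voxel indices, contours as boolean masks).
Per-voxel densities are truncated-normal
(`ρ ~ N(ρ_t, (0.017/3) ρ_t)`, cut at ±3σ so the stated 3σ = 1.7% band is
literal).  Images add i.i.d. Gaussian noise (7 HU SECT; 12/8 HU independent
DECT channels).  Contour tissue assignment is 1-D k-means (scikit-learn,
`n_init=10`, seeded) on the contour's CT numbers, clusters matched to
candidate tissues by rank order of mean HU — the matching rule is a
package choice; ground-truth layouts are recovered exactly in the noiseless
case and with < 1% error at 5× noise separation.

WER is the RSP path integral with exact parametric voxel-boundary
(Siddon-style) traversal — deterministic, additive over ray segments, and
invariant under grid refinement to 10⁻⁹ mm.  The stop depth is a
caller-supplied parameter measured from the volume entry point; dose-engine
or spot-energy bookkeeping is out of scope, so WER differences isolate the
CT-conversion effect.  R80 is the deepest linear-interpolated crossing of
80% of the profile maximum on the distal side; profiles qualify for range
reporting only above 20% of a stated reference dose.

Default problem sizes — a 24×24×60-voxel slab phantom at 2 mm spacing with
16 axial rays — keep the full analysis (all tables plus the range demo) in
the low seconds on one CPU; the statistics are insensitive to enlarging the
grid because the noise averages down along each ray.

## Known limitations

* Theoretical CT numbers only: no beam hardening, scatter, reconstruction
  kernel or partial-volume effects, so all reported errors are lower bounds
  on clinical ones.
* The attenuation table is a transcription on a coarse grid; trace-element
  values (Cl, K) may be ~1–2% off, which is negligible for tissues
  (≤ 0.4% mass) but visible in element-level fits.
* The pediatric database is synthetic (above); quantitative agreement with
  published pediatric statistics is out of reach by construction.
* Single proton energy; no dose calculation, DVH metrics or robustness
  scenarios.
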