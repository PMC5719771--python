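# Methods

This package reconstructs, end to end and at desk scale, a percentage
depth dose (PDD) study in a layered soft-tissue/lung phantom: 5 cm of
acrylic (PMMA) over 13 cm of lung-equivalent material over 10 cm of
acrylic, irradiated by a 15 MV photon beam at SSD 100 cm with square
fields of 1x1 to 10x10 cm².  Three measurement/calculation routes are
modelled and compared on the central axis:

1. **Thermoluminescent dosimetry** (synthetic campaign + full
   reading-to-dose chain),
2. a **Monte Carlo dose engine** in cylindrical slab geometry (the
   reference), and
3. **analytic heterogeneity-correction algorithms** (generalized Batho,
   modified Batho, equivalent TAR) applied to homogeneous beam data, i.e.
   the corrections a correction-based treatment-planning system would use.

The scientific point the pipeline reproduces: correction-based algorithms
contain no electron transport, so under lateral electronic disequilibrium
— small fields in low-density lung — they overestimate the central-axis
lung dose relative to Monte Carlo by large factors, exceeding 100% for
the 1x1 cm² field.

## Materials and physics data

Four materials are embedded (water, PMMA, ICRP lung tissue, LiF), each
with a composition, a bulk density, and per-gram tables on a common log
energy grid (0.001–20 MeV, 140 points, log–log interpolation):

* **Mass collision stopping powers** from the Bethe formula with ICRU-37
  mean excitation energies (75 eV water, 74 eV PMMA, 75.3 eV lung, 94 eV
  LiF) and the generic Sternheimer density-effect parameterization.
  Spot checks against ESTAR agree within ~0.2% at 1 MeV for water, PMMA
  and lung.  The **lung density effect is evaluated at the compact-tissue
  density 1.05 g/cm³** (as in the ICRU-37/ESTAR lung table): polarization
  happens in the condensed septa, not in the air that lowers the bulk
  density to the 0.26 g/cm³ used for transport.  This choice matters: with
  the density effect evaluated at 0.26 g/cm³ the lung/water stopping-power
  ratio would rise above 1 and the Bragg–Gray conversion factors would
  leave their accepted range.
* **Mass attenuation coefficients** assembled per element from the
  Klein–Nishina cross section (incoherent; binding neglected), a
  photoelectric power-law fit and a pair-production fit calibrated on
  water anchors; coherent scattering is excluded (no energy transfer).
  Accuracy is a few percent at megavoltage energies; the Monte Carlo
  engine and its analytic attenuation oracle share these same tables, so
  the transport check is exact with respect to the data it uses.

Tables ship as packaged CSVs; `python -m lungpdd._table_gen` regenerates
them bit-for-bit from the model.

## Beam model

The 15 MV spectrum is a parametric bremsstrahlung stand-in,
w(E) ∝ E·exp(−E/2.0 MeV)·(1−E/15 MeV)^0.2 on 0.25–15 MeV (60 bins).  Its
mean energy is 3.78 MeV and the shape was calibrated once so the
simulated homogeneous-water depth of maximum dose lands at ~3 cm, the
value quoted for the modelled beam; PDD(10 cm) ≈ 75% and PDD(20 cm) ≈ 49%
then follow without further adjustment, close to clinical 15 MV data.

The mean initial secondary-electron energy used by the Bragg–Gray
conversion is E0 = ½·hν·(σ_tr/σ) with both Klein–Nishina cross sections
evaluated at the single mean spectrum energy hν (not spectrum-averaged);
for this spectrum E0 = 1.14 MeV.  The resulting conversion factors,
(S/ρ)_PMMA/(S/ρ)_water = 0.970 and (S/ρ)_lung/(S/ρ)_water = 0.989, vary
by < 0.7% over E0 ∈ [0.5, 5] MeV, so the conversion is insensitive to the
exact E0 definition.

**Direction of the conversion.**  Bragg–Gray gives D_medium/D_water =
(S/ρ)_medium/(S/ρ)_water for a common electron fluence; a water-calibrated
reading converts to dose-to-medium by *multiplying* with the medium/water
ratio (≈0.966 acrylic, ≈0.988 lung).  Media with lower stopping power
than water absorb *less* dose, not more.

## Monte Carlo engine

Cylindrically symmetric slab geometry: a point source at z = −SSD
illuminates a circular field of radius R = L/√π (the equal-area
equivalent of the L×L square field, preserving scatter conditions) on the
slab stack; the world is 15 cm in radius (the 30×30 cm² slab cross
section) and 30 cm deep.

* **Photon transport** is analog with Woodcock (delta) tracking:
  Klein–Nishina Compton sampling (1/ε proposal with exact rejection),
  photoelectric absorption, and pair production above 1.022 MeV with the
  annihilation photons re-emitted isotropically.  Default photon cutoff
  1 keV (the tally is insensitive to anything below ~10 keV at 15 MV; the
  historical 0.1 keV setting remains available in the options).
* **Electron transport** (`kernel` mode) moves secondaries along stepped
  CSDA tracks: steps of 0.05 g/cm², energy loss from the collision
  stopping power of the local material, Highland multiple-scattering
  deflections per step, 70 keV kinetic-energy cutoff.  Steps never cross
  a density boundary (they are capped at slab/chip planes), and each
  step's energy is apportioned over the depth bins its segment crosses —
  midpoint binning would alias, because every electron entering a new
  slab restarts its step grid at the interface and the phase-locked
  deposits produce a spurious spike/dip pattern there.  No bremsstrahlung
  secondaries, δ-rays, or energy straggling: the model is built to capture
  longitudinal buildup and lateral electronic disequilibrium, which the
  study's conclusions rest on, at a small fraction of condensed-history
  cost.
* **Tally**: energy per 0.5 cm depth bin (60 bins) inside a central
  scoring cylinder, divided by the bin's voxel mass.  The default scoring
  radius is the TLD-chip-area radius (πr² = 0.09 cm², r = 0.169 cm).  For
  homogeneous beam-data runs the scoring radius widens to
  min(0.5·R_field, 3 cm): the central-axis dose of a broad field is
  laterally flat at the sub-percent level over that region, and the wider
  cylinder reaches ion-chamber-class statistics at desk-scale history
  counts.  Uncertainties come from 20 contiguous history batches; a
  helper doubles the history count until the maximum-dose bin reaches a
  target relative standard error (run lengths in the original study were
  likewise chosen to reach <0.5% at the dose maximum).
* **Determinism**: a fixed seed reproduces the tally bit for bit.

### Detector perturbation

The TLD chip (3×3×0.9 mm³ LiF) is itself a heterogeneity.  Fcor(d) is the
ratio of the dose absorbed in the chip (chip modelled explicitly in the
geometry) to the dose the undisturbed medium would absorb in the same
chip-sized region.  The paired runs share the seed *and* the Woodcock
majorant (the chip material is registered in both runs), so photon
histories are identical outside the chip's sphere of influence; the ratio
is formed per correlated batch with a jackknife standard error.  In lung,
Fcor ≈ 0.85 for LiF — the cavity reads below the medium dose, as the
LiF/lung stopping-power ratio predicts — and measured doses are divided
by Fcor to remove the perturbation.

## Heterogeneity corrections

All three algorithms consume TMR/TAR beam data derived from the engine's
homogeneous-water PDDs: TMR(d) = PDD(d)·((SSD+d)/(SSD+dmax))², TAR taken
equal to TMR (backscatter-free approximation; the Batho product uses TAR
ratios, so the absolute backscatter scale largely cancels).  Beam data
include sub-centimetre field entries (L = 0.25, 0.5 cm) because the
equivalent-TAR method scales the field radius by the mean relative
electron density, which for lung-dominated paths falls well below the
smallest study field.

With layers numbered upward from the one containing the point, z_m the
distance from the point to the top of layer m, and ρ the electron density
relative to water (the region above the phantom counts as water — the
convention under which a homogeneous water phantom gives exactly 1):

* generalized Batho: CF = Π_m TAR(z_m, r)^(ρ_m − ρ_{m+1});
* modified Batho: the same product on TMR(z_m + dmax, r);
* equivalent TAR (1-D slab form): CF = TAR(d′, r·ρ̄)/TAR(d, r), d′ the
  radiological depth, ρ̄ the thickness-weighted mean relative electron
  density from surface to d.

Numerical choices: Batho-family factors are undefined in buildup, so for
d < dmax the factor is held at its dmax value; TAR arguments are clamped
to ≥ dmax because PDD-derived TAR lacks the electronic-equilibrium
plateau the power law assumes near zero depth; beam-data lookups clamp at
the table edges (the dmax-shifted TMR argument and the ETAR-scaled radius
can fall slightly outside the simulated grid).  Corrected curves are the
homogeneous PDD times CF, renormalized at the smoothed maximum.

A real correction-based TPS differs in its beam data (measured, with
head-scatter modelling) and in ETAR's full 3-D scatter-weighted density;
the 1-D slab simplification is adequate for central-axis slab geometry.

## TLD chain and the synthetic campaign

The processing chain is linear algebra over reader units: batch mean
zero-dose reading TL0; per-chip sensitivities S_i normalized to batch
mean 1; per-session control factors FC_m from 8 control chips exposed to
1 Gy each session; TLcorr = ((raw − TL0)/S_i)/FC_m; unweighted OLS of
dose on mean corrected reading over the 0.25/0.5/1 Gy groups (8 chips
each); per-depth dose from the two-chip mean with an uncertainty that
combines replicate spread, control-factor spread, and the fit covariance
in quadrature.  The lower detection limit is TL0 + 3 sd of the zero
readings, expressed in dose through the calibration curve; readings below
it are flagged, never clamped.

The synthetic campaign draws lognormal sensitivities (σ = 5%), per-chip
zero-dose signals (500 ± 50 reader units), lognormal per-session reader
drifts (σ = 2%) acting on the net signal, and 1% multiplicative read
noise; the latent signal for dose D is (D − B)/A with the study's
calibration line (A = 0.0009 cGy per unit, B = 1.4243 cGy) as ground
truth.  Sensitivity characterization averages 5 irradiation/readout
cycles, the standard TLD-protocol practice; with single-cycle
characterization the per-chip sensitivity error alone (~1.4%) would make
a 2% per-depth recovery target unreachable.  Under these defaults the
chain recovers known doses within 2% at 96% of depth points (pooled over
100 seeds), with zero mean bias and total per-depth uncertainty below 5%.

What the generator does **not** emulate: glow-curve shapes, fading,
supralinearity, dose-rate or energy dependence of LiF response, annealing
failures.  Passing recovery tests therefore validates the *processing
chain*, not TLD physics; the generator's role is to make every pipeline
stage testable with known truth.

## Comparison analysis

PDDs are normalized to 100 at the maximum of an inverse-variance-weighted
3-bin moving average (a single upward-fluctuating bin cannot steal the
normalization; the value at the chosen bin is taken from the raw curve).
Measured-style and simulated curves use the same policy.  Ratio curves
propagate relative errors in quadrature and exclude zero-denominator
bins.  Interface metrics over a 1 cm window (2 bins): lung overdose just
below the soft-tissue→lung interface, soft-tissue underdose just below
the lung→soft-tissue interface, and the maximum |ratio − 1| over all lung
bins.

One subtlety: in the first lung centimetres the correction factors can
dip slightly below 1 because the overlying acrylic's relative electron
density (1.156) exceeds the water the beam data assume; deeper in the
lung all three methods give CF > 1, which is the failure the comparison
quantifies.

## Problem sizes

Default analysis runs use 0.8×10⁶ histories per field (≈5 s each); the
headline 1×1 cm² comparison uses 2×10⁶ histories for beam data and the
homogeneous curve and 4×10⁶ for the heterogeneous reference; the
homogeneous 10×10 precision run doubles from 2×10⁶ until the dose-maximum
bin is below 0.5% relative standard error.  These sizes put the
statistical noise well below every effect being measured (the lung
discrepancy signal is ~100%, measured with ~3% noise).

## Known limitations

* The electron model is straight-line CSDA with Gaussian small-angle
  scattering: no backscatter, no δ-rays, no straggling, no radiative
  losses.  Interface dose structure on the millimetre scale is therefore
  approximate; 0.5 cm bins average over it.
* Attenuation data are fit-based (few-percent accuracy at high energy);
  PDD slopes inherit this, the tuned dmax does not.
* The commercial convolution algorithm (AAA) the original comparison also
  covered is proprietary and out of scope; its interface-specific figures
  are represented only by a constructed-ratio example in the comparison
  tests.
* The equivalent-TAR implementation is the 1-D slab form, not the full
  3-D scatter-weighted version.
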