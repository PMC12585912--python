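# Methods

This note documents the models implemented in `hmgdyn`, the defaults and
their rationale, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Two-state thermal unfolding

The melt model assumes a reversible two-state equilibrium N ⇌ U at every
temperature of the 288–368 K ramp (1 K/min; scan-rate effects are out of
scope). The free energy of unfolding follows Gibbs–Helmholtz:

    ΔG(T) = ΔHm·(1 − T/Tm) + ΔCp·[(T − Tm) − T·ln(T/Tm)]

with fraction unfolded f_U = K/(1+K), K = exp(−ΔG/RT), R = 8.3145
J/(mol·K). The observed fluorescence ratio is the population-weighted sum
of a linear native baseline and a quadratic unfolded baseline, i.e. the
native baseline is weighted by (1 − f_U) and the unfolded one by f_U.
ΔCp is fixed at 0 by default: near Tm the extrapolated populations are
insensitive to it (≤2 percentage points for plausible ΔCp), and it is
poorly determined from a single curve; `fit_dcp=True` frees it.

Fitting is weighted (inverse variance when uncertainties are supplied)
trust-region least squares over {Tm, ΔHm, (ΔCp), 5 baseline
coefficients}. Initialization is data driven: Tm from the steepest signal
slope, baselines from linear fits to the outer 15% of points. A curve
without a resolvable transition inside the ramp returns `converged=False`
instead of raising. The reported Tm uncertainty is floored at 0.3 K, the
instrument-level repeat reproducibility of the measurement.

The melt generator's default baselines produce a 0.5-unit transition step
on a ~1.0 ratio signal — realistic for a domain whose fold buries two
tryptophans — and its default relative noise is 0.5% (the instrument
noise of the ratio trace is not characterized in the source data; this
default is flagged in the generator config). Together these reproduce a
single-fit Tm repeatability near 0.15 K, consistent with the stated
sub-0.3 K technical reproducibility of the measurement. Monte-Carlo
recovery tests use 100 fixed seeds.

## ¹⁵N relaxation and model-free analysis

Decays are fit as I₀·exp(−R·t) by weighted least squares with duplicate
delays treated as replicate observations; hetNOE is I_sat/I₀ with
quadrature error propagation. All R₁/R₂/NOE uncertainties are floored at
3% of the value.

The forward model is the standard dipolar + CSA description of amide ¹⁵N
relaxation with r_NH = 1.02 Å and Δσ = −160 ppm for every residue
(single-field data do not support per-residue CSA). The spectral density
is Lipari–Szabo with the 2/5 prefactor; for axially symmetric diffusion a
three-Lorentzian sum with weights from the NH-to-unique-axis angle is
used. Fully anisotropic per-residue spectral densities are not
implemented (the axial model was statistically sufficient for the data
this pipeline addresses); the tensor estimator still reports a fully
anisotropic fit for model comparison.

Diffusion-tensor estimation follows the quadric approach: each rigid
residue (hetNOE > 0.5 free / 0.6 bound, to exclude flexible sites)
yields a local correlation time from its rigid-limit R₂/R₁ ratio, hence
D_loc = 1/(6τ_loc) ≈ ½·n̂ᵀ(Tr(D)·I − D)n̂. Isotropic, axial and fully
anisotropic forms are compared by F-tests at α = 0.05. For NMR ensembles
the NH vector of each residue is the normalized mean over conformers —
the simplest defensible reduction, since the source procedure does not
state one.

Per-residue model-free fits use the five canonical models (1: S²;
2: S², τₑ; 3: S², R_ex; 4: S², τₑ, R_ex; 5: S²_f, S², τₑ) against
(R₁, R₂, NOE) with the tensor fixed, following the two-step convention
(tensor first, internal motion second; terminal residues are refit with
the diffusion parameters held fixed). Selection follows the staged
goodness-of-fit / F-test procedure: a model is accepted when its χ²
passes a parametric-bootstrap null at α = 0.05 (the bootstrap replaces
tabulated Monte-Carlo critical values; replicate count configurable,
default 500 — tests and scripted checks use 30–100 replicates to keep
runtimes proportionate, which only coarsens the critical-value quantile),
and nested extensions must pass an F-test at α = 0.20. With only three
observables, models 4 and 5 have zero residual degrees of freedom; they
are accepted only on (numerically) exact fits, otherwise the lowest-AIC
model is reported with a warning flag.

## CPMG relaxation dispersion

R₂,eff = −(1/T_relax)·ln(I/I₀). Uncertainties are
max(duplicate-derived rmsd, 0.3 s⁻¹, 2% of R₂,eff); the error floor is
applied after the duplicate rmsd is computed. A residue is flagged
dispersive only when ΔR₂ (lowest-ν minus highest-ν R₂,eff) exceeds
1.5 s⁻¹ **and** the flat no-exchange fit has reduced χ² > 4.

Two engines implement the two-site model (shared parameters p_B, k_ex,
per-residue Δω in ppm converted at the ¹⁵N Larmor frequency, per-field
exchange-free R₂,₀):

- `simulate_bm` — numerical Bloch–McConnell: in-phase single-quantum
  magnetization propagated through the echo train
  (τ–180–2τ–180–τ, τ = T_relax/(4·n_echo)) by matrix exponentials, with
  ideal instantaneous refocusing pulses acting as complex conjugation.
  The TROSY constant-time sequence's finite pulse widths are not
  modelled; parameter-level agreement, not raw spectra, is the target.
- `simulate_cr` — the exact closed form of the Carver–Richards family:
  the echo-unit propagator is assembled from the analytic eigenvalue
  decomposition of the 2×2 exchange Liouvillian and raised to the echo
  count through its own eigenvalues, keeping the initial-condition
  amplitude exactly. It reduces to the classic Carver–Richards (1972)
  expression (`carver_richards_72`, retained for reference) in the
  many-echo limit; the classic form's neglected amplitude factor biases
  it by up to ~4% at low pulsing rates in slow exchange, which is why
  the exact form is the default fit function.

Fields default to 900 and 1200 MHz with T_relax 40 and 30 ms and the
measured ν_CPMG grids (duplicates included). Grouped fitting shares
(p_B, k_ex) across residues with per-residue Δω and per-residue,
per-field R₂,₀; optimization is trust-region least squares with eight
multi-starts over k_ex ∈ [100, 10⁴] s⁻¹ (log-spaced) and seeded jitter on
the Δω starts. Group membership is user input.

Δω signs come from HSQC/HMQC ¹⁵N peak-position comparison. The package
models the observed line of each coherence as the slowly decaying
eigenvalue of the exchange Liouvillian (HMQC = mean of the ZQ and DQ
lines). In the perturbative slow-exchange regime (|Δω_H| well below
|Δω_N|) the MQ lines are shifted further from the major state than the
SQ line, so a downfield minor state gives a *negative* HSQC − HMQC
difference; `dw_sign` encodes that convention and returns 0 below a
threshold defaulting to the ppm equivalent of ~1 Hz at 900 MHz. When
|Δω_H| approaches |Δω_N| the relation is not sign-stable; such residues
should be left undetermined.

## RDCs and geometry

The alignment matrix is parameterized directly in Hz (it absorbs the
dipolar prefactor): D = n̂ᵀA n̂ with A symmetric traceless, solved
linearly (SVD) from ≥5 non-degenerate NH vectors. Q uses the Cornilescu
normalization rms(D_obs − D_calc)/rms(D_obs); a D_a-based normalization
is intentionally not the default. Ensemble Q is computed per conformer
(mean ± sd), matching how ensemble statistics are conventionally quoted.
Missing amide protons are built in the peptide plane opposite the
C′–N/Cα–N bisector at 1.02 Å.

Backbone RMSD uses Kabsch superposition over N, Cα, C′, O (the
conventional "heavy backbone" set). Helix axes are the principal
component of the Cα trace oriented N→C; inter-helix angles use directed
axes so supplementary packings remain distinct. The rms distance of Cα
atoms from the fitted axis (~2.3 Å for an ideal helix) serves as a
non-helicity diagnostic with a 3 Å warning threshold.

The toy-structure generator builds ideal poly-alanine helices from
canonical internal coordinates (φ = −57°, ψ = −47°) via NeRF chain
extension, rotates each segment's PCA axis onto the requested direction
and spaces segments to avoid overlap. Requested inter-axis angles are
recovered within well under 2°. The default alignment tensor
(D_a = 12 Hz, R = 0.2, fixed orientation) back-calculates couplings
spanning roughly −13 to +24 Hz on the default three-helix structure,
matching the measured span.

## Titration CSP

CSP = √(Δ_H² + (Δ_N/6)²) with the ¹⁵N scaling fixed at 6. Thresholds are
the 10% trimmed mean plus one or two standard deviations; the trim is
one-sided (largest 10% removed) — the convention for CSP outlier
rejection, where the perturbed residues *are* the outliers — and the sd
is computed on the trimmed set; both choices are config-exposed. CSP
defaults to the 0% → 100% molar-ratio pair. Occupancy defaults to the
stoichiometric (tight-binding) limit because no dissociation constant is
available; a quadratic-binding mode would take a Kd but is not needed
for the analyses here. Trajectory-direction comparison uses (Δ_H, Δ_N/6)
vectors across the 0–30% ("early") and 70–100% ("late") windows by
default; displacements below 0.005 ppm leave the angle undefined.

The titration generator represents slow-exchange residues by the
followed free-state peak (intensity ∝ 1 − fraction bound, NaN at
saturation); full two-peak bookkeeping, lineshapes and peak overlap are
not simulated.

## Conformational-selection vs induced-fit flux

The four-state square U ⇌ F, F + D ⇌ FD, U + D ⇌ UD, UD ⇌ FD is treated
pseudo-first-order in free DNA. Thermodynamic cycle closure is enforced
(to 10⁻⁶ relative) for closed schemes, so the stationary state is a true
equilibrium and instantaneous net edge fluxes vanish there. The pathway
decomposition therefore quantifies the *relaxation* fluxes: starting
from the unbound condition (U and F at their folding equilibrium, no
complex), the net flux into FD through F→FD (conformational selection)
and through UD→FD (induced fit) is integrated over the whole approach to
equilibrium. The integral is evaluated in closed form: with dp/dt = K·p,
X = ∫(p − p∞)dt solves K·X = p∞ − p₀ (minimum-norm/group-inverse solve;
the null-space ambiguity cancels from net edge fluxes by detailed
balance), and each branch flux is the corresponding linear functional of
X. An edge with zero forward rate constant carries zero pathway flux by
definition (a driven cycle's backward leak is not entry flux). The
independent oracle integrates the master equation explicitly with the
cumulative edge fluxes as auxiliary states. The eigenvalue spectrum of K
is reported for relaxation-time analysis.

The default preset derives its rates from measured quantities: folding
rates from the CPMG exchange rate (k_ex = 3.5·10³ s⁻¹) with the
folded/unfolded split re-derived from the thermal parameters at the
evaluation temperature (identifying the CPMG minor state with the
unfolded species); a common diffusion-limited k_on = 10⁸ M⁻¹s⁻¹ for both
conformers; folded-state affinity K_d = 10 nM; the bound-state folding
equilibrium from the DNA-bound melt parameters (Tm 340.6 K,
ΔH 472 kJ/mol); UD→FD folding at k_f (binding assumed not to slow
folding) with the remaining rate set by cycle closure. Under this preset
conformational selection carries >99.9% of the flux at 310 K across
nM–μM DNA; the result is sensitive mainly to the assumed k_on(U)/k_on(F)
ratio, which is exposed as a parameter.

## Synthetic data: what it does and does not show

Every generator is a deterministic function of (parameters, seed), with
per-data-kind child streams from a root seed. The generators reproduce
the acquisition grids (288–368 K ramp; the R₁/R₂ delay lists; the
900/1200 MHz ν_CPMG grids with duplicates; the 0–120% molar-ratio
series), the stated noise models (0.5% melt, ≥3% relaxation,
max(0.3 s⁻¹, 2%) dispersion, 1 Hz RDC) and the fitted-parameter presets
of the characterized states, so that passing tests demonstrate correct
parameter recovery *in the experimentally relevant regime*. They do not
emulate spectral artifacts — peak overlap, lineshape distortions,
baseline drift, solvent exchange, partial assignment — so passing tests
bound algorithmic correctness, not robustness to raw-spectrum pathology.

## Problem sizes used in scripted checks

The scripted checks use 100-seed melt Monte-Carlo, 10-residue two-field
dispersion groups, 60-residue model-free recovery with 50-replicate
bootstrap, 43-coupling RDC sets and 1000-seed dispersion-screen
false-positive estimation; these sizes match the scale of the real data
sets while keeping the default test run proportionate.
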