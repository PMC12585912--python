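# hmgdyn

Quantitative analysis toolkit for the stability and dynamics of HMG-box
DNA-binding domains (DBDs), built around the free and DNA-bound states of
the Sox2 HMG domain. HMG-box DBDs such as Sox2's are only marginally
stable: at physiological temperature a substantial fraction of the free
domain is (partially) unfolded, yet the folded helical bundle is the
binding-competent species. `hmgdyn` implements the full chain of analyses
needed to characterize this behaviour from biophysical and NMR data, with
a synthetic-data layer that reproduces the statistical structure of every
input so the whole pipeline is testable end to end:

- **Thermal unfolding** (`hmgdyn.thermal`): two-state melt-curve fitting
  with linear/quadratic baselines and population extrapolation via
  Gibbs–Helmholtz,
  ΔG(T) = ΔH·(1 − T/Tₘ) + ΔC·[(T − Tₘ) − T·ln(T/Tₘ)],
  f_U = K/(1+K), K = exp(−ΔG/RT).
- **¹⁵N relaxation / model-free** (`hmgdyn.modelfree`): mono-exponential
  decay fits, hetNOE, rotational diffusion tensor estimation from R₂/R₁,
  and Lipari–Szabo model-free fitting (models 1–5: S², τₑ, R_ex, S²_f)
  with staged statistical model selection.
- **CPMG relaxation dispersion** (`hmgdyn.cpmg`): R₂,eff computation,
  exchange screening, numerical Bloch–McConnell and exact closed-form
  two-site engines, grouped global fits of (p_B, k_ex, Δω), Δω sign
  determination from HSQC/HMQC comparison, and random-coil-shift
  correlation.
- **RDCs and structure geometry** (`hmgdyn.rdc`): SVD alignment-tensor
  fitting, Q = rms(D_obs − D_calc)/rms(D_obs), per-conformer ensemble
  statistics, Kabsch backbone RMSD and inter-helix angles.
- **Titration CSP analysis** (`hmgdyn.csp`):
  CSP = √(Δ_H² + (Δ_N/6)²), 10%-trimmed-mean thresholds, intensity
  ratios and early/late trajectory-direction comparison.
- **Binding-pathway flux** (`hmgdyn.flux`): four-state
  (U, F, U·DNA, F·DNA) kinetic square quantifying conformational
  selection versus induced fit.

## Worked example

Populations of the folded state from two-state melt parameters
(Tₘ in K, ΔH in J/mol):

```python
>>> from hmgdyn.thermal import TwoStateThermo, fraction_unfolded, population_shift
>>> free = TwoStateThermo(tm=311.8, dhm=176e3)
>>> round(100 * fraction_unfolded(310.0, free), 1)   # % unfolded at 37 C
40.3
>>> round(100 * fraction_unfolded(293.0, free))      # % unfolded at 20 C
1
>>> population_shift(free, d_tm=2.0, t_eval=310.0)   # folded, before/after +2 K
(0.5972921769709912, 0.695696030032899)
```

A free HMG domain with Tₘ = 311.8 K and ΔH = 176 kJ/mol is ~40% unfolded
at 310 K but only ~1% at 293 K, and a modest 2 K stabilization (for
example from the electrostatic environment near DNA) raises the folded
population from ~60% to ~70%.

The same computations are reachable from the command line:

```sh
hmgdyn simulate --kind melt --preset bound --out sim
hmgdyn melt-fit sim/melt.csv --t-eval 310 --out fit
```

which fits the synthetic bound-state melt (true Tₘ 340.6 K) and prints
the fitted parameters and populations as JSON. The other subcommands
(`relax-fit`, `modelfree`, `cpmg-fit`, `rdc-fit`, `geometry`, `csp`,
`flux`) follow the same pattern; `hmgdyn --help` lists them.

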