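# Methods

## Model and conventions

The quantity of interest is the reduction free energy ΔG of a protein
disulfide bond: the free-energy difference between the reduced state (two
free cysteine thiols) and the oxidized state (the S–S bond), obtained from
non-equilibrium alchemical switching simulations. Each switching replica
yields a work value; the package consumes those works (or the underlying
dH/dλ series) and carries them to a classified reduction potential.

Conventions fixed across the package:

* λ = 0 is the oxidized state, λ = 1 the reduced state; "forward" means
  oxidized → reduced.
* Backward replicas are recorded on their own 1 → 0 path and stored as the
  work done on that path. Negation into the forward frame happens inside
  the estimators, never in I/O, so raw data stay faithful to the
  simulation output.
* All energies are kJ/mol; k_B = 0.0083145 kJ mol⁻¹ K⁻¹; the default
  temperature is 300 K (β ≈ 0.401 mol/kJ). Potentials appear in mV only at
  the Nernst boundary, with n = 2 electrons and
  F = 96.485 kJ mol⁻¹ V⁻¹.

Work is the λ-integral of dH/dλ, computed by the trapezoidal rule on
whatever grid the input provides. Files indexed by time instead of λ are
mapped linearly onto [0, 1] (reversed for backward series). Duplicate λ
rows are an error, never silently averaged.

## Estimators

**CGI.** Gaussians are fitted (sample mean, n−1 sd) to the forward works
and the negated backward works. ΔG is the intersection abscissa of the two
densities, i.e. the root of

(1/σ_f² − 1/σ_r²)x² − 2(μ_f/σ_f² − μ_r/σ_r²)x + (μ_f²/σ_f² − μ_r²/σ_r²) − 2 ln(σ_r/σ_f) = 0.

Equal variances give the exact midpoint (μ_f + μ_r)/2. Root policy for the
unequal-variance quadratic: the physically meaningful intersection lies
between the two modes, so the real root inside [min(μ), max(μ)] is
preferred; when zero or two roots fall inside, the one nearest the
midpoint is taken and a warning flag is set in the diagnostics; complex
roots fall back to the midpoint with the same flag. Degenerate (zero-sd)
inputs are an error — a Gaussian intersection is undefined there.

**BAR.** With f(t) = 1/(1+eᵗ), M = ln(n_F/n_B) and W̃ = −W_B, ΔG is the
root of g(ΔG) = Σ f(M + β(W_F − ΔG)) − Σ f(−M + β(ΔG − W̃)). g is strictly
monotone (running from −n_B to +n_F), so the root is unique; it is
bracketed on [min − 50, max + 50] kJ/mol over all forward-frame works and
found by Brent's method to a default tolerance of 1e-8 kJ/mol. Two
conditions are reported as non-overlap errors: no sign change on the
bracket, and an objective that underflows to a flat zero plateau around
the nominal root (both Fermi sums vanish between well-separated work
clusters, leaving ΔG undetermined within a wide interval).

**Uncertainty.** The bootstrap is the only uncertainty channel: each
direction is resampled independently with replacement, the estimator is
re-run on each paired resample (vectorized: closed-form for CGI, 60
bisection iterations for BAR, which is exhaustive for double precision on
the bracket), and the SE is the ddof-1 sd over resamples. Resampling is
deterministic given the seed. Resamples on which the estimator fails are
dropped; more than 10 % failures is an error carrying the count.

**Diagnostics.** The Bhattacharyya coefficient between the two fitted
Gaussians has the closed form √(2σ₁σ₂/(σ₁²+σ₂²))·exp(−(μ₁−μ₂)²/(4(σ₁²+σ₂²)));
values near zero flag the non-overlap regime where both estimators
degrade. The per-direction Kolmogorov–Smirnov test against the fitted
Gaussian is a pragmatic normality screen only — it uses fitted parameters,
so its p-values are approximate (conservative nulls), and they gate
nothing automatically.

## Redox pipeline

E_cal(mV) = −ΔG/(n·0.096485). The linear calibration E_corr = slope·E_cal
+ intercept maps computed onto experimentally anchored potentials; the
default is slope 1.5, intercept −43 mV, both overridable. Published
per-bond data shipped in `dsbredox.datasets` include a
`TABLE_CONSISTENT_CALIBRATION` with intercept −47 mV: the published
corrected-potential column is consistent with −47, not with the −43 the
accompanying text states, and reproduction runs must use the value the
table actually used. The datasets module also records, row by row, which
published work values are Nernst-consistent with their printed potentials
(10 of 17 are; the others presumably reflect a different estimator pass),
so reproduction code can choose its input column deliberately.

Classification is applied to the *corrected* potential: functional iff
−330 ≤ E_corr ≤ −89 mV (boundaries inclusive, matching the inclusive
phrasing of the literature window), structural otherwise. The literature
gray zone between −470 and −330 mV is reported as a flag on structural
records but deliberately does not create a third class. Catalytic vs
allosteric sub-typing of functional bonds is user-supplied metadata — it
derives from deletion-construct experiments, not from the potential.

## Hybrid topology

The dual-state residue (CYD) is the oxidized cysteine template expanded by
a dummy atom HUD (chargeless, zero-LJ, no bonded terms at λ = 0; the thiol
hydrogen at λ = 1) and two virtual sites VC and VS constrained to the CB
and S positions, interaction-free in both states. The builder takes the
two residue templates as *inputs* (force-field parameterization is out of
scope; the packaged templates are synthetic stand-ins mimicking the
relevant entries) and guarantees by construction that the A-state
projection equals the oxidized template and the B-state projection the
reduced one — `validate_state_equivalence` re-checks this item by item.

Terms that exist only while the S–S bond does (the bond, both CB–S–S
angles, and the dihedrals whose central axis is S1–S2) span the residue
pair and are emitted as A-state-only cross terms. Which dihedrals across
S1–S2 to retain is genuinely open in the source protocol; the resolution
here is purely topological — every 4-atom path X–S1–S2–Y over the A-state
connectivity — which for the packaged templates yields exactly
CB1–S1–S2–CB2. Virtual sites are written as position-constraint records
rather than any engine's virtual-site algebra. The writer's dialect
(versioned, A/B parameter columns, A-only terms carrying no B parameters)
is pinned bit-for-bit by a golden file.

## Structure analysis

Disulfides are detected as CYS SG–SG pairs within 2.5 Å (the covalent bond
is ~2.05 Å; the margin tolerates strained geometry without reaching
non-bonded sulfur contacts), paired greedily by increasing distance with
each cysteine in at most one bond — equivalent to minimum-weight matching
for realistic geometries, where bonds are far better separated than the
cutoff. First model only; disordered atoms resolve to the
highest-occupancy altloc; residue numbering is as-authored. Bond-to-site
distances use the SG midpoint (the reference point is not standardized;
per-SG distances are also reported). Secondary structure is consumed from
a DSSP-style map reduced to helix/strand/loop, never computed.

## Synthetic data

The Crooks relation admits exactly one Gaussian work-distribution pair:
equal variances σ² and means ΔG ± βσ²/2. The generator draws from that
pair, which makes dissipation a function of σ rather than a free knob, and
satisfies the fluctuation identity analytically (a property test checks
the closed-form log-density ratio equals β(W − ΔG) to 1e-10). Default
panel scale mirrors the study design: 17 bonds × 500 replicas per
direction at 300 K. Work-distribution widths are only shown graphically in
the source, so σ defaults to 4 kJ/mol with 2–8 kJ/mol used across tests as
a plausible range. dH/dλ series are a cosine hump plus seeded noise,
affinely shifted so the trapezoidal integral hits the requested work
exactly.

What the generator does *not* emulate: MD time correlation between
replicas, anharmonic work tails, conformational substates, or per-bond
variance differences. Passing tests therefore demonstrate estimator and
pipeline correctness under the Gaussian-work model the method itself
assumes — not robustness to real-MD pathologies such as skewed work
distributions or slow degrees of freedom.

## Problem sizes and numerical choices

The test suite runs the estimator-recovery grid at 3 ΔG × 3 σ conditions ×
20 seeds with 500 works per direction and 200 bootstrap resamples per
estimate; headline precision numbers use 1000 resamples. Oracle checks use
1e-6-spaced grid scans (BAR root, CGI density intersection) and 10⁶-point
Riemann sums (integrator). The analysis drivers regenerate their panel
deterministically from a fixed seed (1729), so `scratch/` contents are
disposable.

## Known limitations

* CGI assumes Gaussian work distributions; on skewed real data BAR should
  be preferred (both are always reported).
* The KS normality screen is approximate (fitted-parameter null).
* The greedy disulfide pairing can in principle differ from optimal
  matching in pathological geometries where several SG atoms crowd within
  the cutoff.
* The topology writer targets the package's own documented dialect, not
  any specific MD engine's grammar.
* Analytic (non-bootstrap) BAR variance is not implemented.
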