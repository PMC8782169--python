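# Methods

This note records the models behind each analysis stage, the defaults that
matter, what the synthetic generators do and do not emulate, and the places
where a design choice was genuinely open.

## Two-state fast-exchange titration model

A protein P at total concentration P₀ binds a ligand L at total
L₀ = ratio·P₀ with a single site.  The bound protein fraction is the
physical root of the mass balance K_d·[PL] = (P₀−[PL])·(L₀−[PL]),

    f_b = ((P₀+L₀+K_d) − sqrt((P₀+L₀+K_d)² − 4·P₀·L₀)) / (2·P₀),

evaluated in the conjugate form 2·L₀/(S + sqrt(S²−4·P₀·L₀)) to avoid
catastrophic cancellation when K_d ≪ P₀ (at P₀ = 50 µM, K_d = 3.7 µM the
naive form loses several digits at low ratios).  Working with total rather
than free ligand matters in this regime: the free≈total approximation is
qualitatively wrong when the protein depletes a comparable ligand pool.

In fast exchange every amide resonance sits at the population-weighted
average of its free and bound positions, so the combined CSP

    Δδ = sqrt(ΔδH² + (w·ΔδN)²),  w = 0.152,

follows Δδ(ratio) = Δδ_max·f_b(P₀, ratio·P₀, K_d).  The nitrogen weight w
compresses the ~5× wider ¹⁵N shift range onto the ¹H scale; it is an
argument everywhere it appears.

Per-residue fits use `scipy.optimize.curve_fit` with bounds
K_d ∈ [1 nM, 0.1 M], Δδ_max ∈ [0, 10·max observed CSP], multi-started from
K_d = 1, 10, 100 µM to avoid local minima; parameter errors come from the
fit covariance.  A fit is flagged non-converged when the optimizer pins a
bound, when σ(K_d) > K_d, or when the trajectory never exceeds the noise
floor (default 0.015 ppm, ≈3× the shift precision of a careful HSQC
titration).  The global K_d is the unweighted mean over converged residues
with the across-residue sd as dispersion; an inverse-variance-weighted mean
is available but not the default, since per-residue error bars in this kind
of fit are often optimistic and would concentrate weight unduly.  Zero
converged fits is not an error but an explicit "no significant binding"
verdict — the correct answer for a non-binding RNA.

Titration ratios are taken at face value (no dilution correction); if a
titration was performed by adding ligand stock, the caller should correct
P₀ and the ratios before building the series.

## Peak tracking

Assignments are transferred between spectra by greedy one-to-one
nearest-neighbour matching in the weighted (δH, w·δN) plane, chained
point-to-point through a titration so that large cumulative shifts are
followed as a sequence of small steps.  Moves beyond `max_jump` (default
0.2 ppm-equivalents per step; 0.5 for the single free→pool step in SIA,
where saturation is reached in one jump) are left unmatched.  When two
reference peaks contest the same nearest target at comparable distances
(within a factor of 2) both are flagged ambiguous rather than silently
swapped — crossing trajectories are a reporting problem, not something to
guess through.  Residues that lose their peak at any point are dropped from
downstream fitting with a warning.

## SIA scoring

For each scanned position, four pool spectra (base A/C/G/U fixed) are
compared against one free spectrum.  Reporter peaks are those whose maximum
CSP across the pools exceeds mean + 1·sd of the pooled CSP distribution,
with a floor of three reporters topped up deterministically by peak id —
the selection is scale-free and reproducible, two properties a manual
"subset of shifting residues" does not have.  Each reporter's four CSPs are
normalized to that reporter's largest shift *before* averaging across
reporters (per-peak normalization equalizes reporters with different
intrinsic Δδ_max; a global-max variant exists behind a flag for sensitivity
analysis), and the per-base means are rescaled so the top base scores
exactly 1.  A base is called preferred when the second-best score falls
below 1 − margin; the default margin 0.2 operationalizes "significant
specificity" and, under the simulated null (equal affinities), keeps the
false-call rate below 5%.

## Relaxation and rotational correlation time

Peak volumes decay as V(t) = V₀·exp(−t/T); fits are seeded from a
log-linear regression and flagged excluded for constant volumes,
non-positive T, or relative T error above 50%.  Residues with overlapped
peaks are excluded by mask before any averaging (reason "overlap").

τc is inverted from the ratio of the fitted times,

    τc = sqrt(6·T₁/T₂ − 7) / (4π·ν_N),   ν_N = 0.10136905·ν_H,

the standard approximation obtained by dropping high-frequency
spectral-density terms.  Against a full rigid-rotor forward model
(dipolar + CSA) the inversion is biased by only ~1–3% over τc = 2–10 ns at
600–800 MHz — negligible next to the fit noise, and the reason this is the
default in common relaxation tools.  Below T₁/T₂ = 7/6 the expression is
undefined and NaN is returned so the residue drops out of averages.

Domain τc is the mean ± sd over a declared residue subset, after discarding
values outside median ± 1.5·IQR (default on).  The trimming protects the
domain estimate from flexible tails and interdomain linkers, which tumble
faster than the domain core; it is switchable because for very small
subsets the IQR itself is noisy.

## BLI kinetics

Sensorgrams are zeroed on the mean of the final 20% of the baseline stage
and each stage clock is re-zeroed at its start.  Association phases are fit
with R(t) = R_eq·(1 − exp(−k_obs·t)) over a window that drops the first 2 s
(mixing artifact; the window is an argument).  The kinetic analysis is a
closed-form weighted linear regression k_obs = k_on·C + k_off with
inverse-variance weights from the per-fit k_obs errors (low-concentration
fits are noisier), falling back to unweighted with residual-scaled errors
on exact inputs.  K_d = k_off/k_on carries first-order propagated error.  A
negative intercept flags the K_d unreliable and the dissociation-phase
k_off — always computed as a consistency check — becomes the fallback.
Mass-transport limitation is not modelled; a warning fires when the top
concentration deviates from linearity by more than 3σ.

## Synthetic data: what it emulates and what it does not

All simulators are pure functions of a ground-truth record that includes
its seed; identical records give bit-identical outputs.

*Titration*: 50 µM protein, ratios {0, 0.5, 1, 2, 4, 6, 8, 10, 12}, peaks
at δ_free + f_b·Δδ_max + Gaussian noise (0.003 ppm ¹H / 0.02 ppm ¹⁵N,
typical HSQC precision).  Reporter free shifts are drawn over the amide
region with a minimum pairwise separation of 0.6 ppm-equivalents — the
generator emulates *well-dispersed* reporter peaks, the condition under
which assignment transfer is well-posed — and Δδ_max is drawn at
0.05–0.20 ppm (¹H) / 0.2–1.2 ppm (¹⁵N), the scale of direct-contact
residues at a small protein–RNA interface.

*SIA*: each pool is collapsed to a single effective K_d
(= K_d_ref/affinity); the default preferred:non-preferred affinity contrast
is 50×, consistent with a tight GG-recognizing complex whose single-base
mutants are too weak to titrate to saturation.  Pools are sampled at 70 µM
protein, ratio 1:4.

*Relaxation*: T₁/T₂ are manufactured from a rigid isotropic rotor with
N–H dipolar (r = 1.02 Å) and ¹⁵N CSA (−160 ppm) contributions,
J(ω) = (2/5)·τc/(1+ω²τc²), at the standard delay series (T₁: 20–1500 ms,
T₂: 10–150 ms) with 5% multiplicative Gaussian noise.  These constants
exist only to make internally consistent T₁/T₂ pairs; the analysis stage
never depends on them.

*BLI*: 1:1 Langmuir association/dissociation at 1/2/4/8 µM analyte with
k_on = 10⁴ M⁻¹s⁻¹, k_off = 0.04 s⁻¹ (K_d = 4 µM), 60/120/120 s stages at
5 Hz, a static 0.05 nm sensor offset, optional drift, and 0.01 nm read
noise.

What the generators deliberately do **not** emulate: exchange broadening
and intermediate-exchange lineshapes (analysis uses positions only),
peak-intensity loss on binding, spectral crowding beyond the dispersion
floor, anisotropic or internal motion in relaxation (no Lipari–Szabo),
mass-transport-limited or heterogeneous-ligand sensorgrams, and instrument
artifacts beyond white noise and linear drift.  Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
models — not robustness to every pathology of real spectra; the exclusion
flags (overlap, ambiguity, unusable fits) are the designed escape hatches
for such data.

## Problem sizes

The recovery studies use 100 seeded replicates per quantity with 8–11
reporter residues per spectrum and four-sensor concentration ladders —
comfortably enough for stable medians while keeping the whole suite and
the acceptance script in the tens of seconds on one CPU.

## Known limitations

- Single-site 1:1 binding throughout; no cooperative or multi-site models.
- The global K_d averages converged residues only; which residues converge
  depends on the noise floor, so very weak shifters self-select out.
- τc inversion assumes isotropic tumbling and negligible internal motion;
  it reports an *effective* correlation time.
- The kobs-route BLI analysis needs ≥3 concentrations and assumes the
  association phase reaches curvature within the window; a pure linear ramp
  is unusable by design.
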