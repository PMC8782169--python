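# nmrbind

Quantitative analysis of small protein-domain/RNA interactions from solution
NMR and biolayer interferometry (BLI) data — the workflow used to
characterize how individual CCHC zinc-finger (ZnF) domains recognize
single-stranded RNA.

The package is aimed at structural biologists and biophysicists who have
assigned 2D amide peak lists (HSQC/SOFAST-HMQC) and staged sensorgrams in
plain-text form and want a scripted, testable route from those tables to
dissociation constants, nucleobase-preference scores, rotational correlation
times and kinetic rate constants.  A synthetic-data module generates every
input class with known ground truth, so each stage can be validated by
parameter recovery.

## What it computes

**Chemical-shift-perturbation (CSP) titrations.**  For each backbone amide
the combined shift change is

    Δδ = sqrt(ΔδH² + (0.152·ΔδN)²)

In the fast-exchange regime peaks move with the bound protein fraction, which
for a two-state interaction at totals (P₀, L₀) is the exact quadratic root

    f_b = ((P₀+L₀+K_d) − sqrt((P₀+L₀+K_d)² − 4·P₀·L₀)) / (2·P₀)

Per-residue isotherms Δδ(ratio) = Δδ_max·f_b(P₀, ratio·P₀, K_d) are fitted by
nonlinear least squares (no free≈total approximation — at 50 µM protein and
micromolar K_d that shortcut fails) and merged into a global K_d as the
unweighted mean across converged residues.  A titration in which no residue
shifts above the noise floor yields an explicit "no significant binding"
verdict rather than a number.

**Scaffold Independent Analysis (SIA).**  Binding to four quasi-degenerate
RNA pools (one base fixed per scanned position) is compared through per-peak
CSPs at a 1:4 protein:RNA ratio.  Each reporter peak's four pool CSPs are
normalized to that peak's largest shift, averaged across reporters, and
rescaled so the best base scores exactly 1; a base is called preferred only
when the runner-up falls below 1 − margin (default margin 0.2).

**¹⁵N relaxation → τc.**  Per-residue T₁ and T₂ come from mono-exponential
fits V(t) = V₀·exp(−t/T) over the delay series; the domain rotational
correlation time follows from

    τc = sqrt(6·T₁/T₂ − 7) / (4π·ν_N)

averaged (with IQR trimming against flexible tails) over a declared residue
subset.  Comparing τc between adjacent domains tests whether they tumble as
one unit or independently.

**BLI kinetics.**  After baseline alignment, each sensor's association phase
is fitted with R(t) = R_eq·(1 − exp(−k_obs·t)); the linear regression
k_obs = k_on·C + k_off across analyte concentrations gives k_on (slope),
k_off (intercept) and K_d = k_off/k_on, with the dissociation-phase k_off as
an internal consistency check.

## Worked example

Simulate a titration of a 50 µM protein with a tight RNA (true K_d 3.7 µM,
protein:RNA ratios 0–12) and re-analyze it end to end:

```bash
$ nmrbind simulate-titration --kd 3.7e-6 --seed 11 --out demo/titration
wrote 9 peak lists + manifest to demo/titration
$ nmrbind fit-kd --manifest demo/titration/manifest.csv --out demo/kd
{"verdict": "binding detected", "global_kd_M": 4.094650224977744e-06,
 "sd_M": 7.733061825603747e-07, "n_residues": 10}
```

The pipeline tracked all 10 reporter peaks through the nine titration
points, fitted each residue's isotherm, and merged them into a global
K_d = 4.1 ± 0.8 µM (mean ± sd across residues) — one noisy realization of
the 3.7 µM truth; the across-residue sd is the honest dispersion of the
estimate.  The same round trip for BLI:

```bash
$ nmrbind simulate-bli --seed 11 --out demo/bli
wrote 4 sensorgrams to demo/bli
$ nmrbind bli-fit demo/bli/sensor*.csv --out demo/bli/fit
{"kon_per_M_s": 9873.7, "koff_per_s": 0.04036, "kd_uM": 4.088,
 "r_squared": 0.9996, "n_concs": 4, "reliable": true,
 "dissociation_koff_per_s": [0.0408, 0.0389, 0.0404, 0.0397]}
```

Sensors at 1/2/4/8 µM analyte (truth: k_on = 10⁴ M⁻¹s⁻¹, k_off = 0.04 s⁻¹)
return K_d ≈ 4.1 µM with the dissociation-phase k_off values agreeing with
the regression intercept.  The other subcommands — `simulate-sia`,
`sia-score`, `simulate-relaxation`, `fit-relaxation`, `tauc`, `csp` — follow
the same simulate → analyze pattern; every simulator writes a
`ground_truth.json` sidecar for recovery checks.

## Layout

- `src/nmrbind/io_formats.py` — peak-list (TSV/Sparky), construct FASTA and
  sensorgram CSV readers/writers; shared constants
- `src/nmrbind/csp_titration.py` — CSP, bound fraction, peak tracking, K_d
  fitting, saturation comparison, interaction-surface calling
- `src/nmrbind/sia_scoring.py` — pool CSP profiles, reporter selection,
  preference scores and calls
- `src/nmrbind/relaxation.py` — decay fitting, overlap exclusion, τc
- `src/nmrbind/bli_kinetics.py` — alignment, k_obs, kinetic regression
- `src/nmrbind/synthetic_data.py` — ground-truth simulators for all inputs
- `src/nmrbind/cli.py` — `nmrbind` command-line entry points
- `docs/methods.md` — models, assumptions, parameter choices, limitations
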