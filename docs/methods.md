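# Methods

This note documents the models behind `etgating`, the conventions and
numerical choices the implementation fixes where the underlying physics
leaves them open, and what the synthetic-data suites do and do not
demonstrate about real measurements.

## Residue volume scale and size classes

Residue volumes are side-chain-inclusive mean volumes from crystal-structure
surveys (Pontius/Wodak scale), shipped as a plain-text table
(`etgating/data/wodak_volumes.tsv`) and overridable with any two-column
file via `load_volume_scale(path)`. Internal consistency anchors: Gln =
156.4 Å³; the Gly→Ala increment is 24.0 Å³ and Ala→Thr is 34.5 Å³; the
five classical "small" residues (Gly, Ala, Ser, Cys, Thr) all fall at or
below the 130 Å³ class boundary and every other residue above it except
proline. The group boundary is treated as inclusive (≤ 130 Å³): no residue
of the packaged scale sits exactly on it, so the open/closed choice never
changes a classification. Proline is assigned to group II unconditionally
— its backbone ring rigidifies a transmembrane helix regardless of its
modest volume.

## Fluorescence-decay deconvolution

Model: F(t) = Σᵢ Aᵢ·exp(−kᵢt) + c with Aᵢ ≥ 0, kᵢ > 0 and a free constant
offset, three components by default. Normalization is to the first sample
(F(0) = 1); whether the instrument convention is F₀ or F_max does not
affect rate constants, only amplitudes, and the chosen convention is
recorded in reports.

Optimization is separable least squares: trial rates log-spaced across
[1/t_max, 1/t_min], amplitudes solved by non-negative linear least squares
(NNLS) against that basis, then a bounded trust-region refinement of all
parameters with rates parameterized on a log scale. Four additional
restarts with seeded log-normal jitter (sd 0.5 decades) on the initial
rates guard against local minima; the best restart is kept, and
convergence is reported honestly (`converged`, with the best-so-far
parameters attached to the failure if none converges). Components whose
fitted rates coincide within 10⁻⁶ relative are merged (amplitudes summed)
before the descending-rate sort. A constant trace is returned as
zero-amplitude components with the mean as offset, flagged `degenerate`.

The gating (Q_A⁻→Q_B) rate is the largest rate constant among components
whose amplitude exceeds 1% of the total fitted amplitude. The floor is a
package choice: without it, a near-zero-amplitude artefact component could
silently claim the assignment.

Identifiability caveat: with a free offset, the slowest component's rate is
weakly constrained. In the recovery suites "signal-to-noise 100" is defined
**per component** — noise sd equals the smallest component amplitude
divided by 100 (sd 0.001 for the default 0.6/0.3/0.1 amplitude pattern).
At trace-level SNR 100 (sd 0.01) the slowest rate's maximum-likelihood
scatter alone is 10–30%, so a 5% recovery criterion would be testing the
noise realization, not the optimizer.

## Eyring analysis

ln(k/T) = a + b·(1/T) by ordinary least squares; ΔH‡ = −bR,
ΔS‡ = (a − ln(k_B/h))·R with R = 8.314 J mol⁻¹ K⁻¹ and
k_B/h = 2.0836612 × 10¹⁰ K⁻¹ s⁻¹. The transmission coefficient is fixed at
1; any real deviation is absorbed into ΔS‡. Natural logarithms throughout;
k in s⁻¹, T in K; ln(k/T) is treated as dimensionless, matching how such
plots are conventionally drawn. r² is defined through residuals
(1 − SSE/SST), with the convention that an exactly reproduced constant
series has r² = 1 (the Pearson definition is undefined there).

Leveling-off detection fits a continuous two-segment model — linear in 1/T
below the breakpoint, constant above it: y = a + b·max(1/T, 1/T_break) —
by a grid search over observed temperatures with at least two points on
the cold side. A plateau is reported only when the two-segment model cuts
the one-segment SSE by ≥ 10%; the margin is a package choice that keeps
noise from fabricating breakpoints. A reported breakpoint is by
construction one of the observed temperatures, never an extrapolation.

## Effective-temperature calibration

Two unit conventions are fixed package-wide (neither is derivable from the
equations alone, and both are needed for the numbers to cohere):

* In ln(k/T_ref)-vs-volume regressions, volume enters in units of 10³ Å³.
  A Gly-like volume (0.0675 on that scale) with slope −14.5 and intercept
  3.25 then gives ln(k/T) ≈ 2.27, inside the observed 2.1–2.4 band for
  small residues — whereas Å³ units would be off by orders of magnitude.
* In the calibration 1/T_eff = αV + β, inverse temperature is in 10³ K⁻¹
  and volume in Å³, so T_eff = 1000/(αV + β). With α = 0.0081 and β = 2.91
  this evaluates to 239.4 K at V = 156.4 Å³ (Gln).

The mapping step inverts the wild-type line: 1/T_eff = (ln(k/T_ref) − a)/b.
It is undefined for b = 0 and rejects rates that land at non-positive 1/T
(for b < 0 that means a mutant faster than the wild-type line's supremum —
physically a mutant that needs "heating", outside this construct's domain).
The calibration regression is fit on (V, 1000/T_eff), not (V, T_eff),
matching the linear form above. By default only group I residues enter a
calibration (at the crossing-point site only group I mutants are
photoautotrophically viable); `groups=("I", "II")` retains everything for
sites that tolerate larger residues.

The worked prediction at Gln (239.4 K) is reproduced by the end-to-end
pipeline, not just the closed form: generator → wild-type fit → mapping →
calibration → prediction, exact to 10⁻⁶ relative in the noiseless case.
Cooling increments evaluated on the fitted line at the packaged volumes
are −15.4 K for Gly→Ala and −19.5 K for Ala→Thr; approximate literature
figures for these steps (−14, −22 K) are of matching magnitude but their
provenance (fitted line vs individual points) is not reconstructable, so
they are not asserted as exact checks.

## Dynamic force spectroscopy

Loading rate is nominal and constant per sweep group: spring constant ×
tip velocity, with velocity = 2 × sweep amplitude × sweep frequency
(triangular sweep). Force-dependent loading-rate corrections are out of
scope.

Rupture detection compares 3-sample windowed means across each candidate
gap; an event requires a drop ≥ 4 noise-sd (configurable) returning to the
trace baseline (median of the lower half of force samples). One event is
emitted per contiguous run of triggering gaps, at the pre-drop force peak.

Unbinding forces are histogrammed at 5 pN with edges aligned to multiples
of 5. The Bell extrapolation fits mean force against ln(loading rate):
F = (k_BT/x_β)·ln(r·x_β/(k_off0·k_BT)), giving x_β from the slope and the
zero-force off-rate from the intercept. The expression's fixed point is
the modal force; applying it to means imports the known mean-vs-mode bias
(order e^γ on k_off0 in the high-force regime) — reports state that the
fit is to means.

The histogram-to-lifetime transform (Dudko–Hummer–Szabo) maps bin i to
τ(F_i) = (Σ_{j>i} h_j + h_i/2)·ΔF / (r·h_i) at the bin midpoint. The
transform is accurate where sampling is dense; above the modal force the
finite-ramp bias grows (the validation suite checks closed-form agreement
on bins at or below the mode with ≥ 1% occupancy). The ν-model

τ(F) = τ₀·(1 − νFx‡/ΔG‡)^(1−1/ν) · exp(−ΔG‡[1 − (1 − νFx‡/ΔG‡)^(1/ν)])

(ΔG‡ in k_BT units) is fit on log-lifetimes with bounds x‡ ∈ [10⁻⁴, 100] nm,
ΔG‡ ∈ [0.5, 500] k_BT, the well constraint 1 − νFx‡/ΔG‡ > 0 enforced by
clipping inside the residual, and a warm start from the Bell limit plus a
small grid over initial ΔG‡. ν = 1/2 (harmonic cusp) is the default, 2/3
and 1 selectable; at ν = 1 the model reduces exactly to Bell and ΔG‡ drops
out of the likelihood, so it is reported at its initialization value.
k_B = 1.380649 × 10⁻² pN·nm/K.

## Structure, motifs, trajectories

PDB parsing is delegated to biotite; chains A (D1) and D (D2) of the first
PSII monomer are the defaults per the standard deposition convention, and
author residue numbering is used unchanged. Cα–Cα distances are computed
in full precision and rounded to 0.1 Å only in report tables. Interface
profiles take, per residue of the query range, the minimum Cα distance to
the partner range (validated against a brute-force all-pairs scan).

Motifs: an anchor pair of small residues at (i, i+4) is a GxxxG-like hit; a
maximal run of ≥ 3 small residues is a consecutive-small hit. "Small"
means group I under the active volume scale.

H-bond occupancy is the fraction of frames passing geometric criteria:
donor–acceptor distance ≤ 3.5 Å, plus D–H⋯A angle ≥ 120° when hydrogens
are available. The defaults are common practice, not a reconstruction of
any particular MD engine's bonded-state definition; without hydrogens the
check is distance-only and reports say so. Published occupancy
percentages from engine-specific definitions are used only as generator
targets, never as recovery truths.

## Synthetic generators

Each generator draws from a single `numpy.random.default_rng(seed)` stream
and returns its ground truth alongside the data. Default conditions mirror
the study design they emulate: decay components (0.6, 2000 s⁻¹),
(0.3, 200 s⁻¹), (0.1, 10 s⁻¹) — gating, reoxidation-limited and slow
recombination-scale phases with 10× separation; rate series over 273–323 K
(the 0–50 °C measurement window) from ΔH‡ = 15 kJ mol⁻¹,
ΔS‡ = −50 J mol⁻¹ K⁻¹ (order-of-magnitude-typical gating thermodynamics;
the true wild-type parameters are not published numerically) with an
optional plateau near 303 K; mutant panels at the Wodak volumes of the
four viable D1-208 residues, carrying α = 0.0081, β = 2.91; Bell–Evans
ruptures by inverse-CDF sampling of
S(F) = exp(−(k_off0·k_BT)/(r·x)·(e^{Fx/k_BT} − 1)) at 40 pN/nm spring
constant, 100 nm sweep amplitude, 0.3–10 Hz sweep frequencies; alignment
triplets at probabilities 0.894/0.106 (GGS/GGA), n up to 4665; trajectory
bond states i.i.d. per frame at the target occupancy.

What these suites show: the estimators invert their own generating models
correctly at realistic noise, sample sizes and parameter ranges. What they
do not show: robustness to flash artefacts, detector nonlinearity,
baseline drift in force curves, correlated MD frames, or alignment errors
— none of which the generators emulate. Real-data conclusions inherit the
corresponding caveats.

## Problem sizes in the validation suites

Noiseless round trips use 6–15 temperatures, 4-point panels and 200-point
traces; stochastic suites use 20 decay replicates, 50 noisy panels, 10⁵
rupture events per loading rate, 2000-frame trajectories and 5000-sequence
alignments. These sizes put binomial/DKW error comfortably below the
stated tolerances while keeping the whole suite to seconds.

## Known limitations

* The wild-type Eyring parameters and per-mutant rate tables of the
  original study are not published numerically, so all wild-type-dependent
  checks are synthetic round trips; printed r² values (0.88/0.87) and AFM
  lifetimes (9/23/52 ms) are likewise not recomputable and are not
  asserted.
* The Bell and Dudko routes answer subtly different questions (mean-force
  extrapolation vs histogram-resolved lifetimes); they are reported side
  by side without reconciliation.
* The crystal-structure distance checks require a user-supplied 3WU2 file;
  the package ships no structural data.
* Multi-exponential fitting beyond three well-separated components is
  intrinsically ill-conditioned; the fitter reports convergence and RSS
  but cannot manufacture identifiability.
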