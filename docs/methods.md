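# Methods

This note documents the models, conventions, and numerical choices behind
`domaincoupling`, and what the synthetic-data tests do and do not
establish about real data.

## Physical constants and units

All energies are in kcal/mol, temperatures in kelvin, rates in 1/s,
distances in Å.  R = 1.986 cal K⁻¹ mol⁻¹, k_B = 1.380649×10⁻²³ J/K,
h = 6.62607×10⁻³⁴ J·s, 37 °C = 310.15 K.  Natural logarithms are used for
all energies; rate–denaturant extrapolations work in log₁₀ (the field's
chevron convention).

## HDX uptake kinetics (`hdx_uptake`)

%D values are stored **uncorrected for back-exchange** and therefore
compare protection *across states*, not absolute exchange.  Residue and
peptide numbering is 1-based inclusive.

`fit_uptake` performs bounded nonlinear least squares (amplitudes in
[0, 100] %D, rates in [10⁻⁷, 10] s⁻¹) on replicate means, weighted by
1/SEM when every timepoint has ≥3 replicates.  A deterministic multistart
over a decade grid of rate initializations (10⁻⁶…10⁰ s⁻¹; all ordered
pairs for the biexponential) removes starting-point sensitivity.  Order
selection (`order="auto"`) uses the small-sample-corrected Akaike
criterion (AICc) and requires ≥5 distinct timepoints before the
biexponential is even considered.

*Identifiability guard.*  A rate is flagged unidentifiable when its
exponential decays <5% or >99% across the observed window, or its
amplitude is ≈0 (a constant series): outside that range the schedule
carries no rate information.  Unidentifiable rates propagate as errors
into ΔΔG°, not as numbers.

*Information limits.*  On the 3-point labeling schedule (10/240/1200 s)
the mono-exponential has 3 parameters: the fit interpolates the replicate
means, and parameter precision is set entirely by the noise of those
means.  At 1.5 %D replicate noise the simulated median rate error is
≈4%.  For the biexponential on a 5-point schedule the same argument
applies with sharper consequences for the fast rate, which rests on the
two earliest points only: its median sampling error is ≈25% while the
slow (structured-region) rate — the one used for ΔΔG°_open — stays near
5%.  The tests assert these information-limited levels.

`differential_map` uses Welch's unequal-variance two-tailed t-test (the
safer choice at n = 3); p-values require ≥2 replicates in both states.
Degenerate variance (all replicates identical) yields p = 1 when the
means agree and p = 0 otherwise, never NaN.  No multiplicity correction
is applied by default; Benjamini–Hochberg is available behind a flag.
Projection of peptide-level Δ%D onto residues (for structure coloring)
takes the mean over all covering peptides — a convention, since
overlapping-peptide deconvolution is deliberately out of scope.

`ddG_from_rates` implements ΔΔG°(A−B) = −RT ln(k_A/k_B) with the slow
rate of biexponential fits; the sign is positive when state A is more
protected.  Values are labeled approximate: they assume EX2 exchange and
a temperature-jump labeling protocol.

## EX1 deconvolution and Eyring energetics (`ex1_kinetics`)

Envelopes are area-normalized and fitted as a two-Gaussian mixture with
**centroids and widths shared across timepoints** (joint fit); only the
mixing fraction F_f varies per timepoint.  Sharing stabilizes the fit
when individual spectra are nearly unimodal; a per-timepoint mode exists
for diagnostics.  The folded component is the low-mass one.

*Label canonicalization.*  A genuinely unimodal series is symmetric under
swapping the component labels (the absent component can sit anywhere with
zero weight), so the optimizer may return F_f ≈ 0 for pure-folded data.
When the folded component carries <5% total weight, the envelope centroid
does not drift up-mass with time, and the "unfolded" component sits on
the static peak, the labels are swapped and the absent component is
repositioned 4 widths above the real one.  A static unimodal series
therefore reads F_f ≈ 1 (protected).

The unfolding rate comes from ln F_f = −k_u t **constrained through the
origin** (the decay law has no intercept); an unconstrained variant is
for diagnostics only.  F_f ≤ 0.02 is excluded (log blow-up guard).
ΔG‡ = RT ln(k_B T/(h k_u)) and its inverse form an exact bijection.
A dip-test bimodality call is provided; its 10% dip threshold is a
convention, not a measured property.

## Equilibrium stability (`equilibrium_stability`)

`fit_urea_unfolding` first runs a global two-state fit to obtain the
folded/unfolded baselines (constant by default; linear baselines opt-in —
with ~12-point curves, free baseline slopes absorb noise and degrade the
ΔG° estimate).  The fraction unfolded is then computed pointwise,
converted to ΔG = −RT ln(f_u/(1−f_u)), and fitted linearly in [urea] with
**delta-method weights** f_u(1−f_u): sd(ΔG) ∝ RT/(f_u(1−f_u))·sd(f_u), so
near-baseline points would otherwise dominate the fit with pure noise.
Points with f_u outside [0.05, 0.95] are excluded entirely.  A curve that
a straight line explains as well as the two-state model is rejected as
having no transition.

Temperature extrapolation is ordinary least squares of ΔG° versus
temperature (°C) evaluated at 37 °C with a t-based prediction interval
(≥3 temperatures required; the intended design uses 4–5 between 20 and
32 °C).  The interval construction is a standard OLS prediction interval,
which may differ from other software's CI conventions.

`extrapolate_rate` fits log₁₀ k_u linearly in [urea] per temperature
(slope m_ku, intercept log k_u^H₂O), then linearly in temperature to
37 °C.  A negative m_ku warns rather than errors (its sign is
data-dependent).  The activation energy is reported both as
−RT ln(k_u) — a convention lacking the transmission prefactor — and via
the full Eyring relation; the two differ by exactly RT ln(k_B T/h)
(≈18.3 kcal/mol at 310 K), which is asserted in the tests.

`fit_melt` is a four-parameter Boltzmann sigmoid with T_m at the
inflection, reported in °C; a fitted inflection outside the sampled range
is an error.

## Trajectory networks (`trajectory_network`)

All quantities use C-alpha coordinates only.  Superposition is
least-squares rigid-body (Kabsch); RMSF is taken about the mean structure
after superposition.  Native contacts are residue pairs with |i−j| > 3
and reference distance ≤ 8 Å; per frame a contact counts (hard count)
when its distance is ≤ cutoff×1.2.  Both cutoffs are conventions exposed
in the API, since the underlying choice (Cα vs heavy-atom, exact radius)
is not standardized.

The generalized correlation r_MI = √(1 − exp(−2I/3)) uses a hand-written
Kraskov–Stögbauer–Grassberger k-NN estimator (k = 6, max-norm, algorithm
1) between 3-D displacement vectors; a seeded 10⁻¹⁰ Å jitter breaks exact
distance ties.  For jointly Gaussian motion with per-coordinate
correlation ρ, I = −(3/2)ln(1−ρ²) and r_MI = ρ exactly, which the tests
verify at ρ = 0.8 within 0.05.  The estimator's finite-sample null on
independent residues sits near r_MI ≈ 0.06 at 5000 frames (the square
root stretches tiny I values), so correlations below ~0.1 should be read
as noise.

Network edges connect residue pairs within 10 Å in ≥75% of frames with
C_ij ≥ 0.01; the edge distance is −log C_ij.  Communities come from a
Girvan–Newman divisive loop (edge betweenness on the distance weights,
lexicographically smallest edge on ties — fully deterministic), keeping
the partition of **maximum modularity computed on the correlation
weights**.  The inter-community coupling score is the mean C_ij over
retained crossing edges; 1−coupling matches the edge-thickness convention
of community diagrams.  All four choices (estimator, contact filter,
community algorithm, coupling formula) are conventions exposed in the
API, since the cited toolchains do not pin them.

## Synthetic data (`synthetic_data`)

Each generator is the exact inverse of the model its consumer fits, with
Gaussian additive noise on %D and signals and multiplicative noise on
envelope intensities (keeps non-negativity natural).  Defaults encode the
study conditions: labeling at 10/240/1200 s at 37 °C with 3 technical
replicates and 1.5 %D noise; urea titrations 0–6 M at 20–32 °C; envelope
components as Gaussians in mass-offset space (a deliberate simplification
of binomial isotope structure, adequate because the deconvolution also
fits Gaussians).

Trajectories draw residue displacements, independently per cartesian
axis, from a zero-mean Gaussian whose correlation matrix is block-valued
(intra/inter/bridge); indefinite requests are repaired by eigenvalue
clipping with diagonal renormalization (reported, with the realized
matrix, in `ensemble.meta`) or rejected when severe.  The reference lays
residues along a compact lattice walk so contiguous communities occupy
contiguous space.  **Simulated frames carry no global rigid-body
motion**, and their strong planted common modes are unlike real
fluctuations: frame-wise superposition would subtract the common mode and
convert planted block correlation into block anti-correlation.
Correlation analysis of generator output therefore runs with
`superpose=False`; on real (globally moving) trajectories superposition
is required and is the default.

*What passing tests do not show.*  The generators have white replicate
noise, exact two-state/two-population behaviour, Gaussian envelopes, and
stationary harmonic-like dynamics.  Real data add back-exchange
variation, EX1/EX2 mixtures, baseline drift, anharmonic and slowly
converging dynamics, and peptide-coverage gaps — recovery performance
here is an upper bound, and the experimental quantities themselves
(maturation efficiencies, absolute T_m values, printed community weights)
are not reproducible from synthetic data.

## Problem sizes

The verification suite uses 100-seed batches for scalar fits, 5000-frame
trajectories for closed-form fluctuation checks, and a 60-residue ×
1500-frame trajectory for the community-recovery chain — sizes at which
every estimator is well into its asymptotic regime while the whole suite
runs in minutes on one core.
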