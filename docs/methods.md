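# Methods

conformerkit infers the conformational heterogeneity and exchange dynamics of
a multi-domain protein from five complementary measurements, and fuses the
structural evidence into a statistical selection of candidate conformer
pairs.  This note records the models, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Label simulation (AV/ACV)

Dyes and spin labels are tethered to the backbone by flexible linkers, so a
measurement reports a distance between positional *distributions*.  The
accessible volume (AV) places the label at every grid point that (i) lies
within the linker length of the attachment atom, (ii) clears every protein
bead by the bead radius plus a single effective label radius, and (iii) is
connected to the attachment point through clash-free grid cells (6-neighbour
flood fill via `scipy.ndimage.label`).  Weights are uniform.  The accessible
contact volume (ACV) re-weights points within a contact shell of the protein
surface to a user-supplied trapped-dye fraction; the fraction is an input
because in practice it is calibrated against time-resolved anisotropy, which
is out of scope here.

Choices and caveats:

* grid spacing defaults to 1.0 Å (configurable); AV observables converge at
  the few-tenths-of-an-angstrom level at this spacing.
* a single effective label radius replaces the three-radius dye model; this
  coarsens the excluded volume of flat aromatic dyes.
* a sterically trapped pocket smaller than the label head volume
  (4/3 π (linker_width/2)³) is reported as an inaccessible site rather than
  returned as a tiny cloud.
* spin labels reuse the same machinery with MTSSL-like defaults (8 Å linker,
  4.5 Å width, 2.5 Å radius).
* the orientation factor is fixed at κ² = 2/3 (mobile dyes); orientation
  uncertainty must enter through the per-distance σ of the restraints.
* FRET observables are exact pairwise sums; inside the discrimination
  pipeline clouds larger than 1200 points are subsampled
  weight-proportionally (seeded) — an unbiased estimator whose noise
  (≈ 0.1 Å on the FRET-averaged distance) is negligible against restraint
  uncertainties of a few Å.

## TCSPC / FRET

Donor decays are modeled as the product of a multi-exponential donor-only
reference and the FRET-induced donor decay

    ε_D(t) = (1 − x_DOnly) ∫ p(R) exp(−t k₀ (R₀/R)⁶) dR + x_DOnly ,

with k₀ = 1/τ₀ (τ₀ = 4 ns, R₀ = 52 Å defaults).  The (1 − x_DOnly) scaling
makes ε_D(0) = 1 exactly.  The distance model is a one- or two-component
Gaussian mixture with a common width w (default 12 Å, convention
exp(−2((R−R̄)/w)²), i.e. σ = w/2), truncated to the positive quadrature grid
(0.5 Å steps over 10–150 Å) and renormalized.  The FRET-sensitized acceptor
decay is the causal discrete convolution of the quenched donor decay with
the acceptor reference, scaled by the channel width.  Measured histograms
follow g(t) = N_F·f⊗IRF + N_BG·IRF + bg with a unit-sum IRF, an optional
sub-channel IRF shift (linear interpolation, default 0) and an optional
multiplicative linearization curve.

Fitting is Poisson-weighted (σ² = max(counts, 1)) over a window covering the
IRF and 99.9% of the fluorescence.  The photon scale N_F is a linear
nuisance profiled analytically at every evaluation, which removes one free
parameter per dataset from the Levenberg–Marquardt problem.  Global fits
share named parameters (typically the state fraction x₁) across datasets.
Uncertainties come from support-plane (profile-χ²) scans with an F-test
threshold; posterior sampling is intentionally not included.

The maximum-entropy reconstruction maximizes αS − χ²/2 with
S = −Σ p ln(p/m) against a flat prior, parameterized as p = e^u and solved
by L-BFGS with an analytic gradient (including the chain term from the
profiled photon scale — omitting it stalls the optimizer).  The α is chosen
at the maximum-curvature corner of the (log misfit, log entropy) curve.
MEM pulls overlapping modes toward each other: on a 45/60 Å mixture at
2×10⁷ counts the modes are resolved but recovered near 44/56 Å, while
component fractions are accurate to better than 0.1.  Mode positions for
quantitative use should come from the parametric mixture fit instead.

Static FRET-lines are computed analytically from the moment integrals
∫f and ∫t·f of the quenched multi-exponential decay (no time grid needed);
dynamic lines mix two states' integrals linearly in the molecular fraction,
which reproduces photon-weighted averaging and bows the line above the
static reference between its endpoints.

## DEER

The dipolar kernel uses ν_dip = 52.04 MHz·nm³ computed from physical
constants with the free-electron g = 2.0023.  (Using g ≈ 2.006, as sometimes
quoted for nitroxides, would give 52.24 MHz·nm³ — a 0.4% distance-scale
effect.)  Kernel entries are evaluated in closed form with Fresnel
integrals, K = (cos φ·C(κ) + sin φ·S(κ))/κ, κ = √(6φ/π), verified against
high-order Gauss–Legendre quadrature to 10⁻⁷.

The signal model is V(t) = (1 − Δ(1 − Kp))·exp(−kt): a three-dimensional
homogeneous background and a modulation depth Δ (absent from the bare
factorized form, included explicitly because real traces require it).  The
background rate is fitted on the log-signal tail; the inversion solves a
non-negativity-constrained Tikhonov problem (second-difference penalty,
free boundaries) via bounded linear least squares on the distance grid
1.5–8 nm at 0.05 nm.  An unconstrained mode solving the regularized normal
equations directly exists for oracle comparison only.  The regularization
strength is selected at the maximum-curvature corner of the L-curve after
enforcing the monotone trends of misfit and roughness (guards against
numerical non-monotonicity at extreme α).

## Filtered FCS

Species filters are the minimal-variance unbiased unmixing matrix
W = (Mᵀ diag(1/s) M)⁻¹ Mᵀ diag(1/s) over detector×TAC channel patterns M;
W·M = I holds by construction.  Correlation runs on binned weighted signals
with a multi-tau scheme (16 points per cascade, factor-2 coarsening with
averaging); full photon-time-tag correlation is out of scope, so lag times
below the bin width are not accessible.  A discrete-time Markov (telegraph)
simulator provides the slow oracle for exchange kinetics; analytic
multi-exponential construction from the rate-matrix eigenvalues generates
production test data (relaxation times are exactly −1/λ of the nonzero
eigenvalues).

The model is the product of a 3D-Gaussian diffusion term and curve-kind
specific kinetic terms: up to three exponential components whose
amplitudes sum to one (enforced by construction, A₃ = 1 − A₁ − A₂ with
bounds), an anti-correlation amplitude per cross-correlation direction, and
an acceptor-bleaching factor on curves involving the high-FRET species
(characteristic time bounded 1–20 ms).  Global fits share the relaxation
times across variants; the two cross-correlations of a variant share one
effective molecule number; residuals are weighted by per-point SDs from
record splits.  The "average correlation time" reported per variant is the
amplitude-weighted arithmetic mean Σ Aᵢ t_c,i.

## NSE

The rigid-body effective diffusion coefficient D₀(q) averages the
amplitude-weighted quadratic form of (q⃗, q⃗×r⃗) with the 6×6 diffusion
tensor over orientations, normalized by q²F(q).  Units: translational block
nm²/ns, rotational block 1/ns, coordinates relative to the center of
diffusion; with this convention a centered bead gives exactly the
translational trace and rotation enters as |q̂×r⃗|²·D_r.  Orientational
averages use a Gauss–Legendre (cos θ) × uniform (φ) product grid, default
24×48 = 1152 points (≥ 590 enforced), with a seeded Monte-Carlo fallback as
the oracle.  The full intermediate scattering function multiplies an
internal-dynamics factor (1−A) + A·e^(−Γt), a translational factor
exp(−q² D_t H_t t / S(q)) and a rotational expansion over spherical Bessel
functions and real spherical harmonics truncated at l = 15 (convergence
< 0.1% against l = 25 for q·R_g ≤ 3).  Hydrodynamic corrections follow
H_t = 1 − c[η] and the spherical approximation 1 − H_r = (1 − H_t)/3, which
underestimates H_r for elongated particles.  The Debye–Waller bound
u = √(−3 ln(1−err))/q gives 0.347 nm at err = 0.01, q = 0.5 nm⁻¹ — a useful
sensitivity bound on invisible internal motion.  Diffusion tensors are
inputs from external hydrodynamics calculations; the built-in Kirkwood-type
bead approximation (exact for a single sphere, crude otherwise) exists only
to build synthetic tensors for tests and toy systems.

Cumulant analysis fits ln(I/I₀) = K₁t + K₂t²/2 on an initial window by
weighted linear least squares and reports D_eff = −K₁/q² with propagated
uncertainty; a positive K₁ raises a warning rather than an error.

## SAXS

The Debye formula is evaluated exactly for models up to 1200 beads and via
a fine pair-distance histogram (4096 bins, `bincount`) above that; an
optional spherical bead form factor smooths lattice artifacts of
volume-filling models.  A filled-sphere model at spacing/R = 0.05
reproduces the analytic sphere form factor within 1% pointwise away from
the form-factor zeros (no finite bead model can satisfy a pointwise
relative bound *at* the zeros).  Guinier fits iterate the window; the
default q·R_g < 0.85 sits in the low-bias part of the classical q·R_g < 1.3
regime because the sphere-like bias at 1.3 reaches ~2%.  Concentration
series are reduced by per-q linear extrapolation of I/c to c = 0, merged
with the highest-concentration data at high q.  The Percus–Yevick
hard-sphere S(q) uses the Wertheim closed form with a small-qR series
switch; the decoupling correction 1 + β(q)(S−1) handles asymmetric
particles.  Model scoring fits scale and offset analytically; the dof is
N − 2 or the Shannon-channel count (q-range·D_max/π) when D_max is known.
Two-state ensemble fits profile χ²(x) on a fraction grid, report the 68%
interval (Δχ² = 1) and flag boundary solutions.  No hydration-layer model
is included, so absolute χ² against real protein data will be inflated
relative to tools that model the contrast layer.

## Conformer-pair discrimination

Candidate (M1, M2) pairs are scored by (i) the uncertainty-weighted
χ² of AV-predicted label distances against the restraint table —
state-specific rows on the assigned member, shared rows on both, with the
label-assignment swap evaluated and the minimum taken — and (ii) the SAXS
two-state mixture χ².  Each χ² maps to an upper-tail probability and the
two are combined by Fisher's method, X² = −2 ln(p_label·p_SAXS) ~ χ²₄;
pairs below the confidence threshold (default 0.68) are rejected.
Candidates with buried label sites are flagged invalid and always rejected.

Degrees of freedom: the label χ² uses the raw restraint count by default.
The greedy backward-elimination estimate of the effective number of
informative restraints (drop the restraint whose removal best preserves the
Spearman rank correlation of pair scores, stop below a 0.9 threshold) is
implemented and behaves as intended on constructed cases — duplicated
restraint sets halve, orthogonal sets are fully retained — but on small
synthetic pools where every decoy violates every restraint it degenerates
to k_eff ≈ 1 (any single restraint already reproduces the ranking), which
would make the true pair's p-value meaninglessly small.  It is therefore a
stability-analysis tool (`dof_mode="effective"`), not the default.

Ensemble precision: the SD of every pairwise Cα–Cα distance over the
accepted ensemble (alignment-free), normalized by the same quantity for
reference ensembles regenerated with the best model as ground truth and
restraints resampled within their σ; per-residue RMSF after three rounds of
Kabsch superposition to the evolving ensemble mean.

## Synthetic data generator

The generator builds a compact four-body bead protein (40 residues per
body, helical rods folded into a bundle of ~75 Å extent, Cα-like beads of
3 Å radius so standard PDB records carry the models).  M2 rotates the two
distal bodies by 40° about the connector, giving inter-label distance
changes of ~3–25 Å across the 12 FRET and 8 spin pairs; spin pairs are
restricted to ≤ 58 Å so they sit well inside a 4 µs dipolar window.  The
ground-truth state fractions are 0.61/0.39 and the exchange kinetics is a
symmetric nearest-neighbour chain whose rates are solved numerically so the
relaxation spectrum is exactly (2, 23, 297) µs.

Each modality is generated by the corresponding forward model with seeded
noise (per-modality independent streams, so subsets are reproducible):
TCSPC at 2×10⁷ Poisson counts on 16 ps channels with a 254 ps-FWHM Gaussian
IRF; DEER with Δ = 0.4, background 0.08 µs⁻¹ and 0.5% Gaussian noise; fFCS
curves from the analytic model with 0.003 additive noise; NSE mixtures of
the two conformers' rigid-body curves; SAXS mixtures of the exact Debye
curves.  Reported uncertainties are deliberately conservative: restraint
values are drawn with SD = 0.5σ and SAXS σ is quoted at 3× the injected
noise, emulating experimental error budgets that include systematic
contributions.  This matters statistically: if quoted σ equaled the noise
SD, the true pair's χ² would fluctuate around its dof and no method could
retain it at a combined-p threshold of 0.68 with high probability.

Decoy candidates perturb one or two distal blocks by random rotations and
translations, giving Kabsch-aligned RMSDs of ~2–27 Å to the nearest truth
conformer on the default toy.

What the synthetic tests show: correctness of every forward model and
inversion against independent oracles, calibration of the joint fits, and
that the meta-analysis retains the generating pair while rejecting
perturbed geometry under realistic noise.  What they do not show: dye
photophysics beyond κ² = 2/3, hydration-layer scattering, rotamer-specific
spin-label effects, instrument artifacts (afterpulsing, dead time), or
performance on conformational changes more subtle than rigid-body hinge
motion.

## Problem sizes

Default test and reproduction runs use: 50 DEER traces of 200 time points
on a 131-point distance grid; 12 TCSPC datasets of 2000 channels at 2×10⁷
counts; 48 fFCS curves of ~80 lag points; a 2600-bead sphere and a
two-bead dumbbell for NSE; a 33 000-bead sphere for the SAXS Debye
benchmark; and 20 discrimination replicates with 10 candidates each.
These sizes were chosen so every check runs comfortably on a single CPU
while keeping Monte-Carlo/statistical errors well below the assertion
tolerances.
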