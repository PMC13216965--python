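# Methods

## The model

A duplex of N base pairs is described by one transverse displacement
coordinate per pair, `y_i` (nm), measuring the stretch of the pair away
from its equilibrium hydrogen-bonded geometry. The configurational
energy is

    H = Σ_i V_i(y_i) + Σ_{i≥2} W_i(y_i, y_{i-1}),

with an on-site Morse potential for the hydrogen bonds,

    V_i(y) = D_α (e^{-y/λ_α} - 1)²,

where α is the base-pair class of position i (2 classes for DD and RR
duplexes, 4 for DNA/RNA hybrids, which lack the strand-exchange
symmetry), and a twisted harmonic stacking coupling per nearest-neighbour
(NN) step,

    W_i(y, y') = (k_β/2)(y² - 2 y y' cos θ + y'²),

where β is the canonical NN class of the step (10 classes for DD and RR,
16 for DR) and θ a small fixed twist. The depth `D_α` (meV) quantifies
hydrogen-bond strength, `λ_α` (nm) its range, and `k_β` (eV/nm²) the
stacking stiffness. The model is classical and one-dimensional: its
partition function

    Z(T) = ∫ dy_1…dy_N e^{-H/k_B T}

is evaluated exactly (up to quadrature) by iterated one-dimensional
kernel products (the transfer-integral technique), giving also the
per-site thermal averages ⟨y_i⟩ — the opening profile, whose elevation
at the duplex ends is end fraying.

### Melting index and temperature mapping

The model has no entropy of strand dissociation, so it cannot predict an
absolute melting temperature; instead a dimensionless melting index τ is
extracted per sequence and mapped onto measured temperatures by linear
regression. Operationally, τ = T*/T_ref where T* is the model
temperature at which the strand-averaged displacement ⟨y⟩ crosses a
threshold, and

    T'_s = a_0(N) + a_1(N) τ_s,      a_k(N) = b_{0,k} + b_{1,k} √N,

is fitted by ordinary least squares in two levels: per length group
first, then linearly in √N. Predictions always use the second-level
`b` coefficients. Lengths represented by a single sequence are pooled
with the nearest multi-sequence group. Because any affine rescaling of
τ is absorbed by the regression, any monotone, sharp-transition-
consistent definition of τ yields the same fitted temperatures; the
threshold construction used here (threshold 0.1 nm on the strand
average, T_ref = 300 K, bisection/secant to 10⁻⁴ K inside a 100–500 K
window) is recorded in the run metadata. No claim is made that the
numerical τ values coincide with those of other implementations — only
the fitted temperatures are comparable, and those are construction-
invariant by the argument above.

### Parameter fitting

Parameters are estimated by minimizing

    χ²(P) = Σ_s [T_s - T'_s(P)]²,

recomputing every τ_s and refitting the regression at each merit
evaluation. The minimizer is the Nelder–Mead downhill simplex (adaptive
coefficients, seed-normalized coordinates so Morse depths in meV and
stacking constants in eV/nm² are commensurate; non-positive proposals
get a rejection penalty). Because local minima are unavoidable, the
protocol restarts many times per round with initial points drawn
uniformly in ±20% of the round seed, averages the accepted runs (a run
is accepted when its final ⟨ΔT⟩ = mean |T_s - T'_s| lies within 20% of
the round best, excluding stuck minima while averaging the solution
basin), and re-seeds round after round until every averaged parameter
moves by less than 0.1%.

**Identifiability.** χ² is *exactly* flat under a common rescaling of
all D and k: scaling H by c scales every T* (hence τ) by c, and the
regression absorbs it. Near-flat directions also exist (e.g. trading
all D up against all k down shifts τ almost uniformly, which the
regression again absorbs). The multistart protocol handles this the way
the underlying method always has: the seed anchors the overall scale
(seeds come from prior parameter sets of the same scale, or from the
generic weak/strong scheme D = 30/80 meV, k = 2.5 eV/nm² uniform), and
averaging seed-centred starts keeps the reported values in the seed's
basin. Reported parameters are therefore defined *relative to the
seeding convention*, exactly as in the published parameter sets, and
single-parameter uncertainties — especially of stacking constants, the
softer direction — are intrinsically larger than those of the Morse
depths.

**Staged protocols.** Two stage plans ship with the package. The
cosolute plan: round 1 joins the cosolute records with no-cosolute (NC)
reference records and fits the cosolute parameters only, with the NC
parameters frozen and one shared regression over both conditions — this
anchors the new parameters to the reference scale; subsequent rounds
drop the NC records; the last round estimates uncertainties. The
two-round plan used for a fresh single-condition parametrization seeds
from the generic scheme, with the second round again the uncertainty
round.

**Uncertainty rounds.** The final round perturbs the experimental
temperatures with zero-mean Gaussian offsets rescaled so their sample
SD equals the stated experimental uncertainty exactly (0.7 °C for the
cosolute sets, 0.4 °C for the hybrid low-salt set), one independent
draw per minimization. In uncertainty rounds every start begins exactly
at the stage seed (sampling width 0): the reported SD then isolates the
effect of temperature noise rather than mixing it with the start-
sampling spread. Parameter SDs are reported in compact uncertainty
notation, e.g. 22(2) meV.

### No-cosolute reference temperatures

Reference (NC) melting temperatures for the same sequences come from
two-state nearest-neighbour thermodynamics:
Tm = ΔH°/(ΔS° + R ln(Ct/x)) - 273.15, with x = 1 for self-complementary
duplexes (measured at Ct = 200 µM in the emulated datasets) and x = 4
otherwise (100 µM). The packaged DD table transcribes the unified
oligonucleotide NN set (SantaLucia 1998); the packaged DR and RR tables
are synthetic stand-ins with realistic magnitudes, clearly labelled in
their provenance headers — supply published tables for quantitative
hybrid/RNA work. No salt correction is applied.

## Numerical choices

- **Quadrature.** Gauss–Legendre nodes on y ∈ [-0.2, 20] nm with 400
  points by default. The Morse plateau makes the integrand bounded; the
  finite upper bound is the conventional regularizer (at fixed node
  density, extending y_max by 50% moves τ by <0.1%). The resolution
  requirement is set by the stacking kernel width √(k_B T/k) ≈
  0.05–0.15 nm and the Morse width λ = 0.03 nm; the default spacing is
  ≈0.05 nm. Simulation studies use the same node density on a truncated
  domain, y ∈ [-0.2, 6] nm with 130 points: this biases τ by ~1–3%
  *consistently* between the generator and the fitter, which is
  immaterial for recovery comparisons and 5–10× faster.
- **Chain products.** Kernel–vector products are renormalized per site
  with accumulated log factors, so log Z is computable for any practical
  N without overflow. Kernel matrices are symmetric, which makes the
  product direction-independent to floating-point precision without
  splitting the on-site Boltzmann factor across neighbouring kernels.
- **Exponentials.** Boltzmann exponents are clamped at -200 (-80 in
  float32) before exponentiation: the clamped values are ≤1e-35 relative
  to the kernel maximum, and the clamp avoids subnormal outputs whose
  hardware handling would dominate the runtime. The optimizer evaluates
  kernels in float32 (T* agrees with float64 to <10⁻³ K, below the
  root-finding tolerance); the public single-duplex API stays float64.
- **Crossing temperatures.** T* is located by bracketing bisection on
  first evaluation and by a vectorized warm-started secant afterwards
  (all records of equal length advance together through batched
  kernel products); a small secant step is accepted only when the
  opening residual itself is tiny, otherwise the solver falls back to
  bisection.
- **Twist.** θ = 0.01 rad regularizes the θ → 0 translational
  degeneracy of the stacking kernel (the finite y_max alone already
  keeps Z finite at θ = 0). Doubling θ shifts τ by a few percent — the
  crossing statistic feels the open-state confinement — but the shift is
  nearly common-mode across sequences (ρ ≈ 0.998) and the regression
  absorbs it: refit predictions move by ≲0.5 °C. θ is therefore treated
  as a fixed convention, never fitted.
- **λ widths.** Held fixed at 0.030 nm for every pair class (their
  effect on melting temperatures is negligible compared with D);
  overridable per pair in parameter files.
- **Simplex.** xatol 10⁻⁴ (normalized), fatol 10⁻⁶, adaptive
  coefficients; evaluation caps are part of the protocol configuration.
  The shipped experiment configurations cap evaluations per start (400
  for the recovery study) because rounds re-seed at the mean: accuracy
  accrues across rounds rather than within a single descent, and bounded
  travel per start is what keeps the ensemble in the seed's basin given
  the flat directions discussed above.

## The synthetic-data generator

The generator emulates the statistical structure of published
oligonucleotide melting datasets: ~40 duplexes (sets of 30–50 are
typical), mixed lengths 8–16 bp assigned round-robin so every length
group supports its own regression line, and a *designed* composition
series — the target CG fraction sweeps 10–90% evenly within each length
group, with the prescribed count of C/G bases placed at random. This
mirrors how melting sets are constructed (deliberate composition
spread, including AT-rich and CG-rich extremes) and is what makes the
two Morse depths separately identifiable. Hybrid sets can additionally
constrain the pyrimidine content of the DNA strand (the dPy fraction).

Temperatures are generated by the model's own map: τ under a known
ground-truth parameter set, the two-level linear map with known
coefficients, plus Gaussian noise at the experimental uncertainty
(0.4–0.7 °C; 0.5 °C default). The ground-truth coefficients
b = (-42, 0.5, 85, 1.5) were calibrated once so simulated temperatures
span ≈20–80 °C over the length range and the within-length spread of the
composition series (~40 °C for 8-mers, ~50 °C for 16-mers) matches the
model's within-length τ spread — the realistic sensitivity of the index.
The DD/RR ground-truth parameter sets are plausible values inside the
ranges of the packaged hybrid tables; the DR ground truth *is* the
packaged low-salt hybrid set.

What the generator does **not** emulate: melting-curve shapes and
two-state/non-two-state ambiguity, salt and buffer composition effects,
concentration errors, any mechanistic cosolute chemistry (the
"cosolute-like" ground-truth shift weakens hydrogen bonds and AT-only
stacking by fiat), and sequence-correlated measurement error. Passing
recovery tests therefore demonstrates that the estimation pipeline is
correct and well-conditioned under the model's own assumptions — not
that the model describes any particular experiment.

## Known limitations

- Fully complementary, gap-free duplexes only: mismatches, bulges,
  overhangs and modified bases are rejected at parsing.
- The melting index is a relative quantity; absolute temperatures
  require the fitted regression, and parameter values carry the seeding
  convention of their protocol (see Identifiability).
- Single stacking constants, especially rare NN classes in small
  datasets, have large intrinsic uncertainties; compare parameter sets
  by correlation and by groups, not entry by entry.
- The classical 1-D model has no helicoidal/anharmonic stacking and no
  strand-dissociation entropy; opening profiles at low model
  temperatures probe local stiffness, not absolute opening
  probabilities.
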