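# Methods

## Generative model

A sample well contains substrate at concentration S₀ (default 1 μM) in
volume V (default 100 μl) and enzyme characterized by (Km, Vmax). Substrate
consumption follows single-substrate irreversible Michaelis–Menten kinetics,

  dS/dt = −Vmax·S/(Km + S),  S(0) = S₀,

whose implicit solution Km·ln(S₀/S) + (S₀ − S) = Vmax·t is evaluated in
closed form as S(t) = Km·ω(ln(S₀/Km) + (S₀ − Vmax·t)/Km) with ω the Wright
omega function (the principal Lambert-W branch composed with exp, evaluated
without overflow for any argument). This is the simplest law consistent with
the assay's observed saturating, complete hydrolysis; there is no product
inhibition, no enzyme inactivation during the run, and no sequence-resolved
stepping of the exonuclease along the 30-mer — only the release of the
5′-terminal fluorophore-coupled nucleotide is modeled, so "moles hydrolyzed"
means moles of substrate molecules whose 5′ nucleotide has been released.

Fluorescence of a sample well is

  I(t) = bg + (1−q)·k_AU·S(t)·V + k_AU·(S₀−S(t))·V + (a_S + a_E)·t + ε(t),

with background bg, quench efficiency q (fraction of the intact-substrate
fluorophore signal suppressed; default 0.95, so 5% of the signal leaks
through as extra baseline), generative fluorescence coefficient k_AU
(default 10¹³ AU/mol), linear drifts a_S (substrate autohydrolysis /
photobleaching) and a_E (lysate autofluorescence), and i.i.d. Gaussian read
noise ε with SD `noise_sd` (default 2 AU, a few per mil of the full-scale
1000 AU signal). The substrate-only control is
bg + (1−q)·k_AU·S₀·V + a_S·t + ε and the enzyme-only control is
bg + a_E·t + ε. Under the default `sum_of_controls` policy the sample well's
drift is exactly a_S + a_E, which makes the control-subtraction correction
unbiased in expectation; a `custom` policy exists to study robustness to a
violated assumption. Reads run t = 0, 5, …, 720 min (145 reads), t = 0
being the first read after the 30-min preincubation.

Condition effects multiply Vmax:

* inhibition 1/(1 + (c/IC50)^h), or an explicit fixed inhibited fraction
  for panel conditions whose dose–response is not being modeled;
* an activation factor (> 1 for activators such as EDTA or Ca²⁺);
* a Gaussian pH bell exp(−(pH − pH_opt)²/(2σ²)) — chosen over a
  bi-protonation model for identifiability with few points;
* a descending logistic 1/(1 + exp((T − T½)/w)) for heat inactivation;
* substrate chemistry: a 5′-terminal-base factor (defaults ordered
  T 1.0 > A 0.75 > G 0.5 > C 0.3, a qualitative ordering only) and a
  phosphorothioate factor applied only when linkage 0 — the 5′-terminal
  internucleotide bond — is in the substrate's PTO set. The standard
  substrate's 3′-terminal PTO protection therefore leaves its rate
  untouched, as it should: those bonds only block attack from the 3′ end.
  The bundled standard substrate records the three unambiguous internal
  3′ linkages {26, 27, 28} as protected.

The pH and thermal terms activate only when their optimum/midpoint is set,
so the default modifier is exactly neutral. pH/thermal functional forms are
package choices; measured profiles constrain their location, not their
shape.

## Quantification

Correction: I_C(t) = I_M(t) − I_M0 − (s_S + s_E)·t, with I_M0 the mean of
the first m reads (default m = 1, the t = 0 definition; configurable for
noise robustness) and s_S, s_E whole-trace OLS slopes of the controls —
controls are generated and treated as linear drifts, so the whole trace is
the efficient estimator. On noise-free data with q = 1 this recovers
k_AU·(S₀ − S(t))·V to machine precision (the correction is the exact inverse
of the generative model).

Calibration: plateau I_max = mean of the last m reads (default 6,
i.e. the final 30 min), with a warning when the tail slope exceeds 5% of the
trace's maximal rolling slope (digestion incomplete). OLS of I_max on
substrate amount with a free intercept (background-subtraction
imperfections show up there rather than biasing the slope); k = slope.
Note k absorbs the quench efficiency: the fitted coefficient is q·k_AU,
exactly the AU-per-mole of the *released* fluorophore signal, so molar
activities are invariant to q and to any rescaling of k_AU (unit
equivariance, covered by tests).

Rate: dI_C/dt is an OLS chord over the first W reads (default W = 12, 1 h).
The assay is run with substrate in excess, so the early chord is the
meaningful initial rate; a `max_rolling` policy (maximal W-read slope over
the trace) is available for curves with a lag. A window that consumes < 2%
of S₀ keeps the chord within ~0.5% of the true initial rate
k_AU·V·Vmax_eff·S₀/(Km + S₀); the round-trip tests and the acceptance
targets operate in this regime (Vmax 2–5 × 10⁻¹⁰ mol l⁻¹ min⁻¹ at the
standard 1 μM substrate), representing dilute lysate or recombinant enzyme.

Activity A = slope/k (mol/min per reaction); specific activity A per mg
protein (default 5 × 10⁻⁴ mg: 5 ng/μl in 100 μl); integrated activity is
defined here as the trapezoidal AUC of I_C(t) divided by k (mol·min). The
AUC definition is a documented package interpretation of "integrated
activity"; all comparative results in this package use ratios, which agree
between AUC and rate readouts for proportionally scaled conditions.
Negative fitted slopes are reported as-is with a below-detection flag
(knockout-lysate semantics), never truncated.

Replicates aggregate as mean ± SEM (sd/√n), SEM omitted for n = 1.

## Downstream fits

All fits are deterministic nonlinear least squares with data-derived
initializations (no random restarts): Michaelis–Menten (init: Vmax₀ = max
rate, Km₀ = interpolated half-max point; requires ≥ 4 concentrations over a
≥ 4-fold range), four-parameter logistic in log dose with Hill slope bounded
to (0.2, 5) and zero doses anchored 100× below the smallest nonzero dose
(the IC50 plot convention), the Gaussian pH bell, and the descending thermal
logistic. Flat dose–response data raise an undefined-IC50 error rather than
returning an arbitrary number; profile fits fall back to the argmax with a
flag when the optimizer fails, and flag optima that land on the boundary of
the sampled range (profile not peaked within range). Grid-search oracles in
the test suite verify that each fit attains the global optimum on clean
data.

Dunnett's many-to-one comparison is computed from the one-factor
correlation structure of the k treatment-vs-control t statistics
(cᵢ = √(nᵢ/(nᵢ+n₀)) loading on the shared control mean, pooled-variance
denominator): P(max|T| ≤ q) is evaluated by 96-node Gauss–Hermite × 192-node
Gauss–Legendre quadrature of the multivariate-t integral, accurate to ~10⁻⁶
(it reproduces the two-sided t-test exactly in the single-comparison case)
and fully deterministic, handling unbalanced group sizes. Homogeneous
within-group variance is assumed, as in the one-way ANOVA it accompanies.
Exactly identical replicates (zero pooled variance) degenerate to t = 0 or
±∞. Significance stars use the four-tier scheme 0.05/0.01/0.001/0.0001.
Fold-change confidence intervals are seeded bootstrap percentiles (default
2000 resamples). Substrate-preference ranking orders variants by mean
activity and flags, rather than arbitrarily breaks, ties whose mean ± SEM
intervals overlap.

## What the simulator does and does not emulate

It reproduces the assay's structure — control wells, linear drifts,
incomplete quenching, seeded read noise, modifier panels — with known
ground truth, so round-trip tests demonstrate that the analysis chain is
unbiased *under the generative assumptions* (linear drifts equal to the sum
of the controls, additive Gaussian noise, time-invariant enzyme). Real
plates can violate all three: drifts may be nonlinear or well-specific,
noise is often signal-dependent, enzymes lose activity over 12 h, and
condensation or edge effects are not modeled. Passing tests therefore
validate the estimators and the formula algebra, not those physical
assumptions. Secondary structure of unusual substrates and per-nucleotide
processivity are out of scope.

## Reproducibility

A single master seed drives everything: per-well noise streams derive from
(seed, well index) so a plate is reproducible independent of design order,
bootstrap CIs are seeded, and the pipeline manifest records the seed and a
config hash; rerunning a config reproduces result tables byte-identically.
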