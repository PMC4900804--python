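# Methods

This note documents the models implemented in `allokit`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Scientific setting

Muscarinic acetylcholine receptors carry two topographically distinct
ligand sites: the orthosteric pocket buried in the helical bundle (bound by
NMS, QNB, carbachol) and an allosteric site in the extracellular vestibule
(bound by gallamine, strychnine). Occupancy of the vestibule modulates both
the affinity and the exchange kinetics of the orthosteric ligand. The
package implements the quantitative workflow used to compare this behaviour
between receptor monomers and oligomers: empirical binding-curve analysis,
a mechanistic "capping" simulation, FRET spectral unmixing, and
time-resolved anisotropy fitting, each paired with a generator that
produces synthetic data of the same design with known truth.

## Empirical binding models

### Dissociation kinetics

Net dissociation of a pre-bound radioligand is monoexponential,

    B(t) = (B_t0 - B_inf) exp(-k_obsd t) + B_inf.

Traces recorded at graded modulator concentrations are fitted in concert
with per-trace `k_obsd` and `B_t0` and a single shared asymptote `B_inf`;
the shared-vs-free comparison is reported as an extra-sum-of-squares F-test.
Rates are normalised to the modulator-free control (`k0`), giving the
relative-rate curve that feeds the modulation analysis.

### Multiphasic modulation

The response to a modulator A (a relative rate, or binding at a fixed read
time) is a sum of n = 1–3 hyperbolic components:

    Y([A]) = Yinf + (Y0 - Yinf) * sum_j F_j K_j^nH_j / (K_j^nH_j + [A]^nH_j),
    sum_j F_j = 1.

This form has the limits Y(0) = Y0 and Y(inf) = Yinf and reduces to a
single hyperbola at n = 1. Affinities are stored as log10 molar. The sum
constraint on the fractions is enforced by parameterisation (softmax over
n-1 free logits), never by penalty, so it holds exactly after every fit.
Replicates are fitted globally: log K_j, nH_j and F_j shared, plateaus
per experiment. Hill coefficients are fixed at 1 unless the `tested`
policy's F-test rejects the constraint at alpha = 0.05, matching the
standard practice of fixing slopes that are statistically indistinguishable
from 1. The number of components is chosen by nested F-tests that accept a
larger n only at p < 0.05.

An optional `signed_fractions` flag relaxes the fractions to signed values
(still summing to 1) so that bell-shaped profiles — apparent positive
cooperativity at low doses turning inhibitory at high doses — can be
described; the default keeps the printed all-positive form.

Optimisation is Levenberg–Marquardt (scipy `least_squares`, TRF variant
with bounds) with 8 multistarts whose log K seeds are jittered by up to
±1 log unit from quantiles of the sampled concentration range; the
multistart RNG is seeded from the model's `seed` argument, so fits are
reproducible. Fits are unweighted by default (an optional 1/Y weighting is
provided). Components are sorted by ascending log K after fitting so output
order is deterministic.

### Saturation binding

Total binding at total radioligand concentration [P]_t is

    B_obsd = B_sp + NS ([P]_t - c B_sp),
    B_sp = Bmax ([P]_t - c B_sp)^nH / (K^nH + ([P]_t - c B_sp)^nH),

with NS the fraction of free ligand appearing as nonspecific binding and
`c` the signal-to-molar conversion that turns bound signal into a depleted
free concentration. The default is c = 0 (free = total): assay signals are
in arbitrary units and ligand depletion is negligible in the designs
emulated here. With c > 0 the implicit relation is solved per point by
bracketed Brent root-finding on [0, min(Bmax, [P]_t/c)]; the residual is
strictly monotone in B_sp there, so the root is unique. Replicates share
log K, nH and NS with per-experiment Bmax; nH is compared against 1 by
F-test under the default `tested` policy. Residuals are internally scaled
to unit data magnitude so convergence behaves identically for molar-unit
and arbitrary-unit signals.

### Replicate normalisation

For presentation against a single fitted curve, each measured point is
rescaled by Y' = Y f(x, a_mean, b)/f(x, a, b), where a are the
per-experiment parameters (plateaus or Bmax), b the shared parameters, and
a_mean the per-experiment parameters replaced by their means. Points at a
common x are then averaged to mean ± SEM. Applied to already-normalised
data the adjustment is the identity (the refitted per-experiment parameters
all equal their mean), so the operation is idempotent.

## Mechanistic capping kinetics

The ternary-complex scheme restricts access: R binds L or A freely, but
ARL forms only from RL — the vestibule-bound modulator "caps" the
orthosteric site, blocking both association and dissociation of L. With
neither ligand depleted, the four-state system (R, RL, AR, ARL) is linear
with constant coefficients and is integrated with the stiff LSODA solver
(rtol 1e-8, atol 1e-12·R_total); measured mass-conservation drift is
~1e-10 relative. Equilibrium occupancy has the closed form

    occ = (L/K_L)(1 + A/(alpha K_A)) /
          (1 + A/K_A + (L/K_L)(1 + A/(alpha K_A)))

which serves as an independent oracle for the integrator in the tests.

Rate constants derive from the equilibrium constants by partitioning the
cooperativity factor alpha with exponent j (default 2):

    k_-AL = alpha^(-j) k_-A,    k_+AL = alpha^(-(j+1)) k_+A,

so that k_-AL/k_+AL = alpha K_A for every j: the partition shifts kinetics,
never the equilibrium (asserted for j in {0,1,2,3}). The algebraically
equivalent partition k_-AL = alpha^(j+1) k_-A, k_+AL = alpha^j k_+A is
selectable (`partition="direct"`).

Order-of-addition protocols integrate the reduced two-state system for the
stated pre-incubation (default 120 min) before switching on the second
ligand, rather than assuming pre-equilibrium — short or slow
pre-incubations are therefore represented honestly. "Equilibrium" read
times are resolved as 100× the slowest relaxation time of the rate matrix
(the conservation law's zero eigenvalue is excluded by a relative
threshold). Dose–response output at preset read times (5 min, 20 min,
equilibrium) feeds directly into the empirical modulation fitter; a
capping mechanism read at equilibrium yields a monophasic inhibition curve
with unit Hill slope, and a slow-dissociating orthosteric ligand
pre-equilibrated before modulator addition is essentially protected from
modulation at a 3-h read.

## FRET spectral unmixing and apparent efficiency

Per-cell lambda scans (495–640 nm, 5-nm steps) are decomposed onto
unit-peak reference spectra by least squares, non-negative by default
(plain linear regression available). Collinear references (condition
number > 1e8) are rejected as unidentifiable. The acceptor coefficient is
reduced by the direct-excitation fraction (6%: the portion of acceptor
emission excited directly rather than by transfer), and the apparent
efficiency is

    E_app = 100 / (1 + (Q_A/Q_D)(k_D/k_A')(W_D/W_A)) %

with Q_D = 0.70, Q_A = 0.22 and the spectral-integral ratio
W_D/W_A = 0.94 over the acquisition window (recomputable from supplied
references by trapezoidal integration). E_app is reported in percent
throughout and is strictly decreasing in k_D/k_A.

Population behaviour across cells is summarised by a Gaussian fitted by
maximum likelihood on the raw per-cell values (deterministic and bin-free);
a binned least-squares fit (2.5-point bins) is provided for parity with
histogram figures. Paired before/after ligand effects are the mean per-cell
difference with a paired t-test; unpaired comparisons use Welch's t-test.

## Time-resolved anisotropy by iterative reconvolution

Under periodic excitation with repetition time T = 12.5 ns, the total
fluorescence and anisotropy decay as single exponentials,

    F(t) = A/(1 - exp(-T/tau)) exp(-t/tau),    r(t) = r0 exp(-t/phi),

and the polarised channel decays include high-numerical-aperture collection
corrections (k1 = 0.33, k2 = 0.065) and the channel-sensitivity factor
G = 1.061 applied to the parallel channel (a convention flag moves it to
the perpendicular channel):

    d_par  = G (1/3) F (1 + (2 - 3 k1) r),
    d_perp =   (1/3) F (1 - (1 - 3 k2) r).

With k1 = k2 = 0 these reduce to the classical 1+2r and 1-r forms, so
(d_par - d_perp)/(d_par + 2 d_perp) = r(t) exactly — an identity the test
suite asserts. Each decay is circularly convolved with the unit-sum IRF
shifted by a fractional colour offset s (linear interpolation); circularity
implements repetitive excitation, folding fluorescence from earlier periods
back into the window, and conserves counts exactly.

Both channels are fitted globally with A, tau, r0, phi and s free and G,
k1, k2 fixed. The default objective is the Poisson maximum likelihood,
minimised through signed square-root deviance residuals so the
Levenberg–Marquardt machinery applies unchanged. Weighted least squares
with Pearson (model-variance) or Neyman (1/max(counts,1)) weights is
selectable; Neyman weights over-weight downward-fluctuating low-count bins
and bias the recovered correlation time upward when phi exceeds the
observation window, which is why they are not the default. Under
free-fluorophore conditions (tau = 3 ns, phi = 18 ns, 1e6 counts,
16-ps bins) the likelihood objective recovers phi with ~0.6 ns scatter and
no resolvable bias; for receptor-like phi of 30–55 ns, far beyond the
12.5-ns window, the reported standard error grows several-fold, flagging
the limited information honestly. The G factor can also be estimated
directly from a fast-tumbling reference dye as the parallel/perpendicular
count ratio in the tail of the window, where r(t) ~ 0.

## Synthetic data: what it does and does not emulate

Generators produce every input the fitters consume, with the generating
truth returned alongside: log-dose designs with zero- and
saturating-concentration anchor points, replicate curves with log-normal
per-experiment scale variability (spread 0.1), Gaussian noise of 2% of the
response span for binding data and 1% of peak for spectra (defaults chosen
to match the scatter typical of these assays), Poisson counting noise for
photon data, and a Gaussian IRF of 100-ps FWHM. Reference emission spectra
are parameterised log-normal shapes peaking at 530 nm (FlAsH-like donor),
610 nm (mCherry-like acceptor) and 507 nm (eGFP-like marker), with the red
tail characteristic of fluorophore emission. The spectra generator inverts
the efficiency formula (re-adding the 6% direct-excitation contribution
the analysis later removes) so that the noise-free pipeline round-trips a
target efficiency to 1e-9.

Identical seed and parameters give byte-identical output; all randomness
flows through `numpy.random.default_rng(seed)`.

What passing these tests shows: the estimators are consistent and
essentially unbiased under the assumed noise models, the model-selection
F-tests have approximately nominal size on data generated under the null,
and the full pipelines (spectra -> unmixing -> efficiency -> population;
histogram -> reconvolution -> lifetime/correlation time) invert their
generators. What it does not show: robustness to the structure of real
data — baseline drift, correlated residuals, cell-to-cell reference-spectrum
variation, IRF drift or afterpulsing — none of which the generators
emulate.

## Problem sizes and numerical choices

Recovery suites use 100 Monte-Carlo seeds for the closed-form binding
fitters, 50 seeds for TCSPC recovery and 100 random parameter draws for the
mechanistic equilibrium oracle; these sizes give Monte-Carlo standard
errors well below the tolerances being checked while keeping the default
suite fast. Other specifics:

- F-tests are extra-sum-of-squares, two-sided, alpha = 0.05, with
  residual degrees of freedom pooled across replicate curves.
- Fraction ordering after multiphasic fits is by ascending log K
  (tie-break: stable sort), making reports deterministic.
- The TCSPC forward model treats the histogram window as one full period;
  native 4-ps channels are assumed rebinned (~16 ps default in the
  generator) before fitting.
- Degenerate inputs are surfaced, not silently absorbed: flat modulation
  data warn about unconstrained amplitudes, flat saturation curves raise
  an unidentifiability error, all-zero IRFs and collinear reference
  spectra are rejected, and populations of identical efficiencies warn
  before reporting sigma = 0.

## Known limitations

- Single-exponential lifetime and anisotropy only; multi-exponential
  decays and associated anisotropy are out of scope.
- No oligomer-specific mechanistic scheme: intermolecular cooperativity is
  analysed empirically through the multiphasic model only.
- No ligand-depletion kinetics in the ODE model (equilibrium depletion is
  available in the saturation fit via c > 0).
- The bell-shaped (non-monotone) modulation profiles require the
  `signed_fractions` extension; the default printed form is monotone.
- Gaussian population fits assume approximately normal per-cell
  efficiency distributions; heavy tails will distort mu and sigma.
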