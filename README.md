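# allokit

Analysis toolkit for allosteric modulation of G protein-coupled receptors:
radioligand binding curves, mechanistic capping kinetics, FRET spectral
unmixing and time-resolved fluorescence anisotropy.

## Who this is for

Pharmacologists and biophysicists quantifying how a vestibule-bound
allosteric ligand (gallamine, strychnine) modifies orthosteric binding
(NMS, QNB) at muscarinic-type receptors — in particular, distinguishing the
single low-affinity allosteric effect characteristic of receptor monomers
from the multiphasic, partly intermolecular effects of oligomers — and
imaging labs reading conformational change at the allosteric site through a
FRET sensor.

## What it computes

**Empirical binding models** (statsmodels-style `Model.fit() -> Results`):

- `DissociationModel` — monoexponential dissociation
  `B(t) = (B_t0 − B_inf) e^(−k_obsd t) + B_inf`, fitted globally over traces
  at graded modulator concentrations with a shared asymptote (F-tested) and
  control-normalised relative rates k_obsd/k0.
- `ModulationModel` — multiphasic log-dose response
  `Y = Yinf + (Y0 − Yinf) Σ_j F_j K_j^nH / (K_j^nH + [A]^nH)`, Σ F_j = 1,
  n = 1–3 components shared across replicates, Hill slopes fixed at 1
  unless an extra-sum-of-squares F-test demands otherwise;
  `select_components` chooses n by nested F-tests.
- `SaturationModel` — saturation binding with Hill slope, nonspecific
  fraction NS and optional ligand-depletion correction (implicit equation
  solved by bracketed root-finding).
- `normalize_replicates` — presentation of replicate experiments against a
  single mean-parameter curve, `Y' = Y f(x, ā, b)/f(x, a, b)`.

**Mechanistic capping kinetics** (`allokit.capping`): the ternary-complex
scheme in which the allosteric ligand caps the vestibule — ARL is reachable
only via RL — integrated as a stiff ODE system under simultaneous, A-first
or L-first addition protocols, with rate constants derived from equilibrium
constants via the cooperativity partition `k_−AL = α^−j k_−A`,
`k_+AL = α^−(j+1) k_+A` (j = 2 by default) and a closed-form equilibrium
oracle.

**FRET** (`allokit.fret`): non-negative least-squares unmixing of per-cell
emission spectra onto donor/acceptor (and optional third-colour)
references, apparent efficiency
`E_app = 100/(1 + (Q_A/Q_D)(k_D/k_A′)(W_D/W_A))` % with Q_D = 0.70,
Q_A = 0.22, W_D/W_A = 0.94 and a 6% direct-excitation correction to k_A,
and Gaussian population statistics with paired/unpaired tests.

**TCSPC anisotropy** (`allokit.tcspc`): polarised decays under periodic
excitation (T = 12.5 ns) with high-NA corrections (k1 = 0.33, k2 = 0.065)
and G = 1.061, circular IRF reconvolution with a fractional colour offset,
global Poisson-likelihood fitting of lifetime τ and rotational correlation
time φ, and tail-ratio G-factor estimation.

**Synthetic data** (`allokit.synthetic`): seeded generators for every input
above, returning observations plus generating truth.

See `docs/methods.md` for model details and design rationale.

## Worked example

Fit the three-component modulation equation to three replicate synthetic
gallamine-style curves (2% noise, generating affinities
log K = −6.39, −3.15, −2.60):

```python
from allokit import ModulationModel
from allokit.synthetic import gen_modulation

curves, truth = gen_modulation([-6.39, -3.15, -2.60], noise=0.02,
                               replicates=3, seed=21)
res = ModulationModel(curves, n_components=3, seed=0).fit()
print(res.summary())
```

```
Multiphasic modulation fit
============================================================
components: 3    observations: 54    experiments: 3
SSR: 0.0184085    df_resid: 43
Hill slopes: fixed at 1
------------------------------------------------------------
component        log K        SE       F_j        SE      nH
1               -6.472     0.061     0.321     0.010    1.00
2               -3.416     0.251     0.302     0.126    1.00
3               -2.444     0.194     0.377     0.129    1.00
------------------------------------------------------------
rep1: Y0 = 1.036, Yinf = 0.003318
rep2: Y0 = 1.145, Yinf = -0.01115
rep3: Y0 = 1.028, Yinf = -0.01467
```

Each row is one allosteric component: its apparent affinity (log10 molar
dissociation constant with standard error), the fraction of the response
span it carries, and its Hill slope. The high-affinity component is
recovered sharply (−6.47 ± 0.06 against a generating −6.39); the two
low-affinity components, only 0.55 log units apart, carry the large
standard errors such closely spaced transitions deserve. Y0/Yinf are the
per-replicate plateaus absorbing between-experiment scale differences.

## Command line

A thin CLI wraps the library:

```sh
allokit generate --kind modulation --seed 5
allokit fit-modulation synthetic_modulation.csv --n auto --out fit.json
allokit simulate-capping --protocol L-first --out curves.csv
allokit unmix spectra.csv references.csv --colors 2 --out unmixed.json
allokit fit-anisotropy decays.csv --out fit.json
```

Exit codes: 0 success, 2 parse/validation error, 3 fit failure.

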