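# Methods

`wjdf` implements a dynamic (kinetic) metabolic flux analysis of Wharton's
Jelly mesenchymal stromal cell (WJMSC) batch cultures, comparing an early
(P4) and a late (P9) passage. This note documents the model, its
assumptions, the numerical choices, and what the synthetic study emulation
does and does not show.

## Model structure

The packaged network (`src/wjdf/data/wjmsc_network.yaml`) has 55 species
and 50 reactions: 49 enzymatic reactions plus one biomass (growth)
reaction. Pathways: glycolysis (HK, PGI, PFK, PGK, PK, LDH), the pentose
phosphate pathway (G6PDH, TK, NAT, PPRibP), the TCA cycle (PDH, CS, CITS,
AKGDH, SCOAS, SDH, FUMase, MDH, plus the anaplerotic/cataplerotic ME and
PC), the urea cycle (ARGt, ARG1, iNOS, OCT, ASS, ASL), tryptophan
catabolism (IDO, KOT), lumped amino-acid metabolism (ASTA, AlaTA, SDHH,
AAtoSUC, HISARGTA, GLNase, GDH, ASN and seven transporters), and cell
energetics (resp, AK, CK, NHG, NADPHox, ATPase).

Heavily lumped steps are deliberate: PFK includes aldolase/triose-phosphate
isomerase (1 F6P → 2 trioses), PGK includes GAPDH through enolase (GAP →
PEP yielding 1 NADH and 1 ATP), G6PDH stands for the whole oxidative PPP
branch and TK for the whole non-oxidative branch, `resp` lumps the
respiratory chain at a fixed P/O-like yield of 2.5 ATP per NADH, and SDH
carries its FADH2 equivalent as 1.5 ATP directly (these stoichiometric
yields live in the network file and are editable there).

Units: extracellular concentrations in mM, intracellular in mmol per 10^6
cells, cell density X in 10^6 cells/mL, specific fluxes in mmol per 10^6
cells per h.

### Rate laws

Every enzymatic flux is an irreversible multiplicative Michaelis–Menten
product,

    v = vmax * prod_s  c_s / (Km_s + c_s),

optionally scaled by a dimensionless adenylate-state factor

    f(r) = (1 + r/alpha) / (1 + r/beta),    r = AMP/ATP,

carried by hexokinase and lactate dehydrogenase only (the two reactions
with published alpha/beta pairs). f is neutral at alpha = beta or r = 0,
activating for beta > alpha, inhibitory for beta < alpha, and bounded
between min(1, beta/alpha) and max(1, beta/alpha).

Reversible enzymes are represented by a single direction chosen for
network closure: ASTA runs OXA + GLU → ASP + AKG; GLNase runs forward
(GLN → GLU) because the reverse direction would leave imported glutamine
without a consumer and sever the anaplerotic glutaminolysis route; AK runs
in the AMP-salvaging direction (ATP + AMP → 2 ADP) because with one-way
kinetics the textbook direction turns AMP into an absorbing sink and
collapses the adenylate pool.

### Growth

The specific growth rate is

    mu = vmaxgrowth * prod over precursors of c/(Km + c)

with precursors G6P (glycogen), CIT (lipids), R5P (nucleotides), ATP and
extracellular tryptophan — tryptophan is essential, so mu → 0 on its
exhaustion. The growth reaction drains biomass precursors with fixed
coefficients derived from a standard mammalian-cell composition
(protein ≈ 70% of the 3.15e-4 gDW per 10^6 cells at a mean residue weight
of 107.5 g/mol, distributed over thirteen medium amino acids; small G6P,
CIT and R5P drains; ATP cost vgrowthATP = vgrowthADP = 1.19e-2 mmol per
10^6 cells). Contact inhibition is not modeled: growth stops only by
substrate limitation, which is what lets simulations extrapolate past the
72 h harvest.

### Balances

    dX/dt   = mu X
    dc_int/dt = sum_r nu * v_r  -  mu c_int         (growth dilution)
    dc_ext/dt = 1000 * X * sum_r nu * v_r           (mL -> L factor)

Concentrations are clipped at zero inside the right-hand side rather than
terminating on events; this keeps the integrator robust under the
optimizer's exploratory parameter vectors.

## Parameters

234-odd kinetic constants are referenced by the network; 32 of them (the
sensitive subset plus `vmaxresp`) ship with published values per condition
(`table1_parameters.csv`, columns P4 / combined / P9). The remaining ~113
(`default_parameters.csv`) are order-of-magnitude fixture defaults, not
measured claims: Km defaults sit at the substrate's typical concentration
scale (≈1e-7 mmol per 10^6 cells intracellular, 0.1–1 mM extracellular) so
saturation terms start near one half, and vmax defaults were balanced once
so that the default scenario starts near a flux steady state and
reproduces the study's qualitative regimes:

* P4-like cultures are glycolytic (the lactate branch carries the
  majority of the pyruvate-node flux; time-averaged lactate fraction
  ≈ 0.7) and faster-growing (initial mu ≈ 2.7e-2 1/h);
* P9-like cultures are oxidative (TCA branch ≈ 0.5 and rising, lactate
  below half), slower-growing (initial mu ≈ 1.4e-2 1/h), with a higher
  ATP/ADP ratio and a lower AMP/ATP ratio;
* growth extrapolated past harvest ceases only after extracellular
  tryptophan crosses below its growth Km (~100 h for the P4-like
  default), the IDO route and biomass demand being its only sinks.

The passage contrast emerges mechanistically from the published value
differences — halved vmaxHK, 1.7x vmaxresp, 22x vmaxAAtoSUC, shifted
AMP/ATP regulation — through the shared redox pool: higher respiratory
capacity keeps NAD+ available and favours PDH over LDH at the pyruvate
node. The defaults were fixed before the calibration/sensitivity test
suites were built and are not tuned per test.

Known fixture limitations: absolute flux magnitudes are not the study's
(with the published vmaxLDH ≈ 8e-5, the lactate export rate cannot reach
the measured ≈ 5.8e-4 under saturating one-way kinetics); the P9 ATP/ADP
ratio plateaus near 29 rather than declining from 13 to 5; unmeasured
buffer pools (GAP, ASP, OXA) drift toward their dilution-capped levels on
long horizons. Medium composition defaults are an alpha-MEM + 20% FBS
approximation (glucose 5.5 mM, glutamine 2 mM, tryptophan 0.049 mM); the
study does not print its medium concentrations.

## Simulation

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-6, atol 1e-12 (pool scales
reach 1e-10, so the absolute tolerance sits well below them; halving both
tolerances moves every state by < 0.1% above a 1e-9 floor). The
right-hand side is vectorized: all saturation terms are evaluated in one
sweep and folded per reaction with `np.multiply.reduceat`; a full 72 h
culture solves in ≈ 0.1 s, which is what makes the fitting and sensitivity
loops tractable.

## Calibration

Error metric: max-normalized mean squared residual,
E = (1/N) Σ_s Σ_t ((sim − obs)/norm_s)², norm_s = max_t |obs| (floored at
1e-12). Normalizing per species is necessary because observed quantities
span five orders of magnitude. Optional 1/SEM² weighting is available when
replicate SEMs exist.

Two stages, following the study design: (1) a pooled fit of both
conditions' data (each simulated from its own initial state, objective =
sum of the two errors); (2) a per-passage refit of the sensitive subset
plus `vmaxresp`, everything else frozen bitwise at stage-1 values.

Optimizer: bounded trust-region least squares (`least_squares`, trf) over
log10-parameter space — parameters are positive and span decades — with
bounds defaulting to x/÷100 of the starting value, seeded multi-start
(default 8 restarts, log-uniform x[1/3, 3] perturbations), and an explicit
finite-difference step of 1e-2 in log10 space (≈ 2.3% parameter change).
The large step matters: with the default step the numerical Jacobian sits
below the ODE solver's noise floor and the optimizer stalls far from the
optimum. Simulations during fitting may use a looser solver (rtol 1e-5);
reported objectives are recomputed at the returned parameters.

Observed-vs-simulated alignment is exact: the trajectory is evaluated at
the sample times; data are never interpolated.

## Sensitivity analysis

One-at-a-time multiplicative perturbation of each parameter by ±15%, with
score = max over the two directions of |E± − E0|/E0 × 100 (mean reduction
selectable); parameters scoring above 10% are classified sensitive, sorted
by score with alphabetical tie-break. Zero-valued parameters are perturbed
additively by 15% of their bound span (multiplying zero is degenerate).
The baseline error is floored at 1e-30 so self-fit baselines remain
well-defined. On toy models the scores match an independent brute-force
recomputation (separate integrator, hand-evaluated metric) to six
significant figures.

## Synthetic data

The generator forward-simulates a ground-truth parameter set, samples on
the study's schedules (P4: 0, 12, 24, 32, 40, 48, 56, 64, 72 h; P9: 0, 18,
27, 36, 45, 54, 63, 72 h — later passages were sampled more sparsely to
keep ≥3e6 cells per sample), applies mean-one multiplicative lognormal
replicate noise (CV 5% intracellular, 3% extracellular, 10% cell counts;
concentrations are positive and span decades, so noise scales with
signal), and records replicate means and SEMs for n = 3, mirroring the
study's error bars. An optional detection floor censors values below a
quantification limit. The exact noiseless table rides along for oracle
use.

Passing the recovery tests on these fixtures shows the estimation
machinery works under the study's design (schedules, measured panel, noise
scale); it does not validate the biology of the defaults, nor does it
reproduce the study's exact concentration curves, which depend on the
unpublished 234-parameter optimum and medium composition.

## Verification highlights

The test suite checks, among others: closed-form growth arithmetic from
the reported densities (mu = 2.36e-2 / 1.36e-2 1/h, doubling times
29.4 / 51.0 h); the published fold-change labels (22x for vmaxAAtoSUC,
0.5x for vmaxgrowth — the "idem" band is a plain ±15% ratio band, which
reproduces every published label); the one-sided 95% Student's-t reference
2.132 at df = 4; flux-partition normalization to one at every time point;
ODE agreement with the exponential growth limit within 0.1%; the stage-2
freeze contract (bitwise); zero-noise self-fit objective < 1e-10; recovery
of the ten most influential vmax parameters within 25% median error over
five seeds at 5% noise; and bitwise seeded reproducibility of the
end-to-end pipeline.
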