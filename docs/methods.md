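# Methods

This note documents the model, the defaults, the synthetic data, and the
numerical and design choices made where the design was genuinely open.

## Thermodynamic model of transcription

The unit of study is one output gene (*tf3*, product TF3) with up to two
input TFs (TF1, TF2). All regulatory structure is derived from four
sequences: a cis-regulatory nucleotide string and three amino-acid
binding-domain strings. Nothing else (no site annotations) enters the
model, so binding sites can appear and disappear under sequence mutation.

**Coordinates and promoter anatomy.** The rightmost base of the cis
region is position −1 relative to the transcription start site. The core
promoter is anchored there: −10 hexamer at [−12, −7], 17-bp spacer,
−35 hexamer at [−35, −30]; bound RNAP covers the whole footprint
[−35, −7] (29 bp). Regions are 40–300 bp; the generator default is
150 bp, which leaves room for five or more tandem 9-bp sites upstream of
the footprint while keeping the evolutionary search space compact.

**TF–DNA.** Each of the `L_TF` residues contacts one base; energies are
additive over contacts via a 20×4 matrix in kT. `L_TF = 9` by default
(bacterial sites are typically 6–15 bp with ~one residue per base).
`Kd = K0·exp(ΔG)` with a single calibration constant `K0` chosen so that
a perfect site under the shipped matrix reaches ~1 nM while random sites
sit far above 10⁴ nM; the biologically relevant 1–10 000 nM range is then
reachable by tuning site sequences, which is the only property of the
matrix the results depend on.

**RNAP–DNA.** RNAP binds only the core promoter. The two hexamers are
scored against a position-frequency model (`s(b, i)` = observed frequency
over the random fraction 1/4); the binding energy is `−Σ ln s`, and
`q_R = [RNAP]/(K0R·exp(E))`. `K0R` is calibrated so the consensus
promoter has `q_R = 1` at the default 30 nM RNAP; each non-consensus
hexamer base then costs a fixed log-score drop.

**Interactions.** TFs overlapping each other or the RNAP footprint are
mutually exclusive. Two bound TFs with edge-to-edge gap ≤ `d_coop`
(default 18 bp) gain a cooperativity factor `ω_coop` (default 50, in the
validated 10–100 range); cooperativity acts between nearest neighbours
only, so chains gain factors transitively — this is what makes a
linear-scan recursion exact. A bound TF whose gap to the footprint is
≤ `d_act` (default 20 bp) gains a recruitment factor `ω_act` (default 50)
when RNAP is present; several TFs may recruit simultaneously
(multiplicatively). Any overlap with the footprint counts as full
exclusion. `d_coop` must stay below the 29-bp footprint width, because
the scan would otherwise chain cooperativity across bound RNAP.

**Partition sums.** `P_on = Z_on/(Z_on + Z_off)` over all configurations
(the empty one has weight 1). The dynamic program scans start positions
once, keeping per end-position accumulators split into a "recent" window
(cooperativity applies) and an older prefix. Because each configuration's
weight is a monomial in `c3`, the DP carries coefficient vectors and
returns `Z_on`, `Z_off` as polynomials in `c3` of degree ≤ ⌊L/L_TF⌋. The
hot kernel is JIT-compiled (numba) with a pure-Python fallback, and is
verified against exhaustive enumeration to 10⁻⁹ relative on randomized
small systems. Per-site occupancies use matching forward and backward
scans at fixed concentrations.

## Output dynamics

`dc3/dt = β·P_on(c1, c2, c3) − μ·c3`, with transcription and translation
concatenated and no time delays (so no oscillations). Time is measured in
units of the TF3 lifetime (`μ = 1`); `c_max = β/μ = 1000 nM` matches the
upper edge of the input domain. With the polynomial representation the
steady-state condition is the polynomial identity
`β·Z_on(c) − μ·c·(Z_on+Z_off)(c) = 0`, whose sign equals the sign of
`dc3/dt`; trajectories of the one-dimensional ODE are monotone, so the
limit point from any initial condition is the nearest stable root in the
flow direction. Roots are located on a mixed geometric/linear scan grid
(256 points by default; geometric spacing resolves nM-scale low states)
and refined by bisection to ~10⁻¹² relative; every returned state must
pass the residual check `|β·P_on − μ·c| < μ·ε_ss` (`ε_ss = 0.1 nM`).
This is the fixed-point acceleration route explicitly allowed by the
integrator contract; only response times integrate the ODE explicitly
(adaptive RK with relative tolerance 10⁻⁸, terminal event at
`|c3 − c3*| < ε_rt = 1 nM`, time limit 200 τ₀).

**Bistability.** Steady states are always computed twice, from `c3 = 0`
and `c3 = c_max`; if they differ by more than `ε_ss` the squared
difference (in units of c0² = 1 nM²) is added to the fitness deviation,
which eliminates bistable gates from evolving populations. A dense
root scan (`bistability_scan`) reports all stable fixed points for
post-hoc checks.

**Intrinsic noise.** Production/degradation shot noise is treated in the
small-noise (linear-noise) approximation: with `f(c3) = β·P_on` and
derivatives estimated by central differences (step 0.1 nM),

```
σ² = μ·c3* / (V·(μ − f′(c3*))),
```

which reduces to the Poisson copy-number limit `σ = sqrt(c3*/V)` for a
constitutive gene (`f′ = 0`), grows with positive feedback and diverges
as `f′ → μ⁻`; non-positive restoring force is an error flag treated as
maximal noise. The curvature `f″` is computed as a diagnostic of the
linearization but does not enter σ. `V = 1` molecule/nM by default.

## Gates, grids and fitness

Ten gate types: AND/OR/NOR/NAND (two inputs), ACT/IN (one input), and the
linear LACT (`c1`), LIN (`1000 − c1`), MEAN (`(c1+c2)/2`), NMEAN
(`1000 − (c1+c2)/2`). Inputs live on [0, 1000] nM; concentrations at or
above 500 nM count as "high" (the 500 nM tie goes to "high"; the
one-input grid's midpoint sits exactly there and either convention is
symmetric). Two-input gates are scored on the 4×4 grid
{125, 375, 625, 875}² (two concentrations per logic class, symmetric
about the threshold); one-input gates on seven equally spaced values.
`E_RF` sums squared deviations plus bistability penalties; `E_RT` sums
the 32 (or 14) response times from both extreme initial conditions;
`E_N` sums the stationary noise σ over the grid. The dynamical weights
ramp linearly from 0 to their maxima over `t_ramp` cycles (default 200)
so early populations are not trapped in the silent local optimum where
all response times vanish. `S0 = 10⁸` keeps all realized scores positive
(a worst-case two-input genotype can exceed 10⁷ in E_RF plus penalties);
the offset is arbitrary and cancels in ranking.

## Evolutionary algorithm

Population 200, 1000 cycles by default (the shipped stochastic checks run
a scaled-down 60 × 300 version; with the JIT kernel one such run takes
~20 s). Per cycle every genotype is mutated — one cis substitution with
probability 0.5, one single-base insertion/deletion with probability 0.1
(promoter anatomy stays anchored to the TSS; deletions at the 40-bp
minimum and insertions at the 300-bp maximum are skipped), one point
mutation per TF with probability 0.03 — then scored, then the top 20%
survive and refill the population by uniform duplication (ties broken by
stable order). The rates satisfy the usual criteria (enough variation,
persistent elites) and are configurable. One exception to
mutate-everything: the single incumbent best is copied through unchanged,
which with deterministic fitness makes the best score exactly monotone
(under λ ramps the fitness function itself drifts, so monotonicity is
only guaranteed at constant weights). Unchanged genotypes reuse cached
scores; all randomness flows from one seeded generator, so runs are
bit-reproducible.

## Minimal models

Six stylized layouts (explicit site Kds, shared factor ω for
cooperativity and recruitment, normalized RNAP weight p) capture the
recurring design principles: single-site and two-site cooperative
activation, conditional auto-activation, two-operator cooperative
repression with and without an auto-activation site, and the
unequal-operator linear-repression variant. Their partition sums are
written in closed form *and* mapped onto explicit site tables of the full
engine with coordinates that realize exactly the intended interactions
(recruiting sites within `d_act`, cooperative partners within `d_coop`,
operators overlapping the footprint, the auto-activation site of the
repression layouts at gap 19 so it recruits without contacting the
operators); agreement to 10⁻⁴ relative over random parameter sets is the
strongest oracle in the repository. With a single auto-regulatory site
the feedback production is a Möbius (concave) function of the output, so
these layouts are structurally monostable; bistability requires two
cooperative auto-activation sites and is exercised through the general
engine.

Sensitivity `S = |d ln c3*/d ln c1|` is estimated by central log–log
differences (factor 1.01); `max_sensitivity` sweeps log grids (20
points/decade by default) over the operator Kd, ω and p, tabulates the
response on a log input grid and refines around the argmax. For pure
two-operator repression the supremum approaches but never exceeds 2 —
the operator count, which also serves as the reported analytic bound;
with an auto-activation site swept points above 2 exist, and for
conditional auto-activation the attainable steepness keeps growing as
the RNAP weight is lowered (with the feedback Kd co-optimized), with no
Hill-type ceiling. Affinity optimization against one-input goals uses
Nelder–Mead on log₁₀ Kds in [1, 10⁶] nM (the upper bound models site
removal) from ten seeded random restarts, never returning worse than the
best start. The linear-repression identity
`dc3*/dc1 = G_c1 / (1 − G_c3)` (with `G = (β/μ)P_on`; denominator 1
without feedback) is verified with complex-step partial derivatives,
which are exact to machine precision for these rational occupancies.

## Synthetic data and reference designs

The generator ships the complete study conditions: a seeded 20×4 matrix
(per amino acid one favored base at ≈ −3 kT plus ±0.3 kT jitter), a
promoter model peaked on TTGACA/TATAAT (consensus frequency 0.7), and
random genotypes. What it emulates is the *structure* of the published
inputs — one strongly favorable base per residue and an informative
promoter consensus — not their actual values; passing tests therefore
demonstrate the mechanisms (cooperativity, recruitment, feedback) rather
than agreement with any specific organism's energies. Real contact
matrices are denser and noisier, and real promoters have correlated
positions; none of that is modelled.

Reference designs are genotypes engineered by inverting the energy model.
To keep hand-built layouts legible against the diffuse weak-binding
background that any sequence model produces, the design TFs are composed
from amino acids with disjoint favored-base sub-alphabets (TF1: A/C,
TF2: G/T, TF3: A/G) following fixed low-autocorrelation patterns, site
sequences are restricted to favored-plus-poison bases (so shifted frames
of a site stay weak), operator positions overlapping the hexamers hold
those bases fixed, promoter degeneration prefers bases the design TFs
cannot use, and the {C,T} filler is scrubbed by a greedy hill-climb
until no unintended frame binds below ~10⁷ nM. Each design's Kd targets
and basal weight were tuned once against the engine so its behavioral
assertion holds: the hetero-cooperative AND and the conditional
auto-activation AND are high only in the high/high input quadrant, the
auto-activated NAND reproduces its truth table at the corner input
classes with feedback measure F > 10³ nM², the linear-repression design
responds monotonically decreasing, and the two-site auto-activator is
bistable. Even after scrubbing, the residual weak-site background shifts
surfaces by ~100 nM, so the reduced model built from the called sites of
the conditional-auto-activation AND reproduces the full surface to
~100 nM (the shipped check allows 150 nM), while dropping a genuinely
called site degrades it several-fold more; the default simplification
tolerance elsewhere remains 50 nM.

## Analysis conventions

The feedback measure F is the mean over the evaluation grid of the
squared difference between the response surface and the surface
recomputed with every TF3 affinity set to zero; bistable grid points are
excluded with a warning. Computational footprints evaluate every
(TF, site) occupancy at the four corner conditions
(c1, c2) ∈ {0, 1000}² with the output at its self-consistent steady
state; sites are called at the stringent O_max ≥ 0.5 cutoff (pooled
occupancy histograms over evolved populations are strongly bimodal, so
calls are insensitive to the exact value), overlapping same-TF calls
keep the strongest start, and roles are annotated by geometry
(repressor / activator / distal, with an auto- prefix for TF3). Site
calls export as BED (0-based half-open, score = 1000·O_max); in-degree
summaries and run logs as TSV; configuration as JSON.

## Known limitations

Single-strand scanning only (no reverse-complement sites); no DNA
looping, extended −10 elements or DNA bending; no extrinsic noise, no
transcription/translation separation, no delays or oscillations; no
recombination in the evolutionary algorithm, which is an optimizer and
not a population-genetics model. Published tallies of evolved design
frequencies (e.g. how many runs of a given gate adopt a particular
mechanism) depend on the unavailable published energy matrix and
mutation rates and are reproduced only qualitatively, at reduced scale,
by the stochastic checks.
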