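# Methods

This note documents the models implemented in `pfevo`, the parameter
defaults and why they were chosen, what the synthetic data emulate, the
numerical choices, and the known limitations.

## The fitness landscape model

A cell's division rate is the product of a drug-free maximum and two
relative stress factors, `gamma = gamma0 · gamma1 · gamma2`.

**Zeocin factor (`gamma1`).** External zeocin `Z` (mg/ml) enters the cell
at rate `k_in` and is cleared at `k_out`; free internal zeocin `Z_i` binds
unbound resistance protein `R` at rate `k_on`, and complex turnover at
`k_off` recycles the protein while leaving the bound antibiotic
neutralized:

```
dZ_i/dt = k_in Z − k_out Z_i − k_on Z_i R
dB/dt   = k_on Z_i R − k_off B,      R = F − B
```

Setting both derivatives to zero gives a quadratic in `Z_i` with a single
non-negative root (the product of roots is ≤ 0), solved in closed form;
protein is conserved (`B + R = F`). Only the *free* internal zeocin is
damaging: `gamma1 = 1/(1 + (Z_i/K_z)^h_z)`. The turnover formulation is
deliberate: if dissociation returned active zeocin to the free pool, the
steady-state `Z_i` would be independent of `F` and expression could not
protect, contradicting the circuit's observable resistance phenotype.
Both `gamma` forms are package defaults; alternative published forms can
be substituted by swapping the `gamma_*` callables.

**Inducer factor (`gamma2`).** rtTA level is taken equal to the reporter
level `F`; its doxycycline-bound activity saturates with half-constant
`K_C` and poisons growth (squelching) through a Hill term:
`gamma2 = 1/(1 + (F · C/(C + K_C) / K_d)^h_d)`.

**Population fitness** is the arithmetic mean of `gamma` over a sample of
log10-fluorescence values, which makes it exactly linear in mixture
weights.

### Parameter defaults and calibration

The defaults must reproduce the qualitative landscape geometry the system
is known to have: monotone *decreasing* in expression with inducer only
(D2Z0, DiZ0), monotone *increasing* with zeocin only (D0Z2), and an
interior maximum when both drugs are present (DiZ2, D2Z2); plus the
described population behaviors — an On-majority ancestral population in
D2Z0 (fluorescence rises before resistance mutations appear), a bimodal
minority-On population at the intermediate inducer level `Di`, weak
selection in DiZ0, and roughly forty generations per week of culture in
D2Z0. The frozen set:

| parameter | value | units | role |
|---|---|---|---|
| `gamma0` | 0.25 | /h | maximal division rate (~2.8 h doubling, galactose medium) |
| `k_in`, `k_out`, `k_on`, `k_off` | 1.0 | /h | zeocin uptake/clearance/binding/turnover |
| `K_z` | 0.1 | int. zeocin units | kill half-constant |
| `h_z` | 2 | – | kill Hill coefficient |
| `K_C` | 0.6 | µg/ml | dox half-saturation of rtTA activity |
| `K_d` | 500 | protein units | squelching toxicity constant |
| `h_d` | 2 | – | squelching Hill coefficient |
| `r_max`, `K_r`, `n_r` | 0.4 /h, 1.0 µg/ml, 2 | – | Off→On dose response |
| `f` | 0.01 | /h | On→Off (memory loss) |
| Off / On modes | 1.0 / 3.0 | log10 a.u. | expression modes, sd 0.25 |

`gamma0` is anchored on the generation count of the inducer-only
experiment (≈ 40 generations in under a week, including the takeover by
fast-growing knockouts) — a 90-minute doubling time would nearly double
it. `K_C = 0.6` places a ~20 % On-state cost at `Di` and ~66 % at `D2`:
small enough that DiZ0 selection stays too weak to defeat the ancestor in
20 days, large enough that the DiZ2 population measurably under-performs
its landscape peak and adaptation there is intermediate between the steep
monotone conditions and DiZ0. These two constants were iterated against
that qualitative constraint set and then frozen; everything downstream
uses the same values.

## Two-state switching dynamics

Off/On counts evolve by the linear system in the README; the propagator is
the closed-form 2×2 matrix exponential via eigendecomposition, with a
scaling-and-squaring fallback when the eigenvalue gap is below 1e-12. The
long-run growth rate is the dominant eigenvalue and the long-run
composition its eigenvector — except that cultures start all-Off, so when
`r = 0` (no inducer) the On state is unreachable and the ancestral growth
rate is simply `g_L`. Switching-rate inference fits
(`r_max`, `K_r`, `n_r`, `f`) to On-fraction tables by bounded
least squares from eight fixed multi-starts (deterministic given the
data).

## Lumped ODE model of the first evolutionary steps

Population *fractions* of the ancestor and the lumped K/T/G classes follow
replicator dynamics with constant mutational influx
(`mu_h = mu · g_anc/ln 2`, converting per-generation to per-hour through
the ancestral division rate). Class fitnesses per environment:

* **K** — cellular fitness at *basal* (Off-mode) expression. Basal, not
  the grid minimum: a knockout cannot push expression below the uninduced
  level, which also makes K exactly neutral in D0Z2.
* **T** — expectation (or a draw) of cellular fitness uniform in log10 F
  over the intermediate range between the Off and On modes; without
  inducer the range collapses to the Off mode (a tweaked circuit cannot
  express), making T neutral in zeocin-only conditions.
* **G** — expectation (or a draw) uniform between the ancestral fitness
  and the fitness the same genotype would have with zeocin removed.

Mutant classes do not back-mutate or mutate further (single-step model of
initial adaptation). Integration is adaptive RK45 at rtol 1e-8 /
atol 1e-10 with hourly output; fractions are renormalized against
integrator drift. The ancestral half-life is the linearly interpolated
first crossing of 0.5, with an infinite sentinel when never reached.

## Detailed stochastic simulator

State: one row per surviving allele with Off/On cell counts, effect
parameters, origin time and a preexisting flag; population-level internal
drug concentrations; a division counter.

* **Drug uptake.** Internal effective concentrations relax exponentially
  to the external ones (doxycycline 1.0/h, zeocin 0.5/h — the antibiotic,
  a large glycopeptide, equilibrates more slowly than the small-molecule
  inducer). Cells start drug-free; resuspension into fresh medium resets
  nothing internally (cells carry internalized drug).
* **Growth decomposition.** Squelching toxicity slows division. Zeocin
  toxicity `(1 − gamma1)` is cell-cycle arrest first: by default it also
  reduces the division rate (`zeocin_death_share = 0`); a configurable
  share of it can be routed into an explicit death rate instead. The net
  growth rate is the cellular fitness in every case, but the gross
  division rate sets the per-division mutation supply, so the arrest
  interpretation matters: treating zeocin purely as killing would let
  nearly-arrested populations keep producing mutants at full speed.
* **Hybrid integration.** Lineages at or above 10^3 cells advance by the
  exact two-state propagator (rates refreshed whenever internal drug
  levels move by more than 0.1 % of the external scale, or the allele set
  changes); smaller lineages advance in 0.1 h steps by binomial deaths
  (probability `1 − e^{−d·dt}`), then divisions among survivors
  (probability `e^{b·dt} − 1`, which makes the mean one-step growth factor
  exactly `e^{(b−d)dt}`), then switching. Single-cell establishment and
  loss therefore experience genuine drift while bulk growth stays exact.
* **Mutation entry.** New mutants are Poisson in the realized ancestral
  divisions with rate `mu` per genome per generation — 10^-6.2 without
  zeocin, 10^-5.4 with (the DNA-damaging antibiotic elevates the
  beneficial-mutation rate) — and type probabilities
  P(G) = 0.75, P(T) = 0.025, P(K) = 1 − P(G) − P(T) = 0.225. A mutant
  enters as a single cell in the Off/On state of its parent division
  (proportional to state-specific division flux), except knockouts, which
  collapse to basal expression and can never switch On. T carries one
  tweak parameter θ ~ U(0,1) that scales the Off→On rate *and* lowers the
  On-mode expression to `off + θ·(on − off)` in log10 — a partial loss of
  rtTA activity reduces both switching and the induced level. A pure
  switching-rate reduction cannot reproduce T's dominance in D2Z2: the
  dominant eigenvalue of the two-state system is monotone in `r`, so an
  `r`-only tweak is always beaten by either the ancestor or the knockout;
  moving the On state toward the fitness peak is what the recurrent D2Z2
  mutations do phenotypically. G draws a kill-constant multiplier uniform
  between 1 and the cap at which `gamma1` reaches `1 − ε` (ε = 0.01) at
  the cell's current expression state, so the fitness gain never exceeds
  the zeocin-free value; multipliers drawn in a zeocin-free environment
  are materialized from the stored quantile when the allele first meets
  zeocin (the preexisting-mutation variant).
* **Resuspension.** Every 12 h (configurable), if the culture exceeds
  10^6 cells it is diluted multinomially over all (allele, state)
  compartments to exactly 10^6; an exact-scaling deterministic mode
  supports the all-ODE limit. Extinct lineages are pruned.
* **Outputs.** Daily allele frequencies; per-replicate summary (half-life
  from an hourly ancestral-fraction series, alleles above 5 % frequency at
  day 20, type fractions, preexisting mass and allele-count fractions);
  ensemble means ± SEM with never-reached half-lives reported as a
  fraction-reached alongside the mean over reached replicates.
* **Preexisting variant.** 24 h of growth in D0Z0 at the zeocin-free
  mutation rate precedes the condition switch; in D0Z0 every mutation
  class is automatically neutral (no zeocin benefit, no inducer cost), and
  mutations arising there are flagged. The reported contribution is the
  day-20 frequency mass of flagged alleles over total mutant mass.
* **Reproducibility.** One master seed; replicate seeds come from
  `numpy.random.SeedSequence.spawn`, so replicates are independent and
  individually re-runnable; identical seeds give bit-identical
  trajectories.

## Time-course reconstruction

Per (allele, day): the knot is the mean of the Sanger and whole-genome
calls when both exist, else the single call. Linkage groups are inferred
from perfect co-occurrence across clonal isolates; the linked haplotype's
whole-genome estimate is the mean over members (generalized from pairs to
any group size), averaged again with the clone-proportion Sanger estimate
where one exists that day. The ancestral series is one minus the mutant
sum (linked groups counted once), clamped to 0 after its first 0 with the
mutant series deliberately left unnormalized. Trajectories are
second-order (quadratic) splines through the knots — linear for two
knots — clipped to [0, 1]; both raw and clipped curves are exported.
Mutant trajectories are anchored at frequency 0 on day 0 unless observed.

## Phenotyping and statistics

Growth rates are log-linear regression slopes over the contiguous window
(≥ 4 points) with the highest R² (flat windows score 0; ties go to the
longer, then earlier window) — the estimator is scale-invariant in density
units. Resuspension-regime fitness is `ln(N_end/N_start)/interval` per
cycle. Clone phenotypes are two-condition log10 ratios of fitness or mean
fluorescence (antisymmetric, zero at equality). Group comparisons use
two-sided Student's t-tests — independent samples across conditions,
paired within a condition — with Bonferroni-adjusted significance
(α/n comparisons); an unequal-variance option is provided.

## Synthetic data

The generators emulate the four measurement layers the pipeline consumes,
with the statistical structure the methods assume: exponential growth
curves at the population fitness of each of the 13 landscape-mapping
conditions (zeocin 0.5/1/1.5/2 mg/ml; dox 0.2/0.5/1/2 µg/ml; the dox grid
crossed with 2 mg/ml zeocin; untreated control), sampled every 6 h over
72 h with 2 % multiplicative log-normal noise; bimodal log-normal
flow-cytometry samples (10^4 cells) whose On weight follows the switching
model; whole-genome calls as Binomial(coverage, truth)/coverage at 100×
with clonal-isolate genotypes (20/day) drawn multinomially over
haplotypes so linkage is preserved exactly; and dose-response On-fraction
tables with binomial counting noise. Every generator is a pure function
of its inputs and seed.

What they do *not* emulate: instrument-specific artifacts (autofluorescence
drift, OD saturation and shadowing, mapping bias in read counts),
expression-level heritability beyond the two discrete states, and real
mutational target sizes. Passing round-trip tests therefore demonstrates
internal consistency of the estimators with the generative assumptions,
not robustness to these real-data effects.

## Problem sizes

Acceptance-style checks run N = 30 replicates per condition for the
condition scan and N = 60–100 for the preexisting-mutation variant (the
variant comparison pairs replicate seeds across conditions so both share
their pre-phase realizations); ensemble SEMs are reported with every
mean. The parameter-recovery studies use the full 13-condition design
with 2000-cell expression samples. These sizes were chosen so a complete
run takes minutes on a single core while keeping Monte-Carlo error well
inside the tolerances asserted.

## Known limitations

* The landscape constants are calibrated to reproduce the system's
  qualitative geometry and time scale, not fitted to the original
  measurements; absolute half-lives carry that calibration uncertainty,
  which is why the preexisting-contribution and ordering checks use wide
  tolerances.
* Under 2 % growth-curve noise the inducer-toxicity triple
  (`K_C`, `K_d`, `h_d`) is only weakly identifiable — many combinations
  produce nearly identical landscapes; the fitted landscape itself is
  recovered to a few percent even when individual constants are not.
* Alleles are abstract single-step lineages: no double mutants, no
  sequence-level identity, no mutation-specific effect sizes beyond the
  K/T/G draw distributions.
* The two-state reduction ignores continuous expression variation within
  modes; T's expression shift is parameterized by the same θ as its
  switching reduction, the simplest one-parameter coupling consistent
  with partial loss of rtTA function.
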