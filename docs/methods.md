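# Methods

## The model

One autosomal or X-linked biallelic locus in an infinite, randomly mating
population with discrete generations. Fitness acts on viability within the
brood: `w(++) = w(+Y) = 1`, `w(+m) = 1 − h·s`, `w(mm) = w(mY) = 1 − s`.
Mutation is irreversible (`+ → m`); it is applied to brood genotypes
(`++ → +m` at rate 2μ, `+m → mm` and `+Y → mY` at μ) rather than to
parental gametes, so that new mutants appear inside broods and are exposed
to sibling competition like any other brood member.

Reproductive compensation is modelled as *competitive release*: after
selection removes a fraction of a brood, the survivors' collective output
may rise up to `C`-fold, capped at the size of an all-wildtype brood:
`B = min(Z·C, 1)`. Compensation is genotype-blind — whoever survives shares
the released resources — and acts after selection. `C` is a single global
coefficient, identical for every mating type; `C = 1` switches fRC off
exactly.

The recursion tracks the six mating types explicitly, because under fRC the
fate of a genotype depends on which brood it is born into. For each type:
frequency `M_i` (squared term for like×like, doubled cross-product for
unlike pairs; plain male×female product at X-linked loci), brood outcome
(`Z_i`, `B_i`, surviving proportions `P(g)_i`), then
`f′(g) ∝ Σ_i M_i B_i P(g)_i` normalized over genotypes (per sex at X-linked
loci, where broods are 50:50 male:female at fertilization). All twelve
per-mating-type numerators are generated by one generic pipeline
(segregation → mutation → selection) and verified term-by-term against
hand-written expansions in the test suite.

The **dimorphic** variant restricts compensation to within each sex: the
male and female halves of a brood (pre-selection share 0.5 each) are
compensated independently, `B_sex = min(Z_sex·C, 0.5)`. "Full restoration"
here means restoring each sex to its own half-share; a dead male cannot be
replaced by a sister. This per-sex cap is the minimal reading of the
within-sex rule and is this module's principal modelling assumption; it
reproduces the expected grid maximum (≈ 2.8-fold, see below). At `C = 1`
the dimorphic and pooled engines coincide to machine precision (tested).

## Censuses and ω

Three frequency censuses are exposed:

* **adult** — `q̂_a = 0.5 f(+m) + f(mm)` (autosomal) or
  `f♂(mY)/3 + 2[0.5 f♀(+m) + f♀(mm)]/3` (X-linked);
* **gametic** — `q̂_g = q̂_a + (1 − q̂_a)μ`, one extra round of mutation,
  the census under which the classical closed forms
  (`q = μ/(h·s)`, `√(μ/s)`, `3μ/(2hs+s)`) hold exactly;
* **affected males** — `q̂ = f♀(+m)/2 + μ`, the classical census for
  male-lethal X-linked mutations.

The fold increase ω is, by default, the ratio of **adult** equilibria at the
given `C` versus the simulated `C = 1` baseline. The distinction matters:
solving the recursion analytically to leading order in μ gives
`q̂_a(full fRC)/q̂_a(no fRC) = 2 − h·s` exactly, whereas the gametic ratio is
`1 + (1 − h·s)²` — the fresh-mutation term μ common to both censuses
dilutes the ratio, and its relative weight `h·s/[(1−h·s)(2−h·s)]` is not
small when selection is strong. Only the adult census yields the linear
percent-increase law (intercept 100, slope −100 against `h·s`); measured on
the full C = 2 grid the fit is 99.5 / −98.8 (adult) versus 93 / −133
(gametic). Grid records carry both censuses. The baseline is always the
simulated `C = 1` equilibrium, never a closed form, which keeps ω
internally consistent at X-linked loci where the semidominant closed form
is itself approximate (see below).

## Solver

Fixed-point iteration of the full genotype-frequency state. The per-type
brood outcomes depend only on the parameters, so they are computed once per
solve; one generation is then a handful of multiply-adds, and full grids of
hundreds of cells run in seconds.

* **Starts.** Hardy–Weinberg embeddings of q₀ = 1e−9 and 1 − 1e−9 (males at
  q₀ directly). Both must converge to the same value (relative agreement
  within 10× the tolerance) or the result is flagged unconverged. Any
  interior start reaches the same fixed point (tested).
* **Stopping.** The per-generation relative change of the census must fall
  below `rel_tol = 1e−7` *and* a geometric-tail estimate of the remaining
  distance to the limit — `|Δ_t|·λ/(1−λ)` with `λ = |Δ_t|/|Δ_{t−1}|` — must
  be below `rel_tol` as well. The tail condition is essential for two
  reasons: the consecutive-change criterion alone leaves a stopping error
  of order `rel_tol/(1−λ)`, which for weakly contracting cases (small
  `h·s`, or recessive lethals where contraction is ≈ `1 − 2sq̂`) is orders
  of magnitude larger than `rel_tol`; and the all-mutant boundary `q = 1`
  is an exact unstable fixed point of the recursion (no back mutation), so
  the high-start trajectory escapes it slowly and would otherwise satisfy
  the naive criterion while far from equilibrium. While changes grow
  (`λ ≥ 1`) the solver never stops.
* **Degenerate cases.** Lethal all-mutant broods (`Z = 0`, only at `s = 1`)
  contribute nothing; a state in which every brood is extinct raises. The
  iteration cap (10⁷) flags rather than raises; weak-selection corners need
  ~10⁴–10⁵ iterations, everything else far fewer. `s = 0` with `C > 1` is
  accepted with a warning: with no selection there is no balance and q
  drifts to 1 under mutation pressure.

An optional cross-check for autosomal loci roots the one-dimensional map
`q ↦ q̂_a(next_generation(HW(q))) − q` with Brent's method; because the true
equilibrium state is not exactly Hardy–Weinberg under selection it agrees
with the iterated solution only approximately (within 1% at semidominant
parameters; tested as a sanity check, not used as the solver).

## Parameters and defaults

| parameter | meaning | default / range |
|---|---|---|
| h | dominance (heterozygote expresses `h·s`) | ∈ [0, 1] |
| s | selection against `mm` / `mY` | ∈ [0, 1] |
| μ | one-way mutation rate per allele per generation | 1e−5 grids, 1e−7 validation; capped at 0.01 so that mutants stay predominantly heterozygous |
| C | competitive release coefficient | ≥ 1; 1 = no fRC, 100 = effectively full fRC |
| rel_tol | convergence tolerance | 1e−7 |
| grid | h = 0.05…0.95, s = 0.05…0.9, step 0.05; C ∈ {1.1, 1.2, 1.5, 2} | — |

ω is invariant to μ across 1e−5…1e−9 within 1% (tested), so grid sweeps use
μ = 1e−5 for speed.

## Analytic reference results

With fRC absent the engines recover the classical equilibria to better than
1%: `q = μ/(h·s)` (autosomal semidominant), `q = √(μ/s)` (autosomal
recessive), `q = 3μ` (X-linked lethal, affected-male census); with full
compensation, `√(3μ/2)` (autosomal lethal) and `4μ` (X-linked lethal). The
recessive forms are sometimes quoted without the radical; the square-root
versions are the ones consistent with the 1.22-fold lethal result
(√(3/2) = 1.2247) and are canonical here, with the radical-free renderings
available behind `as_printed=True` for transparency.

The X-linked *semidominant* no-fRC closed form `q = 3μ/(2hs+s)` is known to
embed algebraic approximations that the full recursion does not share; the
validation suite reports its deviation (≈ 0.6% at h = 0.5, s = 0.2,
μ = 1e−7) without asserting it.

The breakdown threshold follows from the cap: compensation can replace at
most a fraction `F = 1 − 1/C` of a brood; with rare mutants concentrated in
`++ × +m` broods, mortality there is `0.5·h·s`, so linearity of the percent
increase fails for `h·s > 2F`. Beyond it the simulated ω falls one-sidedly
below `2 − h·s` (tested). At the opposite extreme the `2 − h·s` law also
degrades: for `h·s ≲ 0.05` the equilibrium is high enough that homozygote
selection is no longer negligible (at `h·s = 0.0025`, μ = 1e−5, ω is ≈ 5%
below the linear prediction). The 1% engine-versus-`2 − h·s` agreement is
therefore asserted on `h·s ≥ 0.05`, matching the law's stated range of
validity.

## Design choices

* Broods are built generically and tested against the twelve hand-written
  per-type numerator sets, rather than hard-coding twelve equation blocks.
* The compensation cap is exactly 1 (the all-wildtype reference brood), not
  the marginally smaller `Z₁` of the `++ × ++` mating under mutation.
* The canonical solver is full state iteration for all three locus modes
  (the 1-D root-find is a cross-check only), so autosomal and X-linked
  results come from one code path.
* Convergence is monitored on the population allele frequency; the
  affected-male census is evaluated on the converged state.

## Limitations

* Deterministic, infinite-population dynamics: no drift, no finite-brood
  stochasticity, no overlapping generations, no inbreeding.
* Compensation is linear in `Z` with a hard cap; no genotype-dependent or
  saturating compensation functions.
* Fitness costs are assumed to act entirely within the life-cycle stage
  where compensation operates; mutations also penalized after brood
  dissolution would experience weaker inflation than computed here.
* One-way mutation only; the model has no interior balance when `s = 0`.
* The dimorphic engine's per-sex half-share cap is a modelling choice for
  the strict within-sex rule; other readings (e.g. caps tied to realized
  sex ratios) would change the surface quantitatively.
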