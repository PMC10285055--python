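# Methods

## Model and scope

`herdblup` evaluates first-lactation dairy traits (MY305 kg, AFC months, CI1
months) with a multi-trait animal model: fixed herd, fixed herd-year-season
(HYS) contemporary group, a linear calving-age covariate for traits where age
at calving is not itself the trait (so not for AFC), and a random additive
genetic animal effect with covariance `A ⊗ G0`, where `A` is the pedigree
numerator relationship matrix over *all* pedigree animals — parents without
records receive equations through `A⁻¹` and obtain EBVs from their relatives.
The pooled (multi-country) model is the same model on merged data plus a
country fixed effect.  Genetic groups, maternal effects, repeated lactations,
genomic relationships and country-specific genetic correlations (MACE-style
multiple-trait-across-country models) are out of scope.

## Pedigree machinery

Pedigrees are validated (unique ids, acyclic parentage, sexed parent roles) and
ordered parents-before-offspring with Kahn's algorithm.  Inbreeding
coefficients use the Meuwissen–Luo algorithm (per-animal accumulation of the
`A = LDL'` decomposition).  `A⁻¹` is assembled directly by Henderson's rules
with Mendelian-sampling variances `d_i = 0.5 − 0.25(F_s + F_d)` (0.75 − 0.25F
for one known parent, 1 for none); the inbreeding adjustment can be switched
off to mimic evaluations that ignore F.  Unknown parents are a single
unselected base population.  The dense tabular-method `A` is retained as a
small-pedigree oracle and refuses pedigrees above a configurable size.

## Mixed-model equations

Records with partially missing traits are handled exactly: each record's
residual precision is the inverse of the `R0` submatrix for its observed-trait
pattern, scattered back to trait coordinates.  The coefficient matrix is
`X'R⁻¹X` / `X'R⁻¹Z` / `Z'R⁻¹Z + A⁻¹ ⊗ G0⁻¹` in per-trait blocks; the genetic
part adds `G0⁻¹[i,j]·A⁻¹` to each animal block pair.

**Rank deficiency.** HYS is nested in herd and herd in country, so the fixed
part is structurally rank-deficient (the column space of herd+HYS+country
equals the HYS column space).  A deterministic nested constraint set pins to
zero: the last observed HYS level within every herd; for pooled models the last
observed country level and the last observed herd within every other country;
every level unobserved for a trait; and the age slope when age does not vary
within any observed HYS cell (then the slope is confounded with the
contemporary groups — this occurs in tiny datasets with single-record cells).
One can show this removes exactly the structural dependencies: each dropped HYS
column has disjoint record support inside its herd, so no nonzero combination
of the kept columns vanishes.  EBVs, PEVs and estimable fixed contrasts are
invariant to this constraint choice; tests verify them against an
observation-space GLS oracle that uses a pseudoinverse instead.

**Age covariate.** Centered at the dataset mean.  In pooled models the slope is
nested within country: a single shared slope would transmit information between
countries even with zero genetic links, breaking the requirement that two
unconnected herdbooks evaluated jointly reproduce their within-country EBVs
exactly; with no shared sires the within-country slopes are separately
estimable, so nesting sacrifices nothing.

**Solvers.** Sparse LU (SuperLU) with symmetric-mode minimum-degree ordering
and no pivoting — the constrained system is symmetric positive definite, and
this ordering reduces fill by ~30× over the default — or diagonally
preconditioned conjugate gradients.  Both verify the relative residual
(default 1e-10, hard ceiling 1e-8).  Runs are single-threaded deterministic.

**Reliabilities.** PEV is the exact diagonal of the inverse coefficient matrix
at the animal×trait equations, obtained by unit-vector solves against the
cached factorization (chunked; a subset of animals, e.g. the sire list, can be
requested at herdbook scale).  `r² = 1 − PEV/((1+F_i)σ²_a)`: the `(1+F_i)`
factor is the inbred animal's own genetic variance — without it PEV can
legitimately exceed `σ²_a` and reliabilities would be clipped wrongly.

## Variance components (EM-REML)

Evaluation refuses to run without `G0`/`R0` — there are no silent variance
defaults.  `em_reml` estimates them from complete records with EM-REML updates
built from animal-effect solutions, PEV traces and fitted residuals.  Two
numerical devices keep the E-step exact but affordable: (i) all required
entries of `C⁻¹` live in record-touched columns — the PEV trace over the `A⁻¹`
pattern is rewritten through the MME block identity
`G0⁻¹·T = q·I − (record-gathered terms)`, `T[i,j] = tr(A⁻¹C^{aa}_{ij})` — and
are gathered from chunked unit-vector solves; (ii) the EM map is wrapped in
guarded acceleration (a parameter-expansion rescaling of the genetic update
plus SQUAREM-style squared extrapolation), accepted only when the restricted-
likelihood proxy does not decrease, so the accepted sequence stays monotone and
has the same fixed points as plain EM.  `accelerate=False` gives textbook EM;
the monotonicity property is tested against a directly evaluated
observation-space restricted likelihood on dense toys.  Plain EM needs hundreds
of iterations on low-heritability traits; the accelerated driver typically
converges in 10–25 cycles.  Non-positive-definite updates are ridge-repaired
with a warning.

## Selection response

Selection intensity uses the infinite-population truncated-normal form
`i = φ(z)/p`, `p = k/n`, `z` the upper-p quantile (i = 0 at k = n).  This
reproduces the published within-country and pooled table values at two
decimals with one documented exception: the Kenyan top-5 value prints as 2.08
where the formula gives 2.07 (source unknown — possibly a finite-sample
correction or rounding in the original tables); it is excluded from the checks.
The pooled candidate count defaults to the *sum* of the per-country sire lists
(shared sires counted once per list, 103 + 505 = 608 at published scale),
which is what the published pooled intensities imply; a `dedup` option uses
the union instead.  The accuracy ρ entering `R = i·ρ·σ_g` defaults to the mean
accuracy over all candidate sires (`mean_all`; `mean_top_k` is available —
which convention the original analysis used is not stated).  `%PGG` is
`100·PGG_source/PGG_multi` per trait×k; gains tables round only at the output
layer (2 dp columns plus full-precision companions).  Only the sire-selection
pathway is modeled; reports carry a fixed annotation that this is roughly two
thirds of the total four-pathway progress.

## Study orchestration

Within-country fits use each country's own pedigree and records; the pooled fit
is an independent solve on the merged data (nothing is transferred between
fits).  Animal ids are namespaced `country:id` except sires on the declared
shared-sire list, which are the only cross-country links; herds and HYS groups
are country-nested (a herd exists in exactly one country).  The connectedness
summary counts shared sires with recorded daughters in both countries and
flags shared sires present in both pedigrees but with daughters in only one as
pedigree links only.  Every run writes a manifest with the config digest, seed,
input checksums and the decisions in effect (season rule, pooled-count rule, ρ
mode); reruns with the same config and seed are byte-identical.

## Synthetic herdbooks

The simulator emulates the data structure the model assumes: per country, a
founder generation of AI sires and dams and one recorded daughter generation.
Founder true breeding values are drawn from `G0`; daughters get parent average
plus Mendelian sampling `N(0, ½(1 − (F_s+F_d)/2)G0)`.  Phenotypes add country
mean, herd effects, HYS effects, an age slope (not for AFC) and residuals from
`R0` with per-trait missingness.  Shared sires are identical animals in both
countries; dams never cross countries, so connectedness is sire-only.  Sire
usage is skewed (geometric-like daughter counts with a randomized popularity
order and a one-daughter minimum, so configured sire counts are exactly the
counts of sires *with* recorded daughters); a uniform option exists.

Default truth parameters are declared assumptions, not estimates from any real
herdbook: genetic SDs 528 kg (MY305), 61.19 (AFC), 20.29 (CI1) months;
heritabilities 0.25 / 0.15 / 0.08; genetic correlations −0.2 (MY305–AFC), 0.2
(MY305–CI1), 0.1 (AFC–CI1); residual correlations 0.1; herd and HYS effect SDs
300/150 kg and 6/3, 3/1.5 months; calving age ~ N(30, 3²) months truncated at
20; AFC/CI1 missing at 15%/25%, MY305 complete.  Presets: `paper_scale_config`
(2,333 and 25,208 recorded cows, 103 and 505 sires, 40 shared, Kenyan years
1979–2014, South African 1997–2014, 25/150 herds) and `desk_scale_config`
(300/1,200 cows, 20/60 sires, 10 shared, 6 years) for the test bed.

What the simulator does **not** emulate: selection over time (no drift or
truncation across generations), genotype-by-environment differences between
countries, heterogeneous within-country variances, seasonal calving patterns,
or non-random sire-herd assignment.  Passing tests therefore demonstrate
correctness of the machinery and the *direction* of the pooling benefit under
the stated assumptions — not the magnitudes any particular real herdbook would
show.

## Problem sizes in the test suite

Simulation properties run at sizes chosen to exercise the full pipeline while
keeping the suite quick: the pooling-benefit direction uses 20 replicates of a
200/800-cow two-country study with 8 shared sires; EM-REML recovery uses 3,000
complete records from 60 sires (per-trait single-trait fits, recovery within
30% of truth); EBV–TBV correlation checks use 10 replicates at 60 sires /
3,000 cows (agreement with mean reported accuracy within ±0.07); the
full-published-size smoke test simulates 2,333 + 25,208 records with 40 shared
sires and solves the pooled system (~145k equations) with reliabilities for
the shared sires.

## Known limitations

* EM-REML uses complete records only (the evaluation itself handles missing
  traits exactly) and is a desk-scale tool; very large multi-trait REML runs
  would need a sparser E-step than the record-column solves used here.
* Fixed-effect *estimates* are reported under the package's constraint
  convention; only estimable contrasts are comparable across software.
* The infinite-population intensity formula ignores finite-sample order-
  statistic bias (the Monte-Carlo check bounds the discrepancy at ~0.05 for
  n ≥ 500; it is larger for very small candidate lists).
* With k ≥ n candidates the intensity is zero and %PGG is undefined for a zero
  multi-country baseline; gain tables emit NaN for such degenerate scenarios.
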