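# Methods

## Model

A pedigree is a directed acyclic graph of individuals with sire/dam links,
sex, birth year, herdbook breed code and an estimated breeding value (EBV).
Unknown-parent slots of non-founders are filled with phantom founders so
every individual is either parentless or has two parents; a phantom inherits
its offspring's birth year shifted back by a configurable generation interval
(default 0, so the origin rule is applied at the offspring's own year — the
conservative reading when no parental age information exists).

**Origin classification.** Founders are native when their breed code belongs
to the native breed, or when the breed is unknown and they were born before a
cutoff year (default 1970, the point after which unrecorded ancestry in
European herdbooks overwhelmingly reflects crossbreeding rather than missing
paperwork).  All other founders are migrants.  Migrant contribution then
propagates as the parental average, MC(i) = (MC(s) + MC(d))/2, i.e. the
expected migrant fraction of the genome under Mendelian transmission.
Candidate eligibility uses the herdbook breed code, *not* MC = 0: registered
purebreds of an introgressed breed typically carry substantial MC.

**Kinships.** All pairwise probabilities refer to one allele drawn uniformly
from each of two individuals, with replacement on the diagonal, so
f(i,i) = (1 + F_i)/2 and c'fc is exactly the offspring mean kinship when an
individual can be "selfed by sampling".  Four matrices are computed by a
single tabular-method pass over the topologically ordered pedigree:

| matrix | event | founder base case | diagonal weight |
|---|---|---|---|
| fA | IBD | off-diag 0, diag 1/2 | 1 |
| fN | both alleles native | row n_i·(1−MC_j), diag n_i | n_i |
| fM | both alleles migrant | row m_i·MC_j, diag m_i | m_i |
| Knat | IBD and native | off-diag 0, diag n_i/2 | n_i |

with n_i = 1 − MC_i, m_i = MC_i, and the shared recursion
f(i,j) = (f(s_i,j) + f(d_i,j))/2, f(i,i) = (w_i + f(s_i,d_i))/2.  The fN/fM
founder rows factorize because a founder's allele origin is deterministic and
independent of every non-descendant.  These constructions reduce to the
tabular method when the origin indicator is constant and are verified
*exactly* against exhaustive transmission enumeration (below); that oracle —
not any published recursion — is the semantic arbiter of this package,
including the convention that a founder's self-pair at native alleles counts
the with-replacement same-allele draw (fN(i,i) = n_i for a non-inbred
founder).

Because IBD alleles are copies of one founder allele and therefore share one
origin, the unions defining the conservation kinships are disjoint sums:
fB = Knat + (1 − fN) (IBD or ≥1 migrant allele) and fC = Knat + fM (IBD or
both migrant).  Entrywise fA ≤ fC ≤ fB, and fB − fC equals the
exactly-one-migrant probability 1 − fN − fM.  The kinship at native alleles
for a contribution vector c is fD(c) = 1 − (1 − c'fB c)/(c'fN c), which
equals c'Knat c / c'fN c because contributions sum to one; it is guarded by
ε = 1e-8 on the denominator (fD is undefined for fully migrant offspring).

Matrices are computed over the ancestor closure of the candidate set (memory
O(n²) in the closure size) and then subset.

## Oracles

`enumerate_transmissions` sums over all 2^T equiprobable inheritance patterns
(T = meioses, bounded at 24) and the four equiprobable allele draws per pair
in exact rational arithmetic; since the recursion outputs are dyadic
rationals, recursion-vs-enumeration tests assert bit-exact equality.
`gene_drop` is a seeded, chunk-vectorized Monte-Carlo dropper whose estimates
carry binomial standard errors √(p(1−p)/R); the estimator for a pair is
symmetrized over the two draw orders.  Both oracles also recover MC as the
migrant-allele frequency, tying the three computations of MC (closed form,
recursion, simulation) together.

## Optimization

Structural constraints: c ≥ 0, male and female contributions each sum to
0.5, all dams equal (females are eliminated analytically — fixed at
0.5/n_dams — so the decision variables are the sire contributions, each
bounded by 0.5; an `optimize_both_sexes` option keeps both sexes as
variables instead).  Every quadratic form is restated in the free variables
with constants absorbed.

Bounds: c'fA c ≤ ub.fA, c'fB c ≤ ub.fB, c'fC c ≤ ub.fC, fD(c) ≤ ub.fD,
c'MC ≤ ub.MC, c'EBV ≥ lb.EBV.  The fD bound is rewritten as the quadratic
c'fB c + (1 − ub.fD)·c'fN c ≤ 1, equivalent for contribution vectors summing
to one; with ub.fD ≤ 1 this combination of PSD matrices is PSD, hence
convex (an indefinite instance would be flagged and routed through the
convex–concave path, but does not arise for valid bounds).  Degenerate bound
sets are reported `infeasible` with the violated bounds named, never clipped.

Convex scenarios (quadratic or linear objective, convex bounds) are solved
by SLSQP with analytic gradients from multiple starts (uniform plus seeded
Dirichlet points), with a trust-constr fallback; solutions are checked
post-hoc against all constraints (feasibility tolerance 1e-6 on bounds, 1e-8
on sex sums) and validated in the tests against dense simplex grid searches.

The min-fD objective is a ratio of quadratics and genuinely non-convex.  It
is minimized by Dinkelbach's iteration: solve
min c'Knat c − q·(c'fN c) subject to the scenario constraints, update
q ← fD(c), repeat until |Δq| < tol.  The −q·c'fN c term is concave, so each
subproblem linearizes it around the current iterate (convex–concave
procedure), making the subproblem convex.  Multi-start (uniform, the min-fA
solution under the same bounds, and seeded random points; 5 by default)
mitigates local optima; results carry status `local` and satisfy the
Dinkelbach fixed-point identity c'Knat c − fD·c'fN c = 0 at convergence.

Thresholds: ΔF = 1/(2Ne); ub.fA = f̄A + (1 − f̄A)·ΔF where f̄A is the mean
over distinct candidate pairs (diagonal excluded; configurable); every other
bound is λ·(single-constraint optimum under the fA bound) + (1 − λ)·REF,
with λ = 0.3 as the default policy weight.  The truncation-selection
baseline selects the smallest sire number with
1/Ne ≤ 1/(4·Nsire) + 1/(4·Ndam), ties at the EBV cutoff breaking by
ascending id for determinism.  A sire counts as selected when its
contribution is ≥ 0.00025; the SD of sire contributions includes zeros and
uses the population convention (ddof = 0), matching the divisor-n convention
chosen for EBV normalization.

## Synthetic populations

The generator emulates an introgressed herdbook breed: a native founder
cohort (half with the herdbook code, half with unknown breed but pre-cutoff
birth years, exercising both branches of the classification rule), five
discrete 10-year generations, and migrant founder sires injected into the
1965/1975/1985/1995 offspring cohorts at influx fractions 0.45/0.45/0.45/0.30
— chosen so candidate mean MC lands near 0.6, the level reported for heavily
introgressed dual-purpose cattle.  The final cohort (born 2005–2006) is sired
round-robin by 200 sires of the candidate generation, which therefore become
the male selection candidates; 1000 dams are sampled from the 1300 candidate
females.  EBV = α·MC + trend·generation + N(0, σ²) with trend 0 by default
and α calibrated on the candidate generation so the realized EBV–MC
correlation hits the target 0.33, the positive association reported where
introgression was driven by selection for the trait.  Family structure uses
40 sires per internal generation (half-sib families); generation sizes (250
internal, 1520 candidate cohort, 600 progeny) keep the ancestor closure near
3000 individuals so the full analysis runs at desk scale.

What the generator does *not* emulate: overlapping generations (a
birth-year-window dam sampler is exposed instead), realistic trait
architecture or linkage (gene dropping is single-locus), pedigree errors,
and migrants with hidden purebred ancestry.  Passing tests therefore
demonstrate correctness of the probability machinery and the optimizer, and
the *direction* of the selection responses — not calibrated magnitudes for
any real breed.

## Numerical choices and limitations

* All recursion arithmetic is dyadic; oracle tests assert exact equality.
* Kinship PSD checks use smallest eigenvalue ≥ −1e-8.
* Solver: SLSQP ftol 1e-12, feasibility 1e-6 (bounds) / 1e-8 (sex sums);
  grid-search comparisons at 1e-3 simplex resolution.
* Slack flags in reports use 10× the feasibility tolerance to separate
  numerically grazing a limit from genuine slack; display rounds to 3
  decimals, machine output keeps full precision.
* min-fD reports the best *local* solution found; on the test problems it
  matches global grid search, but no global certificate exists in general.
* Mean-kinship aggregation (`mean_candidate_kinship`) excludes the diagonal
  by default; including it raises f̄A slightly and thus the fA ceiling.
* Native effective population size estimation and marker-based (genomic)
  kinships/MC are out of scope.
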