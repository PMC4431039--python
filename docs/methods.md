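# Methods

## Pedigree model

A genealogy is a finite DAG over individuals identified by positive
integers; each individual has at most one father (male) and one mother
(female), with 0 encoding an unknown parent. **Founders** have both parents
unknown, **half-founders** exactly one. **Probands** default to the
childless individuals of the loaded table — the natural choice for an
ascending genealogy reconstructed from sampled subjects — and every
operation that takes a proband set accepts an explicit override. Generation
indices count back in time from the probands (proband = 0); because
relatives marry, one individual generally occupies a *multiset* of
generation indices, one per (proband, ascending path) placement.

Validation enforces unique positive ids, sexes consistent with parental
roles (an id used as a father must be male and cannot also appear as a
mother), acyclicity (one offending cycle is reported), and resolvable parent
references. By default a parent id referenced without a row of its own is
synthesized as a founder of the appropriate sex (`auto_complete=True`),
since real database extracts routinely omit the terminal ancestors' own
rows. Internal order is a founders-first topological sort with ties broken
by ascending id, making every computation deterministic under row
permutation; ids are otherwise opaque (no assumption that parents have
smaller ids than children).

`branch(probands, ancestors)` keeps the individuals on ascending paths from
the requested probands up to and through the requested ancestors. When two
requested ancestors are unrelated, each contributes its own ascending
closure only where it lies above a requested proband; individuals "between"
them in other branches are dropped. This choice (one of several defensible
readings of sub-genealogy extraction) keeps the result closed under the
parent relation within the retained set.

## Generation occurrences without path enumeration

All per-generation quantities derive from one dynamic programme on the
child → parent relation evaluated in reverse topological order:
`occ(x)[g] = [x is a proband]·[g = 0] + Σ_children c occ(c)[g−1]`.
This counts, for every individual, the number of ascending paths of each
length from the probands — exactly the multiplicity with which the
individual fills ancestor slots — at cost linear in edges × generations,
where explicit path enumeration is exponential on collapsed genealogies.
Enumeration appears only in the test oracles.

From the per-proband programme: completeness C_g = A_g/2^g (A_g occurrences
with multiplicity), implex I_g = distinct_g/2^g, depth = max generation
index + 1, and mean genealogical depth D = Σ_g g·F_g/T_g with F_g the
*occurrences* of founders at generation g. Counting occurrences rather than
distinct founders is what makes the per-generation form and the
per-founder-occurrence form Σ N_f (1/2)^{N_f} the same expectation; both are
checked against each other to 1e-12 in the tests. The founder weights
(1/2)^{N_f} sum to 1 exactly when every lineage terminates at a founder;
half-founders leave the sum short, and D is then the expectation over the
terminating lineages only. The variance Σ_g g²F_g/T_g − D² carries the same
caveat.

Corpus-level completeness is reported as the mean of per-proband profiles
(algebraically identical to pooling occurrence counts); implex additionally
offers a pooled mode (ancestors distinct across the whole proband set),
since for implex the two readings genuinely differ.

## Kinship and inbreeding

Kinship uses the classical recursion with founders pairwise unrelated and
non-inbred: φ(i,i) = (1+f_i)/2 with f_i = φ(father_i, mother_i), and for
i ≠ j, recursing on whichever of the two comes later in topological order,
φ(i,j) = ½(φ(father_i, j) + φ(mother_i, j)); unknown parents contribute 0
(an unknown parent inside a loop acts as a unique unrelated founder).
Values are dyadic rationals scaled by (1+f) factors, computed in double
precision; the test oracle re-derives them in exact rational arithmetic from
the path-sum formula (sum over common ancestors and *disjoint* path pairs of
(1+f_a)(1/2)^{g_ai+g_aj+1}) and the two agree to 1e-12 on random collapsed
pedigrees. Evaluation is iterative (explicit work stack), so genealogy depth
is not limited by Python's recursion limit.

Generation truncation ("kinship at the first d generations") removes the
parent links of every individual whose *minimal* generation relative to the
subject set is ≥ d, so no ancestor beyond d meioses is reachable; first
cousins truncated at d = 1 are unrelated. Truncation is monotone: φ at
depth d ≤ φ at depth d+1 ≤ untruncated φ.

The pairwise matrix can be computed by several threads over row blocks
sharing one memo table. The recursion is a pure function of the pedigree, so
a racy duplicate evaluation writes the same value; results are bit-identical
for any thread count.

## Genetic contribution

GC(s,a) = [s=a] + w_pat·GC(father_s, a) + w_mat·GC(mother_s, a) is evaluated
by one downward sweep per ancestor in topological order (cost linear in
individuals per ancestor). The default weights (½, ½) encode autosomal
inheritance; they are user-settable per parent sex for other inheritance
patterns. For a proband whose lineages all terminate at founders the founder
contributions sum to 1. The cumulative-contribution curve sorts ancestors by
decreasing summed contribution to a proband group (ties by ascending id) and
reports the minimal number of ancestors reaching a requested share of the
gene pool.

## Gene dropping

Per replicate, every individual below the seeded ancestors receives one
gamete per parent in topological order. A gamete carries the tracked allele
with probability min(t·c, 1), where c ∈ {0,1,2} is the parent's copy count
and t the per-copy transmission probability for the (parent sex, child sex)
pair. The default t = ½ is Mendelian: a heterozygous parent transmits with
probability ½ and a homozygous parent with certainty. The min(·,1) form is
this package's extension of custom t to two-copy parents; it preserves
per-gamete expectation E[gamete] = t·E[c] for t ≤ ½.

**Segments.** Segment dropping multiplies each meiosis' transmission
probability by (1 − r_sex), with r taken from the male map for paternal and
the female map for maternal meioses. When only genetic lengths are supplied,
r = 1 − exp(−L/100) (Haldane's map function, L in cM — a Poisson crossover
model with at least one crossover on the segment counting as breakage); an
explicitly supplied r always overrides. Transmission choice and breakage are
treated as independent, giving the ½·(1−r) per-meiosis factorisation. A
segment not transmitted intact is lost to that line; the partial length of a
recombined segment is not modelled (status is binary).

**Viability.** With homozygote survival s < 1, a two-copy individual dies
with probability 1 − s and its two gametes are redrawn until a surviving
genotype results — i.e. the individual's genotype distribution is
conditioned on survival, leaving unrelated lineages and the replicate count
unbiased. A replicate-level rejection mode (`reject_replicates=True`)
discards whole replicates instead, for sensitivity analyses. If survival is
impossible (e.g. two obligate-transmitting parents and s = 0) the engine
raises rather than looping.

**RNG.** Replicates are simulated in fixed chunks of 65,536 driven by the
counter-based Philox generator keyed on (seed, chunk index). Chunking is
independent of the worker count, so one seed gives bit-identical results at
any thread count, and estimates with the same seed are coupled across
parameter settings (used by the monotonicity tests: a longer segment can
only lose replicates).

**IBD sharing.** Per-ancestor sharing seeds one copy of a distinct tracked
allele in that ancestor and reports the fraction of replicates in which both
subjects carry a descendant copy, with SE = √(p(1−p)/n). Common ancestors of
a pair are classified as Founder, MRCA, MRCA-Founder or In between.

For an MRCA the two subjects' descent paths share no individual other than
the ancestor itself, so their carrier states are independent, and when each
subject additionally descends from the MRCA through at most one parent
("single-sided" descent, so it can never carry two copies of one seeded
allele) the sharing probability equals the product of the genetic
contributions, P = GC(i,a)·GC(j,a). Both conditions matter, and exact
enumeration in the tests demonstrates each deviation: a subject whose two
parents both descend from the MRCA has P(carry) = GC − P(2 copies) < GC,
pulling sharing *below* the product; a non-MRCA common ancestor is reached
through overlapping paths whose shared segregation positively correlates the
two subjects, pushing sharing *above* the product. Intermediate collapse is
harmless — a homozygous intermediate transmits with certainty, exactly
preserving the per-gamete expectation.

## Synthetic genealogies

The generator emulates the *shape* of founder-population corpora: discrete
non-overlapping generations, founders on top, uniform random pairing of the
previous generation's males and females (optionally rejecting full-sib
couples), per-couple offspring counts Poisson(λ) truncated at a maximum
(default λ = 2.2, max 8 — a gently growing population), equiprobable sex,
and independent erasure of parental links with a set probability to emulate
incomplete records. The output carries a generation annotation so the
youngest layer can serve as the sampled proband set, and ascending
extraction from those probands mimics a reconstructed corpus.

It deliberately does **not** model overlapping generations, remarriage
dynamics, migration waves, regional sub-structure or demographic growth
curves, so passing tests show algorithmic correctness on realistically
*collapsed and incomplete* pedigrees — not demographic realism for any
particular population. Statistical properties of the generator itself
(offspring moments, reproducibility, validity of every emitted table) are
tested separately.

## Numerical and engineering choices

* All integer-valued combinatorics (occurrence counts, path counts) use
  exact Python integers; probabilities and coefficients use doubles, with
  exact-rational test oracles where identities are asserted (1e-12).
* Matrices are written as TSV with 10 significant digits so values such as
  0.0044 round-trip unambiguously.
* Monte-Carlo unit checks use α = 1e-4 z-bounds per comparison to keep the
  family-wise false-alarm rate negligible across the suite's many
  deterministic-seed comparisons; engine calibration was verified unbiased
  across independent seeds.
* Problem sizes in the test suite and acceptance script (pedigrees of tens
  to hundreds of individuals, 10^5–2·10^5 replicates per estimate) are
  chosen so the full run completes in seconds while keeping Monte-Carlo
  standard errors small relative to the asserted effects.

## Known limitations

* Kinship of very large subject sets is O(n² · pedigree work) and
  memory-bound on the memo table; batching subjects is the intended usage.
* The segment model tracks intact/lost status only — no crossover positions,
  no partial transmitted lengths, no multi-locus linkage.
* Half-founders make the founder-termination weights sum to < 1; D is then a
  conditional expectation (documented above) rather than a full-lineage
  mean.
* The Quebec reference-corpus reproduction test requires that dataset to be
  exported locally (it is not redistributable here); without it that single
  check reports failure while all fixture-based checks remain exact.
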