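# Methods

## Input model and polarization

The unit of analysis is a triplet alignment: two ingroup sequences from one
family and an outgroup, aligned per locus, with loci labeled CDS or NC
(intergenic). Locus filters: CDS alignments with more than 30 gap
characters in total (summed over the three rows) are excluded, as are NC
alignments shorter than 70 columns; the boundary values (30 gaps, 70
columns) are kept. "Total gaps" is read as gap *characters*, not gap
openings — the simplest reading, and the choice only shifts which loci
pass, never the downstream arithmetic.

Each alignment column is polarized by outgroup parsimony: with ingroup
states `x, y` and outgroup `z`, a column yields a conserved observation
when `x = y = z`, and a substitution (ancestral = the state `z` matches,
derived = the other) when `x ≠ y` and `z` equals exactly one of them. All
other patterns are discarded: three distinct states are not assignable to a
single ingroup branch, and columns where the ingroups agree against the
outgroup imply a change on the outgroup lineage — counting them as
conserved would contaminate the matrix diagonal, so they are dropped rather
than counted.

A site's tetranucleotide context is taken from the flanking bases only
when those four positions are gap-free, unambiguous, **and identical across
all three sequences**; a changing flank would make the context assignment
of the substitution ill-defined. For FFD sites the context is read within
the coding frame: positions 1–2 of the codon (which must be conserved and
form one of the 8 fourfold-degenerate prefixes CT, GT, TC, CC, AC, GC, CG,
GG) and positions 1–2 of the *next* codon, giving 8 × 16 = 128 possible FFD
contexts; the last codon of a CDS has no downstream context and is skipped,
as is any codon containing a gap or ambiguity in any sequence. NC columns
within two positions of an alignment end are skipped for lack of context.
Ambiguity codes never fail a locus; they only exclude the affected columns.

## Count matrices and strand folding

Counts accumulate into one 4×4 matrix per (site class, context), rows =
ancestral, columns = derived, order A, C, G, T; every enumerable context is
materialized (as all-zero when unobserved) so reports can distinguish
absent data from absent enumeration. Assuming strand symmetry, the matrix
for context `c` and the complement-transform of the matrix for its reverse
complement (`M'[Ā][D̄] = M[A][D]`, a 180° rotation under this base order)
estimate the same process and are summed into the lexicographically smaller
of the pair. 256 NC contexts fold to 136 canonical classes (120 pairs + 16
self-complementary). Self-complementary contexts receive their own
complement transform on top of themselves: their counts double, which
leaves every rate, ratio, and stationary vector unchanged and keeps the
folded matrix exactly complement-symmetric; the convention is recorded in
the run summary. FFD contexts are folded by the same rule even though the
canonical representative may not itself carry an FFD prefix (the reverse
complement of a coding-frame context is generally not a coding-frame
context); the 128 FFD contexts fold to 100 canonical classes.

## Per-context statistics

* Rates are maximum-likelihood multinomial fractions: row rate =
  off-diagonal row sum / row total (missing, not zero, for empty rows);
  overall rate = off-diagonal total / matrix total. Transition cells are
  A↔G and C↔T; the remaining eight off-diagonal cells are transversions.
  The identities `ts + tv = overall` and `overall = count-weighted mean of
  row rates` are exact in rational arithmetic; floats agree to ≲1 ulp.
* The AT index (ATI) summarizes context A+T content with inner flanks
  weighted 3 and outer flanks 2 (range 0–10); contexts with ATI > 9 are
  classed A+T-rich and ATI < 5 G+C-rich. The weights are one monotone
  choice consistent with those two thresholds and are exposed as options.
* The stationary vector solves `π (P − I) = 0, Σπ = 1` by a dense linear
  solve, where `P` is the row-normalized count matrix including the
  diagonal. A context is flagged (π missing) when any row total is zero or
  the chain is not strongly connected (checked via strongly connected
  components of the positive-entry digraph); such contexts are excluded
  from equilibrium analyses. Reported vectors satisfy `π·P = π` to 1e-9
  (observed residuals are at machine precision).
* Bootstrap: each resample keeps every row's diagonal and off-diagonal
  total and redraws the row's substitutions from a multinomial with the
  observed off-diagonal proportions; default 1000 resamples. Stationary
  vectors for all resamples are obtained by one batched linear solve;
  resamples whose chain degenerates are dropped. Random streams are derived
  from `(master seed, site class, packed context)` so results are
  independent of iteration order.
* CpG tables pool folded matrices by the immediate neighbor only (3'
  neighbor for changes from C, 5' neighbor for changes from G — the two
  strand readings of the same dinucleotide); outer context bases are
  marginalized by summation. The focal change is the CpG-type transition;
  the comparison column pools the other two changes from that base. The
  odds ratio is `(a/b)/(c/d)`, flagged undefined if `b`, `c` or `d` is 0.
* The reporting filter (≥25 substitutions) applies to summary outputs and
  comparisons only; all matrices are serialized in full.
* The Bayes factor for "fraction of contexts with x > y" is the binomial
  point-null BF₁₀ with a uniform Beta(1,1) alternative — marginal
  likelihood `1/(n+1)` against `C(n,k)/2ⁿ` — labeled as such in the run
  summary, since several constructions go by this name. Comparisons default
  to raw rates; log₁₀ transformation is left to the caller.

## The simulator

Sequences evolve under a continuous-time Markov process whose per-site 4×4
rate matrix is looked up from the site's current tetranucleotide context,
so contexts co-evolve with their neighbors. Each branch of a three-taxon
star tree is simulated exactly by thinning a dominating Poisson process at
the maximum per-site rate; this is Gillespie-equivalent and keeps all
random draws vectorizable. Rate models are built per *canonical* context
and mirrored by complement transform, so they are strand-symmetric by
construction, and are normalized to mean total rate 1 so branch lengths are
expected substitutions per site. Two immutable flanking bases on each end
give terminal sites defined contexts and are not emitted.

What the generator emulates: gap-free aligned triplets at plastome-like
divergences (defaults 0.02 expected substitutions per site per branch, an
A+T-rich root composition of 60%, intergenic-sized and gene-sized loci),
with codon structure and no in-frame stop codons at the root for CDS. What
it does not emulate: indels (gap handling is exercised with hand-built
fixtures instead), selection, rate variation among loci, alignment error,
and epigenetically driven rate heterogeneity beyond what the context model
encodes. Passing recovery tests therefore validate the inference machinery
under the stated process, not the biological completeness of that process.

The bundled HKY-style model (`at_biased_model`) sets each context's target
composition from its ATI (equilibrium A+T from 0.15 at ATI 0 to 0.85 at
ATI 10), which both produces the wide equilibrium spread seen in real
plastome data and gives exact analytic ground truth (the HKY target is the
CTMC stationary distribution) for round-trip tests.

## Recovery scoring

`recovery_report` scores inference against the event log. *Polarization
sensitivity* is the fraction of true ingroup-branch events recovered with
the correct ancestral→derived assignment **among events at examined sites**
(context intact in the final alignment and class-eligible). Context
disturbance is an O(branch length) loss — at t = 0.01 per branch roughly
11% of sites lose a conserved flank — and is reported separately as
*context coverage*; folding it into sensitivity would make the metric
measure divergence, not the polarization rule. Multiple hits at the focal
site are what degrade sensitivity (O(t) given an event), so sensitivity
exceeds 0.95 for t ≤ 0.01 and declines slowly with divergence. The
*false-polarization rate* is the fraction of emitted substitutions with no
matching true ingroup event. Per-context count recovery restricts truth to
examined sites for the same reason.

Per-context ts:tv recovery needs ≥10⁴–10⁵ observations *within a context*,
which uniform-composition runs spread over 136 classes cannot provide at
realistic sizes; the recovery scenarios therefore use a homogeneous root
composition (all A, or all G) so one context dominates, and check the
inferred ts:tv of that folded class against the K2P truth κ/2. Problem
sizes used throughout (120–600 kb per scenario) are chosen so every checked
quantity has Monte-Carlo error several times smaller than its tolerance.

## Known limitations

* Raw inferred counts: no multiple-hit or branch-length correction, by
  design — matrices describe observed low-divergence substitution spectra.
* Parsimony polarization is biased when divergences are large or rates are
  extremely asymmetric; the pipeline is intended for closely related
  triplets (t ≲ 0.02 per branch).
* Context conservation conditioning slightly biases counts toward stable
  neighborhoods; the effect is uniform across contexts only under strand
  symmetry and approximate rate homogeneity of the flanks.
* Only the standard/plastid genetic code is supported (the 8 fourfold
  families are identical under both).
* Self-complementary folded classes carry doubled totals; consumers of the
  serialized matrices should use ratios, or halve those classes if absolute
  counts are needed.
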