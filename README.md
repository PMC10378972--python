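# ctxsub — context-dependent substitution analysis of plastid DNA

`ctxsub` measures how the local sequence context shapes nucleotide
substitution in chloroplast genomes. Its input is a set of aligned
three-taxon loci — two closely related ingroup plastomes plus an outgroup —
split into protein-coding (CDS) and intergenic (NC) regions. For every
eligible site it infers the substitution direction by outgroup parsimony and
tallies the result into a 4×4 count matrix for the site's *tetranucleotide
context* (the two flanking bases on each side, N₂N₁[N₀]N₁N₂). From these
matrices it derives the per-context statistics used to characterize plastome
mutation dynamics, and it ships a neighbor-dependent sequence simulator so
every inference step can be validated by parameter recovery.

It is written for molecular-evolution researchers studying neutral-site
substitution spectra, in particular the strong context effects documented in
vascular-plant plastomes.

## The method

For each context `c` and site class (FFD = fourfold-degenerate third codon
positions, eligible in the 128 contexts whose left flank is one of the 8
fourfold-degenerate codon prefixes; NC = intergenic, all 256 contexts):

* **Counts.** `M_AD(c)` counts sites with ancestral base `A` and derived
  base `D` (rows/columns ordered A, C, G, T); conserved sites fill the
  diagonal. Polarization keeps a column only when the ingroups differ and
  the outgroup matches exactly one of them, or when all three agree.
  Because plastid substitutions show no strand asymmetry, each context is
  folded with its reverse complement (`M'[Ā][D̄] += M[A][D]`), leaving 136
  canonical NC classes (120 complementary pairs + 16 self-complementary).
* **Rates.** Row rate = off-diagonal row sum / row total; overall rate =
  off-diagonal total / matrix total; transition (A↔G, C↔T) and transversion
  rates partition the overall rate, giving per-context ts:tv.
* **Equilibrium composition.** Row-normalizing `M` gives an empirical
  Markov transition matrix `P`; the stationary vector `π` (π·P = π) is the
  base composition a site in a conserved context would evolve toward, and
  `π_A + π_T` its equilibrium A+T content. Uncertainty comes from a row-wise
  bootstrap: each resample keeps every row's diagonal and substitution total
  but redraws the off-diagonal cells multinomially (1000 resamples).
* **CpG effect.** 2×2 tables pool, over contexts, the CpG-type transition
  (C→T read from the 3' neighbor; G→A from the 5' neighbor) against the
  other changes from that base, in CG versus non-CG dinucleotides; the odds
  ratio `(a/b)/(c/d)` quantifies the CpG excess.
* **Set comparisons.** Two per-context statistic sets are compared by least
  squares r², the fraction of contexts with x > y, and a binomial
  point-null Bayes factor (Beta(1,1) alternative) for that fraction.

## Worked example

The published CpG-effect count tables for gymnosperm plastomes ship with
the package; feeding them through the odds-ratio computation:

```python
from ctxsub.published import published_cpg_tables, mean_cpg_excess

for t in published_cpg_tables():
    print(t.site_class, t.focal_change, round(t.odds_ratio, 2))
print(f"mean CpG excess: {100 * mean_cpg_excess(published_cpg_tables()):.1f}%")
```

prints

```
FFD G>A 1.24
FFD C>T 1.22
NC G>A 1.24
NC C>T 1.23
mean CpG excess: 23.3%
```

i.e. at both coding and noncoding sites the CpG-type transition is roughly
23% more frequent, relative to other changes, inside CG dinucleotides than
outside — the signature expected from deamination of methylated cytosine.

The full analysis over a simulated dataset is driven by the numbered
scripts (each prints what it found and writes tables under `results/`):

```bash
python analysis/01_simulate_dataset.py   # 200 kb NC + 720 kb CDS triplets
python analysis/02_run_pipeline.py       # filters, matrices, stats, bootstrap
python analysis/03_context_variation.py  # rate / ts:tv / eq-A+T spread
python analysis/04_cpg_odds_ratios.py    # CpG tables, published + simulated
python analysis/05_recovery_check.py     # inference vs simulator ground truth
```

The same steps are scriptable from a shell on real data via the `ctxsub`
CLI (`ctxsub simulate`, `ctxsub ingest`, `ctxsub run`, `ctxsub cpg`), driven
by a manifest TSV (`locus_id, path, locus_type, frame_offset, triplet_id`)
of aligned multi-FASTA triplets.

## Layout

```
src/ctxsub/     library: ingest, sites, matrices, stats, simulate, pipeline, cli
analysis/       numbered narrative drivers (write tables under results/)
tests/          pytest suite, including oracle-based property tests
scripts/        acceptance.py
docs/methods.md model description, numerical choices, limitations
```
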