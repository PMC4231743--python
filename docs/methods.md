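# Methods

## The screen

`slimscreen` asks whether genes whose proteins carry a short linear motif
are over-represented in a gene label set (here called "circadian", but any
label set works). The counting unit throughout is the **non-redundant gene
symbol**: a gene is motif-positive if any one of its protein isoforms
contains at least one match, no matter how many isoforms or matches it
has. This per-gene collapse makes the statistics insensitive to isoform
redundancy and to the scanner's policy of reporting multiple spans per
start.

With `N` universe genes, `n` motif-positive genes, `M` set genes and `k`
motif-positive set genes, the two headline statistics are ratio
comparisons expressed as signed percentages:

* forward: `(k/M − n/N) / (n/N) × 100` — excess of the motif-positive
  fraction among set genes over the whole universe;
* reciprocal: `(k/n − M/N) / (M/N) × 100` — excess of the set-member
  fraction among motif-positive genes over the whole universe.

Both compare `k` with its independence expectation `nM/N`, so they always
share a sign, are zero exactly at independence, equal −100% at `k = 0`,
and are invariant under scaling all four counts. In fact over a single
universe they are *algebraically identical* — each reduces to
`kN/(nM) − 1`. Reporting the two directions separately is only
informative when the counts for each direction come from different
datasets (e.g. a proteome universe for one and an expression-dataset
universe for the other); the `universe=` argument on `MotifScreen` exists
precisely because published screens of this kind use two different totals
without stating the intersection rule. When `n = 0` (or `M = 0`) the
statistic is **undefined** and the row is flagged rather than set to 0 —
zero would assert "exactly at expectation", which is false.

## The pattern dialect and scanner

Patterns are parsed into an ordered element list: fixed classes `[NDS]`,
negated classes `[^P]` (the typographic `∧` is accepted), singleton
letters, and wildcards `X`, optionally repeated `X(m,n)` — the only
element the dialect repeats. Element residues must be among the 20
standard letters; ambiguity codes (B, J, O, U, X, Z appearing *in a
sequence*) match nothing, including wildcards, so ambiguous residues can
never inflate counts. Wildcards at pattern edges must consume real
residues (no boundary matching), matching fuzzpro's behaviour.

Scanning enumerates the (few) wildcard repeat allocations, groups the
resulting fixed-length concrete patterns by total length, and compiles one
lookahead regex per length, which yields every distinct `(start, end)`
span including overlapping hits and two ends sharing a start. Coordinates
are 1-based inclusive so that the first residue of a PXDLS instance is the
proline named by mutants such as P72A. The scanner is validated against
an independent brute-force element-by-element checker on thousands of
random (pattern, sequence) instances.

The PDZ pattern `X[ST]X[LV]` is scanned exactly as written, with no
C-terminal anchoring, since the registry stores patterns as printed.

## Significance layer

The percent statistics carry no sampling model, so two p-values are
offered as an *extension* (clearly secondary to the percentages, and with
no multiple-testing correction by default; a Benjamini–Hochberg column is
optional):

* exact hypergeometric upper tail `P(K ≥ k)` for `K ~ Hyp(N, n, M)`;
* a permutation test resampling size-`M` gene sets uniformly from the
  universe, with the add-one estimator `(1 + #{k* ≥ k}) / (1 + n_perm)`.
  The permutation route genuinely resamples label sets rather than
  sampling hypergeometric variates, so agreement with the analytic tail
  (within Monte-Carlo error) is a real cross-check, and null permutation
  p-values are verified approximately uniform across hundreds of simulated
  screens.

Permutation seeds are mandatory; per-pattern sub-seeds are spawned from
the screen seed so whole screens are reproducible byte-for-byte.

## Synthetic data: what it emulates and what it does not

The generator emulates the screen's inputs at their real scale. Defaults
(chosen once as the study conditions): 20,000 genes, 12.5% labelled
circadian (the ~2,800-of-22,000 proportion typical of liver circadian
expression datasets), 1–2 isoforms per gene of 200–400 residues
(protein-scale lengths), i.i.d. background residues (uniform by default; a
Swiss-Prot-like frequency preset is available so chance-match rates can be
made realistic), and the strict PXDLS variant `PXDLSX(1,2)[KR]` planted in
25% of circadian vs 20% of non-circadian genes. Planting splices one
concrete pattern instantiation (classes and wildcards sampled) at a random
interior position of one isoform — deliberately *one* isoform, to exercise
the per-gene collapse.

The planted class contrast is `(p_c − p_n)/p_n × 100 = +25%`. The
*measured* forward statistic has a strictly smaller expectation, for two
reasons the tests account for analytically:

1. **Mixture dilution.** The population rate `n/N` includes the circadian
   genes themselves, so the denominator is the mixture
   `p̄ = f·p_c + (1−f)·p_n` with `f` the circadian fraction, not `p_n`.
2. **Chance matches.** Background sequence matches the pattern at a small
   per-gene rate `q` (≈ 5×10⁻⁴ at the defaults for the strict variant),
   giving class rates `p' = p + (1−p)q`.

The exact expectation `E[forward] ≈ (p_c' − p̄')/p̄' × 100` (≈ +21.2% at
the defaults) is provided by `expected_forward_statistic_pct` and is what
replicate screens recover: across 50 seeded replicates the mean measured
enrichment falls within the 99% CI of that expectation.

What the generator does **not** emulate: residue autocorrelation, disorder
structure, homology between genes, isoform-shared exons, or any circadian
expression dynamics (the gene set is purely a label). Passing recovery
tests therefore demonstrate correctness of the counting and statistics
machinery under known truth — not that any particular real motif is
enriched in any real dataset.

## Conservation reports

Conservation of a motif across orthologs is reduced to presence/position:
each species' first FASTA record is scanned independently and reported
with its hits; "conserved" operationally means present in every supplied
species. For the PXDLS family the scan tries the five variants broadest
first (`PX[NDS]L[VTSAC]X(1,2)[KR]`, then the `[KR]`-tailed variants, then
the short forms); the **anchor** helper returns the smallest hit start
across all variants, ties resolved toward the broader pattern. No multiple
sequence alignment or phylogenetic scoring is attempted. An optional
urllib-based helper can fetch single accessions from NCBI for assembling
ortholog panels; nothing else in the package touches the network, and the
test suite uses locally generated sequences throughout — including
synthetic stand-ins (random backgrounds with a family instance planted at
residues 72, 440 and 1133) for the REV-ERBα/NRIP1/CBP anchor checks.

## Numerical and degenerate-input choices

* Ratios in double precision; summary tables print percentages to one
  decimal, full precision kept in `to_frame()`/TSV output.
* Undefined enrichment is a flagged row (default) or a typed error
  (`undefined_policy="error"`); never silently dropped or zeroed.
* Empty sequences scan to empty hit lists; an empty FASTA or an empty gene
  set is an error; unmappable FASTA headers are counted in an `unmapped`
  bucket excluded from `N`, never silently discarded.
* Gene symbols are trimmed and upper-cased before comparison.
* Hit tables and screen outputs are deterministically ordered
  (pattern, gene, protein, start, end), so reruns are byte-identical.
* `X(m,n)` expansion is capped at 10,000 allocations to keep pathological
  patterns from exploding; the dialect's real patterns expand to ≤ 2.

## Problem sizes used in the shipped checks

Scanner–oracle equivalence uses 1,000 random instances (≤ 8 elements,
≤ 200 residues); sign coherence is enumerated exhaustively for all count
tuples with N ≤ 30; the hypergeometric tail is checked against explicit
subset enumeration for N ≤ 12; null-uniformity uses 500 simulated screens
of a 1,000-gene universe with 199 permutations each; parameter recovery
uses 50 replicates at the full 20,000-gene study conditions (the
acceptance script reports 16 replicates). These sizes give stable
verdicts at interactive runtimes.

## Known limitations

* The dialect is deliberately the printed subset — no repeats on classes,
  no alternation, no anchors — so it cannot express full PROSITE.
* Enrichment p-values assume exchangeable genes; correlated gene families
  violate that, which is one reason the percentages stay primary.
* Conservation is presence/position only; positional drift is reported,
  not scored.
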