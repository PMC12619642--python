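# Methods

## Model

A query V (or J) segment, expressed in the column space of a germline
multiple sequence alignment (MSA) over the alphabet {A,C,G,T,-,N}, is
modeled as emitted by a hidden Markov chain over 2·G·K states: G database
alleles × K mutation-rate categories, duplicated into a non-chimeric half
U and a chimeric half C. State indices are half-major, then allele-major,
then rate (`index = half·G·K + allele·K + rate`). The initial distribution
is uniform over U only. Transitions per column:

| to | probability |
|---|---|
| same state | 1 − ψ − μ |
| same allele, same half, other rate category | μ/(K−1) |
| other allele, chimeric half | ψ/((G−1)K) |
| other allele, non-chimeric half | 0 |
| same allele, other half | 0 |

so every row sums to 1 and a path ends in C iff it switched allele at
least once. Emissions compare the query symbol with the state allele's
column symbol: 1−m on a nucleotide match, m/3 on a mismatch, and 1 when
either side is '-' or 'N'. Query-side gaps (deletions) and N-padded
columns therefore carry no evidence; query insertions are not modeled at
all and are dropped during threading (they are rare and say little about
which template was copied). Reference-side N is scored symmetrically to
query-side N (emission 1); the choice is ours — an aligned germline set
normally contains no Ns, and symmetry is the least surprising rule.

The chimera posterior is the Forward mass of C in the final column over
the total; Viterbi gives the most probable state path, whose allele
switches are reported as (from, to, breakpoint) events with the
breakpoint at the first MSA column held by the new allele. Breakpoints
are identifiable only up to the interval between the informative columns
flanking the true switch, and are reported in 1-based MSA coordinates
(the model's native frame; query coordinates shift with indels).

## Linear-time lattice

The structured transition matrix lets the Forward induction for state j
decompose into (i) a self term α_t(j)(1−ψ−μ), (ii) a same-allele rate
term (Σ_{same allele, same half} α_t − α_t(j))·μ/(K−1), and (iii) for
chimeric targets only, a cross term (Σ_all α_t − Σ_{same allele, both
halves} α_t)·ψ/((G−1)K). The global and per-allele sums are computed once
per column, so the pass is O(L·G·K) instead of O(L·(GK)²). The backward
pass uses the same decomposition; Viterbi replaces sums with maxima and
keeps the best and second-best per-allele and global scores so each
state's best predecessor outside its own allele is found in O(1).
Agreement of the linear algorithms with a dense quadratic implementation
(`forward_oracle`, retained in the package) and with exhaustive path
enumeration is asserted in the test suite at 1e−9.

## Parameters

- **ψ** (default 0.002 per column): prior probability of a template
  switch. Over L≈300 columns this puts roughly 45% prior mass on "at
  least one switch", spread over all (G−1)K alternatives per column, so
  the emissions dominate the call. Exposed on the CLI; raising it makes
  the detector more sensitive and less specific.
- **μ** (default 0.002): prior probability of moving between mutation-rate
  categories of the same allele (DB mode with K>1 only). With K=1 the
  μ term vanishes by construction; we then also drop μ from the
  self-transition so rows still sum to 1.
- **DB rate grid**: 15 values evenly spaced on [0, 0.25] inclusive for
  immunoglobulin data (rate 0 is allowed; its states simply die on the
  first mismatch). TCR data, which does not hypermutate, uses the single
  fixed rate 0.005 to absorb sequencing error.
- **BW mode** (immunoglobulin default): K=1 with a continuous per-allele
  rate re-estimated per query by Baum-Welch, initialized at 0.05, at most
  10 iterations, stopping when the largest rate change drops below 1e−3.
  The update pools each allele's chimeric and non-chimeric occupancies
  and counts only columns where query and reference are both unambiguous
  nucleotides; rates are clamped to [1e−6, 0.5]. Per-query estimation
  keeps the tool usable without batch context.
- **Threshold** (default 0.95): a query is called chimeric iff its
  posterior strictly exceeds it.
- **min_dfr** (default 0 = off): rows with fewer mismatches than this
  against their own best-match reference are passed through unevaluated.
  Chimeras are more diverged from any single reference than authentic
  reads, so a small threshold (2 is a good choice for TCR data) buys
  runtime with negligible sensitivity cost. Prefiltered rows stay in the
  output, annotated, with an empty probability.

Numerical control is by per-column renormalization of the α and β vectors
with an accumulated log scale (the forward-backward identity
Σ_i α̂_t β̂_t = 1 holds at every column); Viterbi runs in log space and
breaks ties toward the lowest state index for determinism.

## Threading

Queries are not re-aligned. The AIRR row's pairwise alignment
(`v_sequence_alignment` / `v_germline_alignment`, 1-based ungapped
germline coordinates) is walked once: each germline position maps through
the assigned allele's gap structure to an MSA column; the first allele
listed in `v_call` is used (AIRR convention orders by score). Columns the
alignment never covers — before/after the aligned interval and the
assigned allele's own gap columns — are padded with 'N', which keeps
every query in a common L-column lattice at emission probability 1 for
the uncovered part. V and J segments are analyzed in separate runs
against their own MSAs, never combined into one lattice.

## Simulator

The generator reproduces the evaluation design: n sequences (design point
10,000) with an exact round(n·rate) chimeric count (design rate 5%).
Non-chimeric reads are one genotype allele mutated uniformly per site;
chimeras join two uniformly mutated alleles at a breakpoint uniform on
columns 2..L (so both parents contribute). Flat per-site sequencing error
is applied after SHM and joining. The `v_call` is assigned by nearest
Hamming distance over informative columns — the detector never sees the
true parent label. AIRR alignment fields are synthesized directly against
the assigned allele, so detection-side threading reproduces the simulated
sequence exactly (asserted in tests at any error rate).

Synthetic germline databases are generated hierarchically: gene families
~12% diverged from a common ancestor, genes ~5% within their family,
alleles 1–4 substitutions apart, with a few family-correlated deletion
columns so alignments contain gaps. Names follow the
`<locus><family>-<gene>*<allele>` convention but are synthetic.

What the simulator does **not** emulate — and what passing benchmarks on
it therefore cannot show: hotspot-targeted SHM (real SHM concentrates in
WRC/GYW-type motifs; uniform substitution is harsher on specificity
because mutations land anywhere, including exactly where two genes
differ), read-position-dependent sequencing error profiles, clonal
lineage structure and non-uniform allele usage, junction (CDR3)
diversity, and curated germline sets (real loci contain near-identical
gene pairs our generator avoids by construction). On our 61-allele
heavy-chain-style genotype at 10% *uniform* SHM the detector's measured
false-positive rate at the 0.95 threshold is small but not exactly zero
(a few per 9,500; recomputed by `scripts/acceptance.py`): rare reads
accumulate enough coincidental mutations toward a gene ~20 nt away to
cross the threshold. Specificity on real, hotspot-mutated data is
expected to be better than this stand-in suggests.

## Evaluation

ROC curves group tied scores and AUC is trapezoidal (equal to the
Mann-Whitney statistic with ½ credit for ties; asserted against a
brute-force pairwise oracle). Confusion counts use the pipeline's strict
`score > threshold` rule. The recombination count matrix tallies gene
(not allele) pairs of flagged single-event chimeras, left gene =
pre-breakpoint parent; multi-event paths are excluded. The normalized
matrix divides each cell by freq_left × freq_right × total — observed
over expected under independence — which is our choice of normalization;
a germline allele missing from the database shows up as a block of
ratios far above 1 because its reads are explained as recombinants of
its neighbors.

## Problem sizes

The test suite runs its oracle-equivalence checks on 200 randomized
instances (G≤5, K≤3, L≤50) plus exhaustive Viterbi enumeration on ≤4⁸-path
instances; rate recovery uses 50 replicate 300-column queries per rate;
the specificity check uses a full 9,500-read panel at 10% SHM and the
end-to-end AUC check a 2,000-read TCR-style panel. The acceptance script
runs the 10,000-read design point for each panel. These sizes keep a full
run in a few minutes on one core while leaving the binomial noise on the
measured rates well below the asserted margins.

## Known limitations

Detection is reliable for V segments; J detection is supported but has
intrinsically low sensitivity (short segments, few informative columns),
and D segments are too short to analyze at all. Accuracy depends on
reference completeness: missing alleles are systematically mis-called as
chimeras of their neighbors (the normalized recombination matrix is the
diagnostic). The model ignores SHM hotspot bias and query insertions, and
"perfect fake chimeras" — genuine alleles identical to a combination of
two others — are inherently ambiguous; the posterior expresses that
uncertainty rather than resolving it.
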