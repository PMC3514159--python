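# Methods

## Catalog model and counting conventions

A screen hit list is a sequence of `InteractorRecord`s keyed by Entrez
Gene ID; gene symbols are display metadata because the source tables carry
parenthesized aliases ("ADAMTSL4 (TSRC1)") that break symbol joins.  The
merged catalog unions the two orientations' lists; the *overlap* flag
(found in both orientations) is always derived from the orientation sets,
and an explicit both-orientations mark in a fixture is validated against
the derived flag rather than trusted.  Annotation fields (previously
described, co-purification outcome, BiFC call) must agree between the two
lists for a shared protein; disagreement is a hard merge error rather than
a silent preference, because the packaged tables print these fields
redundantly and a mismatch indicates a transcription defect.

Counting mixes two conventions on purpose: the distinct-partner count
excludes the bait's homodimer entry while validation and BiFC counts
include it.  Rather than hard-coding either rule, every counting operation
takes `include_bait_self` explicitly.  On the packaged tables this yields
59 partners (homodimer excluded) but 45 confirmed and 41 BiFC-positive
(homodimer included), which is exactly how the source reports them.

The BiFC cell parser treats commas and the word "and" as the same
separator, matches case-insensitively, and collapses repeats, because the
source tables mix "Nuclear and cytoplasmic" with "Nuclear, vesicular,
cytoplasmic" and "Nuclear, and vesicular".  `/` is a no-signal sentinel,
`n.d.` not-determined; both are excluded from every compartment tally.
Direct counting of the packaged cells gives 18 exclusively-nuclear and 13
mixed-nuclear partners (homodimer excluded); the prose of the source
reports 16/15 for the same split.  The tally reports what the cells say;
the 31 nuclear-containing total agrees either way.

## Direct enrichment

The test is the upper-tail Fisher exact test, evaluated as the
hypergeometric survival function (scipy); only overrepresentation is
tested, since that is the question a screen asks.  Seeds and term members
are intersected with the tested universe before counting — enrichment
against all genes rather than the screenable ORF space would inflate
significance for well-studied terms.

Two correction dialects are offered:

* `paper_simple`: corrected_i = min(1, p_i·m/rank_i), ranks by ascending p
  with ties broken by term id.  This is per-rank Benjamini-Hochberg
  scaling *without* the step-up cumulative-minimum pass; its fingerprint
  is that corrected values need not increase with rank.  The packaged GO
  reference table was computed this way: its corrected/raw ratios at ranks
  1–6 all equal 329/rank, recovering m = 329, and the printed corrected
  values are non-monotone (0.0339 at rank 5 vs 0.0307 at rank 6).  Rows
  further down the printed table imply ranks 7–12, 14, 29 and 30 under the
  same m — the table is a filtered excerpt of a longer ranked list, so
  only the six top pairs are reproducible and only they are asserted.
* `standard_bh`: the textbook step-up procedure, cross-checked against
  statsmodels when m equals the list length.  Both dialects accept an m
  larger than the number of p-values handed in, because terms filtered
  from the report still count as performed tests.

The default m is the number of terms with at least one universe member.
The reported odds ratio is the sample odds ratio with optional Haldane–
Anscombe correction (+0.5 to every cell when any cell is zero).  The
odds-ratio column of the packaged GO reference is *not* a reproduction
target: it depends on annotation-database counts that the table does not
carry, so the implementation is verified by formula properties instead.

## Indirect enrichment

The second-degree set is the union of network neighbors of all in-network
seeds, minus the seeds and minus the bait (both exclusions are exposed as
toggles; keeping seeds would let a seed-dense pathway look indirectly
enriched through its own seeds).  Self-loops never contribute neighbors.
Counting is over distinct proteins, not interactions.

The null randomizes seed identity: each trial draws k nodes (k = number of
in-network true seeds) from the network node set — uniformly, or matched
on degree-decile bins, provided because uniform resampling understates the
reach of hub-heavy seed sets.  The node set, not the full ORFeome, is the
sampling frame so that null seed sets have comparable neighborhoods.  The
empirical FDR of a pathway is the proportion of trials whose count reaches
the observed count; it is an exceedance probability, not a
Benjamini-Hochberg quantity.  Default smoothing is the plain r/N
proportion (which can be exactly 0); an add-one mode, (r+1)/(N+1), is
available for downstream log-scale use.  Each source collection is
corrected as its own Bonferroni family, with m = pathways of that source
having at least one network member; the packaged pathway reference is
internally consistent only under per-source multipliers (120, 150 and 628
for its three sources), not a global one.  Significance requires corrected
FDR < alpha (default 0.05) *and* at least `min_obs` observed proteins
(default 2): the second clause suppresses singleton hits whose exceedance
probability is degenerate.

The permutation loop runs on a bit-packed adjacency engine: nodes map to
bit positions, a trial's neighborhood union is a bitwise OR over packed
adjacency rows, and pathway overlaps are popcounts.  The engine is
verified against the set-algebra route property-wise and against
exhaustive enumeration of all C(n, k) seed sets on small networks; 100,000
trials on a 2,000-node network with 50 pathways complete in a few seconds.
One shared null serves all collections in a run, and a run is a pure
function of the configuration's RNG seed.

## Synthetic data

The generator emulates the scale of a proteome-wide screen by default: a
10,214-gene universe (one gene per tested ORFeome gene), 59 seeds, a
sparse network of mean degree ~6 (typical of curated human PPI maps), and
50 gene sets of heterogeneous size (10–200).  Two graph models are
offered: Erdős–Rényi as the analytically transparent default, and a
power-law configuration model (exponent 2.5, truncated degrees) because
real PPI degree distributions are heavy-tailed and hub bias is what
degree-matched null sampling must be tested against.  Parallel edges are
collapsed and self-loops removed after configuration-model wiring, so
realized degrees can fall below the drawn sequence.

Planted signal: `plant_direct` draws ceil(q·n_seeds) seeds from one term
and the rest from the remainder of the universe; `plant_indirect` adds,
per seed, a fixed number of new edges to distinct random pathway members
(existing pairs are skipped, never duplicated, nothing deleted).  Each
generator call derives its RNG stream from (seed, call label), so adding
one call never shifts another's draws.

What the synthetic benchmarks do *not* emulate: Y2H false
positives/negatives, assay-specific sampling bias of the ORFeome,
annotation-term overlap structure of real ontologies, and the
degree-correlation structure of curated interactomes.  Passing the
recovery and calibration suites therefore demonstrates correctness of the
statistical machinery under the stated generative model, not performance
on any particular real interactome.

## Benchmarks and problem sizes

The validation suite uses: exhaustive Fisher-oracle sweeps over all 2×2
tables with N ≤ 20 (tolerance 1e-12); exhaustive permutation enumeration
on a 6-node network (C(6,2) = 15 seed pairs) against 50,000 Monte-Carlo
trials; null calibration on a 2,000-node network with 40 pathways, 20
uniform seeds, 10,000 trials and 200 replicates (observed fraction of
pathway tests at empirical FDR ≤ 0.05 is ~0.03 against the 0.07 bound —
discreteness of the exceedance statistic makes the test conservative);
direct recovery at n = 1,000, |term| = 50, 30 seeds, q = 0.5 over 100
replicates; indirect recovery at n = 2,000, edge probability 0.004, 20
seeds, 2 planted links each, 10,000 trials over 50 replicates.

## Known limitations

* No identifier mapping: all inputs must share one namespace (symbols or
  Entrez IDs); the PSI-MITAB reader takes the first parseable accession
  per column and reads topology only.
* Gene-set collections are flat: no ontology-graph propagation, no
  ancestor-aware or conditional testing.
* The edge-list writer cannot express isolated nodes; networks that need
  them round-trip alongside a universe file.
* The `paper_simple` dialect is deliberately not a valid FDR-controlling
  procedure; it exists to reproduce the reference tables and is clearly
  separated from `standard_bh`.
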