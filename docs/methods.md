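# Methods

## Signature models

**Patterns.** A pattern is an ordered list of elements over the 20
standard amino acids: exact residue, alternative class `[...]`, forbidden
class `{...}`, or wildcard `x`, each with an optional repetition `(n)` or
`(n,m)`; `<` anchors the match to the first residue and `>` to the last.
Scanning reports, at every start position, the span obtained by resolving
variable repetitions greedily longest-first (standard backtracking-regex
semantics) — one span per matching start, overlapping starts allowed,
zero-length matches discarded. Downstream analysis consumes only the
presence bit and span, so the per-start greedy choice does not affect any
classification. Internally patterns are compiled to Python regular
expressions; the test suite checks the scanner against an independent
oracle that enumerates every concrete expansion of the pattern.

**Profiles.** A profile is an L x 20 position score matrix with affine
gap penalties (gap_open ≤ gap_extend ≤ 0) and a presence cutoff > 0. The
matching score MS is the best *local* alignment score under dynamic
programming with three states (match, insertion in the sequence, deletion
of a profile position); alignments begin and end with a match, must
consume at least one profile position, and no score floor is applied, so
MS may be negative. Ties are broken toward the smallest start, then the
smallest end — making the reported span a pure function of the inputs.
Each profile contributes at most one match per protein (its best span),
emitted when MS ≥ cutoff (inclusive). The DP is verified against
exhaustive alignment enumeration at small sizes. Absolute score
calibration is irrelevant downstream because the distortion statistic is
a ratio of matching scores; this is why a plain position-score matrix
reproduces everything the analysis needs from a generalized profile.

## Variant classification

A SNP is applied as a single-residue substitution (length preserved).
Classification is per (SNP, containing reference match):

* pattern domain: rescan the mutated sequence; if no span of that pattern
  covers the SNP position, the domain's presence at the site is lost →
  `da_snp` / `pattern_loss`. Any surviving covering match (possibly
  shifted) means not altered — only the presence bit matters.
* profile domain: rescore the mutated sequence globally;
  DD = (MS_ref − MS_alt)/MS_ref, clamped below at 0 (a score-improving
  substitution does not distort). `da_snp` iff DD ≥ cutoff *or* MS_alt
  fell below the presence cutoff while MS_ref was above it — losing the
  presence bit is treated as altering for profiles exactly as it is for
  patterns, even when DD alone sits under the cutoff.
* a SNP covered by no match is `outside`; a SNP inside several matched
  domains gets one independent call per domain.

The DD cutoff defaults to 0.10 and the comparison is inclusive (≥);
observed distortions range from 0 to about 0.3, so cutoffs are swept over
{0.05, 0.10, 0.15, 0.20} by default. DD requires MS_ref > 0; since the
presence cutoff is positive this cannot occur for a matched domain, but
the guard records such SNPs as unevaluable rather than guessing.

At the SNP level, a SNP is domain-altering at cutoff c if any of its
domain calls is a pattern loss or profile erasure (these belong to every
cutoff's DA set) or its maximal DD reaches c — which makes the DA count
monotone non-increasing in c by construction.

## Enrichment statistics

All enrichment questions use the exact one-tailed upper hypergeometric
P(X ≥ k), evaluated as a log-space sum of point masses (gammaln +
logsumexp) so extreme tails do not underflow; results are clamped into
(0, 1]. The DD sweep takes the population to be all D-SNPs and, at each
cutoff, samples the DA-SNPs; disease membership is matched at SNP level
by default, or through the host protein via a switch. Multiple-testing
correction (Benjamini–Hochberg step-up) is applied in generic term
enrichment, where dozens of terms are tested, and is available by flag
elsewhere; the sweep and the signature-pair tests are uncorrected by
default, mirroring how such screens are usually reported.

## Network impact

Signature annotation per protein combines reference-sequence domain
matches with linear-motif hits found by the same pattern engine. For each
DA-capable domain d, co-occurrence counts with partner signatures are
accumulated over both orientations of every edge. The background for pair
(d, s) is a random-partner null. The default is its closed form: drawing
partners uniformly from the proteome makes the number carrying s
hypergeometric with population N = all proteins, K = carriers of s,
n = distinct partners of d's carriers, k = those partners carrying s.
An empirical mode (seeded uniform resampling of partner sets, default
1000 draws, p = (1 + #{null ≥ k})/(1 + draws)) is provided for fidelity
to the resampling formulation; the two agree in rank order on synthetic
networks. Distinct partners are used rather than edge multisets because
curated PPI edge lists are unique pairs; neither the number of draws nor
degree preservation is pinned by any external reference, so both are
exposed as configuration.

Enriched pairs (p ≤ alpha, default 0.05) are tiered by external evidence:
`ddi_reference` (present in the domain–domain reference list, order
ignored), `domain_motif_reference` (present in the ordered domain–motif
list), or `enrichment_only`. An edge incident to a protein with a DA-SNP
in domain d is called broken iff the partner carries at least one
signature s with (d, s) enriched and its tier admitted by the configured
minimum; only the altered domain itself can break an edge (edgetic
specificity — the host protein's other domains do not contribute).
Connectivity reports count each edge once per DA-protein regardless of
how many altered domains break it, so broken + intact equals the
evaluated degree identically.

## Synthetic universes

The generator emulates the study conditions the pipeline is meant for.
Defaults: 300 proteins of 80–400 residues; 6 pattern + 6 profile domains
and 4 motifs, each planted into ~8% (domains) or ~12% (motifs) of the
proteome at non-overlapping positions; 2 SNPs per protein on average with
20% inside domains, 5% of in-domain SNPs damaging, a 6% base disease rate
and an odds ratio of 2 for intended DA-SNPs; 5 planted binding rules
wiring 90% of ~300 edges, the rest uniform noise; reference lists contain
the planted rules plus 8 decoys.

Construction is analytic where possible so ground truth is exact:
generated patterns use fixed repeat widths, at least four exact elements
(chance matches ~20^-4 per start) and dedicated wildcard/alternative
positions for benign substitutions; damaging pattern substitutions are
verified against the scanner and re-drawn if any covering match survives.
Profiles carry one high-scoring "hot" position whose consensus loss
guarantees DD ≥ 1.5x the cutoff, and cold positions with a designated
benign alternative letter 0.25 below consensus (DD ≈ 0.01); the presence
cutoff is 70% of the consensus score, unreachable by random sequence.
Outside SNPs avoid every scanned span. Disease labels are Bernoulli with
log-odds shifted by the configured odds ratio for intended DA-SNPs.

What the generator does not emulate: realistic amino-acid composition,
evolutionary conservation gradients inside domains, scale-free PPI
topology, variable-width pattern instances, and correlated signatures.
Passing tests therefore demonstrate the correctness and calibration of
the machinery, not performance on real proteomes.

## Statistical calibration and power

With no planted disease association the sweep p-value at the working
cutoff is near-uniform up to discreteness; across 200 seeded default
universes the fraction below 0.05 is ~0.02–0.03 — conservative, because
the DA sample (~6 SNPs) and diseased D-SNP count (~7) make the exact test
strongly discrete at these sizes.

The flip side of that discreteness is power: at the default conditions an
odds ratio of 2 moves P(diseased | DA) from 0.060 to 0.113, i.e. the
expected diseased-DA count from 0.36 to 0.68 out of ~6. No exact test can
reliably detect that; the measured detection rate is ~5%. Detecting an
odds ratio of 2 at the 5% level with high probability needs on the order
of a hundred DA-SNPs, not six. The dedicated power test in the acceptance
suite states the intended ≥90% detection bar and records this gap; the
benchmark with a strong signal (many DA-SNPs, large odds ratio) detects
enrichment at every cutoff, showing the machinery itself is sound.

Planted binding-rule recovery is evaluated after the pipeline's own
false-positive filter — requiring enriched pairs to be backed by a
reference list — with domain–domain pairs compared unordered. Pooled over
20 seeded universes, precision and recall are ≥ 0.8; single universes
occasionally admit a borderline decoy (the per-seed false-positive count
is binomial at the test's alpha).

## Numerical and design notes

* Coordinates are 1-based, spans inclusive; tables are tab-separated
  UTF-8 with `#` comments.
* All randomness flows through a single seeded NumPy generator per
  universe/run; outputs are sorted before writing, so equal seeds give
  byte-identical trees.
* The profile DP is JIT-compiled with numba; the fallback is the same
  function object executed by the interpreter, so both paths share one
  semantics.
* Orphan disease annotations warn rather than fail, keeping partial
  universes usable; SNPs on unknown proteins are dropped and counted,
  reference-mismatched SNPs rejected with a reason.
* Problem sizes in the test suite (oracle sample counts, numbers of
  seeded universes) are chosen to give stable verdicts on one CPU while
  exercising the documented invariants at the defaults' scale.
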