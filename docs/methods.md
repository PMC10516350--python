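# Methods

This note documents the models, conventions and numerical choices behind
`isodom`, and what the synthetic fixtures do and do not establish about real
data.

## Isotype classification

A domain occurrence is described by its deviation from the Pfam reference
model using only the alignment coordinates that `pfam_scan.pl` prints.
Truncation is measured per end — `hmm_start − 1` residues missing at the
N-terminus, `hmm_length − hmm_end` at the C-terminus — and the larger
magnitude is the truncation size. Reading the C-terminal term as a
magnitude is deliberate: the printed difference `hmm_end − hmm_length` is
never positive, and a signed "largest value" rule would make C-terminal
losses undetectable, contradicting the existence of a truncation category.

The indel size is the aligned query length minus the aligned model length,
so a query longer than the model segment gives a positive value. The sign
convention follows the category definitions (positive fraction ⇒
insertion); metrics use the alignment (`seq_start`/`seq_end`) coordinates,
not the envelope.

Thresholds default to 0.1 on both fractions, with `≥` at the boundary, and
are parameters (`trunc_threshold`, `indel_threshold`) because the
classification's stringency is a tunable of the method, not a constant of
nature. The five categories are exhaustive and mutually exclusive by
construction; a property test asserts this over the full metric space.

## Length-mode counting

Per domain, the observed aligned lengths are examined for multimodality: a
Gaussian KDE (bandwidth = R's `bw.nrd0`, i.e. `0.9·min(sd, IQR/1.34)·n^(−1/5)`,
evaluated on a 512-point grid spanning the data ±3 bandwidths), local maxima
as candidate modes, and an occupancy constraint: observations are assigned
to the mode on their side of the lowest-density point between adjacent
maxima, and any maximum holding less than `min_size` of the observations is
merged — lowest-density violator first — until all retained modes qualify.
Counts are therefore between 1 and `⌊1/min_size⌋` and non-increasing in
`min_size`. Domains with fewer than 10 occurrences are reported as NA
(density estimation below that is meaningless).

A property of this estimator worth knowing: on *flat-topped* distributions
(e.g. plain Gaussians) with integer-valued lengths, sampling wiggles at the
peak produce spurious hairline splits at a few-percent rate at any sample
size, because the bandwidth shrinks as fast as the noise does. Real
length distributions are sharply peaked — most occurrences sit exactly at
the reference length — and the fixtures mirror that (point mass plus
scatter), where the estimator is stable. The multimodal fraction is
reported per `min_size` value since it depends on the occupancy floor.

## Structural comparison

Two domain structures are compared by (1) global sequence alignment with
BLOSUM50, gap open 40, gap extend 4; (2) a single Kabsch least-squares
superposition over all matched Cα pairs (no trimming cycles — divergent
regions are part of the signal); (3) backbone RMSD over those pairs and the
TM-score `Σ 1/(1+(dᵢ/d0)²) / L_target` with
`d0 = 1.24·(L_target − 15)^{1/3} − 1.8`, floored at 0.5 Å for short domains.
`L_target` is the reference-isotype member's domain length, matching the
design where everything is compared against reference isotypes; normalising
by the shorter chain instead is a one-line change in `compare_structures`.

End gaps are *penalised* by default. A semi-global (end-gap-free) variant is
available (`end_gap_free=True`), but with these heavy gap penalties it
collapses unrelated-pair alignments to a handful of residues, which makes
the unrelated-domain baseline ill-defined; the fully global form keeps
alignments spanning while still pairing truncated isotypes correctly
(verified in the tests) and matches the defaults of the pairwise aligners
this workflow descends from.

Filters: a pair is kept only if the aligned subsequence exceeds 20 residues
and the non-reference structure's aligned fraction exceeds 80% of its own
domain length. Note that a cleanly truncated isotype aligns completely, so
its coverage is 1.0 — the coverage filter guards against partial/divergent
alignments, not truncation per se. Per-domain sampling caps comparisons at
9 reference × 21 non-reference structures (plus all reference-reference
pairs), seeded; group means are reported only with ≥ 3 surviving
comparisons. The unrelated baseline draws one reference structure for up to
150 domains, scores all cross-domain pairs, and reports the 5–95 percentile
interval.

The representative backbone atom is Cα; "backbone RMSD" is computed over Cα
traces. PDB files are read with gemmi (first model, first chain by default,
altloc A, unknown residues and residues without Cα dropped from both
sequence and coordinates; residue positions are indexed by order in the
chain, matching the positions a sequence-based domain scan would report).

## Motif clustering

Motif strings are compared with the optimal-string-alignment (restricted
Damerau–Levenshtein) distance — insertions, deletions, substitutions,
adjacent transpositions — as raw character sequences (wildcards are literal
symbols). Complete-linkage hierarchical clustering is cut at height 4, so
motifs in different clusters are more than 4 edits apart; with typical
6-residue motifs that separates genuinely different binding chemistries.
An unrestricted Damerau–Levenshtein variant is available by flag. A cluster
is *considered* for a domain when either isotype group occurs ≥ 3 times in
it, and is *specific* to a group holding ≥ 80% (inclusive) of its motifs;
a domain is flagged when reference and non-reference are specific to
disjoint clusters. The k×2 association test enumerates all fixed-margin
tables when the table space is below 2×10⁶ (p = total probability of tables
no more probable than observed, with the conventional 1+1e-7 tie
tolerance), otherwise a seeded permutation Monte-Carlo estimate.

## Enrichment and isotype skew

Overlap tests are exact hypergeometric (Fisher); the two-sided p uses the
same minimum-likelihood definition as R's `fisher.test`/scipy. The reported
odds ratio is the conditional MLE (scipy's `odds_ratio`), with the sample
cross-product alongside. Gene-set association uses one-sided (greater)
tests per domain with BH-FDR within that domain's family; disease- and
interaction-type tests default to two-sided (sidedness is an argument).
Pipeline filters mirror standard practice: sets sized 10–1000, domains in
≥ 10 genes, both reduced to the common universe, undersized sets dropped
again afterwards. The universe is always an explicit argument — it is the
single most consequential choice in any overlap test.

Skew testing ranks a domain's genes by decreasing average overall variation
(ties broken lexicographically for determinism) and runs preranked GSEA:
weighted KS running sum with weight exponent 1 on |score|, gene-label
permutations (vectorised; seeded), NES = ES normalised by the mean |ES| of
same-sign permutations, p with +1 pseudocount. Positive NES ⇒ the set
concentrates among high-variation (non-reference) genes. Sets covering all
or none of the ranked genes are reported as not tested. When all scores are
zero the hit weights fall back to uniform, so the degenerate input still
yields a well-defined (null) result. Adaptive/multilevel p-value schemes
are out of scope; at the permutation counts used here (10³–10⁴) the simple
estimate is adequate and exactly reproducible.

## Expression switches

The major transcript of a gene in a tissue/cell type is its most expressed
protein-coding transcript (median TPM; exact ties go to the
lexicographically smallest transcript id). For genes whose major transcript
differs between groups, domains are paired across the two transcripts by
`hmm_name` and rank order along the protein (genomic-interval overlap is
used instead when coordinates are supplied); a shared domain with different
five-way isotypes is an isotype switch, a domain present on one side only
is a gain/loss. Because the headline "fraction of switching domains" is
sensitive to its denominator, both conventions are reported: switches over
shared domains, and switches over shared + gain/loss events.

## Synthetic data

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`. They emulate input *shape* and planted effects,
not biological realism — no domain co-occurrence structure, no paralog
phylogeny, no realistic sequence composition:

- `simulate_pfamscan` — records over a catalog of eight domains with
  realistic model lengths (39–264 aa); planted fractions keep ≥ 0.02 clear
  of the 0.1 threshold so category recovery is exact, not boundary-luck.
- `simulate_structures` — an idealised α-helix Cα trace (rise 1.5 Å, 100°
  per residue) with i.i.d. Gaussian coordinate noise; truncation removes a
  leading fraction of residues. Closed-form geometry makes every score
  checkable by an independent oracle.
- `simulate_motifs` — cluster seed strings ≥ 6 edits apart, members within
  1 edit, isotype labels at a set purity.
- `simulate_genesets` / `simulate_enrichment` — per-gene planted variation
  (half high, half zero); skewed sets sample from the top quartile of the
  variation ranking; enriched labels hit a unit set at a planted odds
  ratio.
- `simulate_expression` — two coding transcripts per gene; switch genes
  flip the major transcript between groups, a subset also flips the domain
  isotype (reference → 0.2-truncation).

Passing the planted-recovery tests shows the algorithms implement their
definitions and are well-calibrated under clean, well-separated effects; it
does not show robustness to the messiness of real annotations (fragmented
domains, overlapping hits, mapping ambiguity).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen for statistical
adequacy: 500-record classification fixtures, 35-residue structures with
25–100 Monte-Carlo replicates, 30-domain mode proteomes, 200-gene rankings
with 10³–10⁴ GSEA permutations, exhaustive Fisher verification over all
~3×10⁵ tables with universe ≤ 50. The complete suite runs in about a minute
on one CPU.

## Known limitations

- The His_Phos_1 worked example requires five PDB entries that cannot be
  redistributed with the package; `scripts/fetch_his_phos_1.py` downloads
  them. Without `pfam_scan` coordinates the whole first chain stands in for
  the domain region — a good approximation for these single-domain chains.
- Multi-structure alignment is reproduced as repeated pairwise alignments
  to one anchor; no flexible or sequence-independent structural alignment.
- `pfam_scan` version quirks are handled by tolerant token-order parsing;
  byte-level fixed-width layouts are not assumed.
- Mode counting inherits the KDE instability on flat-topped distributions
  described above.
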