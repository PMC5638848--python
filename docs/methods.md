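# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where several reasonable options existed.

## Amplicon geometry and primers

The assay is modelled on the Mlas-forward / mcrA-reverse degenerate
primer pair (`GGTGGTGTMGGDTTCACMCARTA` / `CGTTCATBGCGTAGTTVGGRTAGT`),
exposed as configuration and marked user-verifiable; no primer sequence
is hard-coded into the science. With a 157-aa peptide the amplicon is
23 nt forward primer + 425 nt insert + 24 nt reverse-complemented
reverse primer = 472 nt, reading frame +1 spanning 157 codons with one
trailing base. The frame fixes the conserved primer translations —
`GGVGFTQ` at the N-terminus (the forward primer's seven full codons) and
`YPNYAMN` at the C-terminus (the reverse primer's in-frame codons at
offset 2) — which the ORF screen uses as anchor motifs. Only the 157-aa
geometry yields an amplicon inside the 472 ± 1 size window; other
lengths in the 155–160 aa screen range correspond to in-frame indel
variants of real data.

## Synthetic communities

The generator is the package's definition of the study conditions:
54 libraries (13 R, 12 A, 15 RA, 14 AA), community profiles equal to the
published per-treatment cluster means renormalised to proportions, and a
default depth of 65,000 read pairs per library (the study's total read
count divided by 54, to order of magnitude); the recovery experiments in
the acceptance layer use 50,000.

Panels evolve hierarchically from one root peptide. Substitutions use an
exact-count model — `round(d·L)` random sites per lineage, uniform
replacement residues, no rate heterogeneity — because the generator's
contracts are identity bounds, not realism: members must sit ≥ 98%
identity to their clade root while clades stay ≤ 96% apart, and the
exact-count model makes those bounds deterministic. Two refinements
matter:

* **Sibling-disjoint substitution sites.** Members of a clade draw their
  (default 3) substitution sites without replacement from a shared pool,
  so any two siblings differ at 6 positions (identity 151/157 ≈ 0.962)
  and never merge at the 97% clustering threshold, while staying ≥ 98%
  identical to the clade root (154/157 ≈ 0.981). With independent draws,
  chance site overlap occasionally pushed sibling identity above 0.97.
* **Codon-edit propagation.** The root peptide is back-translated once
  (respecting the primer patterns at the termini) and every amino-acid
  substitution is applied as the minimal codon edit, so nucleotide
  divergence tracks peptide divergence. Independent back-translation per
  member would scatter silent substitutions everywhere and break both
  the chimera benchmark and dereplication.

Reads are template slices (2×250 nt by default, overlapping by 28 nt at
472 nt); per-base substitution errors, two-parent single-crossover
chimeras (crossover uniform over interior positions), in-frame ±3–30 nt
off-length variants and single ±1 nt frameshifts are mutually exclusive
per-read categories applied at the configured rates, and every read gets
one truth record. Quality strings are constant Q30: the pipeline makes
no quality-based filtering decision after merging, so quality decay is
out of scope, as are PCR-cycle amplification bias and adapters. Passing
tests on these simulations therefore demonstrate correctness of the
algorithms under multinomial sampling plus the modelled artefact types —
not robustness to real Illumina error profiles.

The bundled study panel maps the 25 published cluster ids onto six
clades. Family/genus/clade follow the published assignment where stated
(gottschalkii and ruminantium clades of *Methanobrevibacter*,
*Methanosphaera*, Methanomassiliicoccaceae); where the study stops at
genus or family level the panel supplies synthetic clade labels
(thaueri; two Methanomassiliicoccaceae genera) so that recovery can be
scored at full resolution. Three labelled reference sequences per clade
accompany the community members; pipeline placement runs against the
references only.

## Read merging

The merger scans candidate overlaps between R1 and reverse-complemented
R2 from longest to shortest and accepts the first with mismatch rate
≤ 0.1 and length ≥ 20 nt (BBMerge-like defaults; the study names the
tool but no parameters). Consensus takes the higher-quality base at
overlap mismatches; with equal qualities the R1 base wins, which is the
one case where merging is not exactly strand-symmetric. Merging operates
on dereplicated (R1, R2) mate pairs and fans results back out —
identical inputs merge identically, so this equals per-read merging at a
fraction of the cost. Rejection is a value with a reason code
(`no_overlap`, `too_short`); counts are conserved at every stage.

## Chimera filter

A UCHIME-style two-parent single-crossover model on dereplicated
amplicons. For a query and parent pair, `b2` is the best split of the
query into a left segment matching parent A and right segment matching
parent B (computed from prefix sums of positional match profiles, both
directions); `b1` is the best single-parent identity. A query is flagged
iff

* `b2 ≥ 0.998` (the two-parent model explains the query almost
  perfectly — an error-free bimera gives exactly `b2 = 1`),
* `b2 − b1 ≥ 0.004` (≈ 2 nt on a 472-nt amplicon), and
* each side of the crossover has ≥ 2 diagnostic positions (query matches
  one parent but not the other).

These defaults were set analytically from the required operating point
(sensitivity ≥ 0.90 on error-free bimeras of parents ≤ 0.92 identity,
false-positive rate ≤ 0.02 on genuine rare members): flagging demands
`ceil(Δ·472)` diagnostic differences on each side of the crossover, so a
uniform-interior crossover caps sensitivity at roughly `1 − 2k/D` for
`D` parent differences — with Δ = 0.02 that ceiling is far below 0.90
for any realistic divergence, while Δ = 0.004 with the two-sided
diagnostic rule reaches ≈ `1 − 4/(D+1)`. The high `b2` floor is what
protects genuine members: a real sequence carries private substitutions
that no two-parent combination explains, so its `b2` stays below the
floor, whereas an error-free chimera reaches `b2 = 1` exactly. All
thresholds are configuration.

Candidate parents come from sequences at ≥ 2× the query's abundance
(de novo mode) or the reference panel, ranked by shared 8-mers. Because
whole-query k-mer ranking under-represents the minority parent when the
crossover is off-centre, the filter augments the candidate set with a
second ranking over the query region the best single parent fails to
explain, and the best verdict maximises `(b2, b2 − b1)` — the pair that
best explains the query, not the pair with the largest gap. De novo
detection runs first, then reference mode; removal is the union. A query
occurring verbatim in the panel is never flagged.

## ORF screen

All six frames are translated under the standard code (stops rendered
`*`, trailing partial codons dropped). A frame passes if it is stop-free,
155–160 aa, and its terminal residues match the forward/reverse anchor
motifs with at most `max_motif_mismatches` (default 0 — the conserved
translation is read strictly; a documented switch relaxes to 1). Exactly
one passing frame is required; zero or several is a rejection
(`no_frame`, `multiple_frames`, `stop_codon`, `length`, `motif`), since a
genuine amplicon determines its frame uniquely. Primer-encoded residues
are retained in the peptide (documented alternative: trim before
clustering).

## Peptide clustering

Greedy abundance-sorted centroid clustering (the standard UCLUST-style
reading of "clustered at 97% identity"): dereplicated peptides are
visited in decreasing total abundance, ties broken lexicographically,
and join the first centroid with identity ≥ 0.97, else found a new
cluster. Identity is global-alignment matches over alignment columns
with terminal-gap columns excluded (match +1, mismatch 0, affine gap
10 + k on the unit scale) — for the fixed-length amplicons this almost
always reduces to Hamming identity, but the definition matters for
off-length survivors. The 0.1% abundance floor applies to the pooled run
total (not per sample), inclusively; cluster ids are arbitrary labels
assigned by descending total abundance. Samples with zero retained reads
are flagged and excluded from statistics rather than propagated as
undefined compositions.

## Parsimony placement

Centroids and references are aligned progressively: pairwise
profile-profile Gotoh alignments (mean BLOSUM62 column score, affine
gaps) guided by a UPGMA tree of 3-mer distances. Profile gap costs are
open −13 / extend −2 on the BLOSUM62 scale — strong enough that
equal-length amplicon peptides align gap-free even between families,
while a genuine insertion (conserved flanks out of register) still opens
a gap. Columns with < 85% site coverage are masked; gaps are missing
data in parsimony (MEGA's default), which guarantees masking never adds
changes.

Tree search is Fitch parsimony with 10 random-addition starts refined by
first-improvement SPR hill-climbing over the full one-move neighbourhood
("search level 1"). The Fitch kernel is numba-compiled over bitmask
state sets on an array tree representation; a plain dictionary-based
implementation of the same recursion backs the public `fitch_length` and
the two are cross-checked in the tests, alongside exhaustive-enumeration
oracles at ≤ 7 taxa. Bootstrap support (500 replicates by default)
resamples kept columns as integer column weights — identical to explicit
resampling for Fitch lengths — and re-searches each replicate with
reduced effort (2 random-addition starts, SPR bounded to 2 passes);
branches below 30% support collapse to polytomies. Ties among equally
parsimonious trees enter taxonomy assignment through their strict
consensus.

Each cluster leaf receives the labels shared by the reference members of
the smallest surviving clade containing it, where candidate clades are
both sides of every internal edge — leaf edges yield only trivial splits,
not clades — with ties broken by clade size then lexicographic leaf
names; conflicting labels at a level yield "unassigned", and a fully
collapsed (star) tree falls back to the whole panel with support 0.

## Statistics

Relative abundances are raw counts per cluster scaled to 100% per
sample. Aggregation to family/genus/clade sums member clusters (row sums
preserved exactly; unlabelled clusters pool into "unassigned").
Diversity follows the PRIMER conventions the published values are
consistent with: "richness" is Margalef's `(S−1)/ln N` and Shannon uses
natural log. Bray–Curtis operates on √-transformed abundances; PCoA is
classical scaling with the full eigenvalue spectrum reported (negative
eigenvalues included); nMDS is SMACOF with isotonic regression of
configuration distances on dissimilarity ranks, minimising Kruskal
stress-1, best of 50 random starts (500 iterations, tolerance 1e-6);
dendrograms and the heatmap ordering are group-average (UPGMA)
agglomeration.

The omnibus test per cluster is Kruskal–Wallis (tie-corrected, χ²
p-values) with BH correction across clusters; the pairwise layer is
Wilcoxon rank-sum per treatment pair with BH across all pairs × clusters
(the two families are corrected separately — the study does not state
the family, so this is documented and configurable) and compact letters
via insert-and-absorb. Diversity indices get one-way ANOVA with Tukey
HSD. Degenerate inputs (all values identical) report the null (p = 1)
rather than erroring.

## Scale of the evaluation runs

The recovery experiment simulates the full published design — 54
libraries × 50,000 read pairs, noise-free — and runs the complete
pipeline including the 500-replicate bootstrap (a few minutes on one
CPU, thanks to dereplicated processing and the compiled Fitch kernel).
Group-mean recovery is judged per cluster × treatment cell on the
multinomial standard error of the group mean: with 100 simultaneous
cells a ~0.3% per-cell excursion rate beyond 3 SE is expected from
sampling alone, so the acceptance check requires ≥ 97% of cells within
3 SE and no cell beyond 4.5 SE (the simultaneous ≈ 3-SE band at 100
comparisons); any systematic bias trips both. The chimera benchmark uses
two clades divergent enough that parent templates sit well inside the
≤ 0.92 identity condition, 8 abundant parents, ~400 bimeras and 52 rare
clean members.

## Known limitations

* The simulator's error model is substitution-only with flat Q30
  qualities; no quality decay, adapters, or PCR-cycle bias.
* Chimera detection assumes a single crossover; 3+ parent chimeras are
  out of scope.
* The published run-level numbers that depend on the real raw reads
  (total read count, the exact 25-cluster/96.2% retention, per-sample
  diversity values, the published ordination stress of 0.1) are not
  reproducible without the undeposited data; the pipeline reproduces the
  *procedures* and is validated on synthetic data plus the printed-table
  aggregation identities.
* Strand symmetry of merging breaks on equal-quality overlap mismatches
  (the R1 base wins).
* The progressive aligner is a straightforward profile Gotoh; it is
  adequate for near-fixed-length amplicon peptides, not a general MSA
  replacement.
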