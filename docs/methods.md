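# Methods

## Model and procedure

`codonscout` prepares and post-processes the inputs and outputs of an
alignment-based coding-potential scorer. The scorer itself (and the
multiple aligner) are external tools behind subprocess adapters; the
package's own substance is everything around them: the distance metric,
the iterative retrieval scheme, the diversity-constrained selection, the
windowing of long queries, and the collation of high-scoring segments
(HSS).

### Pairwise distance

Similarity between two sequences is `matches / min(len_a, len_b)` where
`matches` counts identically paired residues in a maximal-scoring
Smith–Waterman local alignment under match +1, mismatch −1, gap open −1,
gap extend −1; distance is `100 (1 − s)` percent. The gap model is
linear (open = extend), so the dynamic program is computed row-wise in
numpy with the within-row dependency resolved by a running maximum; the
traceback is exact. Determinism is part of the contract: among co-optimal
end cells the smallest end coordinate in the first sequence wins, then in
the second; the traceback prefers diagonal over vertical over horizontal
steps. `N` is scored as a mismatch against everything (including `N`) and
never counts as a match; lowercase/softmasked input is uppercased.

A property of this metric worth knowing: with gaps this cheap, the local
alignment of two *unrelated* 600–1000 bp sequences still pairs ~55–65 %
of residues, so measured distances saturate around 40–48 % rather than
approaching 100 %. The 10–60 % selection band therefore effectively
binds only at its lower edge for realistic inputs; distance targets for
the synthetic generator are kept at or below ~40 % for the same reason.

### Iterative retrieval

Word sizes and taxonomic scopes per iteration (direct path / custom-DB
construction): (18/14, none), (14/11, order), (10/9, class), (8/8,
phylum), (7/7, kingdom). The first, unrestricted iteration's best hit
estimates the query's phylogenetic position; later iterations widen scope
around that lineage. Every round uses an E-value cutoff of 0.01 and
requests up to 10,000 hits — near-identical hits cannot be excluded
server-side, so they must be retrieved and then discarded by selection.
Iteration stops early once the clustered representative pool reaches the
16-sequence cap (the schedule continues only "if necessary"). Hits on
records not annotated as genomic (unspliced) DNA are dropped when the
backend is declared nt-like; curated genome collections skip that filter.

Hits are extended to full query length by linear projection of the
unaligned query flanks onto the subject, clipped at the subject bounds
(an estimate, not a re-alignment); minus-strand extracts are
reverse-complemented so every candidate reads in query sense.

### Selection

Band filtering keeps candidates whose distance to the query lies in the
closed interval [10 %, 60 %] (both boundaries inclusive — "minimal and
maximal" read as a closed interval). The density-based clustering then
repeatedly takes an unclustered sequence, gathers its neighbourhood (all
unclustered sequences strictly closer than the 10 % threshold, plus
itself), and if the neighbourhood is larger than a singleton, lets the
member with the largest own neighbourhood become the centroid; the rest
of the winning neighbourhood is deleted and the whole neighbourhood is
marked clustered. Iteration order is ascending E-value, and ties between
equally large neighbourhoods keep the incumbent (the earlier, i.e.
closer, sequence) — both choices for reproducibility. Survivors are
pairwise ≥ 10 % apart; the final set is the best 2–16 by ascending
E-value (ties: smaller distance to query, then id). Fewer than 2
survivors is an error naming the count found.

Two ambiguities in the published pseudocode are resolved as follows: the
inner neighbourhood lookup is evaluated for the competing member (a
literal reading would compare a set against itself), and the two
"clustered" sets are treated as one, so the outer loop terminates.

### Windowing

Queries strictly longer than 1000 bp take the long path. Windows of
exactly 1000 bp are placed every 700 bp from position 0, and the final
window is anchored at the query end rather than left as a short tail,
because the scorer loses statistical power on short blocks. The 300 bp
overlap is a multiple of 3, so a coding region crossing a boundary keeps
its codon phase in both windows; it is also long enough for the scorer to
re-detect a boundary-crossing segment in the second window. The overlap
and the long-query threshold are this package's own defaults (threshold =
chunk length means splitting happens exactly when more than one chunk
would exist).

For the long path a temporary custom database is built first: the
sensitive (build-db) word-size schedule runs until the per-species best
hits reach 300 (or the schedule is exhausted); each retained subject
interval is expanded symmetrically around the hit midpoint to 5× the
query length, clipped to the record, to leave room for intron-length
differences. Per-window searches against this small collection are a
single pass at the most specific settings (word size 18, no restriction)
— with so few targets, distant homologs are found reliably without
iteration.

### Scoring adapters and the tabular dialect

Alignment blocks are validated: ≥ 3 rows (query + ≥ 2 homologs), equal
row lengths, query row first and equal (ungapped) to the window. The
scorer's tabular output is 11 tab-separated columns — HSS id, strand,
frame (1..3), length in amino acids, alignment from/to, reference name,
reference start/end (1-based inclusive), score, p — parsed to 0-based
half-open coordinates and frames 0..2; parse and serialize are exact
inverses. The dialect is frozen from the scorer's documented tabular
format (version 0.3); stub adapters replay canned text so the whole
pipeline runs and is tested without any binary. Subprocess adapters are
provided for Clustal Omega, MAFFT and RNAcode; adapters write their
inputs to a private temporary directory that is removed when the call
returns.

Frames are re-expressed in query space so segments from different
windows are comparable: plus strand, `q_start mod 3`; minus strand,
`(query_length − q_end) mod 3` (codons read right-to-left).

### HSS collation

Post-processing order is merge → shadow resolution → p-filter: merging
first, so fragments of one region re-detected by adjacent windows are
judged once. Merging unions overlapping-or-abutting segments of equal
strand and query frame; the merged segment takes the minimum p and
maximum score of its members (the scorer cannot be re-run on merged
spans without re-alignment — a documented approximation), records all
contributing windows, and is trimmed to codon boundaries anchored at its
most significant member. Shadow resolution keeps, within every connected
group of mutually overlapping segments that disagree in strand or frame,
only the lowest-p segment (ties: higher score, then leftmost) — a strong
coding region statistically induces a weaker "shadow" in another frame
or on the opposite strand, and the published description of the filter
is read as keeping the best segment. The display filter keeps p < 0.05.
No multiple-testing correction is applied; p-values are reported as
produced. Translation uses the standard genetic code; internal stops are
rendered `*` and logged.

Exports: TSV (re-ingestable, query coordinates), BED6 (0-based
half-open), GFF3 (1-based inclusive, source `codonscout`, type
`CDS_region`), protein FASTA, and a run summary echoing the effective
configuration and per-stage counts. All exports are byte-deterministic
for fixed inputs.

## Synthetic data: what it emulates, what it does not

The generator derives homologs from a random root by seeded random
substitutions (batches of 1 % of the length) until the measured pairwise
distance first reaches the target — substitution-only, so the measured
distance tracks the substitution load analytically; indel robustness is
exercised by hand-built fixtures instead. Default family: 600 bp root,
8 homologs at 12–40 % target distance, four-rank lineages spread over
the orders, classes and phyla of one kingdom so taxonomy-restricted
search is exercised, biomol labels assignable per record. An optional
embedded ORF (ATG + non-stop codons + TAA) restricts in-ORF mutation to
wobble positions (synonymous-biased divergence).

The mock backend's discoverability rule mirrors blastn seeding: a
subject is found at word size *w* iff it shares an exact substring of
length ≥ *w* with the query on either strand (computed exactly); the
reported hit is the maximal shared block. The E-value is
`query_len · 2^−block · 2^−30`, floored at 1e-180 — monotone in block
length (its only job is ordering) and scaled so every seeded hit passes
the 0.01 cutoff. Orientation is chosen by the local-alignment score of
the query against each strand of the subject, because at in-band
divergence the longest exact block is ~10 bp and random opposite-strand
blocks would otherwise tie.

Passing tests on this generator therefore demonstrate the pipeline's
logic — scheduling, filtering, selection, coordinate arithmetic,
collation — under controlled divergence and taxonomy. They do not
demonstrate performance on real data: no indels, no rate heterogeneity,
no codon-model evolution, no realistic E-value statistics, and the stub
scorer has no statistical power at all (it replays fixtures).

## Numerical choices and degenerate inputs

- Distance values are exact rationals of the match count; no tolerance is
  applied in band or threshold comparisons.
- Clustering with an empty or singleton pool returns it unchanged; empty
  band-filter output is allowed (the error surfaces at final selection).
- Hit extension never fails on short subjects: the candidate is clipped
  to what the record can provide.
- A long-query window that fails (too few homologs, adapter error) is
  skipped with a warning; the run fails only when every window fails.
- Merged intervals shorter than one codon after trimming fall back to
  the anchor segment's span.
- Problem sizes in the test suite and acceptance script (600–2500 bp
  queries, 3–18 homologs, 320-record custom-DB pools) were chosen as the
  smallest sizes at which every contract is exercised end to end.

## Known limitations

- The distance metric's saturation (above) makes the band's upper edge
  mostly decorative; this mirrors the metric's definition, not a bug.
- Merged-segment p-values are lower bounds of their members, not
  recomputed statistics.
- The live-taxonomy and remote-database paths are deliberately absent;
  lineages come from a required metadata table.
- The scorer tabular dialect is frozen against the documented version
  0.3 format; other scorer versions may need a parser shim.
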