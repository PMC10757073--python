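# codonscout

Alignment-based detection of evolutionarily conserved protein-coding
regions, starting from a **single nucleotide query**.

Comparative coding-sequence detectors exploit the characteristic
substitution pattern of conserved coding DNA — synonymous third-codon
changes, conservative amino-acid replacements — and are far more accurate
than single-sequence methods on short coding regions such as small
peptides (sORFs) or overlooked exons. Their price is that they need a
multiple sequence alignment of suitably divergent homologs, which is
tedious to assemble by hand. `codonscout` automates that preparation as an
offline, fully testable pipeline: it retrieves homologs through a
pluggable search backend, selects an informative subset, windows long
queries, drives an external aligner and coding-potential scorer through
narrow adapters, and collates the resulting high-scoring segments (HSS)
into merged, filtered, exportable predictions.

## The method

**Similarity and distance.** For two sequences the similarity *s* is the
number of matched residues in a Smith–Waterman local alignment
(match +1, mismatch −1, gap open = gap extend = −1) divided by the length
of the shorter sequence; the distance is *d* = 100(1 − *s*) %.

**Retrieval.** A blastn-style search is iterated up to five times with
decreasing word sizes (18, 14, 10, 8, 7 for the direct path) and widening
taxonomic scope (unrestricted, then the order, class, phylum and kingdom
of the first iteration's best hit), with an E-value cutoff of 0.01 and up
to 10,000 hits per round, so that distant homologs are found when the
close ones are uninformative. Hits are extended to full query length by
projecting the unaligned query flanks onto the subject.

**Selection.** Candidates are kept if their distance to the query lies in
a band (default 10–60 %): closer sequences carry no substitution signal,
farther ones cannot be aligned reliably. A density-based clustering
(similar in spirit to DBSCAN) then collapses groups of mutually close
sequences — the member with the largest neighbourhood becomes the
representative, its neighbours are discarded — until all survivors are
pairwise at least 10 % apart. The final 2–16 homologs are taken in order
of increasing E-value.

**Windowing.** Queries longer than 1000 bp are split into overlapping
1000 bp windows (300 bp overlap, final window anchored at the query end).
A temporary custom database — the best hit per species, up to 300
sequences, each expanded to 5× the query length — is searched instead of
the full collection, one pass per window.

**Scoring and collation.** Each window's selected homologs are aligned
(Clustal Omega/MAFFT adapters; deterministic stub for offline runs) and
scored by a coding-potential scorer (RNAcode adapter; stub replays canned
tabular output). Reported HSS are mapped back to query coordinates with a
query-wide codon-phase (frame) label, merged across windows when they
overlap in the same strand and frame, stripped of "shadow" artifacts
(weaker overlapping segments in another frame or strand), filtered at
p < 0.05, and exported as TSV, BED6, GFF3 and translated protein FASTA.

## Worked example

`examples/run_short_query.py` builds a family of 18 homologs at 12–18 %
divergence from a 600 bp root, runs the whole pipeline with the mock
backend and a stub scorer that reports one segment, and prints:

```
query: query, 600 bp
representatives after clustering: 18
homologs selected for alignment:  16 (cap 16)
HSS: query [30,120) strand + frame 0 p=0.0004
```

Eighteen in-band homologs survive clustering (they are pairwise >10 %
apart by construction) and the final set saturates at the 16-sequence
cap; the scorer's segment is placed on the query with its codon phase and
p-value. `examples/diversity_selection.py` shows the selection stages on
a family with a below-band member and a near-duplicate pair, and
`examples/long_query_windows.py` shows a 2500 bp query split into four
windows with one coding region merged across a window boundary.

The same pipeline is available from the shell:

```sh
codonscout run --query q.fa --subjects subjects.fa --metadata meta.tsv \
    --backend mock --aligner stub --scorer stub --out results/
codonscout select --candidates c.fa --sidecar c.tsv --out-prefix selected
codonscout fixtures regenerate --outdir fixtures/ --seed 7
```

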