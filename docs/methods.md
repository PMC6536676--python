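# Methods

## Catalog model

A virome member is one row: name, host strain, family (*Siphoviridae*
/ *Myoviridae* / *Podoviridae* / unclassified), lifestyle
(`induced_active` for mitomycin-C-induced temperate phages,
`insilico_prophage` for predictions in public genome sequences,
`lytic`), a `previously_described` flag, integration strategy
(tyrosine recombinase `tyr`, serine recombinase `ser`, Mu-like
transposase `tnp`), integration-site class and name, genome size, GC%,
gene count, and replicon coordinates (1-based inclusive — the
convention under which printed sizes and coordinate spans agree;
verified on multiple rows). Two prophages split across two contigs
carry a second (accession, start, end) triple and are excluded from
the coordinate/size audit. Lytic phages enter with no integration
metadata and no size (none is on record in the transcribed table), so
size/GC invariants apply only when a value is present.

Site names are normalized to `tRNA-Xaa(ANT)`; anticodon variants stay
distinct; non-tRNA names are casefolded. The `previously_described`
flag (the six earlier-known prophages of *P. aminophilus* JCM 7686 and
the two lytic phages) makes "novel prophages" a filter rather than a
separate file.

The coordinate audit (`cross_validate_sizes`) reports, and never
raises on, rows whose stated size disagrees with the span — two such
rows exist in the packaged table. Similarly, the recombinase-class
tallies are derived from the table rows (39 tyr / 15 ser / 5 tnp, and
30 tRNA-site rows); narrative summaries elsewhere quote marginally
different totals (38/16 and 31), so the package reports table-derived
counts and leaves the discrepancy visible rather than asserting either
number.

## Synthetic lysogens

Host replicons are i.i.d. nucleotide sequences with P(G)=P(C)=GC/2 —
*Paracoccus* replicons sit at roughly 60–68% GC, the default host is
63% — carrying labeled tRNA features at fixed positions and background
CDS at 0.8 genes/kb (lengths 300–1500 bp, non-overlapping). tRNAs are
labeled intervals with arbitrary internal sequence; tRNA
identification is out of scope. No repeat structure exists beyond the
planted att cores, which keeps the direct-repeat recovery oracle
clean; for the same reason the two cassette-terminal bases are forced
to differ from the host bases adjacent to the other repeat copy, so
the planted core is exactly the maximal repeat and "exact recovery" is
well defined.

A prophage cassette is a modular gene layout (integration,
lysis/lysogeny switch, replication, packaging, head–tail, lysis; one
block each by default) at its own GC (default 58%). Integration at a
plus-strand tRNA duplicates the 3′-terminal `att_core_length` bases:
`host[..3′end] + cassette + core + host[3′end+1..]`, so the upstream
copy (attL) completes an intact tRNA and the downstream copy (attR) is
the new repeat. Minus-strand tRNAs mirror this at their genomic-left
3′ end. CDS targets insert mid-gene (the left fragment is flagged
disrupted); intergenic targets duplicate the bases 5′ of a uniformly
chosen insertion point, or nothing when the core length is 0. The
`PlantedTruth` record (cassette interval, attL/attR intervals, core,
target, per-gene module labels) suffices to score every downstream
call.

Proteome generators plant, for each phage pair (i, j), exactly
`shared[i][j]` homolog pairs: a random 20-letter protein (uniform
background, default 250 aa) and a copy point-substituted to the
requested identity (substitutions always change the residue, so the
realized ungapped identity equals the target up to rounding). All
other proteins are unrelated; at these lengths the chance of an
unrelated pair crossing the 80%-identity threshold is negligible.

What the generator does **not** emulate: real gene content and codon
structure, sequence repeats and mobile elements in host DNA,
degenerate or mismatched att repeats, annotation errors, assembly
gaps. Passing recovery tests therefore demonstrates correctness of
the algorithms under clean planted signal, not performance on real
genomes.

## Alignment engine

Exact affine-gap local alignment (Gotoh three-state DP), no seeding or
X-drop heuristics; a gap of length k costs `open + k·ext` (NCBI
convention). Protein default BLOSUM62 with 11/1 and gapped
Karlin–Altschul constants λ=0.267, K=0.041; nucleotide default +2/−3
with 5/2 and λ=0.625, K=0.41. Bit score `(λS − ln K)/ln 2`; E-value
`m·n·2^(−bit)` with n the subject length for a single pair and the
total residue count of the subject set per direction in all-vs-all
runs. Threshold behaviour, not numeric parity with any particular
BLAST build, is the contract.

Determinism: among equal-scoring optima every maximal end cell is
traced back and the hit with the earliest query start, then earliest
subject start, is reported; traceback prefers diagonal over vertical
over horizontal moves. HSP lists are produced greedily — report the
optimum, mask its subject interval, repeat until the raw score falls
below `min_raw_score` (nucleotide default 300 ≈ a 150-nt perfect
match).

The quadratic DP is meant for desk scale — phage proteomes and
kilobase-range genome fragments. The shipped studies use 3–4 kb
genomes and ~200-aa proteins; a 40 kb × 40 kb pair is feasible in
score-only terms but the traceback matrices make memory the binding
constraint above ~10 kb per pair.

## Attachment-site calling

`find_direct_repeats` enumerates all maximal exact common substrings
(≥ `min_core_length`, default 12 — below the shortest attB core in the
packaged table, 13 nt, with margin) between the two flank windows via
diagonal run-length scanning; each occurrence pair is reported once.
Only exact repeats are considered: attL/attR are presented as
identical repeats, and mismatch tolerance would blur the maximality
criterion.

`call_att` scans `flank_bp` (default 2000) outward and `inner_bp`
(500) inward of each rough prophage end, then ranks candidates by a
total order: tRNA 3′-end reconstitution first, then core length, then
summed distance of the repeat pair to the rough ends, then leftmost
position. Reconstitution holds when the att copy on the intact-tRNA
side overlaps or immediately abuts the 3′ terminus (attL/end for
plus-strand tRNAs, attR/start for minus-strand). attB is reported as
the core with `context_bp` (10) of host context on each side after
notional excision of `[attL_start, attR_start)`; attP as the core with
the cassette-interior context joined circularly. Site class: tRNA if
reconstitution holds, gene_disruption if the insertion boundary lies
inside a CDS, intergenic otherwise.

Misses in the recovery study occur only when a random flank happens to
contain a spurious repeat that outranks the planted one; at 2-kb
flanks and cores ≥15 nt this is rare (recovery 100/100 at the shipped
seeds).

## GC boundary refinement

Host background GC is estimated from the sequence outside the rough
interval. Window GC is computed at `window`=1000, `step`=250; a window
qualifies when its *signed* deviation from background — the sign fixed
by the midpoint windows — is at least `min_contrast` (2.5 points), and
the refined interval is the maximal contiguous run of qualifying
windows containing the rough midpoint. Two numerical details matter:

* window noise: the GC s.d. of a 500-bp window at 60–65% GC is ≈2.1
  points, comparable to the 2.5-point threshold, so 500-bp windows
  break runs and extend them spuriously; 1000-bp windows (s.d. ≈1.5)
  are the default for this reason;
* straddle bias: a window passes once roughly
  `min_contrast / contrast` of it lies inside the prophage, so run
  edges overshoot systematically; the edges are pulled in by
  `window · (1 − min_contrast/ĉ)` with ĉ the contrast estimated from
  the run interior.

When the midpoint windows show no qualifying contrast the rough
interval is returned unchanged with a flag. At the shipped study
condition (58% cassette in a 65% host, a 7-point contrast representative
of the catalog's prophage/host pairs) 95–99% of refined boundaries land
within one window of truth; at contrasts near 4 points the hard
threshold becomes unreliable and the flag should be trusted over the
coordinates.

## Networks

Reciprocity is evaluated per protein pair from a single exact DP: the
optimal local alignment is direction-independent, so the two
directions differ only in which side coverage (on the respective
query) and the E-value m are computed. A pair qualifies when identity
≥ 80% and both directions pass coverage ≥ 75% and E ≤ 1e-10
(database-style n per direction). "Number of common proteins" (the
edge weight) is defined as the size of a greedy one-to-one matching by
descending bit score — symmetric, bounded by the smaller proteome, and
auditable (matched pairs are stored on the edge). The
protein-identity network evaluates coverage on the shorter sequence.
Components come from graph traversal; orphans are degree-0 nodes.
GraphML/GEXF exports round-trip nodes, edges, weights and attributes
(GEXF serializes weights as floats; integral weights are restored on
load).

## Ribbon comparison

Both strands of every unordered pair are compared
(reverse-complement coordinates are mapped back to the forward
strand), HSPs filtered at E ≤ 1e-100. Identity bins <85 / 85–95 /
95–99 / ≥99 partition the scale and follow the stated ribbon-colour
semantics (percent identity, not score ratio). Near-identity (99%
identity, 95% mutual merged coverage) is deliberately strict so that
whole-element duplicates, not shared modules, form the class; the
classification is symmetric by construction.

## Problem sizes

The shipped tests and the acceptance script use 12-kb hosts with 3–4
kb cassettes (2-kb flank windows for att discovery), 100 simulations
per recovery study, proteomes of ~180–250-aa proteins, and 3–4-kb
ribbon genomes. These sizes exercise every code path at full
statistical resolution for the planted-truth questions being asked;
the algorithms themselves take arbitrary sequences subject to the
memory note above.

## Known limitations

* Exact DP only — no seeding, so genome-scale all-vs-all runs are
  quadratic; the engine is a desk-scale substrate, not a BLAST
  replacement.
* Exact direct repeats only; degenerate att cores (IUPAC ambiguity)
  are matched in fixtures but not called.
* GC refinement assumes a single contiguous island containing the
  interval midpoint; nested or adjacent islands merge.
* The catalog is a transcription of printed tables; two rows carry
  internally inconsistent size/coordinate data, which the audit
  surfaces but cannot resolve.
* Module-category labels are consumed from annotations (GFF3
  attributes or the keyword table); no gene calling, HMM scanning or
  family classification is performed.
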