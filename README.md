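# paravirome

Prophage mining and comparative genomics for the *Paracoccus* virome —
a reusable pipeline covering prophage completeness screening,
attachment-site (attL/attR/attB/attP) discovery, GC-contrast boundary
refinement, reciprocal protein-similarity (gene-sharing) networks,
whole-genome ribbon comparison, and a virome catalog that reproduces
the census of 66 *Paracoccus* (pro)phages from its packaged table.

It is aimed at phage/prophage genomicists who want each analysis step
as a tested, scriptable library function rather than a chain of web
services, and at method developers who need synthetic lysogens with
machine-readable ground truth to benchmark prophage callers.

## What it computes

**Catalog census.** The packaged TSV lists every virome member (5
mitomycin-C-induced temperate phages, 59 in-silico prophages of which
53 are novel, 2 lytic phages) with host, family, lifestyle,
integration strategy and site, genome size, GC% and replicon
coordinates. Census functions recompute all printed statistics —
virome size, lysogen and polylysogen counts, family tallies,
integration-site and recombinase-class tallies — and audit stated
genome sizes against coordinate spans.

**Attachment sites.** An integrated prophage is flanked by direct
repeats attL/attR sharing a common core; excising `[attL_start,
attR_start)` restores the bacterial site attB and circularizes the
phage around attP. `attsites.call_att` scans a window (default 2 kb)
around each rough prophage end for all maximal exact repeats, prefers
candidates whose upstream copy reconstitutes an intact tRNA gene
(3′-end integration, the most common target), and derives attB/attP.

**Alignment engine.** Exact Smith–Waterman/Gotoh affine-gap local
alignment (numba-accelerated, deterministic tie-breaking), with
Karlin–Altschul statistics

    bit = (λ·S − ln K) / ln 2,      E = m·n·2^(−bit)

using BLOSUM62 (gap 11/1, λ=0.267, K=0.041) for proteins and +2/−3
(gap 5/2, λ=0.625, K=0.41) for nucleotides. Greedy subject-masking
yields non-overlapping HSPs for multi-region comparisons.

**Gene-sharing networks.** Two phages are connected when at least one
protein pair is reciprocally similar (E ≤ 1e-10, HSP query coverage ≥
75%, identity ≥ 80%); the edge weight is the count of one-to-one
reciprocal pairs. Marker networks (integrase, large terminase, major
capsid) and a protein-identity network (≥80% identity over ≥75% of
the shorter sequence) follow the same machinery. Graphs are networkx
objects exported to GraphML/GEXF/TSV.

**Ribbon comparison.** All-vs-all nucleotide HSPs on both strands at a
stringent E-value (1e-100), binned by identity for ribbon colouring,
and classified per genome as unique, near-identical to a partner
(≥99% identity over ≥95% mutual coverage), or locally similar.

**Synthetic data.** `synthetic` generates host replicons at a target
GC with tRNA genes, plants a modular phage cassette (integration,
lysis/lysogeny switch, replication, packaging, head–tail, lysis) with
a duplicated att core at a tRNA 3′ end / inside a CDS / intergenic,
and emits proteome clusters with planted pairwise identity — all with
a `PlantedTruth` record sufficient to score recovery.

## Worked example

```
$ paravirome catalog-stats | head -5
virome_size     66
lysogens        29
polylysogens    14
family_Myoviridae       2
family_Podoviridae      8
```

66 unique virome members; 29 host strains carry at least one
prophage, 14 of them more than one.

Simulate a lysogen and recover the planted attachment site:

```
$ paravirome simulate --seed 7 --host-length 12000 --phage-length 3000 --outdir simdemo
lysogen written to simdemo (prophage at (6056, 9095))
$ paravirome att --genome simdemo/lysogen.fasta --features simdemo/lysogen.gff3 \
      --prophage lysogen:6056-9095 --out att.tsv
att core CTTTGTTGCAGGGGGGGGCG (tRNA)
$ cut -f1-8 att.tsv
att_core  core_length  attL_start  attL_end  attR_start  attR_end  site_class  target_feature
CTTTGTTGCAGGGGGGGGCG  20  6056  6075  9076  9095  tRNA  trna_1
```

The called 20-nt core and both repeat intervals are exactly the
planted ones: the upstream copy ends at the tRNA 3′ terminus, so the
site is classified as a tRNA-reconstituting integration.

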