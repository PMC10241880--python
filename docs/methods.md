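# Methods

## Coordinates and data model

All internal coordinates are 0-based half-open; GTF/GFF3 (1-based closed)
and BED (0-based half-open) conventions are converted only at the I/O
boundary.  A transcript is an ordered chain of non-overlapping exons on one
strand; introns are the gaps between consecutive exons.  The TSS and TTS
are strand-polar genomic points (first exon start on `+`, last exon end on
`-`, and symmetrically for the TTS).  Transcripts with identical exon
chains within a gene are collapsed at read time (first id kept, warning
logged) so pairwise comparison never reports self-events.

## TE location classification

Three successive filters precede chimera calling:

1. **Gene-like removal.**  A gene model is dropped, with all its
   transcripts, when its biotype is `transposable_element_gene` or when
   some TE covers ≥ `gene_like_reciprocal_fraction` (default 0.8) of the
   gene's exonic length while the gene span reciprocally covers the same
   fraction of the TE.  TEs triggering the reciprocal rule are flagged and
   excluded from all downstream calling: they are annotation duplicates of
   the gene, not TEs inserted into it.  The 0.8 default is an explicit,
   logged configuration value.
2. **Intergenic vs intragenic.**  A TE is intragenic when it overlaps at
   least `min_intragenic_overlap_bp` (default 1) of a surviving gene span;
   every qualifying gene is recorded as a host.
3. **Intronic vs exonic.**  An intragenic TE is exonic when it overlaps
   ≥ 1 bp of any exon of any isoform of a host gene; exon status has
   priority over intron status (default), because a TE that is intronic in
   one isoform but exonic in another is precisely an intron-retention
   candidate and must not be hidden in the intronic class.

Strand is ignored in all three steps: antisense TE insertions form
chimeric transcripts as readily as sense insertions.

## Chimera calling

A TE-G transcript call is a (transcript, TE) pair whose total exonic
overlap reaches `min_chimera_overlap_bp` (default 10 bp; 1 bp would accept
spurious boundary touches).  Overlapped exons are recorded as
first/internal/last positions on the transcript's own chain by strand; a
single-exon transcript's exon is both first and last.

## Event taxonomy and operational rules

Events are defined pairwise between isoforms of one gene (not against a
single reference model); identical findings reached through different
isoform pairs are reported once.  For a pair (A, B) on the same strand,
with "donor" the 5′ and "acceptor" the 3′ splice site of an intron:

- **IR** — an intron of A lies inside a single exon of B and A's flanking
  exon outer boundaries equal that exon's boundaries within
  `boundary_tolerance_bp` (default 0, exact; junction wobble is the
  business of upstream assembly, which supplies the isoform models).  The
  region is the intron; the retaining isoform is `iso_with`.
- **ES** — an internal exon of A overlaps no exon of B while both flanking
  exons of A share their adjacent junction with B.  The region is the
  skipped exon; the including isoform is `iso_with`.
- **A5SS / A3SS** — two introns (one per isoform) share their acceptor
  (resp. donor) but differ at the other junction.  The region spans the
  two alternative junctions, and it must lie entirely inside one exon of
  exactly one isoform (`iso_with`, the isoform whose exon extends into
  the region).  This exon-coverage requirement is what separates genuine
  alternative splice sites from artefacts of skipped exons or alternative
  first/last exons, which would otherwise satisfy the shared-junction
  condition.
- **ATSS / ATTS** — the strand-polar termini differ by at least
  `atss_min_shift_bp`/`atts_min_shift_bp` (default 100 bp, so that
  indistinguishable degradation-length variants are not called), or the
  terminal exons do not overlap at all.  The region is the non-shared
  terminal segment, clipped to exonic bases of the extending isoform.
  Subtypes AFE/ALE mark disjoint first/last exons.

An event becomes an ATE-G call when its (exon-clipped) region overlaps a
chimeric TE of the gene by ≥ 1 bp; the TE must also not be gene-like.

Two exact symmetries follow from these definitions and are enforced by
tests: reversing all coordinates *and* flipping strands is a pure
relabeling that preserves every event; reversing coordinates alone
exchanges donor/acceptor and start/termination roles, mapping A5SS↔A3SS
and ATSS↔ATTS.

## Superfamily enrichment

Within an event category (single event type, or the AS = {IR, ES, A5SS,
A3SS} and ATP = {ATSS, ATTS} groups), the population is the N TEs that
survive gene-like removal; K is a superfamily's population count, n the
number of distinct TEs in the category and k the observed superfamily
members among them.  Expected = K·n/N, fold-enrichment = k/expected, and
p-values are hypergeometric tails P(X ≥ k) and P(X ≤ k), BH-corrected
across superfamilies within each category (both raw p and q are emitted).
The inverted ratio expected/k is additionally emitted as `fold_printed`
for traceability with conventions that report it that way.

## Splice-site windows

For every TE-IR event the retained intron contributes one donor and one
acceptor site (the first and last intron base, strand-aware).  Sites are
de-duplicated on (chrom, position, strand, type); each becomes a 9-nt
window (site base ± 4 nt), kept only when the window overlaps a TE
involved in IR events, and its sequence is extracted 5′→3′ on the
transcript strand, so canonical introns read GT at intron +1/+2 in donor
windows and AG at −2/−1 in acceptor windows.  Position labels follow
splice-site nomenclature without a zero: donors run exon −4..−1 then
intron +1..+5, acceptors intron −5..−1 then exon +1..+4.  The
position × base matrix reports counts, frequencies, fold versus a
background (genome base composition by default, uniform 0.25 by flag) and
the hypergeometric upper tail of a subset drawn from the full window set.
`N` bases are excluded from counts and logged.  Windows extending past a
contig end raise an error rather than silently truncating.

## Poly(A) windows

Anchors (read 3′ ends or database sites) become windows of anchor
± `flank` (default 10 bp, i.e. 21 bp wide).  Windows are intentionally not
merged — each anchor is evidence.  Windows running off the contig start
are clamped at 0 with a warning.  Per ATTS-event TE the table reports
whether any window overlaps it, how many, and the per-source breakdown;
the summary is the fraction of ATTS TEs with ≥ 1 site.  Strand-aware
matching is available but off by default, since the intersection is a
plain positional one.

## Methylation calling

The per-context error rate is the pooled ratio Σmc/Σ(mc+umc) over an
unmethylated control contig (e.g. a mitochondrial genome).  Each covered
cytosine is tested one-sided against Binomial(coverage, error rate);
q-values are BH within each context (a per-context correction keeps the
very different CHH site counts from distorting CG calls), and
`called_methylated` requires q < 0.01.  Non-significant sites are treated
as unmethylated: when TE summaries are computed from called records
(default), their methylated counts contribute zero.  TE percent
methylation is the coverage-weighted pool 100·Σmc/Σ(mc+umc) over covered
sites inside the TE, reported per context only with ≥ 5 covered
cytosines; a per-site-mean variant is available by flag because pooling
lets a single deep site dominate.  With a second sample, the difference
in percent versus that control sample is attached wherever both pass the
coverage floor.

## Synthetic-data generator

Each gene occupies a 1.1 kb template window (200 bp flanking margin,
400 bp inter-gene gap, 25 genes per chromosome) and is built from one
fixed geometric template per event type — or a single-isoform "none"
template — so the planted event's identity, region, direction and TE are
known exactly.  Templates are laid out on the `+` orientation and mirrored
in place for `-` strand genes; every planted intron gets canonical GT..AG
boundary dinucleotides written into the genome strand-aware.  The IR
template's TE spans the retained intron including both splice sites, as
exonized TEs do — interior-only TEs would never retain their splice
windows.  Alternative termini differ by 200–250 bp, well above the 100 bp
calling threshold.

Defaults define the study conditions: 60 genes (5 of each of the 8 event
templates plus 20 event-free genes), 150 TEs (planted event TEs are
exonic; event-free genes carry alternating exonic/intronic TEs; the
remainder are intergenic with fraction 0.3 of the extras), GC content
0.36, superfamily weights over the common plant TE vocabulary (LTR/Copia,
LTR/Gypsy, TIR/Mutator, TIR/CACTA, Harbinger, Helitron, TIR/hAT),
methylation profiles that hypomethylate exonic (event) TEs relative to
intronic and intergenic TEs, cytosines at 50 sites × depth 20 per TE
cycling CG/CHG/CHH, a 2 000-cytosine control contig at error rate 0.005,
and poly(A) anchors planted inside 70% of alternative-termination TEs
(the others get an anchor outside the TE).  A `noise` mode adds duplicate
isoforms for robustness testing.

What the generator does *not* emulate: realistic TE sequence content,
junction wobble from raw long reads, overlapping genes, nested TEs, or
biased coverage in methylation data.  Passing tests therefore demonstrate
the correctness of the classification logic and statistics under clean
annotations — exactly the contract of an annotation-driven caller — not
robustness to assembly noise, which belongs to the upstream tools that
produce the isoform models.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately small instances chosen to
make every oracle exact: 200 random instances of ≤ 50 genes/≤ 200 TEs
compared base-by-base against a bitmap oracle; 20 seeds × 20 genes per
event type for planted recovery; exhaustive hypergeometric enumeration for
all populations N ≤ 60; 20 simulation seeds for the methylation null and
poly(A) fraction checks.  Ties in window-to-TE attribution are broken by
largest overlap then TE id; all result tables are written in a fixed sort
order so repeated runs are byte-identical.  Seeds derive from a single
integer; every random draw flows through one `numpy` generator per
simulation.

## Known limitations

- Event definitions are pairwise; a gene with many isoforms can produce
  overlapping event reports that are de-duplicated only when identical in
  (event, subtype, region, TE).
- Mutually-exclusive-exon events are not part of the taxonomy.
- The ATSS/ATTS region is reported as the hull of the exon-clipped
  terminal segments; TE overlap is evaluated against the segments
  themselves.
- Isoform usage quantification, GO enrichment, group statistics
  (e.g. Mann-Whitney comparisons between TE classes) and all read-level
  processing are out of scope; the output tables are shaped for direct
  consumption by standard tools for those steps.
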