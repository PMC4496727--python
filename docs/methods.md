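# Methods

This note describes the models and procedures implemented in `isoscan`, the
parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the known limitations.

## The gene model

`isoscan.ghmm.GhmmSpec` is a generalized (explicit-duration) hidden Markov
model in the GENSCAN family.  States are intergenic `N`; exon states
`Einit`, `Eint`, `Eterm`, `Esngl` (single-exon gene); and one intron state
`I`.  Reading-frame phase and the bases of codons split across introns are
carried as path bookkeeping rather than as separate state copies, which
keeps the state set small while preserving exact ORF semantics.  The exact
internal design of the predictor this model class emulates is not public, so
the topology, window sizes and chain orders below are explicit, configurable
stand-ins rather than a reconstruction.

**Emissions.**  Each base of a path is emitted by exactly one submodel:

- noncoding content (intergenic and intron interiors): homogeneous k-order
  Markov chain (default k = 2);
- coding content: three k-order Markov chains, one per codon position; the
  terminal stop codon is drawn from its own three-way distribution;
- signal windows, emitted by position weight matrices *instead of* the
  content chains: the first 6 intron bases (donor; GT fixed), the last 13
  intron bases (acceptor; AG fixed) and the ATG start triplet.  Each window
  lies wholly inside its own segment.  An earlier design scored wider,
  exon-overlapping windows *on top of* the content chains; because every
  window base was then emitted twice, gene-containing paths carried a large
  systematic penalty relative to all-intergenic explanations of the same
  bases and sampled structures were not recoverable by decoding.  The
  in-segment windows make the model generatively self-consistent.

Hard constraints are structural, not probabilistic: exons start genes with
ATG, terminate them with an in-frame stop, contain no internal in-frame stop
(including codons split across introns), introns begin GT, end AG, and are
at least 20 nt.  Violations score −∞.  Consensus bases required by a signal
(GT/AG/ATG) score as probability 1 in the PWM; their information lives in
the hard constraint.

Two numerical conventions matter to the decoder.  First, all arithmetic is
in log space; desk-scale sequence lengths need no further scaling.  Second,
the first min(k, length) bases of every segment's content region are scored
uniformly (1/4 each), so a segment's score never depends on its neighbours;
this makes the dynamic-programming cell state exact and keeps the model
sub-normalized (the total probability of all legal paths of a sequence is
at most 1, which the test suite verifies by exhaustive enumeration on short
sequences).

**Durations.**  Exon states use empirical histograms with additive
pseudocounts (an optional geometric tail is supported but off in the
bundled models); introns and intergenic gaps are geometric with hard minima
(20 nt and 1 nt).  Every exon is at least 3 nt so that split-codon bases are
always a contiguous suffix of the upstream exon — a simplification that
costs almost nothing biologically and keeps the intron cell key finite.

**Training** (`ghmm.train`) is maximum-likelihood counting with additive
pseudocounts (default 1): transition frequencies from single/multi-exon gene
counts and intron continuation counts, duration histograms, PWM columns from
aligned signal windows (out-of-bounds windows skipped with a logged count),
content chains from spliced CDS (by codon position) and from intergenic plus
intron-interior sequence.  Reverse-strand genes are mirrored onto the
forward strand of the reverse complement before counting; the same mirroring
is used at decode time, halving the state count.

**Sampling** (`ghmm.sample`) draws gene layouts from the transition and
duration models, then emits a complete ORF from the coding chains (interior
stop codons rejected), splits it by introns, and emits signal windows from
the PWMs and noncoding stretches from the noncoding chain.  Sampling is
deterministic under a seed.  The sampler conditions chain contexts across
segment boundaries where the scorer resets them (the uniform-first-k
convention); the discrepancy is at most k bases per segment and is invisible
in practice.

## k-best decoding

`decode.kbest_decode` is a list-Viterbi dynamic program.  A cell is
(segment end, state, phase, split-codon bases); each cell keeps the N
highest-scoring partial paths.  Because future scores depend only on the
cell key, every globally top-N path has a top-N prefix in each cell it
passes through, so per-cell lists of size N are lossless.  Candidate
boundaries are restricted to signal anchors — ATG, GT, AG and stop codons —
and terminal exons end at the *first* in-frame stop, which makes the search
sparse enough for pure-Python decoding of multi-kilobase sequences.

Ranking is deterministic: ties in score are broken lexicographically on the
(state, segment-start) encoding of the path, so the top-k list for k < N is
a prefix of the top-N list.  The unit tests verify, for hundreds of random
≤ 30 nt sequences under a reduced model, that the decoder's top-5 equals
brute-force enumeration of *all* legal segmentations in both membership and
order.

Decode-time truncations: intron length is capped (default 500 nt, against a
geometric model whose mass beyond 500 is ~4·10⁻⁴ under the fixture
parameters) and exon lengths are bounded by their histogram support.

Post-processing follows the published recipe: transcripts without a
complete ORF are dropped, transcripts containing an intron below the
minimum are dropped, and transcripts sharing identical CDS coordinates are
merged keeping the highest-scoring representative.  `cluster_loci` merges
same-strand transcripts whose genomic extents overlap by ≥ 1 bp
(single-linkage, so one long transcript can bridge two clusters), and
`evaluate_predictions` scores exact-CDS matches at transcript and gene
level.  A decoded path may contain several genes (or none), so the decoder's
`ScoredPath` carries a tuple of transcripts.

## RNA-seq validation

Mature transcripts are the spliced CDS with 100 nt genomic flanks on each
side (truncated with a warning at chromosome ends), reverse-complemented
for minus-strand genes.  Reads are consumed as ungapped transcript-space
alignments (SAM against the matures), because junctions appear as
contiguous matches there; gapped or clipped records are rejected with a
logged count.

A junction at mature offset j is covered by read [s, s+len) iff
s ≤ j − L and s + len ≥ j + L; a junction is validated in a dataset when at
least M such reads exist.  The standard rule is (L = 10, M = 1); the
stringent rule is M ≥ 6 and L ≥ 8, with defaults (8, 6) — the most
permissive integers satisfying the strict inequalities.  Counts for the
same genomic junction occurring in several matures are pooled.

A multi-exon transcript is validated in a dataset iff *all* its internal
junctions are covered there.  Tiers for novel transcripts (those whose CDS
is absent from the known set):

- **VHC** — validated under the stringent *and* standard rules in ≥ 1
  dataset, with ≥ 1 novel internal junction (NIJ);
- **VMC** — validated under the standard rule with ≥ 1 NIJ;
- **VLC** — validated under the standard rule but single-exon or without
  any NIJ;
- known transcripts become KNOWN_VALIDATED or UNVALIDATED.

VHC is defined hierarchically (a VHC call always meets the VMC criteria).
This is a definition, not a theorem: with stringent L = 8 below standard
L = 10, a junction could in principle reach 6 reads at 8 nt overhang with
none at 10 nt, so nesting is imposed rather than assumed.  Two further
stand-ins where the published rule is not recoverable in full detail: a
single-exon transcript (which has no junctions) is validated when ≥ 90% of
its CDS bases are covered by ≥ 1 read, and an optional
transcript-coverage knob (`min_tc`, default 0 = off) can additionally
require a minimum covered CDS fraction for multi-exon transcripts.
Tissue specificity means validated in at least one but fewer than five
datasets ("datasets" and "samples" are treated as synonymous, one merged
dataset per biological sample).

`saturation_curve` averages, over random dataset orderings, the number of
transcripts newly validated by each added dataset (deterministic under a
seed); `pcr_panel_summary` turns per-transcript assay outcomes into
per-tier success rates, reported both as fractions and as percentages
rounded to one decimal.

## AS event classification

Events are called pairwise between the CDS structures of isoforms of one
gene (UTR-only differences are ignored), then deduplicated by
(gene, category, signature), where the signature is the set of
distinguishing splice-site or CDS-boundary offsets.  Event magnitude is
measured by the signature's site count, so categories remain comparable
across datasets.  The seven categories and their predicates:

- *exon skipping*: an internal exon of one isoform, absent from the other,
  whose flanking junctions are fused into a single junction there
  (signature: the skipped exon's two sites);
- *alt donor / alt acceptor*: two junctions sharing one site, with
  overlapping exons on the differing side (the overlap requirement keeps
  these disjoint from skipping and mutually exclusive exons); donor/acceptor
  assignment is strand-aware;
- *intron retention*: an intron of one isoform strictly inside a CDS exon
  of the other;
- *mutually exclusive exons*: two non-overlapping internal exons replacing
  each other between shared flanking junctions, with no skipping junction
  present (4 sites);
- *alt translation start / stop*: differing CDS boundary offsets
  (strand-aware; these reflect transcriptional rather than splicing
  variation but are counted among the categories).

The formal definitions behind the published seven-way split are not public;
the predicates above are a reconstruction chosen to be symmetric, brute-
force checkable (the tests compare against all-pairs classification with
independent deduplication), and disjoint on the canonical textbook cases.

`transcripts_per_gene_stats` reports the transcripts-per-gene histogram
(genes with more than 20 isoforms merged into one bucket), the mean, and
the fraction of multi-exon genes carrying a single transcript.

## Proteogenomic filtering

From peptide hits against a combined reference + candidate protein
database: preliminary novel peptides are those scored only against the
candidate database (membership pooled per peptide sequence across hit
rows).  A candidate protein is called novel when mapped by at least two
unique peptides including at least one novel peptide; uniqueness is
evaluated against candidate accessions only, because a reference match
makes a peptide non-novel without disqualifying it as protein-level
evidence.  The external annotation filter then removes calls whose novel
peptides all occur verbatim inside a GENCODE or Swiss-Prot protein — exact
substring matching standing in for a protein-level alignment search, which
is deterministic and conservative at tryptic-peptide lengths.  Spectral FDR
control is upstream of this module; hits are taken as given.

## The census estimator

With I+II the predictions consistent with the known annotation, III the
expected true novel validated transcripts (validated-novel count × assay
precision), IV the true novel transcripts among unvalidated predictions
(0 in lower-bound mode), and K the known-set size, the estimator assumes
the sensitivity measured on known transcripts, Sn = (I+II)/K, extends to
undiscovered transcripts, giving total = (I+II + III + IV)/Sn.  With
III = IV = 0 the estimate reduces to K exactly.  The precision default
applies the percentage rounded to one decimal (the convention of the
published worked example: 31,566 × 84.1% = 26,547); the exact assay
fraction is available behind a flag.  A helper recovers K from a printed
(count, percent) pair — 40,797 / 73.94% ≈ 55,176 — since the set size
itself is never printed; the resulting estimate is 204,947, within 0.1% of
the published 204,950 (the residual is the rounding of K).  No confidence
interval is attached: the estimator is a point lower bound.

## Synthetic fixtures and what passing tests mean

The fixture model (`fixtures.fixture_spec`) uses sharply constrained splice
signals (strong donor consensus GTAAGT, a pyrimidine-tract acceptor),
codon-position-dependent coding composition, uniform exon-length histograms
(30–150 nt), geometric introns (min 20, mean ≈ 80 nt) and geometric
intergenic gaps (mean 150 nt) — compact-gene conditions under which a 2 kb
genome holds 3–5 genes and decoding is fast enough to repeat across
hundreds of seeds.  Read simulation places junction-spanning reads with a
deterministic overhang schedule (L + 0, 2, 5, 9 nt on the short side),
including exact-boundary reads, plus tiling reads for transcript-body
coverage; a per-junction truth table is emitted alongside.  Default
problem sizes in the test suite — 2 kb genomes, top-150/300 candidate
lists, 20–100 seeds, 8 reads per junction — were chosen so the full suite
exercises every pipeline stage at meaningful depth on a single CPU.

The generator emulates the *structure* of the problem, not its full
biology: no UTRs or promoters, no GC-isochore variation, no expression-level
or positional read bias, error-free reads by default (a substitution knob
exists but alignment is assumed solved upstream), and genes denser and more
compact than in real vertebrate genomes.  Passing the closed-loop tests
therefore shows that the algorithms are mutually consistent and correct on
their own model — it does not certify performance on real genomes, where
signal models are weaker and the search space larger.

## Known limitations

- The decoder is exact only up to its duration caps; a sampled intron
  longer than `max_intron` makes that structure unreachable (probability
  ~4·10⁻⁴ per intron under the fixture model).
- Junction-level validation cannot distinguish isoforms that share all
  splice junctions and differ only at translation boundaries; such variants
  reach VHC alongside the true structure (visible in the README example).
  This is inherent to the method and is precisely what the PCR-precision
  deflation of the census corrects for.
- Whole-genome scale is out of scope: the decoder is pure Python and is
  meant for candidate regions of tens of kilobases at most.
- The AS-category predicates and the single-exon validation rule are
  reconstructions where the original definitions are not public; both are
  isolated behind documented functions and flags so alternative conventions
  can be swapped in.
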