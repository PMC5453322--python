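# Methods

## Model and procedure

`exont` treats a coding exon as the genomic footprint of a protein
segment and measures, for each ontology term, how much of an exon
set's coding sequence encodes features carrying that term.

**Coordinate projection.** A protein feature on transcript *t*
spanning amino acids `a..b` (1-based inclusive) occupies coding
nucleotides `3(a−1)+1 .. 3b`. These indices are threaded through the
transcript's CDS segments in coding (5′→3′) order — ascending genomic
positions on the plus strand, descending on the minus strand — and the
resulting genomic intervals are split at CDS-segment boundaries. The
projection is exactly length-preserving (3 nt per aa) before exon
clipping; a codon split across a junction contributes nucleotides to
both flanking exons. Projected intervals are clipped to the coding
sub-interval of each overlapping exon of the same gene, and intervals
of the same (exon, term) pair are unioned, so a nucleotide covered by
two features of one term counts once.

**Exon universe and categories.** The universe is the set of distinct
genomic exons per gene that overlap CDS in at least one transcript.
Position categories (first / internal / last coding) are assigned per
gene in transcription order on the union of coding exons; a
single-coding-exon gene contributes a first-coding exon and is logged
out of internal pools. An exon is *constitutive* when an exon with
identical genomic coordinates appears in every transcript of its gene,
*alternative* otherwise. This exact-coordinate rule is a reproducible
proxy for evidence-based inclusion calls from transcript databases,
which depend on curation thresholds not available here; user exon
lists are matched exactly first, then by ≥90% reciprocal overlap with
a warning.

**Ontology.** Terms form a DAG of `is_a` links (multiple parents
allowed — source ontologies are DAGs even when drawn as trees) sinking
into eight root classes of protein features. A term reachable from
several classes takes the class of its nearest root and is flagged.
Hit propagation to ancestors is ON by default for enrichment (leaf
terms are individually sparse and powerless) and OFF for per-exon
annotation reports (reports should show primary evidence); both are
flags.

**Score.** `score(h, E) = 1000 · covered_nt / total_coding_nt`
(nucleotides per kilo-nucleotide). The nt/knt unit is adopted over the
equivalent dimensionless fraction; the two differ by a constant and
give identical Z-scores. The set score pools numerators and
denominators and therefore equals the coding-length-weighted mean of
per-exon scores; it is invariant to splitting an exon at any coding
position.

**Null and inference.** Null sets are drawn uniformly without
replacement from the chosen control pool, stopping at the first exon
that brings the cumulative coding size to the target (the test set's
size), so realized sizes overshoot by less than one mean exon length.
Nulls are sampled on the fly from a seeded generator rather than from
precomputed size-binned distributions: desk-scale pools make sampling
cheap and remove the binning approximation (a cache would be an
optimization, not a statistical change). One pass per sampled set
scores all terms at once via an exon × term covered-nucleotide matrix.
Scores are log-transformed; a zero score is floored at the score of a
single covered nucleotide over the set's total size, which keeps the
log finite and preserves order. `z = (log s_obs − μ̂)/σ̂` with μ̂, σ̂
from the null log scores (sample SD, ddof 1). The default p-value is
the two-sided normal tail of z; an `empirical` mode computes
`min(1, 2·(1 + min(#null ≥ obs, #null ≤ obs))/(n_sets + 1))` for users
unwilling to lean on log-normality. BH adjustment runs over the tested
terms only; terms below the frequency filter (default 4% of the
control universe, measured with propagation ON) or with a degenerate
null are excluded. Test exons are not removed from the control pool by
default — the canonical designs (alternative vs constitutive exons)
are disjoint by construction — and `exclude_test` exists for
overlapping designs.

## Numerical choices

- Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive, BED 0-based half-open.
- A constant null's sample SD computes to ~1 ulp rather than exactly
  zero, so degeneracy is detected as `σ̂ ≤ 1e−12·max(1, |μ̂|)`; such
  terms are reported `untestable` with NaN z/p/q and skipped by BH.
- Results are sorted by q, then |z| descending, then term id, making
  output tables byte-stable for a fixed seed.
- CDS length not divisible by 3 is a warning, not an error (real
  annotations violate it); a CDS record outside its transcript's exons
  drops that transcript with a logged error.
- Stop codons are treated as part of the last CDS segment when the
  input includes them.

## Synthetic data: what it does and does not emulate

The generator emits multi-exon genes on both strands with UTR-bearing
terminal exons, skipping transcripts that create alternative internal
exons, per-term coverage painted as randomly placed overlapping
intervals (geometric lengths, mean ≈ 30 nt) at configured densities,
single-residue PTM sites, localization motifs inserted into protein
sequences, an interaction file with planted shared partners, and a
truth JSON. Exon coding lengths are drawn log-normally (median 130 nt,
clipped to [30, 2000], rounded to whole codons) to mimic human coding
exons. Coverage is planted within a single exon's codon range through
an independent random substream per (gene, exon, term) cell, which
makes planted term frequencies exact by construction and lets a
spike-in modify only its own cells, leaving every other byte of the
fixture unchanged.

Not emulated: junction-spanning features (covered instead by
hand-built fixtures in the unit tests), the human term-frequency
spectrum and 5000-term ontology, sequence-dependent annotation, and
transcript-evidence-based inclusion calls. Passing tests therefore
demonstrate correctness of the bookkeeping and calibration of the
inference under the stated generative model, not fidelity to any real
genome annotation.

## Study conditions used by the checks

The default fixture holds 30 genes (~220 coding exons, ~32 knt of
coding sequence) and 28 terms whose planted frequencies straddle the
4% filter. Calibration is assessed on test sets of ~80 exons — the
scale of a typical regulated-exon list and within the 100 nt – 32 knt
range over which null distributions are meaningful here — with 200
no-effect trials at 500 null sets each. Spike recovery uses the
fixture's 12-exon test list with a 3× density spike at 1000 null sets,
with propagation off, since with propagation on the planted term's
ancestor classes co-enrich (their coverage is a superset of the
child's) and can edge above it in z, which is correct behaviour but
muddies a rank-1 assertion.

## Known limitations

- The parametric normal tail is approximate for small test lists
  (≲ 20 exons) or sparse terms, where the log score distribution is
  discrete and skewed: per-term type-I error then deviates from
  nominal in both directions even though the pooled rate stays near
  0.05 at realistic list sizes. Use `mode="empirical"` when a test
  list is small.
- Statistical power at desk scale is modest: a 3× spike on a 12-exon
  list yields z ≈ 2–3 and always ranks first, but after BH across
  ~25 terms its q-value fluctuates around 0.05–0.4 depending on the
  realization; larger lists sharpen the null (σ̂ shrinks roughly with
  the square root of the list size).
- The constitutive/alternative call is structural (identical
  coordinates across the supplied transcripts); an annotation with
  incomplete transcript inventories will over-call constitutive.
- Localization-motif patterns ship as an editable configuration with
  conventional defaults (monopartite NLS `K[KR].[KR]`, bipartite NLS
  `[KR][KR].{10,12}[KR]{3}`, NES `L.{2,3}[LIVFM].{2,3}L.[LI]`, PTS1
  `[SAC][KRH][LM]$`); they are data, not code, and carry no claim of
  completeness.
- Protein→transcript resolution requires a provided id map; no remote
  lookups are performed.
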