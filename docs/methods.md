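# Methods

`contamscreen` estimates the foreign-DNA fraction of a prokaryotic
genome assembly with six complementary methods and aggregates them into
a consensus ranking. Everything runs against a synthetic reference
universe with exact ground truth, so every stage is testable without any
public database. This note describes the models, the defaults, and the
choices made where the design was genuinely open.

## The focal-clade trichotomy

All classifiers share one taxonomy (`taxonomy` module): a rooted tree
with a designated *focal clade* — the taxon the assembly is supposed to
belong to. A taxonomic assignment is interpreted as:

* **FOCAL** — inside the focal clade (ancestor-or-self relation);
* **CONTAMINANT** — outside the focal clade and not on its root path;
* **UNKNOWN** — a strict ancestor of the focal clade (e.g. a
  domain-level LCA). Such assignments are classified yet uninformative
  about contamination; they are counted in denominators but never as
  contamination, and never masked during decontamination, because real
  horizontally transferred genes tend to land exactly here;
* **UNCLASSIFIED** — no reference signal at all.

The UNKNOWN rule is structural (strict ancestors of the focal clade)
rather than a list of named high ranks, so it transfers to any taxonomy.
It may label more intermediate nodes UNKNOWN than a name-based
post-processor would.

## The six estimators

**SSU rRNA (`markers.detect_ssu`).** SSU-like loci are located by infix
(semi-global) alignment of each reference SSU against each scaffold,
both strands, iterating with masking to find multiple copies; calls need
an aligned span ≥ 300 nt at ≥ 70% identity, and overlapping calls merge
keeping the best. Each locus is labelled by its best-hit reference
taxon (top-1; a top-k LCA variant is a parameter). Contamination =
foreign loci / predicted loci; an assembly with no predicted SSU returns
a missing value. Alignment uses unit-cost edit distance (edlib) rather
than a match/mismatch scoring matrix: at a 70% identity threshold over
≥ 300 nt the two are interchangeable, and the edit-distance scan is what
makes all-versus-all scaffold×reference search feasible in Python.

**Ribosomal proteins (`markers.detect_rprot_orthologues`).** All
six-frame stop-free windows ≥ 30 aa are searched against the pooled
per-family reference panels; a candidate belongs to the family of its
single best hit (a mutual-best screen against paralogue capture), is
trimmed to its aligned span, and one window may yield several candidates
(the remainder around each aligned span is re-searched, since operon
neighbours can share a reading frame). Candidates whose aligned spans
overlap ≥ 50% deduplicate keeping the best bit score. Each candidate is
labelled by the LCA of its 3 most identity-similar references with
identity ≥ 70% and alignment ≥ 30 aa (ties broken by longer alignment,
then reference id). Contamination = foreign / classified candidates,
pooled over families; UNCLASSIFIED candidates are excluded from the
denominator (the SSU estimator divides by *predicted* loci — a known
asymmetry, kept because an unclassifiable protein candidate says nothing
about its origin).

**Single-copy redundancy (`markers.redundancy_estimate`).** With c_m
detected copies of marker m over a panel of M single-copy families:
completeness = 100·|{m : c_m ≥ 1}|/M and contamination =
100·Σ max(0, c_m − 1)/M. Contamination exceeds 100% when more than one
complete foreign marker set is present. Optional collocation merging
(hits of one family within 5 kb collapse into one countable unit)
emulates tools that count collocated marker sets; it is off by default.

**Signature kmers (`classify.classify_read_kmer`).** Assemblies are cut
into 250-nt non-overlapping pseudo-reads (trailing windows < 21 nt are
dropped — they contain no full kmer). A reference index maps every
canonical 21-mer to the LCA of all reference genomes containing it.
Per read, each kmer votes for its stored taxon; the candidate label is
the deepest node maximising the summed vote along its root-path (ties
resolved by the LCA of the tied nodes). Confidence = votes inside the
candidate's clade / all ACGT-only kmers of the read (hitless kmers
included in the denominator — the cited classifier's manual is ambiguous
here, so it is documented and configurable); while confidence < c
(default 0.04) the label is promoted to its parent, and failing at the
root means UNCLASSIFIED. Contamination = CONTAMINANT reads / all reads.
Assemblies that are themselves part of the reference index get a missing
value: their self-matches make the method uninformative.

**Protein LCA (`classify.classify_read_protein`).** Pseudo-reads are
translated in six frames and searched against the pooled reference
proteomes (Smith–Waterman, BLOSUM62, gap open/extend 11/1, bit scores
from the ungapped Karlin–Altschul constants λ = 0.3176, K = 0.134).
Hits to the assembly's own source genome are excluded; of the rest, hits
with ≥ 80 bits and within 95% of the best bit score collapse by LCA
(minimum 1 hit). The search uses an exact 5-mer amino-acid seed
prefilter requiring two shared words before alignment; at the 80-bit
threshold (a well-matched run of ~35 residues) this changes no retained
hit, and `seed_k=0` gives the exhaustive search used by the oracle
tests. Translated stops score −4 against everything (the BLOSUM62 `*`
column).

**Composition binning (`binning`).** 10-kb non-overlapping segments
(trailing remainders merge into the preceding segment; segments < 1 kb
are discarded) are summarised by canonical tetramer frequency vectors
(136 strand-symmetric classes, pseudocount 1, log-transformed),
centre-scaled, and projected onto the leading principal components (at
most 2 by default — with strand-symmetric tetramers the between-genome
signal concentrates there, while trailing components are segment-level
sampling noise). Diagonal Gaussian mixtures with 1..min(400, 12, n)
components are fitted and the count minimising BIC selected; the
covariance regulariser is 0.3× the mean projected variance, so splitting
only pays off for composition differences well above noise.
Contamination = 100·(1 − largest group share). Known failure mode,
asserted in the tests: hexamer vectors fragment the signal at this
segment size and recover the planted fraction worse than tetramers.

## Consensus

Each method ranks assemblies from most (rank 1) to least contaminated
with averaged ties; missing values stay missing. The global ranking
orders assemblies by the mean over their non-missing ranks (exact ties
broken lexicographically by assembly id — any rule works, this one is
deterministic). Spearman correlations are computed over
pairwise-complete observations. Contamination categories follow the
published banding for the redundancy estimator (0 / ≤5 / >5–10 / >10–15 /
>15%); per-method "flagged" thresholds are >0 for the three marker
methods and ≥1% for the three genome-wide methods (which rarely return
exactly zero); both are configurable.

## Coverage validation and decontamination

Per-segment records combine classification fractions (pseudo-reads
attributed proportionally to their overlap), GC, marker loci and mean
coverage; scaffolds are ordered by ascending mean GC for plotting.
Scaffold class is the length-weighted majority among classified
fractions. Coverage quartiles use linear interpolation (the common
statistical default); the assembly-level quartile coefficient of
dispersion is (Q3−Q1)/(Q3+Q1) over all segment coverages, per-segment
statistics unweighted by length. Coverage comes from a bedGraph track
or from the built-in naive mapper, which places error-free reads at
their unique exact match (either strand) and discards everything else —
adequate for synthetic reads; real data should bring a bedGraph from a
real mapper.

Decontamination masks every CONTAMINANT pseudo-read interval with N
(mask mode conserves scaffold count and lengths) or drops scaffolds
whose classified-contaminant fraction is ≥ 0.5 and masks the survivors.
Foreign-classified marker loci can be masked as well: rRNA regions carry
no protein-level signal, so pseudo-read labels alone systematically
spare foreign rRNA.

## The synthetic universe

`simulate` generates the study conditions end to end; its defaults *are*
those conditions.

* **Taxonomy**: root → domain → 5 phyla × 2 genera × 2 species; phylum 1
  is focal.
* **Composition**: phylum GC targets spread 35–65%. Protein families
  shared by the whole taxonomy are evolved by per-branch substitution
  (phylum/genus/species branches: 0.18/0.10/0.03 per residue), giving
  ≈94% amino-acid identity within genera and ≈74% within phyla — above
  and below the 70% marker-classification threshold respectively.
  Genes are reverse-translated once per genus with codon usage solved to
  hit the phylum GC target, then species apply amino-acid differences
  plus a 4% synonymous codon substitution rate — so genomes in one genus
  share long exact nucleotide stretches (populating genus-level index
  kmers) while phyla share essentially none. Intergenic spacers come
  from per-genome order-3 Markov chains inheriting phylum-level
  transition parameters. Realized genome GC lands within ±3 points of
  the phylum target.
* **Layout**: genomes are gene-dense (≈96% of length in genes, compact
  prokaryotic spacing, leftover length spread across all intergenic gaps
  rather than pooled — a 10-kb random-sequence desert would look like a
  foreign composition island). The 20 ribosomal-protein families
  (120–200 aa) form one operon-like cluster per genome, as real
  r-protein operons do; 1–4 identical SSU copies (1500 nt, 60% of
  positions in an immutable conserved core) are scattered separately.
  Every locus is registered.
* **Chimeras**: the host genome is fragmented (lognormal scaffold
  lengths ≥ 1 kb; fragment boundaries are snapped off marker loci so the
  registry stays exact), and contaminant blocks totalling f/(1−f)×host
  length are spliced in, each becoming its own scaffold or, at the
  chimeric-scaffold rate (default 0.1), concatenated onto a host
  scaffold. By default the blocks cover the contaminant's marker
  cluster and one SSU copy — the condition under which the redundancy
  estimator sees a full extra panel — and are drawn at the 10-kb
  analysis segment scale so the binning statistic's segment-count share
  tracks the base-count share. The realized contaminant fraction is an
  exact base count.
* **Reads**: uniform sampling within single-source intervals (reads do
  not cross chimeric junctions — a simplification) at organism-specific
  depths (defaults 68× host / 26× contaminant, the depth contrast
  observed in real contaminated assemblies), substitution errors at
  0.005/nt, both strands; the exact depth track is recorded.

What the generator does **not** emulate: repeats, plasmids, indels,
real rRNA secondary structure, assembly gaps, GC-biased sequencing
coverage, and real horizontal transfer. Passing tests therefore show
the estimators recover planted, well-separated contamination — not that
they would resolve the much messier boundaries of real data, where
reference incompleteness and HGT dominate the error budget.

## Problem sizes and determinism

Test and analysis runs use 300-kb genomes (20 reference genomes, ~290
ordinary gene families) for the main 10-pair chimera/clean battery and
the dose-response grid, 60–120 kb universes for the smaller checks;
these sizes keep a full battery in minutes on one CPU while every
segment-, marker- and read-level stage still has signal. All
randomness flows from explicit integer seeds through spawned numpy
generators; a fixed seed reproduces every sequence byte for byte.

## Known limitations

* The orthology heuristics of the marker search are a stand-in
  (single-best-hit family assignment); the original tool's heuristics
  are unpublished.
* The protein search is a seed-filtered full Smith–Waterman — fine at
  synthetic scale, not a replacement for a production aligner; external
  search output can be substituted through the 12+2-column tabular hit
  format.
* The binning estimator counts segments, not bases, so short foreign
  scaffolds inflate (and chimeric joins deflate) its estimate relative
  to the true base fraction.
* With very few segments (assemblies ≪ 1 Mb) the mixture fit cannot
  justify splitting off a single outlier segment; the estimator is
  designed for the hundreds-of-segments regime and degrades gracefully
  to 0 below it.
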