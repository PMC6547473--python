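# Methods

This note documents the models, algorithms and design choices behind `ngl`:
a small statically typed pipeline language whose interpreter performs
quality-based read trimming, host-read removal by alignment-length
filtering, and gene-catalog functional profiling, with reproducibility
guarantees built into the language itself.

## The language and its execution model

Scripts are imperative and statically typed with forward type inference.
The type system is closed: `ShortRead`, `ShortReadSet`,
`MappedShortReadSet`, `CountsTable`, `String`, `Integer`, `Bool`, `Void`.
`ShortReadSet` and `MappedShortReadSet` values are file-backed — they name
FASTQ/SAM files on disk rather than in-memory collections, because real
datasets do not fit in memory and because file-backing makes every stage's
output inspectable.

Every script starts with a version declaration (`ngless "1.0"`), and every
import names an explicit module version.  The interpreter accepts language
versions `0.9` and `1.0`; they differ only in that `0.9` accepts the
deprecated function alias `load_sample` (for `load_mocat_sample`), which
keeps the multi-version mechanism honest and testable without maintaining
two real dialects.

The statement subset is deliberately small: assignment, calls with
positional + keyword arguments, `preprocess(x) using |read|:` blocks with
indentation-delimited bodies, `if cond:` with `discard`/`continue`, `len()`,
comparison operators, string concatenation with `+`, and 1-based `ARGV`
indexing (`ARGV[1]` is the first command-line argument).  Loops and
user-defined functions are out of scope.  Blocks are indentation-delimited;
tabs are rejected and the pretty-printer emits canonical 4-space indents.
String concatenation is included because output paths are naturally built
as `ARGV[2] + ".OG.tsv"`; without it scripts could not name their outputs.

Semantics are exclusively pass-by-value.  At runtime this is free: every
stage returns a fresh value and rebinding is the only mutation the language
offers, so `y = x` can never alias-mutate `x`.

Type checking runs to completion and reports *all* findings (unknown
functions, unknown or mistyped keyword arguments, unbound variables,
unknown module versions) with line positions, before any data is touched.

## Pre-flight validation

Before execution, every literal input path, output target and reference
name in the AST is probed: sample directories must exist and contain FASTQ
files, registry references must resolve to existing FASTA files, output
directories must exist and be writable, and every `ARGV` index must be
covered by the provided arguments.  Constant folding over string literals,
`ARGV` and `+` recovers the concrete paths.  All findings are returned as a
list (not just the first), so one failed run surfaces every problem at
once.  The CLI turns a non-empty finding list into exit code 3 before any
stage runs.

## Determinism

Results depend only on the script and its inputs.  The runtime
configuration — thread count, temp directory, seed, `--keep-intermediates`
— may change how results are computed, never what they are; the test suite
asserts byte-identical outputs across repeat runs, thread counts and temp
directories.  Concretely this requires: counts tables sorted
lexicographically with fixed number formatting (up to six decimals,
trailing zeros stripped), gzip output written with a zeroed mtime and no
embedded filename, SAM output without a `@PG` line, and a run report that
serializes without wall-clock times (stage timings stay on the in-memory
`RunReport` object only, since timings are not a function of the inputs).
Execution is single-process and sequential; the parallelism contract
retained is the observable one (outputs independent of `--threads`), which
favours desk-scale correctness over throughput.

## Trimming algorithms

* `substrim(read, q)` returns the longest contiguous substring in which
  every base has quality ≥ `q`.  Ties between equal-length windows break to
  the leftmost (a free choice, fixed for determinism), and bases exactly at
  the threshold are kept (the rule is "at least the requested quality").
  Implementation: longest run of a boolean mask, O(n); verified against an
  O(n²) all-substrings oracle.
* `endtrim(read, q, from_ends)` strips only the maximal low-quality prefix
  and/or suffix (`"both"`, `"5"`, `"3"`); interior low-quality bases stay.
* `smoothtrim(read, q, window)` applies the substrim rule to a centred
  moving average of the qualities, window truncated at the boundaries, and
  returns the *original* bases/qualities on the selected window.  The
  window-mean comparison is done in integer arithmetic
  (`sum ≥ q × count`), so no floating-point boundary artifacts exist, and
  `window=1` reduces exactly to `substrim`.  The truncated-boundary moving
  average is this package's definition of the smoothing step.

The bundled profiles use `substrim` at quality 25 (the midpoint of the
commonly recommended 20–30 trimming range) and then discard reads shorter
than 45 bp, since shorter fragments multi-map excessively.  Both constants
appear verbatim in the bundled scripts for users to edit.  The 45 bp length
filter applies to the post-trimming length.

Preprocessing streams each file once, collecting QC (read/base counts in
and out, per-position mean quality before and after, output length
histogram, GC fraction) in the same pass — no extra I/O.  The QC metric
set itself is this package's choice.  Paired-end bookkeeping: if exactly
one mate survives, it is demoted to the group's singles file rather than
discarded (with `keep_singles=false` it is dropped and counted as
discarded), keeping usable data while preserving pairing invariants.  The
QC report is written next to the script's first write target as
`<target>.qc.tsv`.

## Quality-encoding detection

Offset 33 is inferred whenever any quality character is below `';'`.
Offset 64 is inferred only when the characters both allow it (all ≥ `'@'`)
and exclude offset 33 (some character beyond `'J'`, the Phred+33 encoding
of quality 41).  Ranges legal under both encodings default to 33 with a
logged warning.  Output FASTQ is always canonicalized to Phred+33.

## Mapping

Production mapping goes through external adapters (`bwa mem`, `minimap2`)
when those binaries are available; the package also ships a deterministic
builtin aligner so that the whole pipeline, including tests, runs with no
external binaries.  The builtin aligner indexes every reference k-mer
(k = 21), collects candidate diagonals from read k-mers (sampled every 5
positions, falling back to every position when the sampled seeds find
nothing — so a read is only declared unmapped after a full seed scan),
and evaluates each candidate by ungapped comparison.  Loci with identity
≥ 90% over the overlap are reported: the best match count is primary, ties
break by reference name, then position, then forward strand; the rest are
secondary records (`0x100`, sequence omitted).  Edit distance is emitted as
the `NM` tag.  Mates of a pair are aligned independently (no pair rescue).
At seed stride 1 the reported full-length loci equal a brute-force Hamming
scan of the catalog, which the test suite asserts; the stride-5 default
trades a vanishing amount of sensitivity on heavily errored reads for a
5-fold smaller seed cost.  Reverse-strand hits store the
reverse-complemented sequence per SAM convention; `as_reads` undoes this.

Reference names (`igc`, `hg19`, ...) resolve through a local registry file
(TSV: name, FASTA path, annotation path or `-`); host genomes are simply
references without annotation tables.  No automatic downloading.

## Alignment filtering and host removal

`match_length` is the number of query bases aligned to the reference — the
sum of CIGAR M/=/X lengths, excluding insertions and clips.  `select`
removes alignments below a minimum match length; the boundary is strict
("below 45 bp" are removed), so 44 is removed and exactly 45 survives.
An identity cutoff (`match_identity` = (aligned bases − NM within the
aligned region) / aligned bases) is available but not applied in the
bundled host filter, which uses the 45 bp rule alone; the builtin aligner's
90% identity threshold lives in its own reporting, not in `select`.

Per alignment, `action="unmatch"` converts a mate whose alignments all fail
into an unmapped record (the read stays in the set), while `action="drop"`
removes the records outright.  A template counts as host if *any* of its
alignments survives the length filter (conservative removal); host-removal
mode is `keep="unmapped"`, which then discards all mapped templates.
Surviving-template counts are non-increasing in the threshold, which the
suite checks on a 1,000-template fixture.

## Counting

Per template (read or read pair), the candidate feature set is the
deduplicated union of the features annotated on the genes its surviving
alignments hit; mates pool their candidates first so a fragment contributes
total weight 1.  Policies: `unique_only` counts only single-candidate
templates; `all1` gives every candidate weight 1; `dist1` (default) splits
weight 1 equally — under the identity namespace (`genes`) this conserves
mass exactly (sum of counts = counted templates).  Genes missing from the
annotation table accrue under the reserved feature id `-1` so conservation
stays checkable.  `normed` divides gene-level counts by gene length in
kilobases before aggregating them into features; the feature-level dedup
rule therefore applies to `raw` only, which is the reading of
"each gene's contribution divided by gene length before feature
aggregation" this package adopts.  Defaults (`dist1`, `raw`,
`min_count=0`) are recorded in the output table's metadata so results are
self-describing.  Output TSVs are lexicographic by feature id.

## Bundled biome profiles

Five pipelines (human-gut, marine, mouse-gut, pig-gut, dog-gut) share one
template: preprocess (substrim 25, discard < 45 bp) → host filter for
host-associated biomes (map to the host reference, `select` at 45 bp,
`keep="unmapped"`, `as_reads`) → catalog mapping → `select` at 45 bp →
counts for OG, KO and gene namespaces → write.  The marine profile has no
host stage.  Catalog registry keys are `igc`, `om-rgc`, `mouse-gut`,
`pig-gut`, `dog-gut`; host keys `hg19`, `mm10`, `sus-scrofa`,
`canis-familiaris`.  All namespaces available in the catalog annotations
are emitted.  Each script takes sample directory, output prefix and
aligner name as `ARGV[1..3]`.

## Synthetic data generator

The generator defines the study conditions for all tests:

* **Catalogs** — random gene sequences (defaults: 20 genes, 500–1500 bp)
  with pairwise identity kept below 80% by rejection sampling (edlib
  alignment), each gene carrying ≥ 1 OG and ≥ 1 KO (about 20% of genes get
  a second KO); an optional exact duplicated-gene pair exercises
  multi-mapping.  The profile-recovery condition uses one OG per gene
  (20 OGs): with very few distinct features a rank correlation over so few
  points is degenerate (one adjacent swap among 5 ranks costs 0.1), so a
  near-bijection is the informative desk-scale condition.
* **Host** — a single random sequence (default 100 kb), a synthetic
  stand-in for a real host genome; random sequence shares no 21-mers with
  the catalog in practice, which is what makes exact retention rates
  measurable.
* **Reads** — genes are drawn with probability proportional to
  abundance × length (longer genes shed more fragments), start positions
  uniform, strands random, substitution errors independent per base.
  Qualities follow a parameterized pattern — core quality 38, optional
  degraded tail (tail start fraction, tail quality), Gaussian jitter
  σ = 3 clipped to [2, 41] — emulating the score spread of real base
  callers; the degraded-tail setting specifically exercises `substrim`.
  Read identifiers encode the source (`|geneNNNN` or `|host`) so removal
  and recovery are measured exactly, not estimated.
* **Truth** — the expected feature profile of the generated reads: the
  effective sampling weights (abundance × length, normalized) pushed
  through the same dedup/equal-split assignment rule the counter uses.
  `truth_profile` itself weights by exactly the vector it is given.

What the generator does *not* emulate: indels and platform-specific error
profiles, quality-correlated errors, GC bias, community ecology.  Passing
tests therefore demonstrate the correctness of the algorithms and the
pipeline plumbing under controlled conditions, not calibrated accuracy on
real sequencing data.

## Problem sizes and tolerances

The acceptance checks run at desk scale, chosen so the whole suite
completes in minutes on one CPU: the trimming oracle compares 10,000 random
reads (lengths 0–300, qualities 2–41); filter monotonicity uses 1,000
templates; host removal uses 10,000 reads at 20% host fraction (≥ 99%
host removal, 100% catalog retention, both in fact exact here);
counting-policy agreement uses 1,000 random templates over 50 genes and 10
features (exact agreement, tolerance 1e-9); profile recovery runs 8
replicates of 50,000 reads at 1% substitution error through the full
bundled human-gut pipeline and requires Spearman ≥ 0.95 between the truth
OG profile and the estimate (observed ≈ 0.998 ± 0.002).  Reproducibility is
asserted at byte level.

## Known limitations

* The builtin aligner is ungapped; indels shift the diagonal and are found
  only if a clean seed exists on one side, and reported identity then
  degrades.  Real data should use the bwa/minimap2 adapters.
* `load_mocat_sample` does not auto-detect interleaved FASTQ (explicit
  `deinterleave_fastq` is provided); mis-sniffing interleaving would
  silently corrupt pairing.
* Assembly and ORF-finding stages, taxonomic profiling, reference
  auto-download and distributed execution are out of scope.
* Paired-end mates are aligned independently; there is no insert-size
  model or mate rescue.
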