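# ngl

A small, statically typed pipeline language and profiler for gene-catalog
metagenomics.

Shotgun metagenomes sample all the genomic material in an environment.  A
standard first analysis step turns the raw reads into a *profile* — a table
of functional-feature abundances — by (1) quality-trimming and
length-filtering the reads, (2) discarding reads that align to the host
genome, (3) mapping the survivors against a pre-annotated gene catalog, and
(4) summarizing the alignments into per-feature counts (eggNOG orthologous
groups, KEGG KOs, or raw gene abundances).  `ngl` packages this workflow as
a tiny domain-specific language: pipelines are short, readable scripts that
the interpreter type-checks and I/O-validates *before* touching any data,
and whose results depend only on the script and its inputs — byte-identical
across reruns, thread counts and temp directories.

The core algorithms, in the field's usual notation:

* **substrim** — trim a read to the longest contiguous substring in which
  every base quality `q_i ≥ Q` (default `Q = 25`); reads shorter than
  45 bp afterwards are discarded.  `endtrim` (strip low-quality ends only)
  and `smoothtrim` (substrim on a centred moving average of the qualities)
  are also provided.
* **match length** — the number of query bases aligned to the reference,
  `Σ len(op), op ∈ {M, =, X}` over the CIGAR.  Host removal drops every
  read with a host alignment of match length ≥ 45; spurious short catalog
  alignments are filtered by the same rule.
* **counting** — each template (read or pair) contributes weight 1,
  distributed over the deduplicated union `F` of the features annotated on
  the genes it hits: `unique_only` (only when `|F| = 1`), `all1` (1 to each
  feature), or `dist1` (`1/|F|` to each, the default, which conserves total
  mass).  `normed` divides gene counts by gene length in kb before feature
  aggregation.

A deterministic builtin aligner (21-mer seeds, ungapped extension, ≥ 90%
identity reporting with NM tags) makes the whole pipeline self-contained;
`bwa mem` and `minimap2` adapters are used for production mapping when the
binaries are installed.  A synthetic-data module generates toy catalogs
with known annotations, reads simulated from known abundance vectors, and
host contaminants, so every claim the package makes is testable against
ground truth known by construction.

## A worked example

Generate a synthetic fixture (20-gene catalog with OG/KO annotations, a
synthetic host genome, a registry, and a 20,000-read sample with 1%
substitution errors and 20% host contamination), then profile it:

```sh
ngl make-fixture --out fx --seed 7 --n-reads 20000 --error-rate 0.01 --host-fraction 0.2
ngl profile --biome human-gut --input fx/sample1 --output results --registry fx/registry.tsv
```

The run prints the citation list for the references it used and writes
`results/sample1.OG.tsv`, `.KO.tsv`, `.genes.tsv`, a QC report and a run
report:

```
$ head -6 results/sample1.OG.tsv
feature	count
OG0001	5219
OG0002	1010
OG0003	1921
OG0004	5735
OG0005	2021

$ head -6 results/sample1.OG.tsv.qc.tsv
metric	value
reads_in	20000
reads_out	20000
reads_discarded	0
bases_in	2000000
bases_out	1999891
```

Reading the numbers: all 20,000 reads pass preprocessing (the simulated
qualities are high, so only 109 bases are trimmed); the OG counts sum to
≈ 16,000 because the ~4,000 host-derived reads were removed by the host
filter before catalog mapping; each count is the number of (non-host)
templates assigned to that orthologous group under the `dist1` policy.
Rerunning either command reproduces every output file byte for byte.

The same pipeline is an ordinary script you can read and edit — see
`ngl.profiles.get_profiler_script("human-gut")`:

```
ngless "1.0"
import "mocat" version "1.0"
import "igc" version "1.0"

input = load_mocat_sample(ARGV[1])

input = preprocess(input) using |read|:
    read = substrim(read, min_quality=25)
    if len(read) < 45:
        discard

mapped_host = map(input, reference="hg19", mapper=ARGV[3])
mapped_host = select(mapped_host, min_match_size=45, action="unmatch", keep="unmapped")
input = as_reads(mapped_host)
...
```

`ngl check script.ngl ARGS...` runs the parse → type-check → pre-flight
phases alone (touching no data): a misspelled keyword argument, an unbound
variable or a missing output directory is reported with its line number
before any read is processed.  `ngl run script.ngl ARGS...` executes it.

## Layout

- `src/ngl/lang/` — tokenizer, parser, pretty-printer, type checker,
  ill-typed-corpus generator
- `src/ngl/interpreter.py` — pre-flight validation, execution, run reports,
  citations
- `src/ngl/seqio.py`, `preprocess.py` — FASTQ I/O, sample loading, trimming
  and QC
- `src/ngl/mapping.py`, `references.py`, `filtering.py`, `counting.py` —
  aligners and registry, select/as_reads, feature counting
- `src/ngl/profiles.py` — the bundled per-biome pipeline scripts
- `src/ngl/fixtures.py` — synthetic catalogs, hosts, reads and ground truth
- `docs/methods.md` — models, parameters, numerical choices and limitations
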