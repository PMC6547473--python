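"""Synthetic data generation: toy gene catalogs with known annotations,
reads simulated from known abundances, host contaminants, and ground-truth
profiles.

The generator emulates the shape of real profiling inputs at desk scale:
catalog genes are random sequences screened so that no two exceed 80%
pairwise identity (with an optional exact duplicated-gene pair for
multi-mapper tests); reads are drawn from genes with probability
proportional to abundance x gene length, with uniform start positions,
random strand, independent substitution errors, and a parameterized quality
pattern (a high-quality core with an optional degraded tail, to exercise
quality trimming); host contaminant reads are drawn from a separate host
sequence.  Read identifiers encode their source (``|gene...`` or ``|host``)
so removal and recovery rates can be measured exactly.

The ground truth of a simulated sample is the *expected feature profile of
the generated reads*: the effective gene sampling weights pushed through the
same deduplicated feature-assignment rule the counting stage uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .counting import AnnotationTable, CountsTable, IDENTITY_NAMESPACE
from .errors import NGLError
from .references import ReferenceCatalog, write_registry
from .seqio import ShortRead, reverse_complement, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class CatalogFixture:
    """Paths and in-memory truth of one generated catalog."""

    fasta_path: Path
    annotation_path: Path
    genes: dict[str, str]
    annotations: AnnotationTable

    @property
    def catalog(self) -> ReferenceCatalog:
        return ReferenceCatalog("fixture", self.fasta_path, self.annotation_path)

    def registry_entry(self) -> tuple[Path, Path]:
        return self.fasta_path, self.annotation_path


def make_catalog(out_dir: str | Path, n_genes: int = 20,
                 length_range: tuple[int, int] = (500, 1500), n_ogs: int = 5,
                 n_kos: int = 10, seed: int = 0,
                 duplicate_pair: bool = False) -> CatalogFixture:
    """Generate a toy catalog: FASTA + annotation table, deterministic by seed.

    Every gene carries at least one OG and one KO; pairwise identity is kept
    below 80% by rejection sampling.  With ``duplicate_pair`` the last gene
    is an exact copy of the first (under a different id) for multi-mapper
    tests.
    """
    if not (n_genes >= n_ogs >= 1) or n_kos < 1:
        raise NGLError("need n_genes >= n_OGs >= 1 and n_KOs >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    n_random = n_genes - 1 if duplicate_pair else n_genes
    seqs: list[str] = []
    for _ in range(n_random):
        for _attempt in range(50):
            cand = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            if all(_identity(cand, s) < 0.8 for s in seqs):
                seqs.append(cand)
                break
        else:
            raise NGLError("could not sample catalog genes below 80% pairwise identity")
    if duplicate_pair:
        seqs.append(seqs[0])
    names = [f"gene{i + 1:04d}" for i in range(n_genes)]
    genes = dict(zip(names, seqs))
    # every OG/KO gets at least one gene: first n assigned round-robin-free,
    # the rest drawn at random
    ogs = [f"OG{i + 1:04d}" for i in range(n_ogs)]
    kos = [f"K{i + 1:05d}" for i in range(n_kos)]
    og_of = {}
    ko_of = {}
    for i, name in enumerate(names):
        og_of[name] = (ogs[i],) if i < n_ogs else (ogs[int(rng.integers(n_ogs))],)
        if i < n_kos:
            primary_ko = kos[i]
        else:
            primary_ko = kos[int(rng.integers(n_kos))]
        extra = rng.random() < 0.2 and n_kos > 1
        if extra:
            second = kos[int(rng.integers(n_kos))]
            ko_of[name] = tuple(dict.fromkeys((primary_ko, second)))
        else:
            ko_of[name] = (primary_ko,)
    fasta_path = out_dir / "catalog.fna"
    ann_path = out_dir / "catalog.annotations.tsv"
    write_fasta(genes, fasta_path)
    with open(ann_path, "w") as fh:
        for name in names:
            fh.write(f"{name}\tOG\t{','.join(og_of[name])}\n")
        for name in names:
            fh.write(f"{name}\tKO\t{','.join(ko_of[name])}\n")
    table = AnnotationTable({"OG": og_of, "KO": ko_of})
    return CatalogFixture(fasta_path, ann_path, genes, table)


def make_host(out_dir: str | Path, length: int = 100_000, seed: int = 0) -> Path:
    """A synthetic host genome (single random sequence), stand-in for a real
    host reference at desk scale."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    path = out_dir / "host.fna"
    write_fasta({"host_chr1": _random_sequence(rng, length)}, path)
    return path


@dataclass
class QualityModel:
    """Per-read quality pattern: a high-quality core, positions past
    ``tail_start`` (fraction of read length) degraded to ``tail_quality``,
    plus Gaussian per-base jitter (real base callers emit a spread of
    scores, which is also what lets the Phred-offset sniffer see the full
    character range)."""

    core_quality: int = 38
    tail_start: float = 1.0
    tail_quality: int = 38
    jitter: float = 3.0

    def qualities(self, length: int, rng: np.random.Generator | None = None) -> np.ndarray:
        q = np.full(length, self.core_quality, dtype=float)
        cut = int(round(self.tail_start * length))
        q[cut:] = self.tail_quality
        if rng is not None and self.jitter > 0:
            q = q + rng.normal(0.0, self.jitter, size=length)
        return np.clip(np.rint(q), 2, 41).astype(np.int16)


@dataclass
class SimulatedSample:
    sample_dir: Path
    gene_weights: dict[str, float]  # effective sampling weights (sum to 1 - host)
    truth: dict[str, CountsTable]  # per-namespace expected profiles
    n_reads: int
    n_host_reads: int

    @property
    def host_fraction_observed(self) -> float:
        return self.n_host_reads / self.n_reads if self.n_reads else 0.0


def truth_profile(weights: dict[str, float], annotations: AnnotationTable,
                  namespace: str) -> CountsTable:
    """Expected relative feature abundances for given gene weights, under
    the deduplicated equal-split (dist) assignment rule of the counter."""
    values: dict[str, float] = {}
    for gene, w in weights.items():
        features = tuple(dict.fromkeys(annotations.features_of(gene, namespace)))
        share = w / len(features)
        for f in features:
            values[f] = values.get(f, 0.0) + share
    return CountsTable(namespace=namespace, values=dict(sorted(values.items())),
                       metadata={"kind": "truth", "namespace": namespace})


def simulate_reads(fixture: CatalogFixture, out_dir: str | Path,
                   abundance: np.ndarray | None = None, n_reads: int = 50_000,
                   read_length: int = 100, error_rate: float = 0.0,
                   quality_model: QualityModel | None = None,
                   host_fasta: str | Path | None = None, host_fraction: float = 0.0,
                   seed: int = 0, sample_name: str = "sample1",
                   gzip_output: bool = True) -> SimulatedSample:
    """Simulate a single-end sample directory from known gene abundances.

    Genes are chosen proportional to abundance x length (longer genes shed
    more fragments); start positions are uniform within the gene; strands
    are random; substitution errors are independent per base at
    ``error_rate``.  ``abundance`` defaults to a Dirichlet(1) draw.  The
    returned truth holds the expected per-namespace feature profiles of the
    generated reads.
    """
    if not (0 <= host_fraction < 1):
        raise NGLError("host fraction must be in [0, 1)")
    if host_fraction > 0 and host_fasta is None:
        raise NGLError("host_fraction > 0 requires a host FASTA")
    out_dir = Path(out_dir)
    sample_dir = out_dir / sample_name
    sample_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    qm = quality_model or QualityModel()
    names = list(fixture.genes)
    lengths = np.array([len(fixture.genes[g]) for g in names])
    if int(lengths.min()) < read_length:
        raise NGLError(
            f"read length {read_length} exceeds shortest gene ({int(lengths.min())} bp)")
    if abundance is None:
        abundance = rng.dirichlet(np.ones(len(names)))
    abundance = np.asarray(abundance, dtype=float)
    if abundance.shape != (len(names),):
        raise NGLError("abundance vector length must equal the number of genes")
    if not np.isclose(abundance.sum(), 1.0):
        raise NGLError("abundance vector must sum to 1")
    p = abundance * lengths
    p = p / p.sum()

    host_seq = None
    if host_fasta is not None:
        from .seqio import read_fasta

        host_seqs = read_fasta(host_fasta)
        host_seq = "".join(host_seqs.values())
        if len(host_seq) < read_length:
            raise NGLError("host sequence shorter than the read length")

    is_host = rng.random(n_reads) < host_fraction
    gene_idx = rng.choice(len(names), size=n_reads, p=p)
    strands = rng.random(n_reads) < 0.5
    starts = rng.random(n_reads)  # scaled per read below
    n_errors = rng.binomial(read_length, error_rate, size=n_reads)

    def generate():
        for i in range(n_reads):
            if is_host[i]:
                src_seq, src_name = host_seq, "host"
            else:
                g = names[gene_idx[i]]
                src_seq, src_name = fixture.genes[g], g
            start = int(starts[i] * (len(src_seq) - read_length + 1))
            frag = src_seq[start:start + read_length]
            if strands[i]:
                frag = reverse_complement(frag)
            if n_errors[i]:
                pos = rng.choice(read_length, size=n_errors[i], replace=False)
                frag_arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
                # substitute with a uniformly chosen *different* base
                for j in pos:
                    choices = _BASES[_BASES != frag_arr[j]]
                    frag_arr[j] = rng.choice(choices)
                frag = frag_arr.tobytes().decode("ascii")
            yield ShortRead(f"r{i:06d}|{src_name}", frag, qm.qualities(read_length, rng))

    fq = sample_dir / ("reads.fq.gz" if gzip_output else "reads.fq")
    write_fastq(generate(), fq)
    n_host = int(is_host.sum())
    catalog_share = 1.0 - host_fraction
    gene_weights = {names[k]: float(p[k]) * catalog_share for k in range(len(names))}
    norm = sum(gene_weights.values())
    truth_weights = {g: w / norm for g, w in gene_weights.items()} if norm else {}
    truth = {
        ns: truth_profile(truth_weights, fixture.annotations, ns)
        for ns in ("OG", "KO", IDENTITY_NAMESPACE)
    }
    return SimulatedSample(sample_dir=sample_dir, gene_weights=gene_weights,
                           truth=truth, n_reads=n_reads, n_host_reads=n_host)


def make_fixture_registry(out_dir: str | Path, fixture: CatalogFixture,
                          host_fasta: Path | None = None,
                          catalog_keys: tuple[str, ...] = ("igc",),
                          host_keys: tuple[str, ...] = ("hg19",)) -> Path:
    """Registry file wiring the fixture catalog (and host) to profiler keys."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # absolute paths: registry entries resolve against the registry file's
    # directory, which need not contain the fixture files
    fasta = Path(fixture.fasta_path).resolve()
    ann = Path(fixture.annotation_path).resolve()
    entries = {key: (fasta, ann) for key in catalog_keys}
    if host_fasta is not None:
        for key in host_keys:
            entries[key] = (Path(host_fasta).resolve(), None)
    return write_registry(entries, out_dir / "registry.tsv")
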