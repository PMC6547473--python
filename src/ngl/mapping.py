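"""Mapping reads to a reference catalog.

Three paths produce a :class:`MappedShortReadSet` (a file-backed set of SAM
alignment records grouped by template):

* :func:`parse_sam` — adopt an externally produced SAM file;
* the ``builtin`` aligner — a deterministic exact-seed / ungapped-extension
  aligner (k-mer seeds, Hamming extension, >=90% identity reporting) so the
  whole pipeline runs with no external binaries;
* external adapters — thin wrappers over ``bwa mem`` / ``minimap2`` when
  those binaries are on PATH.

The builtin aligner is intentionally simple: it reports every locus whose
ungapped identity over the overlap is at least ``min_identity``, with the
best-scoring locus primary (ties broken by reference name, then position,
then forward strand) and the rest secondary, and emits the edit-distance
(NM) tag.  Mates of a pair are aligned independently.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .errors import NGLError, SamFormatError
from .references import ReferenceCatalog
from .seqio import ShortRead, ShortReadSet, pair_identifier, reverse_complement

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_FIRST = 0x40
FLAG_LAST = 0x80
FLAG_SECONDARY = 0x100


@dataclass
class MappedRead:
    """One SAM record: query name, flags, locus, CIGAR, NM tag, sequence."""

    query_name: str
    flag: int
    reference_name: str | None  # None when unmapped
    position: int  # 1-based leftmost; 0 when unmapped
    cigar: tuple[tuple[str, int], ...]  # e.g. (("S", 5), ("M", 95))
    edit_distance: int | None
    bases: str | None  # as stored in SAM (reference strand); None for '*'
    qualities: tuple[int, ...] | None
    mapq: int = 0

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def mate(self) -> int:
        """1, 2, or 0 for unpaired."""
        if self.flag & FLAG_FIRST:
            return 1
        if self.flag & FLAG_LAST:
            return 2
        return 0

    def query_consumed_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS=X")


@dataclass
class Template:
    """All alignment records sharing one query (read or read-pair) name."""

    name: str
    records: list[MappedRead] = field(default_factory=list)

    @property
    def is_mapped(self) -> bool:
        return any(r.is_mapped for r in self.records)

    def mapped_records(self) -> list[MappedRead]:
        return [r for r in self.records if r.is_mapped]

    def mates(self) -> dict[int, list[MappedRead]]:
        out: dict[int, list[MappedRead]] = {}
        for r in self.records:
            out.setdefault(r.mate, []).append(r)
        return out


@dataclass
class MappedShortReadSet:
    """File-backed alignment set (SAM on disk) plus its reference catalog."""

    sam_path: Path
    catalog: ReferenceCatalog | None = None

    def iter_templates(self) -> Iterator[Template]:
        """Templates grouped by query name, in input order of first appearance.

        Secondary alignments attach to their template even if not adjacent.
        """
        groups: dict[str, Template] = {}
        order: list[str] = []
        for rec in _read_sam_records(self.sam_path):
            if rec.query_name not in groups:
                groups[rec.query_name] = Template(rec.query_name)
                order.append(rec.query_name)
            groups[rec.query_name].records.append(rec)
        for name in order:
            yield groups[name]

    def n_templates(self) -> int:
        return sum(1 for _ in self.iter_templates())


def _cigar_from_pysam(cigartuples) -> tuple[tuple[str, int], ...]:
    ops = "MIDNSHP=X"
    return tuple((ops[op], n) for op, n in (cigartuples or ()))


def _read_sam_records(path: Path) -> Iterator[MappedRead]:
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for i, a in enumerate(sam, start=1):
                try:
                    cigar = _cigar_from_pysam(a.cigartuples)
                    seq = a.query_sequence
                    if seq is not None and not a.is_unmapped:
                        consumed = sum(n for op, n in cigar if op in "MIS=X")
                        if consumed != len(seq):
                            raise SamFormatError(
                                f"line {i}: CIGAR consumes {consumed} bases but "
                                f"sequence is {len(seq)} long ({a.query_name})")
                    nm = a.get_tag("NM") if a.has_tag("NM") else None
                    quals = tuple(a.query_qualities) if a.query_qualities is not None else None
                    yield MappedRead(
                        query_name=a.query_name,
                        flag=a.flag,
                        reference_name=None if a.is_unmapped else a.reference_name,
                        position=0 if a.is_unmapped else a.reference_start + 1,
                        cigar=cigar,
                        edit_distance=nm,
                        bases=seq,
                        qualities=quals,
                        mapq=a.mapping_quality,
                    )
                except SamFormatError:
                    raise
                except Exception as e:  # malformed individual record
                    raise SamFormatError(f"line {i}: {e}") from e
    except ValueError as e:
        raise SamFormatError(str(e)) from e


def parse_sam(path: str | Path, catalog: ReferenceCatalog | None = None) -> MappedShortReadSet:
    """Adopt a SAM file as a MappedShortReadSet (validated lazily on iteration)."""
    path = Path(path)
    if not path.is_file():
        raise NGLError(f"SAM file not found: {path}")
    return MappedShortReadSet(sam_path=path, catalog=catalog)


# --- SAM writing ----------------------------------------------------------


def sam_header(catalog: ReferenceCatalog) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in catalog.lengths.items()],
    })


class SamWriter:
    """Deterministic SAM writer (no @PG line, stable header order)."""

    def __init__(self, path: str | Path, catalog: ReferenceCatalog):
        self.path = Path(path)
        self.header = sam_header(catalog)
        self._refs = {name: i for i, name in enumerate(catalog.lengths)}
        self._file = pysam.AlignmentFile(str(self.path), "wh", header=self.header)

    def write(self, rec: MappedRead) -> None:
        a = pysam.AlignedSegment(self.header)
        a.query_name = rec.query_name
        a.flag = rec.flag
        if rec.is_mapped:
            a.reference_id = self._refs[rec.reference_name]
            a.reference_start = rec.position - 1
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar) or None
            a.mapping_quality = rec.mapq
        else:
            a.reference_id = -1
            a.reference_start = -1
            a.mapping_quality = 0
        a.next_reference_id = -1
        a.next_reference_start = -1
        if rec.bases is not None:
            a.query_sequence = rec.bases
            if rec.qualities is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rec.qualities))
        if rec.edit_distance is not None:
            a.set_tag("NM", rec.edit_distance, "i")
        self._file.write(a)

    def close(self) -> None:
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


# --- builtin aligner ------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Internal alignment candidate before SAM conversion."""

    reference_name: str
    position: int  # 1-based
    reverse: bool
    cigar: tuple[tuple[str, int], ...]
    edit_distance: int
    matches: int


class KmerIndex:
    """Exact k-mer seed table over a catalog; deterministic construction."""

    def __init__(self, catalog: ReferenceCatalog, k: int = 21):
        self.catalog = catalog
        self.k = k
        self.seqs = catalog.sequences
        index: dict[str, list[tuple[str, int]]] = {}
        for name in self.seqs:  # FASTA order
            seq = self.seqs[name]
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos:pos + k], []).append((name, pos))
        self.index = index


def _extend(index: KmerIndex, seq: str, ref_name: str, diag: int,
            min_identity: float) -> Alignment | None:
    """Ungapped comparison of ``seq`` laid on reference at offset ``diag``
    (0-based start of the read on the reference; may be negative)."""
    ref = index.seqs[ref_name]
    read_start = max(0, -diag)
    ref_start = diag + read_start
    overlap = min(len(seq) - read_start, len(ref) - ref_start)
    if overlap < index.k:
        return None
    sub_read = seq[read_start:read_start + overlap]
    sub_ref = ref[ref_start:ref_start + overlap]
    if sub_read == sub_ref:
        mismatches = 0
    else:
        mismatches = sum(a != b for a, b in zip(sub_read, sub_ref))
    matches = overlap - mismatches
    if matches / overlap < min_identity:
        return None
    cigar = []
    if read_start:
        cigar.append(("S", read_start))
    cigar.append(("M", overlap))
    tail = len(seq) - read_start - overlap
    if tail:
        cigar.append(("S", tail))
    return Alignment(ref_name, ref_start + 1, False, tuple(cigar), mismatches, matches)


def builtin_align(read: ShortRead, index: KmerIndex, min_identity: float = 0.9,
                  seed_stride: int = 5) -> list[Alignment]:
    """All loci with identity >= ``min_identity``; primary first.

    Seeds are sampled every ``seed_stride`` positions, falling back to every
    position when the sampled seeds find nothing (so truly unmapped reads are
    established by the full scan).  Ordering: best match count first; ties by
    reference name, then position, then forward strand.
    """
    k = index.k
    results: dict[tuple[str, int, bool], Alignment] = {}
    for reverse in (False, True):
        seq = reverse_complement(read.bases) if reverse else read.bases
        if len(seq) < k:
            continue
        strides = (seed_stride, 1) if seed_stride > 1 else (1,)
        for stride in strides:
            found = False
            diags = set()
            for off in range(0, len(seq) - k + 1, stride):
                for ref_name, pos in index.index.get(seq[off:off + k], ()):
                    diags.add((ref_name, pos - off))
            for ref_name, diag in diags:
                aln = _extend(index, seq, ref_name, diag, min_identity)
                if aln is not None:
                    found = True
                    key = (ref_name, aln.position, reverse)
                    if key not in results:
                        results[key] = Alignment(
                            aln.reference_name, aln.position, reverse,
                            aln.cigar, aln.edit_distance, aln.matches)
            if found:
                break
    ordered = sorted(results.values(),
                     key=lambda a: (-a.matches, a.reference_name, a.position, a.reverse))
    return ordered


def _alignment_records(read: ShortRead, alignments: list[Alignment],
                       pair_flags: int = 0) -> list[MappedRead]:
    """Convert a read's alignments to SAM records (primary + secondaries);
    an empty alignment list yields one unmapped record."""
    name = pair_identifier(read.identifier)
    if not alignments:
        return [MappedRead(name, FLAG_UNMAPPED | pair_flags, None, 0, (), None,
                           read.bases, tuple(int(q) for q in read.qualities))]
    out = []
    for i, aln in enumerate(alignments):
        flag = pair_flags
        if aln.reverse:
            flag |= FLAG_REVERSE
        if i == 0:
            bases = reverse_complement(read.bases) if aln.reverse else read.bases
            quals = read.qualities[::-1] if aln.reverse else read.qualities
            out.append(MappedRead(name, flag, aln.reference_name, aln.position,
                                  aln.cigar, aln.edit_distance, bases,
                                  tuple(int(q) for q in quals), mapq=60))
        else:
            out.append(MappedRead(name, flag | FLAG_SECONDARY, aln.reference_name,
                                  aln.position, aln.cigar, aln.edit_distance,
                                  None, None, mapq=0))
    return out


def map_reads(reads: ShortReadSet, catalog: ReferenceCatalog, out_sam: str | Path,
              aligner: str = "builtin", k: int = 21,
              min_identity: float = 0.9) -> MappedShortReadSet:
    """Map a read set against a catalog, writing a SAM file.

    Every input read appears exactly once in the output (as mapped or
    unmapped); compressed and multi-lane inputs are merged transparently.
    """
    out_sam = Path(out_sam)
    if aligner == "builtin":
        index = KmerIndex(catalog, k=k)
        with SamWriter(out_sam, catalog) as writer:
            for group in reads.groups:
                if group.paired:
                    for r1, r2 in zip(_iter_file(reads, group.mate1),
                                      _iter_file(reads, group.mate2)):
                        for rec in _alignment_records(
                                r1, builtin_align(r1, index, min_identity),
                                FLAG_PAIRED | FLAG_FIRST):
                            writer.write(rec)
                        for rec in _alignment_records(
                                r2, builtin_align(r2, index, min_identity),
                                FLAG_PAIRED | FLAG_LAST):
                            writer.write(rec)
                if group.singles is not None:
                    for r in _iter_file(reads, group.singles):
                        for rec in _alignment_records(r, builtin_align(r, index, min_identity)):
                            writer.write(rec)
        return MappedShortReadSet(sam_path=out_sam, catalog=catalog)
    if aligner in ("bwa", "minimap2"):
        return _external_map(reads, catalog, out_sam, aligner)
    raise NGLError(f"unknown aligner {aligner!r} (available: builtin, bwa, minimap2)")


def _iter_file(reads: ShortReadSet, path: Path):
    from .seqio import read_fastq

    return read_fastq(path, offset=reads.encoding_offset)


def _external_map(reads: ShortReadSet, catalog: ReferenceCatalog, out_sam: Path,
                  aligner: str) -> MappedShortReadSet:
    """Run an external aligner binary over the (merged, decompressed) reads."""
    if shutil.which(aligner) is None:
        raise NGLError(f"external aligner {aligner!r} not found on PATH")
    from .seqio import write_fastq

    with tempfile.TemporaryDirectory(prefix="ngl-map-") as tmp:
        tmp = Path(tmp)
        merged = tmp / "reads.fq"
        write_fastq(reads.iter_reads(), merged)
        if aligner == "bwa":
            idx_fa = tmp / "ref.fa"
            shutil.copy(catalog.fasta_path, idx_fa)
            _run([aligner, "index", str(idx_fa)])
            proc = _run([aligner, "mem", "-v", "1", str(idx_fa), str(merged)])
        else:
            proc = _run([aligner, "-a", "--sam-hit-only", "-x", "sr",
                         str(catalog.fasta_path), str(merged)])
        out_sam.write_text(proc.stdout)
    return MappedShortReadSet(sam_path=out_sam, catalog=catalog)


def _run(cmd: list[str]) -> subprocess.CompletedProcess:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise NGLError(f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr.strip()}")
    return proc
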