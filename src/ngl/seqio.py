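"""FASTQ/FASTA I/O and sample-directory loading.

Read sets are file-backed: a :class:`ShortReadSet` records *which files on
disk* hold a sample's reads (paired and/or single-end groups, possibly over
several lanes), not the reads themselves.  Gzip compression is handled
transparently by extension; output FASTQ is always emitted at Phred+33
regardless of the input encoding.
"""

from __future__ import annotations

import gzip
import io
import os
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqFormatError, NGLError

log = logging.getLogger("ngl")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FASTQ_EXTS = (".fq", ".fastq", ".fq.gz", ".fastq.gz")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ShortRead:
    """A single sequencing read: identifier, bases and Phred qualities."""

    identifier: str
    bases: str
    qualities: np.ndarray  # int array, same length as bases, values in [0, 93]

    def __post_init__(self):
        q = np.asarray(self.qualities, dtype=np.int16)
        object.__setattr__(self, "qualities", q)
        if len(self.bases) != q.size:
            raise ValueError(
                f"read {self.identifier!r}: {len(self.bases)} bases but {q.size} qualities")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, length: int) -> "ShortRead":
        return ShortRead(self.identifier, self.bases[start:start + length],
                         self.qualities[start:start + length])

    def __eq__(self, other):
        return (isinstance(other, ShortRead)
                and self.identifier == other.identifier
                and self.bases == other.bases
                and np.array_equal(self.qualities, other.qualities))


@dataclass(frozen=True)
class ReadGroup:
    """One lane/file group of a sample: paired files plus optional singles,
    or a lone single-end file."""

    mate1: Path | None = None
    mate2: Path | None = None
    singles: Path | None = None

    @property
    def paired(self) -> bool:
        return self.mate1 is not None and self.mate2 is not None

    def files(self) -> list[Path]:
        return [p for p in (self.mate1, self.mate2, self.singles) if p is not None]


@dataclass(frozen=True)
class ShortReadSet:
    """A sample's reads on disk: one or more file groups + quality encoding."""

    groups: tuple[ReadGroup, ...]
    encoding_offset: int = 33

    def files(self) -> list[Path]:
        return [f for g in self.groups for f in g.files()]

    def iter_reads(self) -> Iterator[ShortRead]:
        """All reads of the set, file order within lexicographic group order."""
        for group in self.groups:
            for f in group.files():
                yield from read_fastq(f, offset=self.encoding_offset)


def _open_text(path: Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 and no embedded filename keep outputs byte-reproducible
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
            return io.TextIOWrapper(gz, encoding="ascii", newline="")
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, offset: int = 33) -> Iterator[ShortRead]:
    """Stream reads from a plain or gzipped FASTQ file.

    Malformed records (sequence/quality length mismatch, missing separator,
    truncation) raise :class:`FastqFormatError` naming the record number.
    """
    path = Path(path)
    n = 0
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise FastqFormatError(str(e), record=n + 1) from e
            except (EOFError, OSError) as e:
                raise FastqFormatError(f"truncated or corrupt input: {e}",
                                       record=n + 1) from e
            n += 1
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"sequence length {len(seq)} != quality length {len(qual)}",
                    record=n)
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            quals -= offset
            if quals.size and (quals.min() < 0 or quals.max() > 93):
                raise FastqFormatError(
                    f"quality value outside [0, 93] at offset {offset}", record=n)
            yield ShortRead(title.split()[0] if title else "", seq, quals)


def write_fastq(reads: Iterable[ShortRead], path: str | Path) -> int:
    """Write reads as FASTQ at Phred+33; gzip chosen by ``.gz`` extension.
    Returns the number of records written."""
    path = Path(path)
    n = 0
    with _open_text(path, "wt") as fh:
        write = fh.write
        for read in reads:
            qual = (read.qualities + 33).astype(np.uint8).tobytes().decode("ascii")
            write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


def count_fastq_records(path: str | Path) -> int:
    with _open_text(path) as fh:
        return sum(1 for _ in fh) // 4


def detect_quality_encoding(reads_or_path, n_records: int = 100) -> int:
    """Guess the Phred offset (33 or 64) from the first records of a file.

    Any quality character below ``';'`` implies offset 33.  Offset 64 is
    only inferred when the characters both allow it (all at or above ``'@'``)
    and exclude offset 33 (some character beyond ``'J'``, the Phred+33
    encoding of quality 41).  Ranges legal under both encodings default to
    33 with a logged warning.
    """
    lo = ord(";")
    hi = ord("@")
    j33_max = ord("J")
    min_c, max_c = 255, 0
    if isinstance(reads_or_path, (str, Path)):
        with _open_text(Path(reads_or_path)) as fh:
            for i, line in enumerate(fh):
                if i // 4 >= n_records:
                    break
                if i % 4 == 3:
                    line = line.rstrip("\n")
                    if line:
                        min_c = min(min_c, min(ord(c) for c in line))
                        max_c = max(max_c, max(ord(c) for c in line))
    else:
        for read in reads_or_path:
            q = np.asarray(read.qualities)
            if q.size:
                min_c = min(min_c, int(q.min()) + 33)
                max_c = max(max_c, int(q.max()) + 33)
    if min_c == 255:
        return 33
    if min_c < lo:
        return 33
    if min_c >= hi and max_c > j33_max:
        return 64
    log.warning("ambiguous quality-encoding range (%c..%c); defaulting to Phred+33",
                chr(min_c), chr(max_c))
    return 33


# --- sample directories ---------------------------------------------------

_PAIR_SUFFIXES = [(".1", ".2"), ("_1", "_2"), ("_R1", "_R2")]


def _strip_fastq_ext(name: str) -> str | None:
    for ext in FASTQ_EXTS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return None


def _pair_key(stem: str) -> tuple[str, int] | None:
    """If ``stem`` ends in a mate suffix, return (shared stem, mate 1|2)."""
    for s1, s2 in _PAIR_SUFFIXES:
        if stem.endswith(s1):
            return stem[: -len(s1)], 1
        if stem.endswith(s2):
            return stem[: -len(s2)], 2
    return None


def pair_identifier(identifier: str) -> str:
    """Template name shared by both mates: strips a trailing /1 or /2."""
    if identifier.endswith(("/1", "/2")):
        return identifier[:-2]
    return identifier


def load_mocat_sample(directory: str | Path, validate_pairs: bool = True) -> ShortReadSet:
    """Load a sample directory (one biological sample = one directory,
    possibly holding multiple single-end/paired-end/multi-lane FASTQ files).

    Files are paired by filename stem (``.1``/``.2``, ``_1``/``_2``,
    ``_R1``/``_R2`` before the extension); unpaired files become single-end
    groups; groups are ordered lexicographically by stem so multi-lane
    samples load deterministically.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NGLError(f"sample directory not found: {directory}")
    entries = []
    for name in sorted(os.listdir(directory)):
        stem = _strip_fastq_ext(name)
        if stem is not None:
            entries.append((stem, directory / name))
    if not entries:
        raise NGLError(f"no FASTQ files found in sample directory {directory}")
    mates: dict[str, dict[int, Path]] = {}
    singles: list[tuple[str, Path]] = []
    for stem, path in entries:
        pk = _pair_key(stem)
        if pk is None:
            singles.append((stem, path))
        else:
            mates.setdefault(pk[0], {})[pk[1]] = path
    groups: list[tuple[str, ReadGroup]] = []
    for shared, d in mates.items():
        if 1 in d and 2 in d:
            groups.append((shared, ReadGroup(mate1=d[1], mate2=d[2])))
        else:  # a lone .1 (or .2) file: treat as single-end
            only = d.get(1) or d.get(2)
            groups.append((shared, ReadGroup(singles=only)))
    for stem, path in singles:
        groups.append((stem, ReadGroup(singles=path)))
    groups.sort(key=lambda g: g[0])
    ordered = tuple(g for _, g in groups)
    if validate_pairs:
        for g in ordered:
            if g.paired:
                n1 = count_fastq_records(g.mate1)
                n2 = count_fastq_records(g.mate2)
                if n1 != n2:
                    raise NGLError(
                        f"paired files {g.mate1.name}/{g.mate2.name} have mismatched "
                        f"record counts ({n1} vs {n2})")
    first = ordered[0].files()[0]
    offset = detect_quality_encoding(first)
    return ShortReadSet(groups=ordered, encoding_offset=offset)


def deinterleave_fastq(path: str | Path, out1: str | Path, out2: str | Path,
                       offset: int = 33) -> tuple[int, int]:
    """Split an interleaved FASTQ (mates alternating) into two mate files."""
    it = read_fastq(path, offset=offset)
    n1 = n2 = 0
    with _open_text(Path(out1), "wt") as f1, _open_text(Path(out2), "wt") as f2:
        for i, read in enumerate(it):
            qual = (read.qualities + 33).astype(np.uint8).tobytes().decode("ascii")
            rec = f"@{read.identifier}\n{read.bases}\n+\n{qual}\n"
            if i % 2 == 0:
                f1.write(rec)
                n1 += 1
            else:
                f2.write(rec)
                n2 += 1
    if n1 != n2:
        raise FastqFormatError("interleaved file holds an odd number of records")
    return n1, n2


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(Path(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
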