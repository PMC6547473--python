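"""Quality-based read trimming and the per-sample preprocessing pass.

Three trimming algorithms are provided:

``substrim``
    Trim the read to the *longest contiguous substring* in which every base
    has at least the requested Phred quality.  Ties between equal-length
    windows break to the leftmost window; bases exactly at the threshold
    are kept.
``endtrim``
    Strip only the maximal low-quality prefix and/or suffix; interior
    low-quality bases are retained.
``smoothtrim``
    Apply the substrim rule to a centred moving average of the qualities
    (window truncated at the read boundaries) and return the *original*
    bases/qualities on the selected window.

The per-sample pass applies a per-read program in a single sweep, collecting
quality-control statistics on both the input and the output as the data
streams through, and handling paired-end bookkeeping: a pair in which only
one mate survives is demoted to the singles file rather than discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .seqio import ReadGroup, ShortRead, ShortReadSet, read_fastq, write_fastq

PerReadFn = Callable[[ShortRead], Optional[ShortRead]]  # None means discard


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True; leftmost on ties; (0,0) if none."""
    if mask.size == 0 or not mask.any():
        return 0, 0
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    i = int(np.argmax(lengths))  # argmax takes the first maximum: leftmost tie-break
    return int(starts[i]), int(lengths[i])


def substrim(read: ShortRead, min_quality: int) -> ShortRead:
    """Longest substring whose bases all have quality >= ``min_quality``."""
    start, length = _longest_true_run(read.qualities >= min_quality)
    return read.slice(start, length)


def endtrim(read: ShortRead, min_quality: int, from_ends: str = "both") -> ShortRead:
    """Strip the maximal prefix/suffix of bases below ``min_quality``.

    ``from_ends`` is ``"both"``, ``"3"`` (suffix only) or ``"5"`` (prefix only).
    """
    if from_ends not in ("both", "3", "5"):
        raise ValueError(f"from_ends must be 'both', '3' or '5', got {from_ends!r}")
    ok = read.qualities >= min_quality
    if not ok.any():
        return read.slice(0, 0)
    first, last = int(np.argmax(ok)), len(ok) - 1 - int(np.argmax(ok[::-1]))
    start = first if from_ends in ("both", "5") else 0
    end = last if from_ends in ("both", "3") else len(ok) - 1
    return read.slice(start, end - start + 1)


def smoothed_qualities(qualities: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with the window truncated at the boundaries."""
    n = qualities.size
    if n == 0:
        return qualities.astype(float)
    h = window // 2
    csum = np.concatenate(([0], np.cumsum(qualities, dtype=np.int64)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smoothtrim(read: ShortRead, min_quality: int, window: int) -> ShortRead:
    """Substrim on boundary-truncated moving-average qualities; returns the
    original bases/qualities on the selected window."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    n = read.qualities.size
    if n == 0:
        return read
    # exact integer comparison: mean(window) >= q  <=>  sum(window) >= q * count
    h = window // 2
    csum = np.concatenate(([0], np.cumsum(read.qualities, dtype=np.int64)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    mask = (csum[hi] - csum[lo]) >= min_quality * (hi - lo)
    start, length = _longest_true_run(mask)
    return read.slice(start, length)


# --- QC statistics --------------------------------------------------------


@dataclass
class _PositionalQuality:
    """Running per-position quality sums over variable-length reads."""

    sums: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def add(self, qualities: np.ndarray) -> None:
        n = qualities.size
        if n > self.sums.size:
            grow = n - self.sums.size
            self.sums = np.concatenate([self.sums, np.zeros(grow, dtype=np.int64)])
            self.counts = np.concatenate([self.counts, np.zeros(grow, dtype=np.int64)])
        self.sums[:n] += qualities
        self.counts[:n] += 1

    def means(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.sums / np.maximum(self.counts, 1), np.nan)


@dataclass
class QCStats:
    """Always-on quality-control summary of one preprocessing pass."""

    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0
    discarded: int = 0
    gc_out: int = 0
    length_histogram: Counter = field(default_factory=Counter)
    pos_quality_in: _PositionalQuality = field(default_factory=_PositionalQuality)
    pos_quality_out: _PositionalQuality = field(default_factory=_PositionalQuality)

    def record_in(self, read: ShortRead) -> None:
        self.reads_in += 1
        self.bases_in += len(read)
        self.pos_quality_in.add(read.qualities)

    def record_out(self, read: ShortRead) -> None:
        self.reads_out += 1
        self.bases_out += len(read)
        self.length_histogram[len(read)] += 1
        self.gc_out += read.bases.count("G") + read.bases.count("C")
        self.pos_quality_out.add(read.qualities)

    def record_discard(self) -> None:
        self.discarded += 1

    @property
    def gc_fraction(self) -> float:
        return self.gc_out / self.bases_out if self.bases_out else 0.0

    def write_tsv(self, path: str | Path) -> None:
        """TSV report: scalar metrics, then per-position mean qualities,
        then the output length histogram."""
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"reads_in\t{self.reads_in}\n")
            fh.write(f"reads_out\t{self.reads_out}\n")
            fh.write(f"reads_discarded\t{self.discarded}\n")
            fh.write(f"bases_in\t{self.bases_in}\n")
            fh.write(f"bases_out\t{self.bases_out}\n")
            fh.write(f"gc_fraction_out\t{self.gc_fraction:.6f}\n")
            fh.write("\nposition\tmean_quality_in\tmean_quality_out\n")
            mi = self.pos_quality_in.means()
            mo = self.pos_quality_out.means()
            for i in range(max(mi.size, mo.size)):
                a = f"{mi[i]:.4f}" if i < mi.size and np.isfinite(mi[i]) else "-"
                b = f"{mo[i]:.4f}" if i < mo.size and np.isfinite(mo[i]) else "-"
                fh.write(f"{i + 1}\t{a}\t{b}\n")
            fh.write("\nlength\tread_count\n")
            for length in sorted(self.length_histogram):
                fh.write(f"{length}\t{self.length_histogram[length]}\n")


# --- the per-sample pass --------------------------------------------------


def preprocess_set(reads: ShortReadSet, per_read: PerReadFn, out_dir: str | Path,
                   keep_singles: bool = True) -> tuple[ShortReadSet, QCStats]:
    """Apply ``per_read`` to every read of the set in one streaming pass.

    ``per_read`` returns the (possibly trimmed) read, or None to discard it.
    Paired groups keep pair files in sync; a pair with exactly one surviving
    mate is demoted to the group's singles file (unless ``keep_singles`` is
    false, in which case the surviving mate is dropped too).  QC statistics
    for input and output are collected in the same pass.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qc = QCStats()
    offset = reads.encoding_offset

    def apply(read: ShortRead) -> ShortRead | None:
        """Trim one read; records input QC and discards (output QC at emit time)."""
        qc.record_in(read)
        result = per_read(read)
        if result is None:
            qc.record_discard()
        return result

    new_groups: list[ReadGroup] = []
    for gi, group in enumerate(reads.groups):
        if group.paired:
            f1 = out_dir / f"group{gi}.pair.1.fq"
            f2 = out_dir / f"group{gi}.pair.2.fq"
            fs = out_dir / f"group{gi}.singles.fq"
            n_pairs = n_singles = 0
            it1 = read_fastq(group.mate1, offset=offset)
            it2 = read_fastq(group.mate2, offset=offset)
            from .seqio import _open_text  # local import to reuse the gzip policy
            with _open_text(f1, "wt") as o1, _open_text(f2, "wt") as o2, \
                    _open_text(fs, "wt") as osingle:
                def emit(handle, read):
                    qc.record_out(read)
                    qual = (read.qualities + 33).astype(np.uint8).tobytes().decode("ascii")
                    handle.write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")

                for r1, r2 in zip(it1, it2):
                    a, b = apply(r1), apply(r2)
                    if a is not None and b is not None:
                        emit(o1, a)
                        emit(o2, b)
                        n_pairs += 1
                    elif a is not None or b is not None:
                        if keep_singles:
                            emit(osingle, a if a is not None else b)
                            n_singles += 1
                        else:
                            qc.record_discard()
                # pre-existing singles of the group stay single
                if group.singles is not None:
                    for r in read_fastq(group.singles, offset=offset):
                        a = apply(r)
                        if a is not None:
                            emit(osingle, a)
                            n_singles += 1
            g = ReadGroup(mate1=f1 if n_pairs else None,
                          mate2=f2 if n_pairs else None,
                          singles=fs if n_singles else None)
            if not n_pairs:
                f1.unlink()
                f2.unlink()
            if not n_singles:
                fs.unlink()
            if g.files():
                new_groups.append(g)
        else:
            fo = out_dir / f"group{gi}.fq"

            def surviving():
                for x in read_fastq(group.singles, offset=offset):
                    r = apply(x)
                    if r is not None:
                        qc.record_out(r)
                        yield r

            n = write_fastq(surviving(), fo)
            if n:
                new_groups.append(ReadGroup(singles=fo))
            else:
                fo.unlink()
    return ShortReadSet(groups=tuple(new_groups), encoding_offset=33), qc
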