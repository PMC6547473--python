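"""Alignment filtering and read extraction.

``select`` removes spurious alignments by minimum match length (the number
of query bases aligned to the reference: CIGAR M/=/X, excluding insertions
and clips).  The boundary is strict: with a 45 bp threshold, a 44 bp
alignment is removed and a 45 bp alignment survives.  An optional identity
cutoff is available through ``min_identity``.

Per alignment, the failing record is either converted to unmapped
(``action="unmatch"``: the mate stays in the set as an unmapped record) or
removed outright (``action="drop"``).  A template counts as mapped if *any*
of its alignments survives; the ``keep`` policy then retains all templates
(``"all"``), only mapped ones (``"mapped"``), or only unmapped ones
(``"unmapped"`` — host-removal mode, where any surviving host alignment
disqualifies the whole template).

``as_reads`` converts a mapped set back to FASTQ, restoring the original
orientation of reverse-strand alignments and re-forming pairs.
"""

from __future__ import annotations

from pathlib import Path

from .errors import NGLError, StageError
from .mapping import (FLAG_REVERSE, FLAG_SECONDARY, FLAG_UNMAPPED, MappedRead,
                      MappedShortReadSet, SamWriter, Template)
from .seqio import ReadGroup, ShortRead, ShortReadSet, reverse_complement


def match_length(aln: MappedRead) -> int:
    """Number of query bases aligned to the reference (CIGAR M/=/X)."""
    if not aln.is_mapped:
        raise NGLError(f"match_length of unmapped record {aln.query_name!r}")
    return sum(n for op, n in aln.cigar if op in "M=X")


def match_identity(aln: MappedRead) -> float:
    """(aligned bases - edit distance within the aligned region) / aligned bases."""
    if aln.edit_distance is None:
        raise NGLError(f"record {aln.query_name!r} has no edit-distance (NM) tag")
    m = match_length(aln)
    if m == 0:
        return 0.0
    # NM may include inserted/deleted bases; only count up to m against identity
    nm = min(aln.edit_distance, m)
    return (m - nm) / m


def _unmapped_from(rec: MappedRead) -> MappedRead:
    """An unmapped record carrying the read content in original orientation."""
    bases, quals = rec.bases, rec.qualities
    if bases is not None and rec.is_reverse:
        bases = reverse_complement(bases)
        quals = quals[::-1] if quals is not None else None
    flag = (rec.flag | FLAG_UNMAPPED) & ~(FLAG_REVERSE | FLAG_SECONDARY)
    return MappedRead(rec.query_name, flag, None, 0, (), None, bases, quals, mapq=0)


def select_template(template: Template, min_match_size: int = 0,
                    min_identity: float | None = None,
                    action: str = "unmatch") -> Template | None:
    """Apply the per-alignment filter to one template.

    Returns the filtered template, or None when ``action="drop"`` leaves
    nothing at all.
    """
    if action not in ("unmatch", "drop"):
        raise NGLError(f"select action must be 'unmatch' or 'drop', got {action!r}")
    new_records: list[MappedRead] = []
    for mate, records in sorted(template.mates().items()):
        surviving = []
        primary_like = None
        for rec in records:
            if not rec.is_mapped:
                primary_like = primary_like or rec
                continue
            if not rec.is_secondary:
                primary_like = primary_like or rec
            ok = match_length(rec) >= min_match_size
            if ok and min_identity is not None:
                ok = match_identity(rec) >= min_identity
            if ok:
                surviving.append(rec)
        if surviving:
            new_records.extend(surviving)
        elif primary_like is not None and (action == "unmatch" or not primary_like.is_mapped):
            # unmatch keeps the mate as an unmapped record; an already-unmapped
            # mate has no alignments for "drop" to remove, so it survives too
            new_records.append(_unmapped_from(primary_like))
    if not new_records:
        return None
    return Template(template.name, new_records)


def select(mapped: MappedShortReadSet, out_sam: str | Path, min_match_size: int = 0,
           min_identity: float | None = None, action: str = "unmatch",
           keep: str = "all") -> MappedShortReadSet:
    """Filter a mapped set into a new SAM file.

    ``keep``: "all" | "mapped" | "unmapped" (template-level, applied after
    the per-alignment filter).
    """
    if keep not in ("all", "mapped", "unmapped"):
        raise NGLError(f"select keep policy must be 'all', 'mapped' or 'unmapped', "
                       f"got {keep!r}")
    if mapped.catalog is None:
        raise NGLError("select requires a mapped set with a reference catalog")
    out_sam = Path(out_sam)
    with SamWriter(out_sam, mapped.catalog) as writer:
        for template in mapped.iter_templates():
            filtered = select_template(template, min_match_size, min_identity, action)
            if filtered is None:
                continue
            if keep == "mapped" and not filtered.is_mapped:
                continue
            if keep == "unmapped" and filtered.is_mapped:
                continue
            for rec in filtered.records:
                writer.write(rec)
    return MappedShortReadSet(sam_path=out_sam, catalog=mapped.catalog)


def _read_from_record(rec: MappedRead, suffix: str = "") -> ShortRead:
    if rec.bases is None:
        raise StageError("as_reads", f"record {rec.query_name!r} carries no sequence ('*')")
    bases, quals = rec.bases, rec.qualities
    if rec.is_reverse:
        bases = reverse_complement(bases)
        quals = quals[::-1] if quals is not None else None
    if quals is None:
        raise StageError("as_reads", f"record {rec.query_name!r} carries no qualities")
    return ShortRead(rec.query_name + suffix, bases, list(quals))


def as_reads(mapped: MappedShortReadSet, out_dir: str | Path) -> ShortReadSet:
    """Extract reads back out of a mapped set (one read per template record;
    pairs restored as pairs; reverse-complemented records undone)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    f1 = out_dir / "reads.1.fq"
    f2 = out_dir / "reads.2.fq"
    fs = out_dir / "reads.fq"
    n_pairs = n_singles = 0
    from .seqio import _open_text

    def emit(handle, read: ShortRead):
        qual = "".join(chr(int(q) + 33) for q in read.qualities)
        handle.write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")

    with _open_text(f1, "wt") as o1, _open_text(f2, "wt") as o2, \
            _open_text(fs, "wt") as osingle:
        for template in mapped.iter_templates():
            mates = template.mates()
            per_mate: dict[int, ShortRead] = {}
            for mate, records in sorted(mates.items()):
                primaries = [r for r in records if not r.is_secondary]
                if not primaries:
                    continue
                suffix = f"/{mate}" if mate else ""
                per_mate[mate] = _read_from_record(primaries[0], suffix)
            if 1 in per_mate and 2 in per_mate:
                emit(o1, per_mate[1])
                emit(o2, per_mate[2])
                n_pairs += 1
            else:
                for read in per_mate.values():
                    emit(osingle, read)
                    n_singles += 1
    groups = []
    if n_pairs:
        groups.append(ReadGroup(mate1=f1, mate2=f2))
    else:
        f1.unlink()
        f2.unlink()
    if n_singles:
        groups.append(ReadGroup(singles=fs))
    else:
        fs.unlink()
    return ShortReadSet(groups=tuple(groups), encoding_offset=33)
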