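"""Alignment-length filtering (select), the 45 bp boundary, monotonicity,
and as_reads extraction."""

import pytest

from ngl.errors import NGLError
from ngl.filtering import as_reads, match_identity, match_length, select
from ngl.mapping import (FLAG_SECONDARY, FLAG_UNMAPPED, MappedRead,
                         MappedShortReadSet, SamWriter, map_reads)
from ngl.seqio import (ReadGroup, ShortRead, ShortReadSet, read_fastq,
                       reverse_complement, write_fastq)


def cigar(spec):
    """'20S30M' -> (('S', 20), ('M', 30))"""
    out, num = [], ""
    for c in spec:
        if c.isdigit():
            num += c
        else:
            out.append((c, int(num)))
            num = ""
    return tuple(out)


def rec(name="r1", flag=0, ref="gene1", pos=1, cig="50M", nm=0, seq=None, quals=None):
    n = sum(x for op, x in cigar(cig) if op in "MIS=X") if cig != "*" else 50
    seq = seq if seq is not None else "A" * n
    quals = quals if quals is not None else tuple([40] * len(seq))
    if flag & FLAG_UNMAPPED:
        return MappedRead(name, flag, None, 0, (), None, seq, quals)
    return MappedRead(name, flag, ref, pos, cigar(cig), nm, seq, quals, mapq=60)


def mapped_set(tmp_path, records, catalog, name="t.sam"):
    path = tmp_path / name
    with SamWriter(path, catalog) as w:
        for r in records:
            w.write(r)
    return MappedShortReadSet(sam_path=path, catalog=catalog)


@pytest.fixture()
def catalog(tiny_catalog):
    return tiny_catalog.catalog


class TestMatchLength:
    @pytest.mark.parametrize("cig,expected", [
        ("50M", 50),
        ("20S30M", 30),
        ("20M5I20M10S", 40),  # insertions and clips excluded
        ("10M2D10M", 20),  # deletions consume no query bases
    ])
    def test_cigar_rules(self, cig, expected):
        assert match_length(rec(cig=cig)) == expected

    def test_unmapped_rejected(self):
        with pytest.raises(NGLError):
            match_length(rec(flag=FLAG_UNMAPPED, cig="*"))


class TestMatchIdentity:
    @pytest.mark.parametrize("cig,nm,expected", [
        ("100M", 0, 1.0),
        ("100M", 5, 0.95),
        ("50M", 50, 0.0),
    ])
    def test_formula(self, cig, nm, expected):
        assert match_identity(rec(cig=cig, nm=nm)) == pytest.approx(expected)

    def test_missing_nm_tag_names_record(self):
        r = rec()
        r.edit_distance = None
        with pytest.raises(NGLError, match="r1"):
            match_identity(r)


def ref_name(catalog):
    return next(iter(catalog.sequences))


class TestSelectBoundary:
    def test_44_removed_45_retained_at_threshold_45(self, tmp_path, catalog):
        g = ref_name(catalog)
        records = [rec(name="short", ref=g, cig="44M6S"),
                   rec(name="exact", ref=g, cig="45M5S")]
        ms = mapped_set(tmp_path, records, catalog)
        out = select(ms, tmp_path / "f.sam", min_match_size=45, action="unmatch")
        by_name = {t.name: t for t in out.iter_templates()}
        assert not by_name["short"].is_mapped  # 44 < 45: unmatched
        assert by_name["exact"].is_mapped  # exactly 45 survives

    def test_template_survives_via_longer_alignment(self, tmp_path, catalog):
        g = ref_name(catalog)
        records = [rec(name="t", ref=g, cig="44M6S"),
                   rec(name="t", flag=FLAG_SECONDARY, ref=g, pos=100, cig="50M",
                       seq=None, quals=None)]
        ms = mapped_set(tmp_path, records, catalog)
        out = select(ms, tmp_path / "f.sam", min_match_size=45, action="unmatch")
        (t,) = out.iter_templates()
        assert t.is_mapped
        assert len(t.mapped_records()) == 1
        assert match_length(t.mapped_records()[0]) == 50

    def test_drop_removes_template_entirely(self, tmp_path, catalog):
        g = ref_name(catalog)
        ms = mapped_set(tmp_path, [rec(name="t", ref=g, cig="30M20S")], catalog)
        out = select(ms, tmp_path / "f.sam", min_match_size=45, action="drop")
        assert list(out.iter_templates()) == []

    def test_idempotent_at_fixed_threshold(self, tmp_path, catalog):
        g = ref_name(catalog)
        records = [rec(name=f"t{i}", ref=g, cig=f"{30 + i}M{20 - i}S") for i in range(20)]
        ms = mapped_set(tmp_path, records, catalog)
        once = select(ms, tmp_path / "f1.sam", min_match_size=45, action="unmatch")
        twice = select(once, tmp_path / "f2.sam", min_match_size=45, action="unmatch")
        assert (tmp_path / "f1.sam").read_bytes() == (tmp_path / "f2.sam").read_bytes()

    def test_surviving_templates_monotone_in_threshold(self, tmp_path, catalog, rng):
        g = ref_name(catalog)
        records = []
        for i in range(300):
            m = int(rng.integers(20, 101))
            records.append(rec(name=f"t{i}", ref=g, cig=f"{m}M{100 - m}S",
                               seq="A" * 100, quals=tuple([40] * 100)))
        ms = mapped_set(tmp_path, records, catalog)
        counts = []
        for i, thr in enumerate(range(0, 110, 10)):
            out = select(ms, tmp_path / f"f{i}.sam", min_match_size=thr, action="unmatch")
            counts.append(sum(1 for t in out.iter_templates() if t.is_mapped))
        assert counts == sorted(counts, reverse=True)

    def test_keep_unmapped_is_host_removal(self, tmp_path, catalog):
        g = ref_name(catalog)
        records = [rec(name="host", ref=g, cig="100M", seq="A" * 100,
                       quals=tuple([40] * 100)),
                   rec(name="microbial", flag=FLAG_UNMAPPED, cig="*")]
        ms = mapped_set(tmp_path, records, catalog)
        out = select(ms, tmp_path / "f.sam", min_match_size=45, action="unmatch",
                     keep="unmapped")
        names = [t.name for t in out.iter_templates()]
        assert names == ["microbial"]

    def test_min_identity_filter(self, tmp_path, catalog):
        g = ref_name(catalog)
        records = [rec(name="good", ref=g, cig="100M", nm=2, seq="A" * 100,
                       quals=tuple([40] * 100)),
                   rec(name="poor", ref=g, cig="100M", nm=20, seq="A" * 100,
                       quals=tuple([40] * 100))]
        ms = mapped_set(tmp_path, records, catalog)
        out = select(ms, tmp_path / "f.sam", min_identity=0.9, action="unmatch")
        by_name = {t.name: t.is_mapped for t in out.iter_templates()}
        assert by_name == {"good": True, "poor": False}


class TestAsReads:
    def test_roundtrip_through_mapping(self, tiny_catalog, tmp_path, rng):
        """as_reads ∘ map restores every read's content exactly, including
        reverse-strand hits and unmapped reads."""
        genes = list(tiny_catalog.genes.values())
        reads = []
        for i in range(10):
            seq = genes[i % len(genes)][:100]
            if i % 2:
                seq = reverse_complement(seq)  # maps on the reverse strand
            reads.append(ShortRead(f"r{i:02d}", seq,
                                   list(rng.integers(2, 42, size=100))))
        reads.append(ShortRead("r98", "".join(rng.choice(list("ACGT"), size=100)),
                               [30] * 100))
        f = tmp_path / "in.fq"
        write_fastq(reads, f)
        rs = ShortReadSet(groups=(ReadGroup(singles=f),))
        mapped = map_reads(rs, tiny_catalog.catalog, tmp_path / "m.sam")
        back = as_reads(mapped, tmp_path / "back")
        restored = sorted(back.iter_reads(), key=lambda r: r.identifier)
        assert restored == sorted(reads, key=lambda r: r.identifier)

    def test_pairs_restored_as_pairs(self, tiny_catalog, tmp_path):
        seq = next(iter(tiny_catalog.genes.values()))
        m1 = [ShortRead(f"p{i}/1", seq[:100], [40] * 100) for i in range(3)]
        m2 = [ShortRead(f"p{i}/2", reverse_complement(seq[50:150]), [40] * 100)
              for i in range(3)]
        f1, f2 = tmp_path / "s_1.fq", tmp_path / "s_2.fq"
        write_fastq(m1, f1)
        write_fastq(m2, f2)
        rs = ShortReadSet(groups=(ReadGroup(mate1=f1, mate2=f2),))
        mapped = map_reads(rs, tiny_catalog.catalog, tmp_path / "m.sam")
        back = as_reads(mapped, tmp_path / "back")
        (group,) = back.groups
        assert group.paired
        got1 = list(read_fastq(group.mate1))
        got2 = list(read_fastq(group.mate2))
        assert [r.bases for r in got1] == [r.bases for r in m1]
        assert [r.bases for r in got2] == [r.bases for r in m2]

    def test_missing_sequence_is_an_error(self, tmp_path, catalog):
        g = ref_name(catalog)
        records = [MappedRead("r1", 0, g, 1, cigar("50M"), 0, None, None, 60)]
        ms = mapped_set(tmp_path, records, catalog)
        with pytest.raises(NGLError, match="no sequence"):
            as_reads(ms, tmp_path / "back")
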