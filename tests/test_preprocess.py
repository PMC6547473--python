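"""Trimming algorithms against independent oracles, plus the streaming
per-sample pass with paired-end bookkeeping and QC accounting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngl.preprocess import endtrim, preprocess_set, smoothtrim, substrim
from ngl.seqio import ReadGroup, ShortReadSet, read_fastq, write_fastq
from tests.conftest import mkread

# --- independent oracles --------------------------------------------------


def substrim_oracle(quals, minq):
    """O(n^2) enumeration of all substrings; leftmost longest all-passing."""
    best_start, best_len = 0, 0
    n = len(quals)
    for i in range(n):
        for j in range(i, n):
            if quals[j] < minq:
                break
            if j - i + 1 > best_len:
                best_start, best_len = i, j - i + 1
    return best_start, best_len


def smooth_oracle(quals, minq, window):
    """Per-position truncated-window mean (plain Python), then substrim rule."""
    from fractions import Fraction

    n = len(quals)
    h = window // 2
    smoothed = []
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        smoothed.append(Fraction(sum(quals[lo:hi]), hi - lo))
    passing = [1000 if s >= minq else 0 for s in smoothed]
    return substrim_oracle(passing, 1000)


quals_strategy = st.lists(st.integers(min_value=2, max_value=41), min_size=0, max_size=120)


class TestSubstrim:
    @pytest.mark.parametrize(
        "quals,minq,start,length",
        [
            ([40, 40, 40, 40], 25, 0, 4),  # all pass: whole read
            ([30, 30, 10, 30, 30, 30], 25, 3, 3),  # longest run right of the dip
            ([30, 30, 10, 30, 30], 25, 0, 2),  # tie broken to the leftmost
            ([10, 10, 10], 25, 0, 0),  # nothing passes: empty read
            ([25, 25], 25, 0, 2),  # boundary: exactly-at-threshold bases kept
            ([], 25, 0, 0),
        ],
    )
    def test_examples(self, quals, minq, start, length):
        read = mkread(quals, bases="".join("ACGT"[i % 4] for i in range(len(quals))))
        out = substrim(read, minq)
        assert out.bases == read.bases[start:start + length]
        assert list(out.qualities) == quals[start:start + length]

    @settings(max_examples=200, deadline=None)
    @given(quals_strategy, st.integers(min_value=0, max_value=45))
    def test_matches_bruteforce_oracle(self, quals, minq):
        out = substrim(mkread(quals), minq)
        start, length = substrim_oracle(quals, minq)
        assert list(out.qualities) == quals[start:start + length]

    @settings(max_examples=100, deadline=None)
    @given(quals_strategy, st.integers(min_value=0, max_value=45))
    def test_idempotent(self, quals, minq):
        once = substrim(mkread(quals), minq)
        twice = substrim(once, minq)
        assert twice == once

    @settings(max_examples=100, deadline=None)
    @given(quals_strategy, st.integers(min_value=0, max_value=40))
    def test_monotone_in_threshold(self, quals, minq):
        assert len(substrim(mkread(quals), minq + 1)) <= len(substrim(mkread(quals), minq))


class TestEndtrim:
    def test_interior_low_quality_kept(self):
        out = endtrim(mkread([10, 30, 10, 30, 10]), 25)
        assert list(out.qualities) == [30, 10, 30]

    def test_all_passing_unchanged(self):
        read = mkread([30, 31, 32])
        assert endtrim(read, 25) == read

    def test_all_failing_empty(self):
        assert len(endtrim(mkread([10, 10]), 25)) == 0

    def test_single_end_modes(self):
        quals = [10, 30, 10]
        assert list(endtrim(mkread(quals), 25, "5").qualities) == [30, 10]
        assert list(endtrim(mkread(quals), 25, "3").qualities) == [10, 30]

    @settings(max_examples=100, deadline=None)
    @given(quals_strategy, st.integers(min_value=0, max_value=45))
    def test_endtrim_contains_substrim(self, quals, minq):
        """endtrim output is a superstring (or equal) of the substrim output."""
        sub = substrim(mkread(quals), minq)
        end = endtrim(mkread(quals), minq)
        assert len(end) >= len(sub)
        if len(sub):
            joined = "".join(chr(q + 33) for q in end.qualities)
            needle = "".join(chr(q + 33) for q in sub.qualities)
            assert needle in joined


class TestSmoothtrim:
    @settings(max_examples=100, deadline=None)
    @given(quals_strategy, st.integers(min_value=0, max_value=45))
    def test_window_one_equals_substrim(self, quals, minq):
        assert smoothtrim(mkread(quals), minq, 1) == substrim(mkread(quals), minq)

    @settings(max_examples=150, deadline=None)
    @given(quals_strategy, st.integers(min_value=0, max_value=45),
           st.sampled_from([1, 3, 5, 7]))
    def test_matches_moving_average_oracle(self, quals, minq, window):
        out = smoothtrim(mkread(quals), minq, window)
        start, length = smooth_oracle(quals, minq, window)
        # original (not smoothed) qualities on the selected window
        assert list(out.qualities) == quals[start:start + length]

    def test_constant_qualities_keep_whole_read(self):
        read = mkread([30] * 10)
        assert smoothtrim(read, 30, 5) == read

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smoothtrim(mkread([30]), 25, 4)


# --- the per-sample pass --------------------------------------------------


def profiler_block(read):
    """The bundled preprocessing: substrim at 25, discard below 45 bp."""
    out = substrim(read, 25)
    return None if len(out) < 45 else out


class TestPreprocessSet:
    def _set_from(self, tmp_path, reads, paired=None):
        if paired:
            f1, f2 = tmp_path / "in_1.fq", tmp_path / "in_2.fq"
            write_fastq(paired[0], f1)
            write_fastq(paired[1], f2)
            return ShortReadSet(groups=(ReadGroup(mate1=f1, mate2=f2),))
        f = tmp_path / "in.fq"
        write_fastq(reads, f)
        return ShortReadSet(groups=(ReadGroup(singles=f),))

    def test_clean_reads_pass_unchanged(self, tmp_path):
        reads = [mkread([40] * 100, name=f"r{i}") for i in range(100)]
        rs = self._set_from(tmp_path, reads)
        out, qc = preprocess_set(rs, profiler_block, tmp_path / "out")
        assert qc.reads_in == qc.reads_out == 100
        assert list(out.iter_reads()) == reads

    def test_read_with_44_base_run_discarded(self, tmp_path):
        # longest >=25-quality run is 44 bases: below the 45 bp length filter
        quals = [40] * 44 + [2] + [40] * 10
        rs = self._set_from(tmp_path, [mkread(quals)])
        out, qc = preprocess_set(rs, profiler_block, tmp_path / "out")
        assert qc.reads_out == 0 and qc.discarded == 1

    def test_read_with_45_base_run_kept(self, tmp_path):
        quals = [40] * 45 + [2] + [40] * 10
        rs = self._set_from(tmp_path, [mkread(quals)])
        out, qc = preprocess_set(rs, profiler_block, tmp_path / "out")
        assert qc.reads_out == 1
        (read,) = out.iter_reads()
        assert len(read) == 45

    def test_half_surviving_pair_demoted_to_singles(self, tmp_path):
        good = [mkread([40] * 60, name="a/1"), mkread([40] * 60, name="b/1")]
        bad_then_good = [mkread([2] * 60, name="a/2"), mkread([40] * 60, name="b/2")]
        rs = self._set_from(tmp_path, None, paired=(good, bad_then_good))
        out, qc = preprocess_set(rs, profiler_block, tmp_path / "out")
        (group,) = out.groups
        assert group.paired  # pair b survived as a pair
        pairs = list(read_fastq(group.mate1))
        assert [r.identifier for r in pairs] == ["b/1"]
        singles = list(read_fastq(group.singles))
        assert [r.identifier for r in singles] == ["a/1"]
        assert qc.reads_in == 4 and qc.reads_out == 3 and qc.discarded == 1

    def test_qc_conservation_and_accounting(self, tmp_path, rng):
        reads = [mkread(list(rng.integers(2, 42, size=80)), name=f"r{i}")
                 for i in range(200)]
        rs = self._set_from(tmp_path, reads)
        out, qc = preprocess_set(rs, profiler_block, tmp_path / "out")
        assert qc.reads_in == qc.reads_out + qc.discarded
        assert qc.bases_out <= qc.bases_in
        assert sum(qc.length_histogram.values()) == qc.reads_out
        assert qc.reads_out == sum(1 for _ in out.iter_reads())

    def test_qc_report_tsv_layout(self, tmp_path):
        rs = self._set_from(tmp_path, [mkread([40] * 50)])
        _, qc = preprocess_set(rs, profiler_block, tmp_path / "out")
        report = tmp_path / "qc.tsv"
        qc.write_tsv(report)
        text = report.read_text()
        assert text.startswith("metric\tvalue\n")
        assert "position\tmean_quality_in\tmean_quality_out" in text
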