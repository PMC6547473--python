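"""Counting policies against an independent per-template enumeration oracle,
conservation laws, normalization and output formatting."""

import pytest

from ngl.counting import (AnnotationTable, CountsTable, count, format_value,
                          write_counts)
from ngl.errors import NGLError
from ngl.mapping import FLAG_SECONDARY, MappedRead, MappedShortReadSet, SamWriter
from ngl.references import ReferenceCatalog
from ngl.seqio import write_fasta


def make_catalog_files(tmp_path, genes, annotations):
    """genes: {name: length}; annotations: {namespace: {gene: (features,)}}"""
    fasta = tmp_path / "cat.fna"
    write_fasta({g: "A" * n for g, n in genes.items()}, fasta)
    ann_path = tmp_path / "ann.tsv"
    with open(ann_path, "w") as fh:
        for ns, mapping in annotations.items():
            for g, feats in mapping.items():
                fh.write(f"{g}\t{ns}\t{','.join(feats)}\n")
    return ReferenceCatalog("test", fasta, ann_path), AnnotationTable.load(ann_path)


def mapped_from_templates(tmp_path, catalog, template_genes, name="c.sam"):
    """Build a SAM where template i hits exactly the given genes."""
    path = tmp_path / name
    with SamWriter(path, catalog) as w:
        for i, genes in enumerate(template_genes):
            for j, g in enumerate(sorted(genes)):
                flag = 0 if j == 0 else FLAG_SECONDARY
                seq = "A" * 50 if j == 0 else None
                quals = tuple([40] * 50) if j == 0 else None
                w.write(MappedRead(f"t{i:05d}", flag, g, 1, (("M", 50),), 0,
                                   seq, quals, mapq=60))
            if not genes:
                w.write(MappedRead(f"t{i:05d}", 0x4, None, 0, (), None,
                                   "A" * 50, tuple([40] * 50)))
    return MappedShortReadSet(sam_path=path, catalog=catalog)


def oracle(template_genes, annotations, namespace, policy):
    """Independent enumeration: per template, dedup the feature union, then
    apply the policy definition literally."""
    totals = {}
    for genes in template_genes:
        if not genes:
            continue
        feats = set()
        for g in genes:
            if namespace == "genes":
                feats.add(g)
            else:
                feats.update(annotations.by_namespace[namespace].get(g, ("-1",)))
        weights = {}
        if policy == "unique_only":
            if len(feats) == 1:
                weights = {next(iter(feats)): 1.0}
        elif policy == "all1":
            weights = {f: 1.0 for f in feats}
        else:
            weights = {f: 1.0 / len(feats) for f in feats}
        for f, w in weights.items():
            totals[f] = totals.get(f, 0.0) + w
    return totals


@pytest.fixture()
def simple(tmp_path):
    genes = {"g1": 1000, "g2": 500, "g3": 2000}
    anns = {"OG": {"g1": ("OG1",), "g2": ("OG1", "OG2"), "g3": ("OG3",)}}
    return make_catalog_files(tmp_path, genes, anns)


class TestPolicies:
    def test_unique_hits_count_one_each(self, tmp_path, simple):
        catalog, ann = simple
        ms = mapped_from_templates(tmp_path, catalog, [{"g1"}] * 10)
        table = count(ms, ann, "OG", policy="dist1")
        assert table.values == {"OG1": 10.0}

    def test_multimapper_policies_differ_as_specified(self, tmp_path, simple):
        catalog, ann = simple
        # one template hitting genes annotated OG1 and OG3
        templates = [{"g1", "g3"}]
        ms = mapped_from_templates(tmp_path, catalog, templates)
        assert count(ms, ann, "OG", policy="dist1").values == {"OG1": 0.5, "OG3": 0.5}
        assert count(ms, ann, "OG", policy="all1").values == {"OG1": 1.0, "OG3": 1.0}
        assert count(ms, ann, "OG", policy="unique_only").values == {}

    def test_shared_feature_deduplicated_before_weighting(self, tmp_path, simple):
        catalog, ann = simple
        # g1 and g2 share OG1: the template's candidate set is {OG1, OG2}
        ms = mapped_from_templates(tmp_path, catalog, [{"g1", "g2"}])
        assert count(ms, ann, "OG", policy="dist1").values == {"OG1": 0.5, "OG2": 0.5}
        # two genes whose only feature is shared -> one unit under all policies
        ms2 = mapped_from_templates(tmp_path, catalog, [{"g1"}], name="c2.sam")
        for policy in ("unique_only", "all1", "dist1"):
            assert count(ms2, ann, "OG", policy=policy).values == {"OG1": 1.0}

    def test_unannotated_gene_goes_to_reserved_bucket(self, tmp_path):
        catalog, ann = make_catalog_files(
            tmp_path, {"g1": 100, "gX": 100}, {"OG": {"g1": ("OG1",)}})
        ms = mapped_from_templates(tmp_path, catalog, [{"gX"}, {"g1"}])
        assert count(ms, ann, "OG", policy="dist1").values == {"-1": 1.0, "OG1": 1.0}

    def test_pair_counts_once_per_template(self, tmp_path, simple):
        catalog, ann = simple
        path = tmp_path / "p.sam"
        with SamWriter(path, catalog) as w:
            # mates hit different genes; the template pools candidates first
            w.write(MappedRead("p0", 0x1 | 0x40, "g1", 1, (("M", 50),), 0,
                               "A" * 50, tuple([40] * 50), 60))
            w.write(MappedRead("p0", 0x1 | 0x80, "g3", 1, (("M", 50),), 0,
                               "A" * 50, tuple([40] * 50), 60))
        ms = MappedShortReadSet(sam_path=path, catalog=catalog)
        assert count(ms, ann, "OG", policy="dist1").values == {"OG1": 0.5, "OG3": 0.5}
        assert count(ms, ann, "genes", policy="dist1").total() == pytest.approx(1.0)


class TestOracleAgreement:
    def test_random_templates_match_enumeration(self, tmp_path, rng):
        n_genes, n_feats = 50, 10
        genes = {f"g{i:03d}": int(rng.integers(200, 2000)) for i in range(n_genes)}
        ann_map = {}
        for g in genes:
            k = int(rng.integers(1, 4))
            ann_map[g] = tuple(sorted({f"OG{int(rng.integers(n_feats)):03d}"
                                       for _ in range(k)}))
        catalog, ann = make_catalog_files(tmp_path, genes, {"OG": ann_map})
        names = list(genes)
        template_genes = []
        for _ in range(1000):
            k = int(rng.integers(1, 5))
            template_genes.append(set(rng.choice(names, size=k, replace=False)))
        ms = mapped_from_templates(tmp_path, catalog, template_genes)
        for policy in ("unique_only", "all1", "dist1"):
            for ns in ("OG", "genes"):
                got = count(ms, ann, ns, policy=policy).values
                expect = oracle(template_genes, ann, ns, policy)
                assert set(got) == set(expect)
                for f in got:
                    assert got[f] == pytest.approx(expect[f]), (policy, ns, f)

    def test_dist1_conservation_and_policy_ordering(self, tmp_path, rng):
        genes = {f"g{i}": 500 for i in range(20)}
        ann_map = {g: (f"OG{i % 7}",) for i, g in enumerate(genes)}
        catalog, ann = make_catalog_files(tmp_path, genes, {"OG": ann_map})
        names = list(genes)
        template_genes = [set(rng.choice(names, size=int(rng.integers(1, 4)),
                                         replace=False)) for _ in range(500)]
        ms = mapped_from_templates(tmp_path, catalog, template_genes)
        dist1 = count(ms, ann, "genes", policy="dist1")
        # conservation: total mass equals the number of counted templates
        assert dist1.total() == pytest.approx(len(template_genes))
        uo = count(ms, ann, "OG", policy="unique_only").values
        d1 = count(ms, ann, "OG", policy="dist1").values
        a1 = count(ms, ann, "OG", policy="all1").values
        for f in a1:
            assert uo.get(f, 0.0) <= d1.get(f, 0.0) + 1e-9
            assert d1.get(f, 0.0) <= a1.get(f, 0.0) + 1e-9


class TestNormalizationAndOutput:
    def test_normed_divides_by_gene_kilobases(self, tmp_path, simple):
        catalog, ann = simple
        # 10 templates on g1 (1000 bp) and 10 on g2 (500 bp)
        ms = mapped_from_templates(tmp_path, catalog, [{"g1"}] * 10 + [{"g2"}] * 10)
        normed = count(ms, ann, "genes", normalization="normed")
        assert normed.values["g1"] == pytest.approx(10.0)  # 10 / 1.0 kb
        assert normed.values["g2"] == pytest.approx(20.0)  # 10 / 0.5 kb
        og = count(ms, ann, "OG", normalization="normed")
        # g1 -> OG1; g2 -> OG1 and OG2 (gene value added to each feature)
        assert og.values["OG1"] == pytest.approx(30.0)
        assert og.values["OG2"] == pytest.approx(20.0)

    def test_min_count_threshold_applied_after_aggregation(self, tmp_path, simple):
        catalog, ann = simple
        ms = mapped_from_templates(tmp_path, catalog, [{"g1"}] * 5 + [{"g3"}])
        table = count(ms, ann, "OG", min_count=2)
        assert table.values == {"OG1": 5.0}

    def test_unknown_namespace_rejected(self, tmp_path, simple):
        catalog, ann = simple
        ms = mapped_from_templates(tmp_path, catalog, [{"g1"}])
        with pytest.raises(NGLError, match="unknown namespace"):
            count(ms, ann, "KO")

    def test_write_counts_format(self, tmp_path):
        table = CountsTable("OG", {"OG2": 0.5, "OG1": 0.5, "OG3": 10.0})
        out = tmp_path / "c.tsv"
        write_counts(table, out)
        assert out.read_text() == "feature\tcount\nOG1\t0.5\nOG2\t0.5\nOG3\t10\n"

    def test_empty_table_writes_header_only(self, tmp_path):
        out = tmp_path / "c.tsv"
        write_counts(CountsTable("OG", {}), out)
        assert out.read_text() == "feature\tcount\n"

    @pytest.mark.parametrize("value,text", [
        (10.0, "10"), (0.5, "0.5"), (1 / 3, "0.333333"), (0.0, "0")])
    def test_value_formatting(self, value, text):
        assert format_value(value) == text
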