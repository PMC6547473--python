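"""Feature counting: summarize a mapped read set into per-feature abundances.

Each template (read or read pair) contributes according to the genes its
surviving alignments hit.  The candidate feature set of a template is the
*deduplicated union* of the features annotated on those genes (mates of a
pair pool their candidates first, so a fragment contributes total weight 1).
Multi-mapper policies:

``unique_only``
    Count only templates with exactly one candidate feature (weight 1).
``all1``
    Give weight 1 to every candidate feature.
``dist1``
    Split weight 1 equally among the candidate features (the default) —
    under the identity namespace this conserves mass: the counts sum to the
    number of counted templates.

``normed`` divides each gene's contribution by the gene length in kilobases
before aggregating gene counts into features (so here the policy weighting
happens at gene level, then lengths are divided out, then gene values are
summed into each gene's features).  Mapped genes missing from the
annotation table accumulate under the reserved feature id ``-1`` rather
than being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import NGLError
from .mapping import MappedShortReadSet

NAMESPACES = ("OG", "KO", "SEED", "BiGG")
IDENTITY_NAMESPACE = "genes"
UNANNOTATED = "-1"

POLICIES = ("unique_only", "all1", "dist1")
NORMALIZATIONS = ("raw", "normed")


@dataclass
class AnnotationTable:
    """Gene → feature-id lists, one mapping per namespace.

    File format: TSV with rows ``gene id <TAB> namespace <TAB>
    comma-separated feature ids``.
    """

    by_namespace: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", header=None,
                            names=["gene", "namespace", "features"], dtype=str,
                            comment="#")
        table: dict[str, dict[str, tuple[str, ...]]] = {}
        for row in frame.itertuples(index=False):
            ns = table.setdefault(row.namespace, {})
            if row.gene in ns:
                raise NGLError(
                    f"{path}: duplicate annotation for gene {row.gene!r} "
                    f"in namespace {row.namespace!r}")
            features = tuple(f for f in str(row.features).split(",") if f)
            if not features:
                raise NGLError(f"{path}: empty feature list for gene {row.gene!r}")
            ns[row.gene] = features
        return cls(table)

    def namespaces(self) -> list[str]:
        return sorted(self.by_namespace)

    def features_of(self, gene: str, namespace: str) -> tuple[str, ...]:
        """Features of one gene; the identity namespace maps a gene to itself,
        and unannotated genes fall into the reserved ``-1`` bucket."""
        if namespace == IDENTITY_NAMESPACE:
            return (gene,)
        ns = self.by_namespace.get(namespace)
        if ns is None:
            raise NGLError(f"unknown namespace {namespace!r} "
                           f"(available: {', '.join(self.namespaces() + [IDENTITY_NAMESPACE])})")
        return ns.get(gene, (UNANNOTATED,))


@dataclass
class CountsTable:
    """feature id → abundance, with self-describing metadata."""

    namespace: str
    values: dict[str, float]
    metadata: dict[str, object] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        return s.sort_index()

    def total(self) -> float:
        return float(sum(self.values.values()))


def template_gene_sets(mapped: MappedShortReadSet):
    """Yield the set of distinct genes hit by each template's surviving
    alignments (templates with no mapped record yield nothing)."""
    for template in mapped.iter_templates():
        genes = {rec.reference_name for rec in template.records if rec.is_mapped}
        if genes:
            yield genes


def count_template(genes: set[str], annotations: AnnotationTable, namespace: str,
                   policy: str) -> dict[str, float]:
    """Weights contributed by one template under a policy (the brute-force
    definition; the streaming counter must agree with it)."""
    features = sorted({f for g in genes for f in annotations.features_of(g, namespace)})
    if policy == "unique_only":
        return {features[0]: 1.0} if len(features) == 1 else {}
    if policy == "all1":
        return {f: 1.0 for f in features}
    if policy == "dist1":
        w = 1.0 / len(features)
        return {f: w for f in features}
    raise NGLError(f"unknown multiple-mapper policy {policy!r} "
                   f"(available: {', '.join(POLICIES)})")


def count(mapped: MappedShortReadSet, annotations: AnnotationTable,
          namespace: str = "OG", policy: str = "dist1", normalization: str = "raw",
          min_count: float = 0.0) -> CountsTable:
    """Summarize a mapped set into a per-feature abundance table."""
    if policy not in POLICIES:
        raise NGLError(f"unknown multiple-mapper policy {policy!r} "
                       f"(available: {', '.join(POLICIES)})")
    if normalization not in NORMALIZATIONS:
        raise NGLError(f"unknown normalization {normalization!r} "
                       f"(available: {', '.join(NORMALIZATIONS)})")
    if namespace != IDENTITY_NAMESPACE:
        annotations.features_of("", namespace)  # validate the namespace eagerly
    totals: dict[str, float] = {}
    n_templates = 0
    if normalization == "raw":
        for genes in template_gene_sets(mapped):
            n_templates += 1
            for f, w in count_template(genes, annotations, namespace, policy).items():
                totals[f] = totals.get(f, 0.0) + w
    else:
        # gene-level counts first, then divide by gene length (kb), then
        # aggregate into features
        if mapped.catalog is None:
            raise NGLError("normed counting requires the reference catalog lengths")
        gene_totals: dict[str, float] = {}
        for genes in template_gene_sets(mapped):
            n_templates += 1
            for g, w in count_template(genes, annotations, IDENTITY_NAMESPACE,
                                       policy).items():
                gene_totals[g] = gene_totals.get(g, 0.0) + w
        lengths = mapped.catalog.lengths
        for g, v in gene_totals.items():
            v_normed = v / (lengths[g] / 1000.0)
            for f in annotations.features_of(g, namespace):
                totals[f] = totals.get(f, 0.0) + v_normed
    values = {f: v for f, v in sorted(totals.items()) if v >= min_count}
    return CountsTable(
        namespace=namespace,
        values=values,
        metadata={
            "namespace": namespace,
            "multiple": policy,
            "normalization": normalization,
            "min_count": min_count,
            "templates_counted": n_templates,
        },
    )


def format_value(v: float) -> str:
    """Fixed precision up to 6 decimals, trailing zeros stripped."""
    s = f"{v:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_counts(table: CountsTable, path: str | Path) -> None:
    """TSV with header ``feature<TAB>count``, rows lexicographic by feature."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("feature\tcount\n")
        for feature in sorted(table.values):
            fh.write(f"{feature}\t{format_value(table.values[feature])}\n")
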