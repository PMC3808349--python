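"""Gene, protein, domain-interaction and pathway layers.

Connects a pathway catalog (GMT), a SNP-to-gene annotation, and
gene/protein/domain tables into one immutable :class:`LayeredStructure`,
and assigns every gene a domain-interaction confidence class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

VALID_RELATIONS = frozenset({"coding", "upstream", "downstream"})


class AnnotationParseError(ValueError):
    pass


class InteractionClass(IntEnum):
    """Domain-interaction confidence, ordered descending EV > HC > MC > LC.

    NONE marks genes with no proteins, no domains, or no interactions.
    """

    NONE = 0
    LC = 1
    MC = 2
    HC = 3
    EV = 4


_CONFIDENCE_ORDER = (
    InteractionClass.EV,
    InteractionClass.HC,
    InteractionClass.MC,
    InteractionClass.LC,
)


class PathwayCatalog:
    """pathway_id -> (name, member genes), with a gene -> pathways inverse."""

    def __init__(self, entries: Mapping[str, tuple[str, Iterable[str]]]):
        self._pathways: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, (name, genes) in entries.items():
            genes = frozenset(genes)
            if not genes:
                raise AnnotationParseError(f"pathway {pid!r} has no genes")
            self._pathways[pid] = (name, genes)
        inverse: dict[str, set[str]] = {}
        for pid, (_, genes) in self._pathways.items():
            for g in genes:
                inverse.setdefault(g, set()).add(pid)
        self._gene_pathways = {g: frozenset(ps) for g, ps in inverse.items()}

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self):
        return iter(self._pathways)

    def __contains__(self, pathway_id) -> bool:
        return pathway_id in self._pathways

    def name_of(self, pathway_id: str) -> str:
        return self._pathways[pathway_id][0]

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self._pathways[pathway_id][1]

    def pathways_of_gene(self, gene_id: str) -> frozenset[str]:
        return self._gene_pathways.get(gene_id, frozenset())

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(self._gene_pathways)

    def without(self, pathway_id: str) -> "PathwayCatalog":
        return PathwayCatalog(
            {
                pid: (name, genes)
                for pid, (name, genes) in self._pathways.items()
                if pid != pathway_id
            }
        )


class SnpGeneMap:
    """Bidirectional SNP <-> gene links with per-link relation tags."""

    def __init__(self, links: Iterable[tuple[str, str, str]]):
        self._snp_genes: dict[str, set[str]] = {}
        self._gene_snps: dict[str, set[str]] = {}
        self._relation: dict[tuple[str, str], str] = {}
        for snp, gene, relation in links:
            if relation not in VALID_RELATIONS:
                raise AnnotationParseError(
                    f"unknown relation tag {relation!r} for SNP {snp!r}"
                )
            self._snp_genes.setdefault(snp, set()).add(gene)
            self._gene_snps.setdefault(gene, set()).add(snp)
            self._relation[(snp, gene)] = relation

    def genes_of_snp(self, snp_id: str) -> frozenset[str]:
        return frozenset(self._snp_genes.get(snp_id, ()))

    def snps_of_gene(self, gene_id: str) -> frozenset[str]:
        return frozenset(self._gene_snps.get(gene_id, ()))

    def relation(self, snp_id: str, gene_id: str) -> str:
        return self._relation[(snp_id, gene_id)]

    @property
    def snp_ids(self) -> frozenset[str]:
        return frozenset(self._snp_genes)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self._gene_snps)

    def links(self) -> list[tuple[str, str, str]]:
        return [(s, g, r) for (s, g), r in sorted(self._relation.items())]


@dataclass(frozen=True)
class InteractionLayers:
    """gene -> proteins, protein -> domains, and domain-domain interactions.

    Interactions are keyed by the unordered domain pair; duplicate entries
    keep the highest confidence.
    """

    gene_to_proteins: Mapping[str, frozenset[str]]
    protein_to_domains: Mapping[str, frozenset[str]]
    interactions: Mapping[frozenset, InteractionClass]

    def domains_of_gene(self, gene_id: str) -> frozenset[str]:
        domains: set[str] = set()
        for protein in self.gene_to_proteins.get(gene_id, ()):
            domains |= self.protein_to_domains.get(protein, frozenset())
        return frozenset(domains)


@dataclass(frozen=True)
class LayeredStructure:
    """The connected layers plus the per-gene interaction class map."""

    dataset: object  # GenotypeDataset or None
    snp_gene: SnpGeneMap
    catalog: PathwayCatalog
    layers: InteractionLayers
    gene_classes: Mapping[str, InteractionClass] = field(default_factory=dict)

    def snps_of_genes(self, genes: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for g in genes:
            out |= self.snp_gene.snps_of_gene(g)
        return frozenset(out)


# ---------------------------------------------------------------------------
# Loaders / writers
# ---------------------------------------------------------------------------

def load_pathway_catalog(gmt_path) -> PathwayCatalog:
    """Parse a GMT file: tab-separated ``id<TAB>description<TAB>gene...``.

    Duplicate genes within a line are collapsed; empty lines are skipped.
    """
    entries: dict[str, tuple[str, list[str]]] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationParseError(
                    f"{gmt_path}:{lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            pid, name = fields[0], fields[1]
            if pid in entries:
                raise AnnotationParseError(f"{gmt_path}:{lineno}: duplicate pathway {pid!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g.strip()))
            if not genes:
                raise AnnotationParseError(f"{gmt_path}:{lineno}: pathway {pid!r} has no genes")
            entries[pid] = (name, genes)
    if not entries:
        log.warning("%s: empty GMT file -> empty catalog", gmt_path)
    return PathwayCatalog(entries)


def write_gmt(catalog: PathwayCatalog, path) -> None:
    with open(path, "w") as fh:
        for pid in catalog:
            genes = "\t".join(sorted(catalog.genes_of(pid)))
            fh.write(f"{pid}\t{catalog.name_of(pid)}\t{genes}\n")


def load_snp_gene_map(annotation_path, snps) -> SnpGeneMap:
    """Load SNP->gene links from a TSV with columns snp_id, gene_id, relation.

    ``snps`` is the dataset's SNP universe (an iterable of ids or an object
    with ``snp_ids``); links to SNPs outside it are dropped with a log line.
    Dataset SNPs absent from the annotation simply stay unmapped.
    """
    if hasattr(snps, "snp_ids"):
        snps = snps.snp_ids
    universe = set(snps)
    df = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"snp_id", "gene_id", "relation"}
    if not required.issubset(df.columns):
        raise AnnotationParseError(
            f"{annotation_path}: missing columns {sorted(required - set(df.columns))}"
        )
    in_universe = df["snp_id"].isin(universe)
    n_dropped = int((~in_universe).sum())
    if n_dropped:
        log.info(
            "%s: dropped %d links to SNPs outside the dataset", annotation_path, n_dropped
        )
    df = df[in_universe]
    return SnpGeneMap(df[["snp_id", "gene_id", "relation"]].itertuples(index=False, name=None))


def write_snp_gene_tsv(snp_gene: SnpGeneMap, path) -> None:
    pd.DataFrame(snp_gene.links(), columns=["snp_id", "gene_id", "relation"]).to_csv(
        path, sep="\t", index=False
    )


def load_interaction_layers(
    gene_protein_path, protein_domain_path, domain_interaction_path
) -> InteractionLayers:
    gp = pd.read_csv(gene_protein_path, sep="\t", dtype=str)
    pdm = pd.read_csv(protein_domain_path, sep="\t", dtype=str)
    ddi = pd.read_csv(domain_interaction_path, sep="\t", dtype=str)
    for df, cols, path in (
        (gp, {"gene_id", "protein_id"}, gene_protein_path),
        (pdm, {"protein_id", "domain_id"}, protein_domain_path),
        (ddi, {"domain_a", "domain_b", "confidence"}, domain_interaction_path),
    ):
        if not cols.issubset(df.columns):
            raise AnnotationParseError(f"{path}: missing columns {sorted(cols - set(df.columns))}")

    gene_to_proteins: dict[str, set[str]] = {}
    for gene, protein in gp[["gene_id", "protein_id"]].itertuples(index=False, name=None):
        gene_to_proteins.setdefault(gene, set()).add(protein)
    protein_to_domains: dict[str, set[str]] = {}
    for protein, domain in pdm[["protein_id", "domain_id"]].itertuples(index=False, name=None):
        protein_to_domains.setdefault(protein, set()).add(domain)

    interactions: dict[frozenset, InteractionClass] = {}
    for da, db, conf in ddi[["domain_a", "domain_b", "confidence"]].itertuples(
        index=False, name=None
    ):
        try:
            cls = InteractionClass[conf]
        except KeyError:
            raise AnnotationParseError(
                f"{domain_interaction_path}: confidence {conf!r} not in EV/HC/MC/LC"
            ) from None
        if cls is InteractionClass.NONE:
            raise AnnotationParseError(
                f"{domain_interaction_path}: confidence NONE is not a valid label"
            )
        pair = frozenset((da, db))
        if pair not in interactions or interactions[pair] < cls:
            interactions[pair] = cls
    return InteractionLayers(
        gene_to_proteins={g: frozenset(v) for g, v in gene_to_proteins.items()},
        protein_to_domains={p: frozenset(v) for p, v in protein_to_domains.items()},
        interactions=interactions,
    )


def write_interaction_layers(
    layers: InteractionLayers,
    gene_protein_path,
    protein_domain_path,
    domain_interaction_path,
) -> None:
    rows = [
        (g, p) for g, ps in sorted(layers.gene_to_proteins.items()) for p in sorted(ps)
    ]
    pd.DataFrame(rows, columns=["gene_id", "protein_id"]).to_csv(
        gene_protein_path, sep="\t", index=False
    )
    rows = [
        (p, d) for p, ds in sorted(layers.protein_to_domains.items()) for d in sorted(ds)
    ]
    pd.DataFrame(rows, columns=["protein_id", "domain_id"]).to_csv(
        protein_domain_path, sep="\t", index=False
    )
    rows = []
    for pair, cls in sorted(layers.interactions.items(), key=lambda kv: sorted(kv[0])):
        members = sorted(pair)
        da, db = (members[0], members[-1])
        rows.append((da, db, cls.name))
    pd.DataFrame(rows, columns=["domain_a", "domain_b", "confidence"]).to_csv(
        domain_interaction_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Interaction classes
# ---------------------------------------------------------------------------

def assign_interaction_class(gene_id: str, layers: InteractionLayers) -> InteractionClass:
    """Median-style confidence class of a gene's pooled domain interactions.

    Pools every interaction touching any domain of any of the gene's
    proteins (deduplicated by unordered domain pair) and returns the most
    confident class c such that at least 50% of the pooled interactions
    have confidence >= c.  Genes with nothing pooled get NONE.
    """
    domains = layers.domains_of_gene(gene_id)
    if not domains:
        return InteractionClass.NONE
    pooled = [cls for pair, cls in layers.interactions.items() if pair & domains]
    if not pooled:
        return InteractionClass.NONE
    n = len(pooled)
    for cls in _CONFIDENCE_ORDER:
        if sum(1 for c in pooled if c >= cls) * 2 >= n:
            return cls
    return InteractionClass.LC  # unreachable: LC always satisfies the rule


def build_layered_structure(ds, catalog, snp_gene, layers) -> LayeredStructure:
    """Assemble the immutable layered structure; classes are computed for
    every gene appearing in the catalog or the SNP annotation."""
    genes = catalog.all_genes | snp_gene.gene_ids
    classes = {g: assign_interaction_class(g, layers) for g in sorted(genes)}
    return LayeredStructure(
        dataset=ds,
        snp_gene=snp_gene,
        catalog=catalog,
        layers=layers,
        gene_classes=classes,
    )
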