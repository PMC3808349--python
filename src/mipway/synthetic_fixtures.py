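"""Synthetic genotype datasets and annotation layers with known structure.

Everything the pipeline consumes — PLINK bed/bim/fam, a GMT catalog, the
SNP->gene map and the gene/protein/domain tables — can be generated at
small scale, optionally with one implanted associated pathway whose SNPs
carry a chosen allelic odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np

from .annotation_layers import (
    InteractionClass,
    InteractionLayers,
    LayeredStructure,
    PathwayCatalog,
    SnpGeneMap,
    build_layered_structure,
    write_gmt,
    write_interaction_layers,
    write_snp_gene_tsv,
)
from .genotype_core import MISSING, GenotypeDataset, SnpRecord, write_plink_dataset


class FixtureConfigError(ValueError):
    pass


class AnnotationBundle(NamedTuple):
    catalog: PathwayCatalog
    snp_gene: SnpGeneMap
    layers: InteractionLayers

    def build_structure(self, ds=None) -> LayeredStructure:
        return build_layered_structure(ds, self.catalog, self.snp_gene, self.layers)


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    n_snps: Optional[int] = None  # None -> exactly the annotated SNPs
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_pathway: Optional[str] = None
    per_snp_odds_ratio: float = 1.0
    missing_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise FixtureConfigError("maf_range must lie within (0, 0.5]")
        if self.per_snp_odds_ratio < 1.0:
            raise FixtureConfigError("per_snp_odds_ratio must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise FixtureConfigError("need at least one case and one control")
        if not 0.0 <= self.missing_rate < 1.0:
            raise FixtureConfigError("missing_rate must be in [0, 1)")


def case_frequency_for_odds_ratio(p_control: float, odds_ratio: float) -> float:
    """Closed-form case allele frequency realizing an allelic odds ratio."""
    odds = odds_ratio * p_control / (1.0 - p_control)
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

_DEFAULT_CLASS_MIX = {"EV": 0.2, "HC": 0.2, "MC": 0.2, "LC": 0.2, "NONE": 0.2}
_RELATIONS = ("coding", "upstream", "downstream")


def simulate_annotation(
    n_genes: int,
    n_pathways: int,
    genes_per_pathway: int,
    overlap_fraction: float = 0.0,
    class_mix: Optional[dict[str, float]] = None,
    snps_per_gene: tuple[int, int] = (1, 3),
    seed: Optional[int] = None,
) -> AnnotationBundle:
    """Random catalog + SNP map + interaction layers.

    Neighbouring pathways share ``round(overlap_fraction *
    genes_per_pathway)`` genes (cyclically), which exercises the
    characteristic-set logic.  Gene classes are drawn from ``class_mix``;
    each non-NONE gene receives interactions that realise its class
    exactly under the >= 50% rule.
    """
    if min(n_genes, n_pathways, genes_per_pathway) < 1:
        raise FixtureConfigError("counts must be positive")
    if not 0.0 <= overlap_fraction < 1.0:
        raise FixtureConfigError("overlap_fraction must be in [0, 1)")
    lo, hi = snps_per_gene
    if not 1 <= lo <= hi:
        raise FixtureConfigError("snps_per_gene bounds must satisfy 1 <= lo <= hi")
    mix = dict(class_mix or _DEFAULT_CLASS_MIX)
    if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
        raise FixtureConfigError("class_mix must be a non-negative, non-zero mixture")

    k_overlap = round(overlap_fraction * genes_per_pathway)
    unique_per = genes_per_pathway - k_overlap
    if unique_per < 1:
        raise FixtureConfigError("overlap_fraction leaves no pathway-unique genes")
    if n_pathways * unique_per > n_genes:
        raise FixtureConfigError(
            f"need {n_pathways * unique_per} genes for {n_pathways} pathways, "
            f"have {n_genes}"
        )

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]

    blocks = [
        genes[i * unique_per : (i + 1) * unique_per] for i in range(n_pathways)
    ]
    entries = {}
    for i in range(n_pathways):
        members = list(blocks[i])
        if k_overlap and n_pathways > 1:
            members += blocks[(i + 1) % n_pathways][:k_overlap]
        entries[f"PW{i + 1:03d}"] = (f"pathway {i + 1}", members)
    catalog = PathwayCatalog(entries)

    labels = list(mix)
    probs = np.array([mix[c] for c in labels], dtype=float)
    probs /= probs.sum()
    drawn = rng.choice(len(labels), size=n_genes, p=probs)

    gene_to_proteins = {}
    protein_to_domains = {}
    interactions = {}
    for g, li in zip(genes, drawn):
        cls_name = labels[li]
        protein, domain = f"P_{g}", f"D_{g}"
        gene_to_proteins[g] = frozenset({protein})
        protein_to_domains[protein] = frozenset({domain})
        if cls_name == "NONE":
            continue
        cls = InteractionClass[cls_name]
        interactions[frozenset((domain, f"X_{g}_0"))] = cls
        # one extra interaction of equal-or-lower confidence keeps the class
        # (the >= 50% boundary is inclusive) while exercising the median rule
        if rng.random() < 0.5:
            lower = InteractionClass(rng.integers(1, cls + 1))
            interactions[frozenset((domain, f"X_{g}_1"))] = lower
    layers = InteractionLayers(
        gene_to_proteins=gene_to_proteins,
        protein_to_domains=protein_to_domains,
        interactions=interactions,
    )

    links = []
    snp_counter = 0
    for g in genes:
        for _ in range(int(rng.integers(lo, hi + 1))):
            snp_counter += 1
            links.append(
                (f"rs{snp_counter:06d}", g, _RELATIONS[rng.integers(0, 3)])
            )
    return AnnotationBundle(catalog, SnpGeneMap(links), layers)


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    cfg: SimulationConfig,
    annotation: AnnotationBundle,
) -> GenotypeDataset:
    """Case/control genotypes under HWE, with an optional implanted effect.

    Control genotypes are binomial(2, maf) draws; SNPs of genes in
    ``cfg.effect_pathway`` have their case allele frequency tilted to the
    closed-form value matching ``cfg.per_snp_odds_ratio``.  Fully
    reproducible from ``cfg.seed``.
    """
    catalog, snp_gene = annotation.catalog, annotation.snp_gene
    mapped = sorted(snp_gene.snp_ids)
    n_snps = cfg.n_snps if cfg.n_snps is not None else len(mapped)
    if n_snps < len(mapped):
        raise FixtureConfigError(
            f"n_snps={n_snps} smaller than the {len(mapped)} annotated SNPs"
        )
    snp_ids = mapped + [f"rsU{i + 1:06d}" for i in range(n_snps - len(mapped))]

    effect_snps: frozenset[str] = frozenset()
    if cfg.effect_pathway is not None:
        if cfg.effect_pathway not in catalog:
            raise KeyError(f"effect pathway {cfg.effect_pathway!r} not in catalog")
        effect_genes = catalog.genes_of(cfg.effect_pathway)
        effect_snps = frozenset().union(
            *(snp_gene.snps_of_gene(g) for g in effect_genes)
        )

    rng = np.random.default_rng(cfg.seed)
    n_case, n_ctrl = cfg.n_cases, cfg.n_controls
    n_samples = n_case + n_ctrl
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=n_snps)

    p_case = maf.copy()
    if cfg.per_snp_odds_ratio != 1.0 and effect_snps:
        is_effect = np.array([s in effect_snps for s in snp_ids])
        p_case[is_effect] = case_frequency_for_odds_ratio(
            maf[is_effect], cfg.per_snp_odds_ratio
        )

    geno = np.empty((n_samples, n_snps), dtype=np.int8)
    geno[:n_case, :] = rng.binomial(2, p_case[None, :], size=(n_case, n_snps))
    geno[n_case:, :] = rng.binomial(2, maf[None, :], size=(n_ctrl, n_snps))
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno[mask] = MISSING

    snps = [
        SnpRecord(sid, "1", 1000 * (j + 1), "A", "B")
        for j, sid in enumerate(snp_ids)
    ]
    phenotype = np.concatenate(
        [np.ones(n_case, dtype=np.int8), np.zeros(n_ctrl, dtype=np.int8)]
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    return GenotypeDataset(
        snps=snps, sample_ids=sample_ids, phenotype=phenotype, genotypes=geno
    )


def with_duplicated_snps(ds: GenotypeDataset, copies: int = 2) -> GenotypeDataset:
    """Tile every SNP into ``copies`` perfectly correlated columns
    (synthetic total LD) for the LD-robustness property tests."""
    if copies < 2:
        raise FixtureConfigError("copies must be >= 2")
    snps = []
    cols = []
    for j, rec in enumerate(ds.snps):
        for c in range(copies):
            sid = rec.snp_id if c == 0 else f"{rec.snp_id}_dup{c}"
            snps.append(SnpRecord(sid, rec.chrom, rec.pos + c, rec.allele1, rec.allele2))
            cols.append(j)
    return GenotypeDataset(
        snps=snps,
        sample_ids=list(ds.sample_ids),
        phenotype=ds.phenotype.copy(),
        genotypes=ds.genotypes[:, cols].copy(),
    )


def write_fixture(ds: GenotypeDataset, annotation: AnnotationBundle, outdir) -> dict:
    """Write the PLINK triple, GMT and the four annotation TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": outdir / "fixture.bed",
        "bim": outdir / "fixture.bim",
        "fam": outdir / "fixture.fam",
        "gmt": outdir / "pathways.gmt",
        "snp_gene": outdir / "snp_gene.tsv",
        "gene_protein": outdir / "gene_protein.tsv",
        "protein_domain": outdir / "protein_domain.tsv",
        "domain_interaction": outdir / "domain_interaction.tsv",
    }
    write_plink_dataset(ds, outdir / "fixture")
    write_gmt(annotation.catalog, paths["gmt"])
    write_snp_gene_tsv(annotation.snp_gene, paths["snp_gene"])
    write_interaction_layers(
        annotation.layers,
        paths["gene_protein"],
        paths["protein_domain"],
        paths["domain_interaction"],
    )
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# the worked pathway-overlap example
# ---------------------------------------------------------------------------

def figure4_fixture(seed: int = 7):
    """Three-pathway overlap fixture with hand-assigned gene classes.

    Pathway ``x`` holds genes 1-5; gene 1 (class EV, SNPs snp1-snp3) is
    shared with pathways ``y`` and ``z``, gene 2 is EV, gene 3 is HC and
    genes 4-5 carry no interactions.  Class assignments beyond the shared
    EV gene are a plausible reconstruction, chosen so that exactly six
    distinct sets exist for ``x``.  Returns ``(structure, dataset)`` with
    a small 20-sample genotype matrix attached.
    """
    entries = {
        "x": ("pathway x", ["gene1", "gene2", "gene3", "gene4", "gene5"]),
        "y": ("pathway y", ["gene1", "gene6"]),
        "z": ("pathway z", ["gene1", "gene7"]),
    }
    catalog = PathwayCatalog(entries)

    snp_of_gene = {
        "gene1": ["snp1", "snp2", "snp3"],
        "gene2": ["snp4", "snp5"],
        "gene3": ["snp6", "snp7"],
        "gene4": ["snp8", "snp9"],
        "gene5": ["snp10", "snp11"],
        "gene6": ["snp12", "snp13"],
        "gene7": ["snp14", "snp15"],
    }
    links = [
        (snp, gene, "coding")
        for gene, snps in snp_of_gene.items()
        for snp in snps
    ]
    snp_gene = SnpGeneMap(links)

    cls_of_gene = {
        "gene1": "EV",
        "gene2": "EV",
        "gene3": "HC",
        "gene6": "EV",
        "gene7": "HC",
    }
    gene_to_proteins = {g: frozenset({f"P_{g}"}) for g in snp_of_gene}
    protein_to_domains = {
        f"P_{g}": (frozenset({f"D_{g}"}) if g != "gene4" else frozenset())
        for g in snp_of_gene
    }  # gene4: protein without domains; gene5: domain without interactions
    interactions = {
        frozenset((f"D_{g}", f"X_{g}")): InteractionClass[c]
        for g, c in cls_of_gene.items()
    }
    layers = InteractionLayers(
        gene_to_proteins=gene_to_proteins,
        protein_to_domains=protein_to_domains,
        interactions=interactions,
    )

    snp_order = sorted(snp_gene.snp_ids, key=lambda s: int(s.replace("snp", "")))
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, 0.3, size=(20, len(snp_order))).astype(np.int8)
    ds = GenotypeDataset(
        snps=[
            SnpRecord(sid, "1", 1000 * (j + 1), "A", "B")
            for j, sid in enumerate(snp_order)
        ],
        sample_ids=[f"S{i + 1:03d}" for i in range(20)],
        phenotype=np.array([1] * 10 + [0] * 10, dtype=np.int8),
        genotypes=geno,
    )
    structure = build_layered_structure(ds, catalog, snp_gene, layers)
    return structure, ds
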