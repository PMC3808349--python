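"""Construction of the four families of pathway-derived SNP sets.

For each pathway up to ten sets exist: one *simple* set (all SNPs of all
member genes), one *characteristic* set (only genes occurring in no other
pathway), four nested *interaction* tiers keyed by gene confidence class
(ultra = EV, high = +HC, medium = +MC, low = +LC) and four
*characteristic-interaction* tiers (the intersection of both ideas).
SNP-identical variants are collapsed by default, keeping the
least-restrictive label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .annotation_layers import InteractionClass, LayeredStructure

log = logging.getLogger(__name__)

SIMPLE = "simple"
CHARACTERISTIC = "characteristic"
INTERACTION = "interaction"
CHARACTERISTIC_INTERACTION = "characteristic_interaction"

FAMILIES = (SIMPLE, CHARACTERISTIC, INTERACTION, CHARACTERISTIC_INTERACTION)

TIER_CLASSES: dict[str, frozenset[InteractionClass]] = {
    "ultra": frozenset({InteractionClass.EV}),
    "high": frozenset({InteractionClass.EV, InteractionClass.HC}),
    "medium": frozenset({InteractionClass.EV, InteractionClass.HC, InteractionClass.MC}),
    "low": frozenset(
        {InteractionClass.EV, InteractionClass.HC, InteractionClass.MC, InteractionClass.LC}
    ),
}

# order in which set variants are generated; doubles as the deduplication
# precedence (first surviving variant keeps the label)
_BUILD_ORDER: list[tuple[str, str]] = (
    [(SIMPLE, "none"), (CHARACTERISTIC, "none")]
    + [(INTERACTION, t) for t in ("low", "medium", "high", "ultra")]
    + [(CHARACTERISTIC_INTERACTION, t) for t in ("low", "medium", "high", "ultra")]
)

# family precedence used for deterministic tie-breaking in best lists
FAMILY_RANK = {SIMPLE: 0, INTERACTION: 1, CHARACTERISTIC: 2, CHARACTERISTIC_INTERACTION: 3}
TIER_RANK = {"none": 0, "low": 1, "medium": 2, "high": 3, "ultra": 4}


class PathwayLookupError(KeyError):
    pass


@dataclass(frozen=True)
class PathwaySet:
    """One SNP set for one pathway."""

    pathway_id: str
    family: str
    tier: str
    snp_ids: frozenset[str]
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if (self.tier == "none") != (self.family in (SIMPLE, CHARACTERISTIC)):
            raise ValueError(
                f"tier {self.tier!r} is incompatible with family {self.family!r}"
            )
        if self.tier != "none" and self.tier not in TIER_CLASSES:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def set_id(self) -> str:
        return f"{self.pathway_id}:{self.family}:{self.tier}"

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sort_key(self):
        return (self.pathway_id, FAMILY_RANK[self.family], TIER_RANK[self.tier])


def build_sets_for_pathway(
    pathway_id: str,
    structure: LayeredStructure,
    dedup: bool = True,
    min_snps: int = 2,
    snp_universe: Optional[Iterable[str]] = None,
) -> list[PathwaySet]:
    """All set variants of one pathway, smallest-first discarded.

    ``snp_universe`` optionally restricts SNP membership (used by the
    sensitivity stages after top-SNP exclusion).  Sets with fewer than
    ``min_snps`` SNPs are dropped; with ``dedup`` SNP-identical variants
    are collapsed onto the first one in build order.
    """
    catalog = structure.catalog
    if pathway_id not in catalog:
        raise PathwayLookupError(pathway_id)
    universe = None if snp_universe is None else frozenset(snp_universe)
    genes = catalog.genes_of(pathway_id)
    exclusive = frozenset(
        g for g in genes if len(catalog.pathways_of_gene(g)) == 1
    )

    def snps_of(gene_subset: frozenset[str]) -> frozenset[str]:
        snps = structure.snps_of_genes(gene_subset)
        return snps if universe is None else snps & universe

    built: list[PathwaySet] = []
    seen: dict[frozenset[str], PathwaySet] = {}
    n_small = 0
    for family, tier in _BUILD_ORDER:
        members = genes if family in (SIMPLE, INTERACTION) else exclusive
        if tier != "none":
            allowed = TIER_CLASSES[tier]
            members = frozenset(
                g for g in members if structure.gene_classes.get(g) in allowed
            )
        snps = snps_of(members)
        if len(snps) < max(min_snps, 1):
            n_small += 1
            continue
        pset = PathwaySet(pathway_id, family, tier, snps, members)
        if dedup:
            if snps in seen:
                continue
            seen[snps] = pset
        built.append(pset)
    if n_small:
        log.debug("pathway %s: discarded %d empty/undersized variants", pathway_id, n_small)
    return built


def enumerate_all_sets(
    structure: LayeredStructure,
    dedup: bool = True,
    min_snps: int = 2,
    snp_universe: Optional[Iterable[str]] = None,
) -> dict[str, list[PathwaySet]]:
    """Sets for every pathway, ordered by pathway id then build precedence."""
    universe = None if snp_universe is None else frozenset(snp_universe)
    out: dict[str, list[PathwaySet]] = {}
    for pid in sorted(structure.catalog):
        sets = build_sets_for_pathway(
            pid, structure, dedup=dedup, min_snps=min_snps, snp_universe=universe
        )
        if sets:
            out[pid] = sets
    log.info(
        "built %d sets over %d pathways", sum(len(v) for v in out.values()), len(out)
    )
    return out


def dump_sets_tsv(sets_by_pathway: dict[str, list[PathwaySet]], path) -> None:
    """Audit dump: one row per set with its full SNP membership."""
    with open(path, "w") as fh:
        fh.write("pathway_id\tfamily\ttier\tn_genes\tn_snps\tsnp_ids\n")
        for pid in sets_by_pathway:
            for s in sets_by_pathway[pid]:
                fh.write(
                    f"{s.pathway_id}\t{s.family}\t{s.tier}\t{s.n_genes}\t{s.n_snps}\t"
                    + ",".join(sorted(s.snp_ids))
                    + "\n"
                )
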