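"""Four-stage sensitivity pipeline: score all pathway sets, repeat after
excluding top SNPs, intersect the per-stage best lists, and attribute the
winning sets to their construction method.

Stage 0 uses every QC'd SNP; each further stage drops SNPs whose observed
single-marker p-value falls below its exclusion threshold (1e-3, 1e-4,
1e-5 by default), rebuilds the sets on the surviving SNP universe and
rescores them.  A pathway is *consistent* when it carries a set with
p <= alpha in every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .annotation_layers import LayeredStructure
from .genotype_core import GenotypeDataset, allelic_association_pvalues
from .pathway_sets import FAMILIES, FAMILY_RANK, TIER_RANK, enumerate_all_sets
from .set_statistics import SetResult, score_sets

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: tuple[Optional[float], ...] = (None, 1e-3, 1e-4, 1e-5)


@dataclass
class StageResult:
    exclusion_threshold: Optional[float]
    n_snps_used: int
    results: list[SetResult]
    best_list: dict[str, SetResult]

    def to_rows(self) -> list[dict]:
        rows = []
        for r in self.results:
            s = r.pathway_set
            rows.append(
                dict(
                    pathway_id=s.pathway_id,
                    family=s.family,
                    tier=s.tier,
                    n_genes=s.n_genes,
                    n_snps=s.n_snps,
                    statistic=r.statistic,
                    exceedances=r.exceedances,
                    n_perm=r.n_perm,
                    p_value=r.p_value,
                    p_display=r.p_display,
                )
            )
        return rows


@dataclass
class MipReport:
    stages: list[StageResult]
    consistent: dict[str, list[float]]
    attribution: list[dict[str, float]]
    parameters: dict = field(default_factory=dict)
    qc: Optional[dict] = None

    def to_dict(self) -> dict:
        return dict(
            parameters=self.parameters,
            qc=self.qc,
            stages=[
                dict(
                    exclusion_threshold=s.exclusion_threshold,
                    n_snps_used=s.n_snps_used,
                    results=s.to_rows(),
                    best_list={
                        pid: dict(
                            family=r.pathway_set.family,
                            tier=r.pathway_set.tier,
                            p_value=r.p_value,
                            p_display=r.p_display,
                        )
                        for pid, r in sorted(s.best_list.items())
                    },
                )
                for s in self.stages
            ],
            consistent_pathways={
                pid: ps for pid, ps in sorted(self.consistent.items())
            },
            attribution=self.attribution,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def best_list(results: Iterable[SetResult], alpha: float = 0.05) -> dict[str, SetResult]:
    """Per pathway, the single most significant set with p <= alpha.

    Ties at minimal p are broken deterministically: larger SNP count,
    then family precedence (simple > interaction > characteristic >
    characteristic-interaction), then tier precedence, then set id.
    """
    def key(r: SetResult):
        s = r.pathway_set
        return (
            r.p_value,
            -s.n_snps,
            FAMILY_RANK[s.family],
            TIER_RANK[s.tier],
            s.set_id,
        )

    winners: dict[str, SetResult] = {}
    for r in sorted(results, key=key):
        pid = r.pathway_set.pathway_id
        if pid not in winners:
            winners[pid] = r
    return {pid: r for pid, r in winners.items() if r.p_value <= alpha}


def run_stage(
    ds: GenotypeDataset,
    structure: LayeredStructure,
    exclusion_threshold: Optional[float],
    n_perm: int = 5000,
    seed=None,
    alpha: float = 0.05,
    min_set_size: int = 2,
    dedup: bool = True,
) -> StageResult:
    """One pipeline stage on one SNP universe.

    Observed per-SNP p-values are computed once; SNPs below the exclusion
    threshold are removed up front, sets are rebuilt on the survivors and
    scored against a shared permutation stream derived from ``seed``.
    """
    if exclusion_threshold is not None and not 0.0 < exclusion_threshold < 1.0:
        raise ValueError("exclusion_threshold must be None or in (0, 1)")
    assoc = allelic_association_pvalues(ds)
    if exclusion_threshold is None:
        universe = set(ds.snp_ids)
    else:
        keep = assoc.p_value >= exclusion_threshold
        universe = {sid for sid, k in zip(ds.snp_ids, keep) if k}
    sets_by_pathway = enumerate_all_sets(
        structure, dedup=dedup, min_snps=min_set_size, snp_universe=universe
    )
    flat = [s for sets in sets_by_pathway.values() for s in sets]
    if not flat:
        log.warning(
            "stage threshold=%s: no set survives the minimum-size rule",
            exclusion_threshold,
        )
        return StageResult(exclusion_threshold, len(universe), [], {})
    results = score_sets(flat, ds, n_perm=n_perm, seed=seed)
    return StageResult(
        exclusion_threshold=exclusion_threshold,
        n_snps_used=len(universe),
        results=results,
        best_list=best_list(results, alpha=alpha),
    )


def consistent_pathways(stages: Sequence[StageResult]) -> dict[str, list[float]]:
    """Pathways present in every stage's best list, with per-stage p-values."""
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    common = set(stages[0].best_list)
    for s in stages[1:]:
        common &= set(s.best_list)
    return {
        pid: [s.best_list[pid].p_value for s in stages] for pid in sorted(common)
    }


def method_attribution(best_lists) -> dict[str, float]:
    """Fraction of best-list entries won by each set family.

    Accepts one best list (mapping pathway -> SetResult), several of them,
    or a plain iterable of SetResults.  Fractions over the four families
    sum to 1.
    """
    entries: list[SetResult] = []
    if isinstance(best_lists, Mapping):
        entries = list(best_lists.values())
    else:
        for item in best_lists:
            if isinstance(item, Mapping):
                entries.extend(item.values())
            elif isinstance(item, SetResult):
                entries.append(item)
            else:
                raise TypeError(f"cannot interpret {type(item).__name__} as best-list entry")
    if not entries:
        raise ValueError("method attribution of an empty best list is undefined")
    n = len(entries)
    fractions = {fam: 0.0 for fam in FAMILIES}
    for r in entries:
        fractions[r.pathway_set.family] += 1.0 / n
    return fractions


def interaction_fraction(fractions: Mapping[str, float]) -> float:
    """Share of wins from the two interaction-based families."""
    return fractions.get("interaction", 0.0) + fractions.get(
        "characteristic_interaction", 0.0
    )


def run_mip(
    ds: GenotypeDataset,
    structure: LayeredStructure,
    thresholds: Sequence[Optional[float]] = DEFAULT_THRESHOLDS,
    n_perm: int = 5000,
    seed=None,
    alpha: float = 0.05,
    min_set_size: int = 2,
    dedup: bool = True,
    qc_report=None,
) -> MipReport:
    """Run every stage with per-stage seeds spawned from the master seed."""
    if not thresholds:
        raise ValueError("need at least one stage threshold")
    children = np.random.SeedSequence(seed).spawn(len(thresholds))
    stages = [
        run_stage(
            ds,
            structure,
            threshold,
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            alpha=alpha,
            min_set_size=min_set_size,
            dedup=dedup,
        )
        for threshold, child in zip(thresholds, children)
    ]
    consistent = consistent_pathways(stages) if len(stages) >= 2 else {}
    attribution = [
        method_attribution(s.best_list) if s.best_list else {}
        for s in stages
    ]
    return MipReport(
        stages=stages,
        consistent=consistent,
        attribution=attribution,
        parameters=dict(
            version=__version__,
            thresholds=list(thresholds),
            n_perm=n_perm,
            seed=seed,
            alpha=alpha,
            min_set_size=min_set_size,
            dedup=dedup,
            n_samples=ds.n_samples,
            n_cases=ds.n_cases,
            n_snps=ds.n_snps,
        ),
        qc=qc_report.to_dict() if qc_report is not None else None,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_report(report: MipReport, outdir) -> None:
    """TSV tables per stage plus a JSON manifest, under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    for i, stage in enumerate(report.stages):
        pd.DataFrame(stage.to_rows()).to_csv(
            outdir / f"stage{i}_results.tsv", sep="\t", index=False
        )
        rows = [
            dict(
                pathway_id=pid,
                family=r.pathway_set.family,
                tier=r.pathway_set.tier,
                n_snps=r.pathway_set.n_snps,
                p_value=r.p_value,
                p_display=r.p_display,
            )
            for pid, r in sorted(stage.best_list.items())
        ]
        pd.DataFrame(rows).to_csv(outdir / f"stage{i}_best.tsv", sep="\t", index=False)

    rows = [
        {"pathway_id": pid, **{f"stage{i}_p": p for i, p in enumerate(ps)}}
        for pid, ps in sorted(report.consistent.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "consistent_pathways.tsv", sep="\t", index=False)

    rows = []
    for i, fr in enumerate(report.attribution):
        row = {"stage": i, **{fam: fr.get(fam, float("nan")) for fam in FAMILIES}}
        row["interaction_methods"] = (
            interaction_fraction(fr) if fr else float("nan")
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "attribution.tsv", sep="\t", index=False)

    (outdir / "manifest.json").write_text(
        json.dumps(
            dict(parameters=report.parameters, qc=report.qc),
            sort_keys=True,
            indent=2,
        )
    )
    (outdir / "report.json").write_text(report.to_json())
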