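"""End-to-end validation benchmarks: oracle equivalence, null calibration,
power, sensitivity-stage behaviour, structural invariants and determinism.

Each function generates its own inputs from a master seed, runs the
package and measures the outcome, so results are recomputed from scratch
on every call.  Problem sizes are deliberately small enough for a single
CPU; sample sizes and permutation counts follow the validation protocol
fixed for this package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .annotation_layers import build_layered_structure
from .genotype_core import (
    allelic_association_pvalues,
    read_plink_dataset,
    write_plink_dataset,
)
from .mip_pipeline import run_mip
from .pathway_sets import (
    CHARACTERISTIC,
    CHARACTERISTIC_INTERACTION,
    INTERACTION,
    SIMPLE,
    build_sets_for_pathway,
    enumerate_all_sets,
)
from .set_statistics import exact_permutation_pvalue, permutation_set_pvalue, score_sets
from .synthetic_fixtures import (
    SimulationConfig,
    simulate_annotation,
    simulate_dataset,
)


def _spawn_ints(seed: int, n: int) -> list[int]:
    """n reproducible child seeds from one master seed."""
    return [
        int(child.generate_state(1)[0])
        for child in np.random.SeedSequence(seed).spawn(n)
    ]


# ---------------------------------------------------------------------------
# 1. Monte-Carlo scorer vs full-enumeration oracle
# ---------------------------------------------------------------------------

def oracle_equivalence(seed: int = 0) -> dict:
    """Compare the production scorer (in enumeration mode) against the
    brute-force oracle on a 10-sample dataset; they must agree exactly."""
    ann = simulate_annotation(
        n_genes=3, n_pathways=1, genes_per_pathway=3, snps_per_gene=(2, 2), seed=seed
    )
    cfg = SimulationConfig(n_cases=5, n_controls=5, seed=seed + 1)
    ds = simulate_dataset(cfg, ann)
    structure = ann.build_structure(ds)
    pset = build_sets_for_pathway("PW001", structure)[0]

    fast = permutation_set_pvalue(pset, ds, n_perm=300, seed=seed)  # 252 < 300
    oracle = exact_permutation_pvalue(pset, ds)
    return dict(
        n_arrangements=oracle.n_perm,
        fast_p=fast.p_value,
        oracle_p=oracle.p_value,
        exact_match=bool(
            fast.exhaustive
            and fast.n_perm == oracle.n_perm
            and fast.exceedances == oracle.exceedances
            and fast.p_value == oracle.p_value
        ),
    )


# ---------------------------------------------------------------------------
# 2. null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int = 0,
    n_datasets: int = 200,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Set p-values over replicate null datasets (500 SNPs, 100+100
    samples, 10 disjoint pathways, shared permutations): KS uniformity
    p-value and empirical type-I rate at ``alpha``."""
    ann = simulate_annotation(
        n_genes=100,
        n_pathways=10,
        genes_per_pathway=10,
        snps_per_gene=(5, 5),
        seed=seed,
    )
    structure = ann.build_structure()
    sets = [
        s
        for sets in enumerate_all_sets(structure).values()
        for s in sets
        if s.family == SIMPLE
    ]
    assert len(sets) == 10

    pvals: list[float] = []
    for ds_seed, perm_seed in zip(
        _spawn_ints(seed + 1, n_datasets), _spawn_ints(seed + 2, n_datasets)
    ):
        cfg = SimulationConfig(n_cases=100, n_controls=100, seed=ds_seed)
        ds = simulate_dataset(cfg, ann)
        results = score_sets(sets, ds, n_perm=n_perm, seed=perm_seed)
        pvals.extend(r.p_value for r in results)

    pvals_arr = np.asarray(pvals)
    return dict(
        n=len(pvals),
        ks_pvalue=float(kstest(pvals_arr, "uniform").pvalue),
        type1_rate=float((pvals_arr <= alpha).mean()),
    )


# ---------------------------------------------------------------------------
# 3. power / parameter recovery
# ---------------------------------------------------------------------------

def power_recovery(
    seed: int = 0,
    n_seeds: int = 50,
    n_perm: int = 1000,
    odds_ratio: float = 1.3,
) -> dict:
    """Detection and top-rank rates for a 20-SNP implanted pathway
    (odds ratio ``odds_ratio`` per SNP, 1000 cases + 1000 controls)."""
    ann = simulate_annotation(
        n_genes=20,
        n_pathways=10,
        genes_per_pathway=2,
        snps_per_gene=(10, 10),
        seed=seed,
    )
    structure = ann.build_structure()
    sets = [
        s
        for sets in enumerate_all_sets(structure).values()
        for s in sets
        if s.family == SIMPLE
    ]
    effect = "PW001"
    assert any(s.pathway_id == effect and s.n_snps == 20 for s in sets)

    detected = top_ranked = 0
    for ds_seed, perm_seed in zip(
        _spawn_ints(seed + 3, n_seeds), _spawn_ints(seed + 4, n_seeds)
    ):
        cfg = SimulationConfig(
            n_cases=1000,
            n_controls=1000,
            effect_pathway=effect,
            per_snp_odds_ratio=odds_ratio,
            seed=ds_seed,
        )
        ds = simulate_dataset(cfg, ann)
        results = score_sets(sets, ds, n_perm=n_perm, seed=perm_seed)
        by_rank = sorted(results, key=lambda r: (r.p_value, -r.statistic))
        effect_res = next(r for r in results if r.pathway_set.pathway_id == effect)
        if effect_res.p_value <= 0.05:
            detected += 1
        if by_rank[0].pathway_set.pathway_id == effect:
            top_ranked += 1
    return dict(
        n=n_seeds,
        detection_rate=detected / n_seeds,
        top_rank_rate=top_ranked / n_seeds,
    )


# ---------------------------------------------------------------------------
# 4. sensitivity-stage behaviour
# ---------------------------------------------------------------------------

def sensitivity_behaviour(seed: int = 0, n_perm: int = 499) -> dict:
    """One ultra-significant SNP carries an otherwise-null pathway: it must
    be significant with all SNPs and vanish once top SNPs are excluded.

    The fixture's defining property is that the carrier pathway is null
    apart from the spiked SNP, so candidate draws whose remaining SNPs are
    nominally associated by chance are rejected (checked with the analytic
    chi-square tail of the combined statistic) before the pipeline runs.
    """
    from scipy.stats import chi2 as _chi2_dist

    ann = simulate_annotation(
        n_genes=15, n_pathways=5, genes_per_pathway=3, snps_per_gene=(3, 3), seed=seed
    )
    structure = ann.build_structure()
    spike_gene = sorted(ann.catalog.genes_of("PW001"))[0]
    spike = sorted(ann.snp_gene.snps_of_gene(spike_gene))[0]

    ds = spike_p = None
    for ds_seed in _spawn_ints(seed + 1, 100):
        cand = simulate_dataset(
            SimulationConfig(n_cases=250, n_controls=250, seed=ds_seed), ann
        )
        j = int(cand.snp_indices([spike])[0])
        rng = np.random.default_rng(ds_seed + 1)
        cand.genotypes[cand.case_mask, j] = rng.binomial(2, 0.75, size=cand.n_cases)
        cand.genotypes[~cand.case_mask, j] = rng.binomial(2, 0.3, size=cand.n_controls)
        assoc = allelic_association_pvalues(cand)
        if assoc.p_value[j] >= 1e-5:
            continue
        p_of = dict(zip(cand.snp_ids, assoc.p_value))
        clearly_null = True
        for threshold in (1e-3, 1e-4, 1e-5):
            universe = {s for s, p in p_of.items() if p >= threshold}
            for variant in build_sets_for_pathway(
                "PW001", structure, snp_universe=universe
            ):
                t = float(
                    sum(-2.0 * np.log(p_of[s]) for s in variant.snp_ids)
                )
                if _chi2_dist.sf(t, 2 * variant.n_snps) < 0.2:
                    clearly_null = False
        if clearly_null:
            ds = cand
            spike_p = float(assoc.p_value[j])
            break
    if ds is None:
        raise RuntimeError("no draw satisfied the otherwise-null fixture property")
    report = run_mip(ds, structure, n_perm=n_perm, seed=seed + 3)
    in_stage0 = "PW001" in report.stages[0].best_list
    in_later = [("PW001" in s.best_list) for s in report.stages[1:]]
    return dict(
        spike_snp_p=spike_p,
        significant_with_all_snps=bool(in_stage0),
        absent_from_all_exclusion_stages=not any(in_later),
        excluded_from_consistent=("PW001" not in report.consistent),
        criterion_met=bool(in_stage0 and "PW001" not in report.consistent),
    )


# ---------------------------------------------------------------------------
# 5. structural invariants over randomized annotations
# ---------------------------------------------------------------------------

def structural_invariants(seed: int = 0, n_annotations: int = 100) -> dict:
    """Subset-chain checks over randomized annotations; counts violations."""
    violations = 0
    checked = 0
    for s in _spawn_ints(seed + 5, n_annotations):
        ann = simulate_annotation(
            n_genes=24,
            n_pathways=6,
            genes_per_pathway=4,
            overlap_fraction=0.25,
            snps_per_gene=(1, 4),
            seed=s,
        )
        structure = ann.build_structure()
        for pid in structure.catalog:
            d = {
                (ps.family, ps.tier): ps.snp_ids
                for ps in build_sets_for_pathway(
                    pid, structure, dedup=False, min_snps=1
                )
            }
            get = lambda fam, tier: d.get((fam, tier), frozenset())
            simple = get(SIMPLE, "none")
            chain = [get(INTERACTION, t) for t in ("ultra", "high", "medium", "low")]
            ok = chain[0] <= chain[1] <= chain[2] <= chain[3] <= simple
            ok &= get(CHARACTERISTIC, "none") <= simple
            for tier in ("ultra", "high", "medium", "low"):
                ok &= get(INTERACTION, tier) <= get(INTERACTION, "low")
                ok &= get(CHARACTERISTIC_INTERACTION, tier) <= get(INTERACTION, tier)
                ok &= get(CHARACTERISTIC_INTERACTION, tier) <= get(
                    CHARACTERISTIC, "none"
                )
            checked += 1
            if not ok:
                violations += 1
    return dict(n=checked, violations=violations)


# ---------------------------------------------------------------------------
# 6. determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int = 0, workdir=None) -> dict:
    """Same master seed twice -> byte-identical reports; PLINK round trip
    is bit-exact (written to ``workdir`` when given, else a temp dir)."""
    import tempfile
    from pathlib import Path

    ann = simulate_annotation(
        n_genes=12, n_pathways=3, genes_per_pathway=4, snps_per_gene=(2, 3), seed=seed
    )
    cfg = SimulationConfig(n_cases=50, n_controls=50, seed=seed + 1)
    ds = simulate_dataset(cfg, ann)
    structure = ann.build_structure(ds)
    a = run_mip(ds, structure, n_perm=200, seed=seed + 2)
    b = run_mip(ds, structure, n_perm=200, seed=seed + 2)
    reports_identical = a.to_json() == b.to_json()

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        write_plink_dataset(ds, tmp / "a")
        back = read_plink_dataset(tmp / "a.bed", tmp / "a.bim", tmp / "a.fam")
        write_plink_dataset(back, tmp / "b")
        roundtrip_exact = all(
            (tmp / f"a{ext}").read_bytes() == (tmp / f"b{ext}").read_bytes()
            for ext in (".bed", ".bim", ".fam")
        )
    return dict(
        reports_identical=bool(reports_identical),
        plink_roundtrip_bit_exact=bool(roundtrip_exact),
    )
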