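"""Tests for stages, best lists, consistency, attribution and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from mipway.cli import main as cli_main
from mipway.genotype_core import allelic_association_pvalues
from mipway.mip_pipeline import (
    best_list,
    consistent_pathways,
    interaction_fraction,
    method_attribution,
    run_mip,
    run_stage,
    write_report,
)
from mipway.pathway_sets import PathwaySet
from mipway.set_statistics import SetResult
from mipway.synthetic_fixtures import (
    SimulationConfig,
    simulate_annotation,
    simulate_dataset,
)


def fake_result(pathway_id, p, family="simple", tier="none", n_snps=3, n_perm=999):
    snps = frozenset(f"{pathway_id}:{family}:{tier}:s{i}" for i in range(n_snps))
    pset = PathwaySet(pathway_id, family, tier, snps, frozenset({"g"}))
    r = max(0, round(p * (n_perm + 1)) - 1)
    return SetResult(pset, statistic=1.0, n_perm=n_perm, exceedances=r, p_value=p)


# ---------------------------------------------------------------------------
# best list
# ---------------------------------------------------------------------------

def test_best_list_keeps_minimal_p():
    results = [
        fake_result("pw", 0.2),
        fake_result("pw", 0.01, family="interaction", tier="low"),
        fake_result("pw", 0.04, family="characteristic"),
    ]
    best = best_list(results)
    assert set(best) == {"pw"}
    assert best["pw"].p_value == 0.01


def test_best_list_drops_pathway_above_alpha():
    results = [fake_result("pw", 0.06), fake_result("pw", 0.9, family="interaction", tier="low")]
    assert best_list(results) == {}


def test_best_list_boundary_is_inclusive():
    assert set(best_list([fake_result("pw", 0.05)])) == {"pw"}


def test_best_list_tie_broken_by_snp_count():
    small = fake_result("pw", 0.01, family="interaction", tier="low", n_snps=2)
    large = fake_result("pw", 0.01, family="characteristic", n_snps=9)
    best = best_list([small, large])
    assert best["pw"] is large


def test_best_list_tie_broken_by_family_precedence():
    a = fake_result("pw", 0.01, family="characteristic", n_snps=4)
    b = fake_result("pw", 0.01, family="interaction", tier="low", n_snps=4)
    best = best_list([a, b])
    assert best["pw"].pathway_set.family == "interaction"


def test_best_list_one_entry_per_pathway():
    results = [fake_result(f"pw{i}", 0.01) for i in range(3)] + [
        fake_result("pw0", 0.002, family="interaction", tier="high")
    ]
    best = best_list(results)
    assert len(best) == 3
    assert best["pw0"].p_value == 0.002


# ---------------------------------------------------------------------------
# consistency + attribution
# ---------------------------------------------------------------------------

class _FakeStage:
    def __init__(self, best):
        self.best_list = best


def test_consistent_pathways_rule():
    stages = [
        _FakeStage({"a": fake_result("a", 0.01), "b": fake_result("b", 0.02)}),
        _FakeStage({"a": fake_result("a", 0.03)}),
        _FakeStage({"a": fake_result("a", 0.04), "b": fake_result("b", 0.01)}),
    ]
    consistent = consistent_pathways(stages)
    assert set(consistent) == {"a"}
    assert consistent["a"] == [0.01, 0.03, 0.04]


def test_consistent_pathways_empty_stage_gives_empty_intersection():
    stages = [_FakeStage({"a": fake_result("a", 0.01)}), _FakeStage({})]
    assert consistent_pathways(stages) == {}


def test_consistent_pathways_needs_two_stages():
    with pytest.raises(ValueError):
        consistent_pathways([_FakeStage({})])


def test_consistent_invariant_under_stage_order():
    stages = [
        _FakeStage({"a": fake_result("a", 0.01), "b": fake_result("b", 0.02)}),
        _FakeStage({"a": fake_result("a", 0.03), "b": fake_result("b", 0.01)}),
    ]
    assert set(consistent_pathways(stages)) == set(consistent_pathways(stages[::-1]))


def test_attribution_all_interaction():
    entries = [fake_result(f"p{i}", 0.01, family="interaction", tier="low") for i in range(5)]
    fr = method_attribution(entries)
    assert fr["interaction"] == pytest.approx(1.0)
    assert interaction_fraction(fr) == pytest.approx(1.0)


def test_attribution_eleven_of_twentyfour():
    entries = [
        fake_result(f"p{i}", 0.01, family="interaction", tier="low") for i in range(11)
    ] + [fake_result(f"q{i}", 0.01) for i in range(13)]
    fr = method_attribution(entries)
    assert interaction_fraction(fr) == pytest.approx(0.4583, abs=5e-5)


def test_attribution_fractions_sum_to_one():
    entries = (
        [fake_result(f"p{i}", 0.01, family="interaction", tier="ultra") for i in range(3)]
        + [fake_result(f"q{i}", 0.01, family="characteristic") for i in range(2)]
        + [fake_result("r0", 0.01)]
    )
    fr = method_attribution(entries)
    assert sum(fr.values()) == pytest.approx(1.0)


def test_attribution_empty_is_undefined():
    with pytest.raises(ValueError):
        method_attribution([])


def test_attribution_accepts_best_list_mappings():
    bl1 = {"a": fake_result("a", 0.01, family="interaction", tier="low")}
    bl2 = {"b": fake_result("b", 0.01)}
    fr = method_attribution([bl1, bl2])
    assert fr["interaction"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# stages on simulated data
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def modest_effect_data():
    ann = simulate_annotation(
        n_genes=15, n_pathways=3, genes_per_pathway=5, snps_per_gene=(2, 3), seed=21
    )
    cfg = SimulationConfig(
        n_cases=120,
        n_controls=120,
        seed=22,
        effect_pathway="PW001",
        per_snp_odds_ratio=1.8,
    )
    ds = simulate_dataset(cfg, ann)
    return ds, ann.build_structure(ds)


def test_stage_none_uses_full_universe(modest_effect_data):
    ds, structure = modest_effect_data
    stage = run_stage(ds, structure, None, n_perm=200, seed=1)
    assert stage.n_snps_used == ds.n_snps


def test_stage_threshold_excludes_significant_snps(modest_effect_data):
    ds, structure = modest_effect_data
    assoc = allelic_association_pvalues(ds)
    threshold = 1e-3
    stage = run_stage(ds, structure, threshold, n_perm=200, seed=1)
    assert stage.n_snps_used == int((assoc.p_value >= threshold).sum())
    excluded = {sid for sid, p in zip(ds.snp_ids, assoc.p_value) if p < threshold}
    for res in stage.results:
        assert res.pathway_set.snp_ids.isdisjoint(excluded)


def test_stage_threshold_validation(modest_effect_data):
    ds, structure = modest_effect_data
    with pytest.raises(ValueError):
        run_stage(ds, structure, 1.5, n_perm=10, seed=0)


def test_stage_universe_monotone_in_threshold(modest_effect_data):
    # a larger exclusion threshold removes at least as many SNPs
    ds, structure = modest_effect_data
    report = run_mip(ds, structure, n_perm=100, seed=3)
    by_threshold = sorted(
        report.stages, key=lambda s: s.exclusion_threshold or 0.0
    )
    used = [s.n_snps_used for s in by_threshold]
    assert used == sorted(used, reverse=True)
    assert report.stages[0].n_snps_used == max(used)


def test_run_mip_deterministic(modest_effect_data):
    ds, structure = modest_effect_data
    a = run_mip(ds, structure, n_perm=150, seed=42)
    b = run_mip(ds, structure, n_perm=150, seed=42)
    assert a.to_json() == b.to_json()


def test_run_mip_report_schema(modest_effect_data):
    ds, structure = modest_effect_data
    report = run_mip(ds, structure, n_perm=100, seed=5)
    d = report.to_dict()
    assert set(d) == {
        "parameters",
        "qc",
        "stages",
        "consistent_pathways",
        "attribution",
    }
    assert len(d["stages"]) == 4
    thresholds = [s["exclusion_threshold"] for s in d["stages"]]
    assert thresholds == [None, 1e-3, 1e-4, 1e-5]
    for stage in d["stages"]:
        for row in stage["results"]:
            assert 0 < row["p_value"] <= 1
            assert row["p_value"] == (row["exceedances"] + 1) / (row["n_perm"] + 1)
    for pid, ps in d["consistent_pathways"].items():
        assert len(ps) == 4
        assert all(p <= 0.05 for p in ps)


def test_spiked_pathway_drops_out_after_exclusion():
    # one huge-effect SNP carries an otherwise-null pathway: significant with
    # all SNPs, gone once SNPs below the stage thresholds are excluded
    ann = simulate_annotation(
        n_genes=15, n_pathways=5, genes_per_pathway=3, snps_per_gene=(3, 3), seed=30
    )
    cfg = SimulationConfig(n_cases=250, n_controls=250, seed=31)
    ds = simulate_dataset(cfg, ann)
    spike = sorted(ann.snp_gene.snps_of_gene(sorted(ann.catalog.genes_of("PW001"))[0]))[0]
    j = ds.snp_indices([spike])[0]
    rng = np.random.default_rng(32)
    ds.genotypes[ds.case_mask, j] = rng.binomial(2, 0.75, size=ds.n_cases)
    ds.genotypes[~ds.case_mask, j] = rng.binomial(2, 0.3, size=ds.n_controls)

    assoc = allelic_association_pvalues(ds)
    assert assoc.p_value[j] < 1e-5

    structure = ann.build_structure(ds)
    report = run_mip(ds, structure, n_perm=499, seed=33)
    assert "PW001" in report.stages[0].best_list
    for stage in report.stages[1:]:
        assert "PW001" not in stage.best_list
    assert "PW001" not in report.consistent


def test_null_data_rarely_yields_consistent_pathways():
    # type-I control: needing p <= 0.05 in all four stages makes spurious
    # "consistent" pathways rare under the null
    ann = simulate_annotation(
        n_genes=9, n_pathways=3, genes_per_pathway=3, snps_per_gene=(3, 3), seed=50
    )
    structure = ann.build_structure()
    counts = []
    for rep in range(20):
        ds = simulate_dataset(
            SimulationConfig(n_cases=60, n_controls=60, seed=1000 + rep), ann
        )
        report = run_mip(ds, structure, n_perm=200, seed=rep)
        counts.append(len(report.consistent))
    assert np.mean(counts) <= 0.05 * 3


def test_implanted_pathway_consistent_across_stages():
    # a diffuse modest effect (no single SNP below 1e-3) must survive every
    # exclusion stage and come out consistent
    ann = simulate_annotation(
        n_genes=12, n_pathways=3, genes_per_pathway=4, snps_per_gene=(3, 3), seed=60
    )
    for ds_seed in range(61, 75):
        cfg = SimulationConfig(
            n_cases=300,
            n_controls=300,
            effect_pathway="PW001",
            per_snp_odds_ratio=1.25,
            seed=ds_seed,
        )
        ds = simulate_dataset(cfg, ann)
        if allelic_association_pvalues(ds).p_value.min() >= 1e-3:
            break
    else:
        pytest.fail("no draw without a sub-threshold SNP")
    structure = ann.build_structure(ds)
    report = run_mip(ds, structure, n_perm=400, seed=62)
    assert all("PW001" in s.best_list for s in report.stages)
    assert "PW001" in report.consistent


def test_write_report_outputs(tmp_path, modest_effect_data):
    ds, structure = modest_effect_data
    report = run_mip(ds, structure, n_perm=100, seed=5)
    write_report(report, tmp_path)
    for name in (
        "stage0_results.tsv",
        "stage3_results.tsv",
        "stage0_best.tsv",
        "consistent_pathways.tsv",
        "attribution.tsv",
        "manifest.json",
        "report.json",
    ):
        assert (tmp_path / name).exists()
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["parameters"]["n_perm"] == 100


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_simulate_then_run_and_sets(tmp_path):
    runner = CliRunner()
    fixture_dir = tmp_path / "fx"
    res = runner.invoke(
        cli_main,
        [
            "simulate",
            "--n-cases", "60", "--n-controls", "60",
            "--n-genes", "12", "--n-pathways", "3", "--genes-per-pathway", "4",
            "--snps-per-gene", "2,3", "--seed", "9",
            "--out", str(fixture_dir),
        ],
    )
    assert res.exit_code == 0, res.output

    ann_args = [
        "--gmt", str(fixture_dir / "pathways.gmt"),
        "--snp-gene", str(fixture_dir / "snp_gene.tsv"),
        "--gene-protein", str(fixture_dir / "gene_protein.tsv"),
        "--protein-domain", str(fixture_dir / "protein_domain.tsv"),
        "--domain-interactions", str(fixture_dir / "domain_interaction.tsv"),
    ]
    out_dir = tmp_path / "out"
    res = runner.invoke(
        cli_main,
        [
            "run",
            "--bed", str(fixture_dir / "fixture.bed"),
            "--bim", str(fixture_dir / "fixture.bim"),
            "--fam", str(fixture_dir / "fixture.fam"),
            *ann_args,
            "--permutations", "100",
            "--seed", "1",
            "--out", str(out_dir),
        ],
    )
    assert res.exit_code == 0, res.output
    assert (out_dir / "report.json").exists()

    sets_out = tmp_path / "sets.tsv"
    res = runner.invoke(
        cli_main,
        ["sets", "--bim", str(fixture_dir / "fixture.bim"), *ann_args,
         "--out", str(sets_out)],
    )
    assert res.exit_code == 0, res.output
    assert sets_out.read_text().startswith("pathway_id\t")
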