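"""Generator contracts: pedigree structure, Mendelian transmission,
planted-variant and background-tag guarantees, determinism, file round-trips."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from famead import (
    AnnotatedVariant, PlantSpec, SimulationConfig, add_duplicate, read_phenotypes,
    read_truth, read_vcf, simulate_cohort, simulate_genotypes, simulate_pedigree,
    simulate_replication_cohort, write_cohort,
)
from famead.filtering import FilterCriteria, apply_filters, passes_segregation
from famead.simulate import TruthRecord, common_snp_variants
from famead.variants import MISSING


def test_sibling_and_avuncular_truth_degrees():
    """Affected siblings are 1st degree; a nephew through an unobserved
    sibling is 2nd degree to the other affected members."""
    cfg = SimulationConfig(n_families=8, family_size_range=(3, 3),
                           p_second_degree=1.0, seed=2)
    graph, truth = simulate_pedigree(cfg)
    saw_second = False
    for fam, members in truth.families.items():
        sibs = members["affected"][:-1]
        nephew = members["affected"][-1]
        for i, a in enumerate(sibs):
            for b in sibs[i + 1:]:
                assert truth.degree_of(a, b) == "1st"
            assert truth.degree_of(a, nephew) == "2nd"
            saw_second = True
    assert saw_second


def test_min_affected_rejected():
    with pytest.raises(ValueError, match=">= 2 affected"):
        SimulationConfig(family_size_range=(1, 3))


def test_pedigree_determinism():
    cfg = SimulationConfig(n_families=5, seed=42)
    g1, t1 = simulate_pedigree(cfg)
    g2, t2 = simulate_pedigree(SimulationConfig(n_families=5, seed=42))
    assert sorted(g1.edges) == sorted(g2.edges)
    assert t1.degrees == t2.degrees


def test_founder_heterozygosity_at_maf_half(rng):
    """A founder at MAF 0.5 is heterozygous at half of sites (binomial 3-sigma)."""
    cfg = SimulationConfig(n_families=1, n_common_snps=10_000,
                           common_maf_range=(0.5, 0.5), seed=1)
    graph, _ = simulate_pedigree(cfg)
    geno = simulate_genotypes(graph, cfg, rng)
    founder = geno.loc["F01_P1"]
    assert abs((founder == 1).mean() - 0.5) < 0.02


def test_mendelian_consistency_exhaustive():
    """Every non-founder genotype is reachable from its parents' genotypes."""
    cfg = SimulationConfig(n_families=4, n_common_snps=500, seed=3)
    graph, _ = simulate_pedigree(cfg)
    geno = simulate_genotypes(graph, cfg)
    half = {0: {0}, 1: {0, 1}, 2: {1}}
    for child in graph.nodes:
        parents = sorted(graph.predecessors(child))
        if not parents:
            continue
        gc = geno.loc[child].to_numpy()
        gp1 = geno.loc[parents[0]].to_numpy()
        gp2 = geno.loc[parents[1]].to_numpy()
        for c, a, b in zip(gc, gp1, gp2):
            assert c in {x + y for x in half[a] for y in half[b]}


def test_hom_ref_parents_give_hom_ref_child():
    cfg = SimulationConfig(n_families=1, n_common_snps=2000,
                           common_maf_range=(0.05, 0.5), seed=4)
    graph, _ = simulate_pedigree(cfg)
    geno = simulate_genotypes(graph, cfg)
    child = next(v for v in graph.nodes if graph.in_degree(v) == 2)
    p1, p2 = sorted(graph.predecessors(child))
    both_ref = (geno.loc[p1] == 0) & (geno.loc[p2] == 0)
    assert (geno.loc[child][both_ref] == 0).all()


def test_cyclic_pedigree_rejected():
    g = nx.DiGraph([("a", "b"), ("b", "a")])
    with pytest.raises(ValueError, match="cycle"):
        simulate_genotypes(g, SimulationConfig(n_common_snps=10))


def test_duplicate_sample_mode():
    cfg = SimulationConfig(n_families=1, n_common_snps=100, seed=5)
    graph, _ = simulate_pedigree(cfg)
    geno = simulate_genotypes(graph, cfg)
    out = add_duplicate(geno, "F01_A1", "F01_A1_dup")
    assert (out.loc["F01_A1_dup"] == out.loc["F01_A1"]).all()


def test_missingness_applied():
    cfg = SimulationConfig(n_families=2, n_common_snps=5000, missingness=0.1, seed=6)
    graph, _ = simulate_pedigree(cfg)
    geno = simulate_genotypes(graph, cfg)
    frac = (geno.to_numpy() == MISSING).mean()
    assert 0.08 < frac < 0.12


class TestPlantedVariants:
    def test_planted_segregates_and_passes_filters(self, small_cohort):
        truth = small_cohort.truth
        by_id = {v.variant_id: v for v in small_cohort.rare_variants}
        assert truth.planted  # default plan plants in the first families
        for fam, vid in truth.planted.items():
            v = by_id[vid]
            members = truth.families[fam]
            assert passes_segregation(v, members["affected"], members["unaffected"])
            assert v.qd >= 5 and (v.af_gnomad is None or v.af_gnomad < 0.001)
            res = apply_filters([v], FilterCriteria(),
                                affected=members["affected"],
                                unaffected=members["unaffected"])
            assert res.survivors == [v]

    def test_background_variants_fail_exactly_their_tag(self, small_cohort):
        truth = small_cohort.truth
        by_id = {v.variant_id: v for v in small_cohort.rare_variants}
        from famead.filtering import passes_consequence, passes_maf, passes_qd
        crit = FilterCriteria()
        for vid, tag in truth.background_tags.items():
            v = by_id[vid]
            fam = next(f for f in truth.families
                       if v.gene and v.gene.startswith(f"BG_{f}_"))
            members = truth.families[fam]
            checks = {
                "fail_qd": passes_qd(v, crit),
                "fail_consequence": passes_consequence(v, crit),
                "fail_maf": passes_maf(v, crit),
                "fail_segregation": passes_segregation(
                    v, members["affected"], members["unaffected"]),
            }
            assert not checks.pop(tag), (vid, tag)
            assert all(checks.values()), (vid, tag, checks)

    def test_unknown_family_in_plan_rejected(self):
        cfg = SimulationConfig(n_families=2, n_common_snps=10,
                               planted_variant_plan={5: PlantSpec("vus_panel", "BIN1")},
                               n_background_rare=0, seed=1)
        graph, truth = simulate_pedigree(cfg)
        from famead import plant_rare_variants
        with pytest.raises(ValueError, match="unknown family index"):
            plant_rare_variants(truth, cfg)


class TestReplicationCohort:
    def test_null_carrier_frequency_independent_of_label(self):
        cfg = SimulationConfig(replication_sizes=(300, 300, 400),
                               n_replication_genes=5, replication_beta=0.0, seed=7)
        rep = simulate_replication_cohort(cfg)
        assert rep["labels"].value_counts()["EOAD"] == 300
        freqs = rep["carriers"].groupby(rep["labels"]).mean()
        assert (freqs.max() - freqs.min()).max() < 0.06

    def test_strong_effect_orders_carrier_proportions(self):
        cfg = SimulationConfig(replication_sizes=(3000, 3000, 4000),
                               n_replication_genes=3, replication_beta=2.0,
                               causal_genes=(0,), seed=8)
        rep = simulate_replication_cohort(cfg)
        freq = rep["carriers"]["GENE001"].groupby(rep["labels"]).mean()
        assert freq["EOAD"] > freq["LOAD"] > freq["control"]

    def test_zero_sized_cohort(self):
        cfg = SimulationConfig(replication_sizes=(0, 0, 0), seed=1)
        rep = simulate_replication_cohort(cfg)
        assert len(rep["carriers"]) == 0 and len(rep["labels"]) == 0


class TestWriteCohort:
    def test_round_trip_and_determinism(self, tmp_path, small_cohort):
        paths = write_cohort(small_cohort, tmp_path / "a")
        back = read_vcf(paths["vcf"])
        orig = common_snp_variants(small_cohort.genotypes) + small_cohort.rare_variants
        key = lambda v: v.variant_id
        assert sorted(back, key=key) == sorted(orig, key=key)
        assert read_phenotypes(paths["phenotypes"]).shape == small_cohort.phenotypes.shape
        truth = TruthRecord.from_dict(read_truth(paths["truth"]))
        assert truth.planted == small_cohort.truth.planted

        cohort2 = simulate_cohort(small_cohort.config)
        paths2 = write_cohort(cohort2, tmp_path / "b")
        for k in paths:
            assert (tmp_path / "a" / paths[k].split("/")[-1]).read_bytes() == \
                   (tmp_path / "b" / paths2[k].split("/")[-1]).read_bytes(), k

    def test_vcf_header_declares_all_info_keys(self, tmp_path, small_cohort):
        import pysam
        paths = write_cohort(small_cohort, tmp_path)
        with pysam.VariantFile(paths["vcf"]) as vcf:
            declared = set(vcf.header.info.keys())
            used = set()
            for rec in vcf:
                used |= set(rec.info.keys())
        assert used <= declared

    def test_empty_variant_list_yields_valid_header_only_vcf(self, tmp_path):
        from famead import write_vcf
        path = tmp_path / "empty.vcf"
        write_vcf(path, [], samples=["S1", "S2"])
        assert read_vcf(path) == []


def test_planted_variant_ids_exist_in_vcf(tmp_path, small_cohort):
    paths = write_cohort(small_cohort, tmp_path)
    ids = {v.variant_id for v in read_vcf(paths["vcf"])}
    for vid in small_cohort.truth.planted.values():
        assert vid in ids
    for vid in small_cohort.truth.background_tags:
        assert vid in ids
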