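"""Synthetic cohorts with the statistical structure the pipeline assumes.

Emulates a familial early-onset Alzheimer cohort: small pedigrees (2-4
affected per family, optionally one unaffected elderly relative),
genome-wide unlinked common SNPs for kinship estimation (founders in
Hardy-Weinberg equilibrium, Mendelian gene dropping), one planted
fully-segregating rare coding variant in a configurable subset of
families, tagged background rare variants that each violate exactly one
filter stage (for filter audits), APOE genotype mixes, polygenic-score
dosages with a population control set, and an unrelated EOAD/LOAD/
control replication cohort with ancestry covariates drawn from the true
cumulative-logit model.

All randomness flows from ``SimulationConfig.seed``; identical configs
produce identical cohorts and identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import io as fio
from .kinship import classify_degree
from .variants import HET, HOM_REF, MISSING, AnnotatedVariant

PATHOGENIC_GENE_ROTATION = ("APP", "GRN", "PSEN1", "PSEN1", "PSEN1", "PSEN1", "PSEN1", "SORL1")
VUS_GENE_ROTATION = ("ABCA7", "BIN1", "CR1", "FERMT2", "MADD", "PRNP", "SORL1", "SQSTM1")
PTV_GENES = frozenset({"SORL1", "GRN"})

#: APOE genotype mix among affected members (heavy e4 load, rare e2 —
#: the mix the study cohort displays).
APOE_MIX = (("44", 0.30), ("34", 0.35), ("33", 0.30), ("24", 0.02), ("23", 0.03))

BACKGROUND_TAGS = ("fail_qd", "fail_consequence", "fail_maf", "fail_segregation")


@dataclass
class PlantSpec:
    """Per-family planted-variant choice."""

    kind: str  # "pathogenic_panel" | "vus_panel" | "none"
    gene: Optional[str] = None
    cadd: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("pathogenic_panel", "vus_panel", "none"):
            raise ValueError(f"unknown plant kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Shape and parameters of a synthetic cohort.

    Defaults mirror the study conditions: 36 families of 2-4 affected,
    10,000 unlinked common SNPs (allele frequency above 5%) for kinship,
    76 background rare variants per family, a 980-sample population
    control set for PRS centering, and a replication cohort of 833 EOAD,
    521 LOAD and 6,949 controls with 10 ancestry covariates.
    """

    n_families: int = 36
    family_size_range: tuple = (2, 4)
    n_unaffected_elderly: int = 0          # 0 or 1 per family
    n_common_snps: int = 10_000
    common_maf_range: tuple = (0.05, 0.5)
    n_background_rare: int = 76
    planted_variant_plan: Optional[dict] = None   # family index -> PlantSpec
    apoe_plan: Optional[dict] = None              # family index -> list of genotypes
    novel_candidate_plan: tuple = ()              # dicts: gene, families, identical, cadd
    prs_weights: Optional[pd.DataFrame] = None
    n_prs_controls: int = 980
    missingness: float = 0.0
    p_second_degree: float = 0.3
    replication_sizes: tuple = (833, 521, 6949)
    n_replication_genes: int = 37
    replication_carrier_freq: float = 0.05
    replication_beta: float = 0.0
    causal_genes: tuple = ()
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.common_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("common_maf_range must lie within (0, 0.5]")
        if self.family_size_range[0] < 2:
            raise ValueError("families need >= 2 affected members")
        if self.family_size_range[0] > self.family_size_range[1]:
            raise ValueError("family_size_range must be (min, max) with min <= max")
        if self.n_unaffected_elderly not in (0, 1):
            raise ValueError("n_unaffected_elderly must be 0 or 1")
        for name in ("n_families", "n_common_snps", "n_background_rare",
                     "n_prs_controls", "n_replication_genes", "n_pcs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.replication_sizes):
            raise ValueError("replication_sizes must be >= 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for audits and oracle tests."""

    degrees: dict = field(default_factory=dict)        # "a|b" -> degree
    families: dict = field(default_factory=dict)       # fam -> {affected, unaffected}
    planted: dict = field(default_factory=dict)        # fam -> variant_id
    planted_kind: dict = field(default_factory=dict)   # fam -> kind
    background_tags: dict = field(default_factory=dict)  # variant_id -> tag
    apoe: dict = field(default_factory=dict)           # sample -> genotype
    prs_true: dict = field(default_factory=dict)       # sample -> raw PRS
    novel_candidates: dict = field(default_factory=dict)  # gene -> {families, rule}

    @staticmethod
    def pair_key(a: str, b: str) -> str:
        return "|".join(sorted((a, b)))

    def degree_of(self, a: str, b: str) -> str:
        return self.degrees.get(self.pair_key(a, b), "unrelated")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**{k: d.get(k, {}) for k in cls.__dataclass_fields__})


# --------------------------------------------------------------------------
# pedigrees

def _exact_kinship(graph: nx.DiGraph) -> dict:
    """Exact kinship coefficients for all node pairs by the recursive formula."""
    order = list(nx.topological_sort(graph))
    index = {v: i for i, v in enumerate(order)}
    parents = {v: sorted(graph.predecessors(v)) for v in order}
    memo: dict = {}

    def phi(a: str, b: str) -> float:
        if index[a] < index[b]:
            a, b = b, a  # a is the later node, recurse through its parents
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            ps = parents[a]
            val = 0.5 * (1 + phi(*ps)) if len(ps) == 2 else 0.5
        else:
            ps = parents[a]
            val = 0.5 * sum(phi(p, b) for p in ps) if ps else 0.0
        memo[key] = val
        return val

    out = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            out[TruthRecord.pair_key(a, b)] = phi(a, b)
    return out


def simulate_pedigree(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[nx.DiGraph, TruthRecord]:
    """Generate per-family pedigrees and record true pairwise degrees.

    Each family descends from two unobserved founders; affected members
    are siblings, and (with probability ``p_second_degree``, for families
    of three or more affected) the last one is instead a nephew through
    an unobserved sibling, creating second-degree affected pairs. An
    optional unaffected elderly member is an observed founder parent.
    Node attributes: ``family``, ``affected``, ``observed``.
    """
    rng = rng or np.random.default_rng(config.seed)
    graph = nx.DiGraph()
    truth = TruthRecord()
    lo, hi = config.family_size_range
    for fi in range(config.n_families):
        fam = f"F{fi + 1:02d}"
        n_aff = int(rng.integers(lo, hi + 1))
        p1, p2 = f"{fam}_P1", f"{fam}_P2"
        parent_observed = config.n_unaffected_elderly == 1
        graph.add_node(p1, family=fam, affected=False, observed=parent_observed)
        graph.add_node(p2, family=fam, affected=False, observed=False)
        use_nephew = n_aff >= 3 and rng.random() < config.p_second_degree
        n_sibs = n_aff - 1 if use_nephew else n_aff
        sibs = []
        for si in range(n_sibs):
            s = f"{fam}_A{si + 1}"
            graph.add_node(s, family=fam, affected=True, observed=True)
            graph.add_edge(p1, s)
            graph.add_edge(p2, s)
            sibs.append(s)
        affected = list(sibs)
        if use_nephew:
            link, spouse, nephew = f"{fam}_X1", f"{fam}_X2", f"{fam}_A{n_sibs + 1}"
            graph.add_node(link, family=fam, affected=False, observed=False)
            graph.add_edge(p1, link)
            graph.add_edge(p2, link)
            graph.add_node(spouse, family=fam, affected=False, observed=False)
            graph.add_node(nephew, family=fam, affected=True, observed=True)
            graph.add_edge(link, nephew)
            graph.add_edge(spouse, nephew)
            affected.append(nephew)
        unaffected = [p1] if parent_observed else []
        truth.families[fam] = {"affected": affected, "unaffected": unaffected}
    observed = [v for v, d in graph.nodes(data=True) if d["observed"]]
    kin = _exact_kinship(graph)
    for key, phi in kin.items():
        a, b = key.split("|")
        if a in observed and b in observed:
            deg = classify_degree(phi) if phi > 0 else "unrelated"
            truth.degrees[key] = deg
    return graph, truth


def pedigree_with_degrees() -> tuple[nx.DiGraph, dict]:
    """A fixed extended pedigree covering 1st, 2nd and 3rd degree pairs.

    Three generations: grandparents G1/G2, their children A and B (with
    unrelated spouses), grandchildren C (child of A) and E (child of B).
    Observed pairs span parent-offspring and full siblings (1st degree),
    grandparent and avuncular (2nd degree), and first cousins (3rd
    degree). Returns the graph and expected degrees for observed pairs.
    """
    g = nx.DiGraph()
    founders = ["G1", "G2", "SpA", "SpB"]
    for v in founders:
        g.add_node(v, family="X", affected=False, observed=(v == "G1"))
    for v in ("A", "B", "C", "E"):
        g.add_node(v, family="X", affected=True, observed=True)
    g.add_edge("G1", "A"); g.add_edge("G2", "A")
    g.add_edge("G1", "B"); g.add_edge("G2", "B")
    g.add_edge("A", "C"); g.add_edge("SpA", "C")
    g.add_edge("B", "E"); g.add_edge("SpB", "E")
    expected = {}
    for pair, phi in _exact_kinship(g).items():
        a, b = pair.split("|")
        if g.nodes[a]["observed"] and g.nodes[b]["observed"] and phi > 0:
            expected[pair] = classify_degree(phi)
    return g, expected


# --------------------------------------------------------------------------
# genotypes

def simulate_genotypes(graph: nx.DiGraph, config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Mendelian gene dropping at unlinked common SNPs.

    Founders are drawn in Hardy-Weinberg equilibrium at per-site allele
    frequencies uniform on ``common_maf_range``; each non-founder
    receives one allele of each parent uniformly at random. Returns a
    (sample x site) frame of 0/1/2 codes (-1 after optional missingness)
    for every node, observed or not.
    """
    rng = rng or np.random.default_rng(config.seed)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("pedigree graph contains a cycle")
    m = config.n_common_snps
    freqs = rng.uniform(*config.common_maf_range, size=m)
    haplo: dict = {}
    for v in nx.topological_sort(graph):
        parents = sorted(graph.predecessors(v))
        if not parents:
            haplo[v] = (rng.random(m) < freqs, rng.random(m) < freqs)
        elif len(parents) == 2:
            picks = []
            for p in parents:
                h = rng.integers(0, 2, size=m).astype(bool)
                picks.append(np.where(h, haplo[p][0], haplo[p][1]))
            haplo[v] = tuple(picks)
        else:
            raise ValueError(f"node {v} has {len(parents)} parents; need 0 or 2")
    samples = sorted(graph.nodes)
    G = np.vstack([(haplo[s][0].astype(np.int8) + haplo[s][1]) for s in samples])
    if config.missingness > 0:
        mask = rng.random(G.shape) < config.missingness
        G[mask] = MISSING
    cols = [f"snp_{j + 1}" for j in range(m)]
    return pd.DataFrame(G, index=samples, columns=cols)


def add_duplicate(genotypes: pd.DataFrame, source: str, new_id: str) -> pd.DataFrame:
    """Append a technical-duplicate sample with calls identical to *source*."""
    out = genotypes.copy()
    out.loc[new_id] = genotypes.loc[source]
    return out


# --------------------------------------------------------------------------
# rare variants

def _default_plant_plan(config: SimulationConfig) -> dict:
    """Eight pathogenic-panel families, eight VUS families, rest none."""
    plan = {}
    for fi in range(config.n_families):
        if fi < 8:
            plan[fi] = PlantSpec("pathogenic_panel",
                                 PATHOGENIC_GENE_ROTATION[fi % len(PATHOGENIC_GENE_ROTATION)])
        elif fi < 16:
            plan[fi] = PlantSpec("vus_panel",
                                 VUS_GENE_ROTATION[(fi - 8) % len(VUS_GENE_ROTATION)])
        else:
            plan[fi] = PlantSpec("none")
    return plan


class _VariantFactory:
    """Allocates unique loci and builds cohort-wide genotype columns."""

    def __init__(self, all_samples: Sequence[str]):
        self.all_samples = list(all_samples)
        self.counter = 0

    def locus(self) -> tuple[str, int]:
        self.counter += 1
        chrom = str((self.counter - 1) % 22 + 1)
        pos = 50_000_000 + self.counter * 100
        return chrom, pos

    def genotypes(self, het: Sequence[str] = (), hom_alt: Sequence[str] = ()) -> dict:
        g = {s: HOM_REF for s in self.all_samples}
        for s in het:
            g[s] = HET
        for s in hom_alt:
            g[s] = 2
        return g


def plant_rare_variants(truth: TruthRecord, config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None,
                        all_samples: Optional[Sequence[str]] = None
                        ) -> list[AnnotatedVariant]:
    """Planted segregating variants plus tagged background variants.

    The planted variant of each planned family is heterozygous in all
    its affected members, absent elsewhere, and passes every filter
    stage. Each background variant violates exactly the stage its tag
    names (recorded in the truth record) and passes the other three.
    Optional novel-candidate structure plants filter-passing variants in
    a chosen gene across several families.
    """
    rng = rng or np.random.default_rng(config.seed)
    plan = config.planted_variant_plan
    if plan is None:
        plan = _default_plant_plan(config)
    fam_names = sorted(truth.families)
    for key in plan:
        if not (0 <= key < len(fam_names)):
            raise ValueError(f"plant plan references unknown family index {key}")
    if all_samples is None:
        all_samples = sorted(s for fam in truth.families.values()
                             for role in ("affected", "unaffected") for s in fam[role])
    factory = _VariantFactory(all_samples)
    variants: list[AnnotatedVariant] = []

    def rare_af():
        return 0.0 if rng.random() < 0.4 else round(float(rng.uniform(1e-6, 9e-4)), 6)

    for fi, fam in enumerate(fam_names):
        members = truth.families[fam]
        affected, unaffected = members["affected"], members["unaffected"]
        spec = plan.get(fi, PlantSpec("none"))
        if spec.kind != "none":
            gene = spec.gene or (PATHOGENIC_GENE_ROTATION[fi % 8]
                                 if spec.kind == "pathogenic_panel"
                                 else VUS_GENE_ROTATION[fi % 8])
            chrom, pos = factory.locus()
            if spec.kind == "pathogenic_panel":
                truncating = gene in PTV_GENES
                consequence = "frameshift" if truncating else "missense"
                cadd = None if truncating else (spec.cadd or round(float(rng.uniform(25, 35)), 1))
                calls = ("NA",) * 3 if truncating else ("damaging",) * 3
                db_path = not truncating  # novel PTVs are absent from databases
            else:
                consequence = "missense"
                cadd = spec.cadd or round(float(rng.uniform(18, 25)), 1)
                calls = ("damaging", "damaging", rng.choice(["damaging", "tolerated"]))
                db_path = False
            v = AnnotatedVariant(
                chrom=chrom, pos=pos, ref="C", alt="T",
                qd=round(float(rng.uniform(10, 35)), 2), gene=gene,
                consequence=consequence, af_gnomad=rare_af(), af_gnomad_nfe=rare_af(),
                cadd=cadd, sift=calls[0], polyphen2=calls[1], muttaster=calls[2],
                db_pathogenic=bool(db_path),
                genotypes=factory.genotypes(het=affected), tag="planted",
            )
            variants.append(v)
            truth.planted[fam] = v.variant_id
            truth.planted_kind[fam] = spec.kind

        for bi in range(config.n_background_rare):
            tag = BACKGROUND_TAGS[bi % len(BACKGROUND_TAGS)]
            chrom, pos = factory.locus()
            qd = round(float(rng.uniform(10, 35)), 2)
            consequence = "missense"
            splice_distance = None
            af = rare_af()
            carriers = affected
            if tag == "fail_qd":
                qd = round(float(rng.uniform(0.5, 4.9)), 2)
            elif tag == "fail_consequence":
                consequence = str(rng.choice(["synonymous", "intronic"]))
                if consequence == "intronic":
                    splice_distance = int(rng.integers(3, 500))
            elif tag == "fail_maf":
                af = round(float(rng.uniform(0.002, 0.05)), 6)
            elif tag == "fail_segregation":
                if unaffected:
                    carriers = affected + [unaffected[0]]
                elif len(affected) > 1:
                    carriers = affected[:1]
                else:
                    carriers = []  # hom-alt pattern below
            genotypes = (factory.genotypes(hom_alt=affected[:1])
                         if tag == "fail_segregation" and not carriers
                         else factory.genotypes(het=carriers))
            v = AnnotatedVariant(
                chrom=chrom, pos=pos, ref="G", alt="A", qd=qd,
                gene=f"BG_{fam}_{bi + 1:03d}", consequence=consequence,
                splice_distance=splice_distance, af_gnomad=af,
                af_gnomad_nfe=af, cadd=round(float(rng.uniform(0, 30)), 1),
                sift="damaging", polyphen2="damaging", muttaster="damaging",
                genotypes=genotypes, tag=tag,
            )
            variants.append(v)
            truth.background_tags[v.variant_id] = tag

    for cand in config.novel_candidate_plan:
        gene = cand["gene"]
        fams = [fam_names[i] for i in cand["families"]]
        cadds = cand.get("cadd", 20.0)
        if np.isscalar(cadds):
            cadds = [cadds] * len(fams)
        identical = bool(cand.get("identical", False))
        vids = []
        if identical:
            chrom, pos = factory.locus()
            het = [s for fam in fams for s in truth.families[fam]["affected"]]
            v = AnnotatedVariant(
                chrom=chrom, pos=pos, ref="A", alt="G",
                qd=round(float(rng.uniform(10, 35)), 2), gene=gene,
                consequence="missense", af_gnomad=rare_af(),
                cadd=round(float(cadds[0]), 1), sift="damaging",
                polyphen2="damaging", muttaster="damaging",
                genotypes=factory.genotypes(het=het), tag="novel_candidate",
            )
            variants.append(v)
            vids.append(v.variant_id)
        else:
            for fam, cadd in zip(fams, cadds):
                chrom, pos = factory.locus()
                v = AnnotatedVariant(
                    chrom=chrom, pos=pos, ref="A", alt="G",
                    qd=round(float(rng.uniform(10, 35)), 2), gene=gene,
                    consequence="missense", af_gnomad=rare_af(),
                    cadd=round(float(cadd), 1), sift="damaging",
                    polyphen2="damaging", muttaster="damaging",
                    genotypes=factory.genotypes(het=truth.families[fam]["affected"]),
                    tag="novel_candidate",
                )
                variants.append(v)
                vids.append(v.variant_id)
        truth.novel_candidates[gene] = {"families": fams, "variant_ids": vids,
                                        "identical": identical}
    return variants


# --------------------------------------------------------------------------
# APOE, PRS, phenotypes

def assign_apoe(truth: TruthRecord, config: SimulationConfig,
                rng: Optional[np.random.Generator] = None) -> None:
    rng = rng or np.random.default_rng(config.seed)
    fam_names = sorted(truth.families)
    plan = config.apoe_plan or {}
    for key in plan:
        if not (0 <= key < len(fam_names)):
            raise ValueError(f"apoe plan references unknown family index {key}")
    genos, probs = zip(*APOE_MIX)
    for fi, fam in enumerate(fam_names):
        members = truth.families[fam]
        planned = plan.get(fi)
        for i, s in enumerate(members["affected"]):
            if planned is not None:
                truth.apoe[s] = planned[i % len(planned)]
            else:
                truth.apoe[s] = str(rng.choice(genos, p=probs))
        for s in members["unaffected"]:
            truth.apoe[s] = str(rng.choice(["33", "34"], p=[0.8, 0.2]))


def simulate_prs_dosages(samples: Sequence[str], weights: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Hard-call risk-allele dosages, binomial at each panel variant's AF."""
    af = weights["af"].to_numpy(dtype=float)
    D = rng.binomial(2, af, size=(len(samples), len(af)))
    return pd.DataFrame(D, index=list(samples), columns=list(weights["variant_id"]))


def simulate_replication_cohort(config: SimulationConfig,
                                rng: Optional[np.random.Generator] = None) -> dict:
    """Unrelated EOAD/LOAD/control cohort with per-gene carrier indicators.

    Carriers are Bernoulli per gene; outcome labels are drawn from the
    cumulative-logit model with cutpoints matching the target class
    proportions and effect ``replication_beta`` on the carrier indicator
    of each gene named in ``causal_genes`` (so beta = 0 gives an exact
    null with exact class sizes). Ancestry covariates are standard
    normal.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_eoad, n_load, n_ctrl = config.replication_sizes
    n = n_eoad + n_load + n_ctrl
    genes = [f"GENE{g + 1:03d}" for g in range(config.n_replication_genes)]
    carriers = pd.DataFrame(
        rng.random((n, len(genes))) < config.replication_carrier_freq,
        columns=genes, index=[f"R{i + 1:05d}" for i in range(n)],
    )
    pcs = pd.DataFrame(rng.standard_normal((n, config.n_pcs)),
                       columns=[f"PC{k + 1}" for k in range(config.n_pcs)],
                       index=carriers.index)
    causal = [genes[i] if isinstance(i, (int, np.integer)) else i
              for i in config.causal_genes]
    # ordering: control (0) < LOAD (1) < EOAD (2)
    props = np.array([n_ctrl, n_load, n_eoad], dtype=float)
    if n == 0:
        labels = pd.Series([], dtype=object, index=carriers.index)
        return {"carriers": carriers, "labels": labels, "pcs": pcs}
    props /= n
    names = np.array(["control", "LOAD", "EOAD"])
    if not causal or config.replication_beta == 0:
        codes = np.repeat([0, 1, 2], [n_ctrl, n_load, n_eoad])
        codes = rng.permutation(codes)
    else:
        cum = np.cumsum(props)[:-1]
        alpha = np.log(cum / (1 - cum))
        eta = config.replication_beta * carriers[causal].to_numpy(dtype=float).sum(axis=1)
        cumprob = 1.0 / (1.0 + np.exp(-(alpha[None, :] - eta[:, None])))
        u = rng.random(n)
        codes = (u[:, None] > cumprob).sum(axis=1)
    labels = pd.Series(names[codes], index=carriers.index, name="status")
    return {"carriers": carriers, "labels": labels, "pcs": pcs}


# --------------------------------------------------------------------------
# cohort orchestration

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    graph: nx.DiGraph
    truth: TruthRecord
    genotypes: pd.DataFrame          # observed samples x common SNPs
    rare_variants: list
    phenotypes: pd.DataFrame
    weights: pd.DataFrame
    prs_dosages: pd.DataFrame        # cohort samples
    control_dosages: pd.DataFrame    # population control set
    replication: dict

    @property
    def observed_samples(self) -> list:
        return list(self.phenotypes["sample_id"])


def simulate_cohort(config: Optional[SimulationConfig] = None) -> SimulatedCohort:
    """End-to-end synthetic cohort generation from one seeded config."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    graph, truth = simulate_pedigree(config, rng)
    geno_all = simulate_genotypes(graph, config, rng)
    observed = sorted(v for v, d in graph.nodes(data=True) if d["observed"])
    genotypes = geno_all.loc[observed]
    rare = plant_rare_variants(truth, config, rng, all_samples=observed)
    assign_apoe(truth, config, rng)

    weights = config.prs_weights if config.prs_weights is not None else fio.load_prs_weights()
    prs_dosages = simulate_prs_dosages(observed, weights, rng)
    controls = [f"CTRL{i + 1:04d}" for i in range(config.n_prs_controls)]
    control_dosages = simulate_prs_dosages(controls, weights, rng)
    w = weights.set_index("variant_id")["weight"].astype(float)
    use = weights.loc[~weights["is_apoe_region"].astype(bool), "variant_id"]
    for s in observed:
        truth.prs_true[s] = float((prs_dosages.loc[s, use] * w[use]).sum())

    rows = []
    for fam in sorted(truth.families):
        members = truth.families[fam]
        for s in members["affected"]:
            onset = round(float(rng.normal(61, 6)), 1)
            status = "MCI" if rng.random() < 0.1 else ("EOAD" if onset < 70 else "LOAD")
            rows.append((s, fam, status, onset, truth.apoe[s]))
        for s in members["unaffected"]:
            rows.append((s, fam, "unaffected", np.nan, truth.apoe[s]))
    phenotypes = pd.DataFrame(rows, columns=fio.PHENOTYPE_COLUMNS)

    replication = simulate_replication_cohort(config, rng)
    return SimulatedCohort(config, graph, truth, genotypes, rare, phenotypes,
                           weights, prs_dosages, control_dosages, replication)


def common_snp_variants(genotypes: pd.DataFrame) -> list[AnnotatedVariant]:
    """Wrap a common-SNP genotype frame as VCF-writable variant records."""
    samples = list(genotypes.index)
    G = genotypes.to_numpy()
    out = []
    for j in range(G.shape[1]):
        chrom = str(j % 22 + 1)
        pos = 10_000 + (j // 22 + 1) * 10
        out.append(AnnotatedVariant(
            chrom=chrom, pos=pos, ref="A", alt="G",
            genotypes={s: int(G[i, j]) for i, s in enumerate(samples)},
        ))
    return out


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the cohort in the pipeline's input formats.

    Emits one VCF v4.2 (common SNPs and annotated rare variants,
    genotypes for all observed samples), the phenotype and weight TSVs,
    PRS dosage matrices, the replication tables, and the truth record as
    JSON. Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = cohort.observed_samples
    variants = common_snp_variants(cohort.genotypes) + list(cohort.rare_variants)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "weights": outdir / "weights.tsv",
        "prs_dosages": outdir / "prs_dosages.tsv",
        "control_dosages": outdir / "control_dosages.tsv",
        "replication_carriers": outdir / "replication_carriers.tsv",
        "replication_labels": outdir / "replication_labels.tsv",
        "replication_pcs": outdir / "replication_pcs.tsv",
        "truth": outdir / "truth.json",
    }
    fio.write_vcf(paths["vcf"], variants, samples=samples)
    fio.write_phenotypes(paths["phenotypes"], cohort.phenotypes)
    fio.write_weights(paths["weights"], cohort.weights)
    cohort.prs_dosages.to_csv(paths["prs_dosages"], sep="\t", index_label="sample_id")
    cohort.control_dosages.to_csv(paths["control_dosages"], sep="\t", index_label="sample_id")
    cohort.replication["carriers"].astype(int).to_csv(
        paths["replication_carriers"], sep="\t", index_label="sample_id")
    cohort.replication["labels"].to_frame().to_csv(
        paths["replication_labels"], sep="\t", index_label="sample_id")
    cohort.replication["pcs"].to_csv(paths["replication_pcs"], sep="\t",
                                     index_label="sample_id")
    fio.write_truth(paths["truth"], cohort.truth.to_dict())
    return {k: str(v) for k, v in paths.items()}
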