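"""End-to-end orchestration: simulate -> kinship -> families -> filter ->
classify -> prioritize -> risk scores -> family statistics -> categories.

``run_pipeline`` executes the whole analysis on a synthetic cohort and
returns a report of per-stage counts and the family summary table;
``run_table1_report`` computes the cohort statistics and actionability
categories directly from the packaged published family table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .burden import gene_burden
from .classify import classify_variant, prioritize_novel, screen_panel
from .filtering import FilterCriteria, apply_filters, build_family_view
from .io import AFFECTED_STATUSES, load_gene_panel
from .kinship import FamilyClusterer
from .risk import ApoeModel, PolygenicScorer, apoe_risk, family_average
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort
from .stats import categorize, category_counts, summarize_cohort


def build_family_summaries(families, classified_by_family: dict,
                           apoe_by_family: pd.Series, prs_by_family: pd.Series,
                           phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-family summary table from pipeline stage outputs."""
    pheno = phenotypes.set_index("sample_id")
    rows = []
    for fam in families:
        fid = fam.family_id
        classified = classified_by_family.get(fid, [])
        pv = [c for c in classified if c.label == "pathogenic" and c.panel_member]
        vus = [c for c in classified if c.label == "VUS" and c.panel_member]
        affected = fam.affected
        onset = pheno.loc[[s for s in affected if s in pheno.index], "onset_age"]
        apoe_genos = [str(pheno.loc[s, "apoe"]) for s in affected if s in pheno.index]
        rows.append({
            "family_id": fid,
            "n_patients": len(affected),
            "onset_age": float(np.nanmean(onset)) if len(onset) else np.nan,
            "pv_gene": ";".join(sorted({c.variant.gene for c in pv})) if pv else "",
            "vus_gene": ";".join(sorted({c.variant.gene for c in vus})) if vus else "",
            "has_pv": bool(pv),
            "has_vus": bool(vus),
            "has_e44": any(g == "44" for g in apoe_genos),
            "apoe_risk": float(apoe_by_family.get(fid, np.nan)),
            "prs": float(prs_by_family.get(fid, np.nan)),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: Optional[SimulationConfig] = None,
                 cohort: Optional[SimulatedCohort] = None,
                 max_degree: str = "2nd",
                 criteria: Optional[FilterCriteria] = None,
                 panel=None, literature_flags=None, blacklist=None,
                 prs_flag_threshold: float = 0.45,
                 run_burden: bool = False) -> dict:
    """Run the full analysis on a (simulated) cohort; deterministic per seed.

    Returns a report dict with per-stage counts, the family summary
    table, subgroup statistics, category counts, and (optionally) the
    replication burden-test results.
    """
    if cohort is None:
        cohort = simulate_cohort(config or SimulationConfig())
    panel = load_gene_panel() if panel is None else frozenset(panel)
    report: dict = {"seed": cohort.config.seed, "stages": {}}

    # 1. kinship + family reconstruction
    pheno = cohort.phenotypes
    samples = list(pheno["sample_id"])
    affected_mask = pheno["status"].isin(AFFECTED_STATUSES).to_numpy()
    clusterer = FamilyClusterer(max_degree=max_degree).fit(
        cohort.genotypes.loc[samples].to_numpy(), affected_mask, sample_ids=samples)
    families = clusterer.families_
    report["stages"]["kinship_pairs"] = len(clusterer.kinship_)
    report["stages"]["families"] = len(families)

    # 2. per-family filtering
    criteria = criteria or FilterCriteria()
    survivors_by_family: dict = {}
    audits = {}
    for fam in families:
        view = build_family_view(cohort.rare_variants, fam)
        result = apply_filters(view, criteria, family=fam)
        survivors_by_family[fam.family_id] = result.survivors
        audits[fam.family_id] = result.audit
    report["filter_audits"] = audits
    report["stages"]["surviving_variants"] = sum(
        len(v) for v in survivors_by_family.values())

    # 3. classification against the panel
    classified_by_family = {}
    for fid, survivors in survivors_by_family.items():
        hits, _ = screen_panel(survivors, panel)
        classified_by_family[fid] = [classify_variant(v, panel) for v in hits]
    solved = {fid for fid, cls in classified_by_family.items()
              if any(c.label == "pathogenic" for c in cls)}
    report["stages"]["solved_families"] = len(solved)

    # 4. novel-gene prioritization over the unsolved families
    nonpanel_by_family = {
        fid: [v for v in survivors if v.gene not in panel]
        for fid, survivors in survivors_by_family.items()
    }
    candidates = prioritize_novel(nonpanel_by_family, solved_families=solved,
                                  blacklist=blacklist,
                                  literature_flags=literature_flags, panel=panel)
    report["candidates"] = [
        {"gene": c.gene, "rule": c.selection_rule, "families": c.family_ids}
        for c in candidates
    ]
    report["stages"]["novel_candidates"] = len(candidates)

    # 5. risk scores: population-centered PRS and APOE, family-averaged
    scorer = PolygenicScorer(weights=cohort.weights).fit(cohort.control_dosages)
    prs_scaled = scorer.transform(cohort.prs_dosages)
    model = ApoeModel()
    apoe_scores = pd.Series(
        {s: apoe_risk(g, model) for s, g in zip(pheno["sample_id"], pheno["apoe"])})
    membership = pd.concat([
        pd.DataFrame({"sample_id": fam.affected, "family_id": fam.family_id,
                      "affected": True})
        for fam in families
    ], ignore_index=True) if families else pd.DataFrame(
        columns=["sample_id", "family_id", "affected"])
    prs_by_family = family_average(prs_scaled, membership)
    apoe_by_family = family_average(apoe_scores, membership)

    # 6. summaries, subgroup statistics, categories
    summaries = build_family_summaries(families, classified_by_family,
                                       apoe_by_family, prs_by_family, pheno)
    report["family_summaries"] = summaries
    if len(summaries) >= 4:
        report["statistics"] = summarize_cohort(summaries, prs_flag_threshold)
    assignments = categorize(summaries, prs_flag_threshold)
    report["categories"] = category_counts(assignments)

    # 7. optional replication burden test on the unrelated cohort
    if run_burden:
        rep = cohort.replication
        report["burden"] = gene_burden(rep["carriers"], rep["labels"], rep["pcs"])
    return report


def run_table1_report(prs_flag_threshold: float = 0.45) -> dict:
    """Cohort statistics and categories from the packaged published table."""
    from .stats import load_table1

    df = load_table1()
    report = {"n_families": len(df),
              "statistics": summarize_cohort(df, prs_flag_threshold)}
    report["categories"] = report["statistics"]["categories"]
    report["assignments"] = categorize(df, prs_flag_threshold)
    return report
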