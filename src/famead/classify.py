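"""Gene-panel screening, variant classification, and cross-family
prioritization of novel candidate genes.

Classification operationalizes the study's reading of the ACMG
guidance with two explicit rules, evaluated pathogenic-first:

* pathogenic — reported pathogenic in variant databases, or a
  truncating (nonsense/frameshift) variant in a gene where such
  protein-truncating variants are established as highly penetrant
  (default {SORL1, GRN});
* likely benign — called "tolerated" by at least two of the three
  in-silico predictors (SIFT, PolyPhen2, MutationTaster) and/or a
  scaled CADD score below 10;
* otherwise a variant of uncertain significance (VUS).

Novel-gene prioritization (run after removing families with a confirmed
monogenic cause) selects: identical variants shared by >= 2 families;
genes hit by distinct variants in >= 3 families; and genes hit in
exactly 2 families where both variants have CADD > 15 and the gene has
a literature link to dementia/neurodegeneration (a per-gene boolean
input). Candidates whose every supporting variant matches a blacklist
(regions or variant ids modelling manual IGV review) are flagged and
dropped from the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .variants import AnnotatedVariant

PTV_CLASSES = frozenset({"nonsense", "frameshift"})
DEFAULT_PTV_GENES = frozenset({"SORL1", "GRN"})

LABELS = ("pathogenic", "VUS", "likely_benign")
RULES = ("shared_variant_2plus", "gene_3plus_families", "gene_2fam_cadd15_lit")


@dataclass
class ClassifiedVariant:
    variant: AnnotatedVariant
    panel_member: bool
    label: str
    rationale: list

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


@dataclass
class PrioritizedCandidate:
    gene: str
    variant_ids: list
    family_ids: list
    selection_rule: str
    blacklist_flag: bool = False


@dataclass
class Blacklist:
    """Regions (chrom, start, end; 1-based inclusive) and exact variant ids."""

    regions: list = field(default_factory=list)
    variant_ids: frozenset = frozenset()

    def matches(self, v: AnnotatedVariant) -> bool:
        if v.variant_id in self.variant_ids:
            return True
        return any(chrom == v.chrom and start <= v.pos <= end
                   for chrom, start, end in self.regions)


def screen_panel(variants: Iterable[AnnotatedVariant],
                 panel: Iterable[str]) -> tuple[list, list]:
    """Partition variants into (panel hits, non-panel)."""
    panel = frozenset(panel)
    hits, rest = [], []
    for v in variants:
        (hits if v.gene in panel else rest).append(v)
    return hits, rest


def classify_variant(v: AnnotatedVariant,
                     panel: Iterable[str] = (),
                     ptv_genes: frozenset = DEFAULT_PTV_GENES) -> ClassifiedVariant:
    """Assign exactly one label with the rules that fired as rationale."""
    panel = frozenset(panel)
    rationale: list[str] = []
    if v.db_pathogenic:
        rationale.append("reported pathogenic in variant databases")
    if v.consequence in PTV_CLASSES and v.gene in ptv_genes:
        rationale.append(
            f"truncating ({v.consequence}) variant in high-penetrance PTV gene {v.gene}")
    if rationale:
        return ClassifiedVariant(v, v.gene in panel, "pathogenic", rationale)

    n_tol = v.n_predictors("tolerated")
    if n_tol >= 2:
        rationale.append(f"tolerated by {n_tol}/3 prediction tools")
    if v.cadd is not None and v.cadd < 10:
        rationale.append(f"CADD {v.cadd:g} < 10")
    if rationale:
        return ClassifiedVariant(v, v.gene in panel, "likely_benign", rationale)

    if v.cadd is None and v.n_predictors("NA") == 3:
        rationale.append("insufficient evidence: no predictor calls, no CADD")
    else:
        rationale.append("not database-pathogenic; damaging/uncertain predictions")
    return ClassifiedVariant(v, v.gene in panel, "VUS", rationale)


def prioritize_novel(survivors_by_family: Mapping[str, Sequence[AnnotatedVariant]],
                     solved_families: Iterable[str] = (),
                     blacklist: Optional[Blacklist] = None,
                     literature_flags: Optional[Mapping[str, bool]] = None,
                     panel: Iterable[str] = (),
                     min_cadd_two_family: float = 15.0,
                     return_flagged: bool = False):
    """Select candidate genes shared across families.

    Parameters map the study's manual steps to data: *solved_families*
    (confirmed monogenic cause) are removed first; *panel* genes are not
    novel and are skipped; *literature_flags* is the per-gene curated
    dementia/neurodegeneration link; *blacklist* models IGV review.

    Returns the selected candidates (one per gene, rules checked in
    priority order shared-variant > 3-family gene > 2-family CADD/lit);
    with ``return_flagged=True`` also returns the blacklist-excluded ones.
    """
    solved = set(solved_families)
    panel = frozenset(panel)
    literature_flags = literature_flags or {}
    blacklist = blacklist or Blacklist()

    by_gene: dict[str, dict] = {}
    for fam, variants in survivors_by_family.items():
        if fam in solved:
            continue
        for v in variants:
            if v.gene is None or v.gene in panel:
                continue
            g = by_gene.setdefault(v.gene, {"families": set(), "variants": {},
                                            "fam_max_cadd": {}})
            g["families"].add(fam)
            g["variants"].setdefault(v.variant_id, {"families": set(), "variant": v})
            g["variants"][v.variant_id]["families"].add(fam)
            prev = g["fam_max_cadd"].get(fam)
            cadd = v.cadd if v.cadd is not None else float("-inf")
            g["fam_max_cadd"][fam] = max(prev, cadd) if prev is not None else cadd

    selected, flagged = [], []
    for gene in sorted(by_gene):
        info = by_gene[gene]
        shared = {vid: rec for vid, rec in info["variants"].items()
                  if len(rec["families"]) >= 2}
        rule = None
        if shared:
            rule, vids = "shared_variant_2plus", sorted(shared)
            fams = sorted(set().union(*(rec["families"] for rec in shared.values())))
        elif len(info["families"]) >= 3:
            rule, vids = "gene_3plus_families", sorted(info["variants"])
            fams = sorted(info["families"])
        elif len(info["families"]) == 2:
            if (all(c > min_cadd_two_family for c in info["fam_max_cadd"].values())
                    and literature_flags.get(gene, False)):
                rule, vids = "gene_2fam_cadd15_lit", sorted(info["variants"])
                fams = sorted(info["families"])
        if rule is None:
            continue
        all_black = all(blacklist.matches(info["variants"][vid]["variant"])
                        for vid in vids)
        cand = PrioritizedCandidate(gene, vids, fams, rule, blacklist_flag=all_black)
        (flagged if all_black else selected).append(cand)
    if return_flagged:
        return selected, flagged
    return selected
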