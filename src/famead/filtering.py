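"""Per-family variant views and the four-stage rare-variant segregation filter.

The filter stages, applied in order, keep variants that are
(1) confidently called (quality-by-depth >= 5),
(2) coding (missense / nonsense / frameshift) or within 2 bp of an
    exon-intron junction,
(3) rare (gnomAD allele frequency < 0.1%), and
(4) segregating: heterozygous in every affected family member and
    homozygous reference in every unaffected member.

Missing QD or allele frequency passes its stage (absence of evidence —
novel variants are often absent from gnomAD); a missing consequence
fails stage 2 (coding status cannot be confirmed). The stages are
conjunctive, so the surviving set is order-independent even though the
per-stage audit counts are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .kinship import FamilyUnit
from .variants import HET, HOM_REF, AnnotatedVariant

STAGES = ("qd", "consequence", "maf", "segregation")

CODING_CLASSES = frozenset({"missense", "nonsense", "frameshift"})


@dataclass
class FilterCriteria:
    """Thresholds of the four-stage filter (defaults are the study settings)."""

    min_qd: float = 5.0
    consequence_whitelist: frozenset = CODING_CLASSES
    splice_window: int = 2
    max_maf: float = 0.001
    use_nfe: bool = False  # gate on the NFE frequency instead of the total

    def __post_init__(self) -> None:
        if self.min_qd < 0 or self.max_maf <= 0 or self.splice_window < 0:
            raise ValueError("filter thresholds must be positive")


@dataclass
class FilterResult:
    survivors: list
    audit: dict = field(default_factory=dict)


def build_family_view(variants: Sequence[AnnotatedVariant],
                      family: FamilyUnit) -> list[AnnotatedVariant]:
    """Restrict a cohort variant list to one family.

    Keeps records with at least one non-reference call among family
    members and subsets genotype columns to the family. Raises KeyError
    naming the sample if a member is absent from a record.
    """
    members = family.sample_ids
    view = []
    for v in variants:
        sub = v.subset(members)  # raises KeyError naming a missing sample
        if any(g in (HET, 2) for g in sub.genotypes.values()):
            view.append(sub)
    return view


def passes_qd(v: AnnotatedVariant, criteria: FilterCriteria) -> bool:
    return v.qd is None or v.qd >= criteria.min_qd


def passes_consequence(v: AnnotatedVariant, criteria: FilterCriteria) -> bool:
    if v.consequence is None:
        return False
    if v.consequence in criteria.consequence_whitelist:
        return True
    if v.consequence == "splice":
        return v.splice_distance is None or v.splice_distance <= criteria.splice_window
    if v.consequence == "intronic":
        return (v.splice_distance is not None
                and v.splice_distance <= criteria.splice_window)
    return False


def passes_maf(v: AnnotatedVariant, criteria: FilterCriteria) -> bool:
    af = v.af_gnomad_nfe if criteria.use_nfe else v.af_gnomad
    return af is None or af < criteria.max_maf


def passes_segregation(v: AnnotatedVariant, affected: Sequence[str],
                       unaffected: Sequence[str] = ()) -> bool:
    """Heterozygous in all affected, homozygous reference in all unaffected.

    A missing genotype in either group fails: segregation cannot be
    confirmed without the call.
    """
    return (all(v.genotypes.get(s) == HET for s in affected)
            and all(v.genotypes.get(s) == HOM_REF for s in unaffected))


def apply_filters(view: Sequence[AnnotatedVariant],
                  criteria: Optional[FilterCriteria] = None,
                  affected: Sequence[str] = (),
                  unaffected: Sequence[str] = (),
                  family: Optional[FamilyUnit] = None) -> FilterResult:
    """Apply the four filter stages in order, keeping per-stage audit counts.

    Affected/unaffected sample lists may be given directly or through a
    FamilyUnit. The audit maps each stage to the number of variants it
    removed, plus ``input`` and ``surviving`` totals.
    """
    criteria = criteria or FilterCriteria()
    if family is not None:
        affected, unaffected = family.affected, family.unaffected
    if not affected:
        raise ValueError("segregation filtering needs at least one affected sample")
    stage_tests = {
        "qd": lambda v: passes_qd(v, criteria),
        "consequence": lambda v: passes_consequence(v, criteria),
        "maf": lambda v: passes_maf(v, criteria),
        "segregation": lambda v: passes_segregation(v, affected, unaffected),
    }
    audit = {"input": len(view)}
    current = list(view)
    for stage in STAGES:
        kept = [v for v in current if stage_tests[stage](v)]
        audit[stage] = len(current) - len(kept)
        current = kept
    audit["surviving"] = len(current)
    return FilterResult(survivors=current, audit=audit)
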