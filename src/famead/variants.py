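"""Domain types for annotated variants and genotype codes.

Genotypes are coded per sample as ``0`` (hom-ref), ``1`` (het), ``2``
(hom-alt) and ``-1`` (missing). Records are biallelic; multi-allelic VCF
records are decomposed into one record per alternate allele on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: Closed vocabulary for the functional consequence of a variant.
CONSEQUENCE_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "synonymous", "intronic"}
)

#: In-silico predictor call vocabulary (SIFT / PolyPhen2 / MutationTaster).
PREDICTOR_CALLS = frozenset({"damaging", "tolerated", "NA"})


@dataclass
class AnnotatedVariant:
    """One biallelic variant with its annotations and per-sample genotypes.

    Annotation fields (``qd``, ``cadd``, allele frequencies, predictor
    calls) are treated as input data: they come from an external
    annotation pipeline and are never recomputed here. Any of them may be
    missing (``None``), which the filters handle explicitly.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qd: Optional[float] = None
    gene: Optional[str] = None
    consequence: Optional[str] = None
    splice_distance: Optional[int] = None
    af_gnomad: Optional[float] = None
    af_gnomad_nfe: Optional[float] = None
    cadd: Optional[float] = None
    sift: str = "NA"
    polyphen2: str = "NA"
    muttaster: str = "NA"
    db_pathogenic: bool = False
    genotypes: dict = field(default_factory=dict)
    tag: Optional[str] = None  # generator bookkeeping (truth audit), not used by filters

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("af_gnomad", "af_gnomad_nfe"):
            af = getattr(self, name)
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {af}")
        if self.consequence is not None and self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class: {self.consequence!r}")
        for name in ("sift", "polyphen2", "muttaster"):
            if getattr(self, name) not in PREDICTOR_CALLS:
                raise ValueError(f"{name} must be one of {sorted(PREDICTOR_CALLS)}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def predictor_calls(self) -> tuple:
        return (self.sift, self.polyphen2, self.muttaster)

    def n_predictors(self, call: str) -> int:
        return sum(c == call for c in self.predictor_calls)

    def genotype(self, sample: str) -> int:
        try:
            return self.genotypes[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} missing from variant {self.variant_id}")

    def subset(self, samples) -> "AnnotatedVariant":
        """Copy of this record with genotype columns restricted to *samples*."""
        for s in samples:
            if s not in self.genotypes:
                raise KeyError(f"sample {s!r} missing from variant {self.variant_id}")
        out = AnnotatedVariant(
            chrom=self.chrom, pos=self.pos, ref=self.ref, alt=self.alt,
            qd=self.qd, gene=self.gene, consequence=self.consequence,
            splice_distance=self.splice_distance, af_gnomad=self.af_gnomad,
            af_gnomad_nfe=self.af_gnomad_nfe, cadd=self.cadd, sift=self.sift,
            polyphen2=self.polyphen2, muttaster=self.muttaster,
            db_pathogenic=self.db_pathogenic,
            genotypes={s: self.genotypes[s] for s in samples}, tag=self.tag,
        )
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotatedVariant):
            return NotImplemented
        return (
            self.chrom == other.chrom and self.pos == other.pos
            and self.ref == other.ref and self.alt == other.alt
            and self.qd == other.qd and self.gene == other.gene
            and self.consequence == other.consequence
            and self.splice_distance == other.splice_distance
            and self.af_gnomad == other.af_gnomad
            and self.af_gnomad_nfe == other.af_gnomad_nfe
            and self.cadd == other.cadd
            and self.predictor_calls == other.predictor_calls
            and self.db_pathogenic == other.db_pathogenic
            and self.genotypes == other.genotypes
        )
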