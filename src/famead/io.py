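"""Reading and writing the pipeline's file formats.

VCF v4.2 is handled through pysam. Because htslib stores INFO floats as
float32, annotation floats are rounded to 6 decimals on both write and
read; generators emit values already at that precision, so a write ->
read cycle is lossless.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import MISSING, AnnotatedVariant

_GT_TO_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
_CODE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}

PHENOTYPE_COLUMNS = ["sample_id", "family_id", "status", "onset_age", "apoe"]
AFFECTED_STATUSES = frozenset({"EOAD", "LOAD", "MCI"})

_INFO_FIELDS = [
    ("QD", "1", "Float", "Quality by depth"),
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ_CLASS", "1", "String", "Consequence class"),
    ("SPLICE_DIST", "1", "Integer", "Distance (bp) to nearest exon-intron junction"),
    ("AF_GNOMAD", "1", "Float", "gnomAD total allele frequency"),
    ("AF_GNOMAD_NFE", "1", "Float", "gnomAD non-Finnish European allele frequency"),
    ("CADD", "1", "Float", "Scaled CADD deleteriousness score"),
    ("SIFT", "1", "String", "SIFT call"),
    ("POLYPHEN2", "1", "String", "PolyPhen2 call"),
    ("MUTTASTER", "1", "String", "MutationTaster call"),
    ("DB_PATH", "0", "Flag", "Reported pathogenic in variant databases"),
]


def _round6(x):
    return None if x is None else round(float(x), 6)


def _vcf_header(samples: Sequence[str], contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(path, variants: Sequence[AnnotatedVariant], samples: Optional[Sequence[str]] = None) -> None:
    """Write variants as a VCF v4.2 file with genotypes and INFO annotations.

    All variants must carry genotypes for the same sample set. An empty
    variant list yields a valid header-only VCF (samples may then be
    passed explicitly).
    """
    if samples is None:
        samples = sorted(variants[0].genotypes) if variants else []
    contigs = sorted({v.chrom for v in variants}, key=_contig_key) or ["1"]
    header = _vcf_header(samples, contigs)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (_contig_key(v.chrom), v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            info = rec.info
            if v.qd is not None:
                info["QD"] = _round6(v.qd)
            if v.gene is not None:
                info["GENE"] = v.gene
            if v.consequence is not None:
                info["CSQ_CLASS"] = v.consequence
            if v.splice_distance is not None:
                info["SPLICE_DIST"] = int(v.splice_distance)
            if v.af_gnomad is not None:
                info["AF_GNOMAD"] = _round6(v.af_gnomad)
            if v.af_gnomad_nfe is not None:
                info["AF_GNOMAD_NFE"] = _round6(v.af_gnomad_nfe)
            if v.cadd is not None:
                info["CADD"] = _round6(v.cadd)
            for key, val in (("SIFT", v.sift), ("POLYPHEN2", v.polyphen2), ("MUTTASTER", v.muttaster)):
                if val != "NA":
                    info[key] = val
            if v.db_pathogenic:
                info["DB_PATH"] = True
            for s in samples:
                rec.samples[s]["GT"] = _CODE_TO_GT[v.genotypes.get(s, MISSING)]
            out.write(rec)


def _contig_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def read_vcf(path) -> list[AnnotatedVariant]:
    """Read a VCF into AnnotatedVariant records, decomposing multi-allelics."""
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                genotypes = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes[s] = MISSING
                    else:
                        # re-code per alternate allele: count copies of allele ai+1
                        genotypes[s] = sum(a == ai + 1 for a in gt)
                info = rec.info

                def _f(key, ndigits):
                    # undo float32 storage noise: QD/CADD carry <= 2 decimals,
                    # allele frequencies <= 6
                    val = info.get(key)
                    return None if val is None else round(float(val), ndigits)
                out.append(AnnotatedVariant(
                    chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                    qd=_f("QD", 4), gene=info.get("GENE"),
                    consequence=info.get("CSQ_CLASS"),
                    splice_distance=info.get("SPLICE_DIST"),
                    af_gnomad=_f("AF_GNOMAD", 6), af_gnomad_nfe=_f("AF_GNOMAD_NFE", 6),
                    cadd=_f("CADD", 4), sift=info.get("SIFT", "NA"),
                    polyphen2=info.get("POLYPHEN2", "NA"),
                    muttaster=info.get("MUTTASTER", "NA"),
                    db_pathogenic=bool(info.get("DB_PATH", False)),
                    genotypes=genotypes,
                ))
    return out


def genotype_matrix(variants: Sequence[AnnotatedVariant], samples: Sequence[str]) -> np.ndarray:
    """Stack genotype codes into an (n_samples, n_variants) int8 matrix."""
    G = np.empty((len(samples), len(variants)), dtype=np.int8)
    for j, v in enumerate(variants):
        for i, s in enumerate(samples):
            G[i, j] = v.genotypes.get(s, MISSING)
    return G


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, columns=PHENOTYPE_COLUMNS)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str, "apoe": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_weights(path, weights: pd.DataFrame) -> None:
    weights.to_csv(path, sep="\t", index=False)


def load_prs_weights(path=None) -> pd.DataFrame:
    """Load a PRS weight table (default: the packaged synthetic 35-variant set).

    The packaged table is a synthetic stand-in of realistic magnitude for
    the study's supplementary weight list, which is not publicly printed.
    """
    if path is None:
        ref = resources.files("famead.data") / "prs_weights_s3_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "risk_allele", "weight", "imputation_r2", "is_apoe_region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if not np.isfinite(df["weight"]).all():
        raise ValueError("weights must be finite")
    return df


def load_gene_panel(path=None) -> frozenset:
    """Load a gene panel (one symbol per line, ``#`` comments allowed).

    The packaged default is a synthetic stand-in panel assembled from
    canonical AD / FTD-ALS / prion / parkinsonism genes.
    """
    if path is None:
        ref = resources.files("famead.data") / "dementia_panel_synthetic.txt"
        with resources.as_file(ref) as p:
            text = p.read_text()
    else:
        text = Path(path).read_text()
    genes = [line.strip() for line in text.splitlines()]
    return frozenset(g for g in genes if g and not g.startswith("#"))


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
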