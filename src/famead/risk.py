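"""Polygenic and APOE risk scoring on a population-centered log-odds scale.

The polygenic risk score (PRS) is the weighted sum of risk-allele
dosages over the non-APOE panel variants, gated on imputation quality
(variants with R^2 below 0.3 are dropped; array-genotyped panels use a
0.6 gate). Scores are centered by subtracting the mean raw PRS of a
population-based control set (study reference: n = 980), so 0 is the
population mean and exp(score) is an odds ratio.

APOE risk uses fixed per-allele meta-GWAS effects: +1.20 per e4 allele
and -0.47 per e2 allele, minus a population-mean offset. The offset is
calibrated so that the neutral e3/e3 genotype scores -0.36 on the
centered scale (an e3/e3 individual sits 0.36 log-odds below the
population mean, which itself carries e4 alleles); e4/e4 then scores
2.04. Family-level risk is the arithmetic mean over affected members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import load_prs_weights

APOE_GENOTYPES = frozenset({"22", "23", "24", "33", "34", "44"})

DEFAULT_MIN_R2 = 0.3       # imputed sequencing data
ARRAY_MIN_R2 = 0.6         # array-genotyped / high-quality imputation gate


@dataclass
class ApoeModel:
    """Per-allele APOE effects and the population-mean offset.

    ``risk(e3/e3) = -population_mean_offset`` by construction.
    """

    effect_e4: float = 1.20
    effect_e2: float = -0.47
    population_mean_offset: float = 0.36


def apoe_risk(genotype, model: Optional[ApoeModel] = None) -> float:
    """Population-scaled APOE risk of one diplotype (e.g. ``"34"``).

    Missing genotypes (None or ``"NA"``) propagate as NaN.
    """
    model = model or ApoeModel()
    if genotype is None:
        return float("nan")
    g = str(genotype)
    if g in ("NA", "nan", ""):
        return float("nan")
    if g not in APOE_GENOTYPES:
        raise ValueError(f"unknown APOE genotype {genotype!r}")
    n4, n2 = g.count("4"), g.count("2")
    return model.effect_e4 * n4 + model.effect_e2 * n2 - model.population_mean_offset


def compute_prs(dosages: pd.DataFrame, weights: Optional[pd.DataFrame] = None,
                min_r2: float = DEFAULT_MIN_R2) -> pd.Series:
    """Raw weighted PRS per sample.

    *dosages* is samples x variants with risk-allele dosages in [0, 2]
    (hard calls or fractional imputed dosages). Panel variants flagged
    ``is_apoe_region`` or with imputation R^2 below *min_r2* are dropped
    before summation; a missing (NaN) dosage skips that variant for that
    sample only.
    """
    weights = load_prs_weights() if weights is None else weights
    use = weights.loc[~weights["is_apoe_region"].astype(bool)
                      & (weights["imputation_r2"] >= min_r2)]
    ids = [v for v in use["variant_id"] if v in dosages.columns]
    if not ids:
        raise ValueError("no panel variants left after quality gating")
    D = dosages[ids].astype(float)
    finite = D.to_numpy()[~np.isnan(D.to_numpy())]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    w = use.set_index("variant_id").loc[ids, "weight"].astype(float)
    return (D * w).sum(axis=1, skipna=True).rename("prs_raw")


def scale_to_population(prs_raw: pd.Series, control_scores) -> pd.Series:
    """Center raw scores on the mean of a population control set."""
    control = np.asarray(control_scores, dtype=float)
    if control.size == 0:
        raise ValueError("control score set must be non-empty")
    return (prs_raw - control.mean()).rename("prs_scaled")


class PolygenicScorer(BaseEstimator, TransformerMixin):
    """Population-centered PRS as a scikit-learn transformer.

    ``fit`` learns the population mean from a control dosage matrix;
    ``transform`` returns centered scores for new samples on the same
    weight panel.
    """

    def __init__(self, weights: Optional[pd.DataFrame] = None,
                 min_r2: float = DEFAULT_MIN_R2):
        self.weights = weights
        self.min_r2 = min_r2

    def fit(self, X: pd.DataFrame, y=None):
        raw = compute_prs(X, self.weights, self.min_r2)
        self.population_mean_ = float(raw.mean())
        self.n_controls_ = len(raw)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "population_mean_"):
            raise AttributeError("PolygenicScorer is not fitted")
        raw = compute_prs(X, self.weights, self.min_r2)
        return (raw - self.population_mean_).rename("prs_scaled")


def family_average(values: Union[pd.Series, Mapping[str, float]],
                   membership: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of per-sample scores over affected members per family.

    *membership* needs columns ``sample_id``, ``family_id`` and either a
    boolean ``affected`` column or a ``status`` column ({EOAD, LOAD, MCI}
    count as affected). Unaffected relatives are excluded; every family
    must retain at least one affected member with a finite score.
    """
    values = pd.Series(values, dtype=float)
    df = membership.copy()
    if "affected" not in df.columns:
        if "status" not in df.columns:
            raise ValueError("membership needs an 'affected' or 'status' column")
        df["affected"] = df["status"].isin(("EOAD", "LOAD", "MCI"))
    df = df.loc[df["affected"].astype(bool)]
    df = df.assign(score=df["sample_id"].map(values))
    out = df.groupby("family_id")["score"].mean()
    bad = out.index[out.isna()]
    if len(bad):
        raise ValueError(f"families without a scored affected member: {list(bad)}")
    return out


def beta_to_or(beta):
    """Log-odds effect size to odds ratio."""
    return np.exp(beta)


def prs_source_correlation(prs_a: pd.Series, prs_b: pd.Series) -> dict:
    """Diagnostic R^2 between two dosage sources' scores on shared samples."""
    shared = prs_a.index.intersection(prs_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    r = float(np.corrcoef(prs_a.loc[shared], prs_b.loc[shared])[0, 1])
    return {"n": int(len(shared)), "r": r, "r2": r ** 2}
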