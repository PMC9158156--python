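"""Pairwise kinship estimation, relationship-degree classification, and
family clustering.

The kinship coefficient phi is estimated from biallelic genotype calls
with the robust within-family moment estimator of Manichaikul et al.
(the KING-robust form)::

    phi = (N_het,het - 2 * N_opp,hom) / (N_het_i + N_het_j)

where counts run over sites non-missing in both samples, after removing
sites with sample-set minor allele frequency at or below the common-
variant cutoff (default 5%). The ratio of expectations is exactly 0.5
for duplicates, 0.25 / 0.125 / 0.0625 for 1st / 2nd / 3rd degree pairs
and 0 for unrelated pairs, independent of the allele-frequency spectrum.

Degrees are inferred with the standard powers-of-two midpoint bands
(2^-3/2 ... 2^-9/2). Families are connected components of the graph whose
edges join pairs related at or closer than a maximum degree (default
2nd), keeping components with at least two affected members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .variants import MISSING

#: Inference bands: phi > 0.354 duplicate/MZ; (0.177, 0.354] 1st; etc.
DEGREE_CUTOFFS = (0.354, 0.177, 0.0884, 0.0442)
DEGREE_NAMES = ("duplicate/MZ", "1st", "2nd", "3rd", "unrelated")
#: Rank of each degree, closer relationships first (for "degree <= max" tests).
DEGREE_RANK = {name: i for i, name in enumerate(DEGREE_NAMES)}

MIN_USABLE_SITES = 100


@dataclass
class KinshipEstimate:
    sample_i: str
    sample_j: str
    n_sites: int
    n_het_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int
    phi: float
    degree: str
    low_sites: bool = False


@dataclass
class FamilyUnit:
    """A cluster of related samples with affected/unaffected roles."""

    family_id: str
    members: dict = field(default_factory=dict)  # sample_id -> "affected" | "unaffected"
    degrees: dict = field(default_factory=dict)  # frozenset({i, j}) -> degree

    @property
    def affected(self) -> list:
        return sorted(s for s, role in self.members.items() if role == "affected")

    @property
    def unaffected(self) -> list:
        return sorted(s for s, role in self.members.items() if role == "unaffected")

    @property
    def sample_ids(self) -> list:
        return sorted(self.members)


def classify_degree(phi: float) -> str:
    """Map a kinship coefficient to a relationship-degree label.

    Interval boundaries belong to the closer-relationship side
    (half-open intervals), NaN maps to ``"unknown"``.
    """
    if phi is None or (isinstance(phi, float) and np.isnan(phi)):
        return "unknown"
    for cutoff, name in zip(DEGREE_CUTOFFS, DEGREE_NAMES):
        if phi > cutoff:
            return name
    return DEGREE_NAMES[-1]


def _common_site_mask(G: np.ndarray, maf_filter: float) -> np.ndarray:
    """Sites whose sample-set minor allele frequency exceeds *maf_filter*."""
    valid = G != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(valid, G, 0).sum(axis=0) / (2.0 * valid.sum(axis=0))
    maf = np.minimum(af, 1.0 - af)
    return np.nan_to_num(maf, nan=0.0) > maf_filter


def kinship_pair(genotypes_i, genotypes_j, maf_filter: float = 0.05,
                 sample_i: str = "i", sample_j: str = "j",
                 prefiltered: bool = False) -> KinshipEstimate:
    """Kinship estimate for one pair of genotype vectors on a shared site list.

    With ``prefiltered=False`` the common-variant filter is computed from
    the two-sample allele frequencies; pass ``prefiltered=True`` when sites
    were already restricted to common variants at cohort level.
    """
    gi = np.asarray(genotypes_i, dtype=np.int16)
    gj = np.asarray(genotypes_j, dtype=np.int16)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length: disjoint site sets?")
    G = np.vstack([gi, gj])
    keep = np.ones(gi.shape[0], bool) if prefiltered else _common_site_mask(G, maf_filter)
    both = keep & (gi != MISSING) & (gj != MISSING)
    if not both.any():
        raise ValueError(f"no shared usable sites for pair ({sample_i}, {sample_j})")
    a, b = gi[both], gj[both]
    n_het_het = int(np.sum((a == 1) & (b == 1)))
    n_opp_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    n_het_i = int(np.sum(a == 1))
    n_het_j = int(np.sum(b == 1))
    denom = n_het_i + n_het_j
    phi = np.nan if denom == 0 else (n_het_het - 2.0 * n_opp_hom) / denom
    n_sites = int(both.sum())
    low = n_sites < MIN_USABLE_SITES
    if low:
        warnings.warn(
            f"only {n_sites} usable sites for pair ({sample_i}, {sample_j})",
            stacklevel=2,
        )
    return KinshipEstimate(sample_i, sample_j, n_sites, n_het_het, n_opp_hom,
                           n_het_i, n_het_j, phi, classify_degree(phi), low)


def pairwise_kinship(G: np.ndarray, sample_ids: Sequence[str],
                     maf_filter: float = 0.05) -> pd.DataFrame:
    """All-pairs kinship from an (n_samples, n_sites) genotype matrix.

    The common-variant filter uses allele frequencies pooled over the
    input sample set. Returns one row per unordered pair.
    """
    G = np.asarray(G)
    if G.shape[0] != len(sample_ids):
        raise ValueError("genotype matrix rows must match sample_ids")
    keep = _common_site_mask(G, maf_filter)
    G = G[:, keep]
    V = (G != MISSING)
    H = ((G == 1) & V).astype(np.float32)
    A = ((G == 0) & V).astype(np.float32)
    B = ((G == 2) & V).astype(np.float32)
    Vf = V.astype(np.float32)
    HH = H @ H.T
    OH = A @ B.T + B @ A.T
    NHi = H @ Vf.T          # het count of row sample over sites shared with col sample
    NS = Vf @ Vf.T
    rows = []
    n = len(sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            denom = NHi[i, j] + NHi[j, i]
            phi = np.nan if denom == 0 else (HH[i, j] - 2.0 * OH[i, j]) / denom
            n_sites = int(NS[i, j])
            rows.append((sample_ids[i], sample_ids[j], n_sites, int(HH[i, j]),
                         int(OH[i, j]), int(NHi[i, j]), int(NHi[j, i]),
                         phi, classify_degree(phi), n_sites < MIN_USABLE_SITES))
    return pd.DataFrame(rows, columns=[
        "sample_i", "sample_j", "n_sites", "n_het_het", "n_opp_hom",
        "n_het_i", "n_het_j", "phi", "degree", "low_sites",
    ])


def cluster_families(estimates: pd.DataFrame, affected: dict,
                     max_degree: str = "2nd", min_affected: int = 2) -> list[FamilyUnit]:
    """Cluster samples into family units from pairwise kinship estimates.

    Edges join pairs at *max_degree* or closer; connected components with
    at least *min_affected* affected members become families. Family ids
    are deterministic: components are ordered by their sorted member ids.
    """
    if max_degree not in DEGREE_RANK or max_degree == "unrelated":
        raise ValueError(f"max_degree must be one of {DEGREE_NAMES[:-1]}")
    graph = nx.Graph()
    graph.add_nodes_from(affected)
    degree_of = {}
    for row in estimates.itertuples(index=False):
        degree_of[frozenset((row.sample_i, row.sample_j))] = row.degree
        if row.degree in DEGREE_RANK and DEGREE_RANK[row.degree] <= DEGREE_RANK[max_degree]:
            graph.add_edge(row.sample_i, row.sample_j)
    components = sorted((sorted(c) for c in nx.connected_components(graph)))
    families = []
    for members in components:
        n_aff = sum(bool(affected.get(s, False)) for s in members)
        if n_aff < min_affected:
            continue
        fam = FamilyUnit(
            family_id=f"FAM{len(families) + 1:03d}",
            members={s: ("affected" if affected.get(s, False) else "unaffected")
                     for s in members},
            degrees={pair: deg for pair, deg in degree_of.items()
                     if pair <= set(members)},
        )
        families.append(fam)
    return families


class FamilyClusterer(BaseEstimator):
    """Cluster samples into families from genotype calls at common SNPs.

    A scikit-learn style clusterer: ``fit(X, y)`` takes an
    (n_samples, n_sites) genotype matrix (codes 0/1/2, -1 missing) and a
    boolean affection-status vector, estimates all pairwise kinship
    coefficients, classifies degrees, and connects samples related at
    ``max_degree`` or closer. Components with fewer than ``min_affected``
    affected members are labelled noise (-1).

    Attributes
    ----------
    kinship_ : DataFrame of pairwise estimates (phi, counts, degree).
    families_ : list of FamilyUnit in deterministic id order.
    labels_ : ndarray of family index per sample, -1 for unclustered.
    """

    def __init__(self, maf_filter: float = 0.05, max_degree: str = "2nd",
                 min_affected: int = 2):
        self.maf_filter = maf_filter
        self.max_degree = max_degree
        self.min_affected = min_affected

    def fit(self, X, y, sample_ids: Optional[Sequence[str]] = None):
        X = np.asarray(X)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_sites) aligned with y")
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(X.shape[0])]
        self.sample_ids_ = list(sample_ids)
        self.kinship_ = pairwise_kinship(X, self.sample_ids_, self.maf_filter)
        affected = dict(zip(self.sample_ids_, y))
        self.families_ = cluster_families(self.kinship_, affected,
                                          self.max_degree, self.min_affected)
        label_of = {}
        for k, fam in enumerate(self.families_):
            for s in fam.members:
                label_of[s] = k
        self.labels_ = np.array([label_of.get(s, -1) for s in self.sample_ids_])
        return self

    def fit_predict(self, X, y, sample_ids=None):
        return self.fit(X, y, sample_ids=sample_ids).labels_
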