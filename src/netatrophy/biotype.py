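"""Biotype discovery from individual network-weighted abnormality profiles.

Patients are compared by the Pearson correlation of their network-weighted
W-score profiles (a patients x patients similarity matrix, higher = more
alike); k-means with Euclidean distance on the similarity-matrix rows
partitions the cohort, the mean silhouette over k = 2..10 selects the
number of biotypes, and the subgroups are contrasted on drug-use variables
with a two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import CohortData

__all__ = ["ClusterResult", "similarity_matrix", "cluster_biotypes", "compare_subgroups"]

WEAK_STRUCTURE_SILHOUETTE = 0.25


@dataclass
class ClusterResult:
    similarity: np.ndarray
    labels: np.ndarray                 # 1..k, cluster 1 is the largest
    silhouette: pd.Series              # mean silhouette per candidate k
    chosen_k: int
    restarts: int
    weak_structure: bool


def similarity_matrix(profiles: np.ndarray) -> np.ndarray:
    """Patients x patients Pearson similarity of abnormality profiles."""
    p = np.asarray(profiles, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3:
        raise ValueError("need >= 3 patient profiles")
    if np.any(p.std(axis=1) == 0):
        raise ValueError("constant patient profile: correlation undefined")
    s = np.corrcoef(p)
    np.fill_diagonal(s, 1.0)
    return s


def cluster_biotypes(
    similarity: np.ndarray,
    k_range: range = range(2, 11),
    restarts: int = 100,
    seed: int = 0,
    features: str = "similarity_rows",
    profiles: np.ndarray | None = None,
) -> ClusterResult:
    """Best-of-restarts k-means with silhouette model selection.

    Feature vectors are the rows of the similarity matrix (the default) or
    the raw profiles (``features="profiles"``, a sensitivity mode). For each
    k the best of ``restarts`` random initializations (lowest within-cluster
    sum of squares) is kept; the k with the highest mean silhouette wins,
    smaller k breaking ties. Labels are relabeled by descending cluster
    size, so biotype 1 is the larger subgroup. A maximum silhouette below
    0.25 flags weak cluster structure.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    n = s.shape[0]
    if max(k_range) > n - 1:
        raise ValueError("k_range exceeds n - 1")
    if features == "similarity_rows":
        feat = s
    elif features == "profiles":
        if profiles is None:
            raise ValueError("features='profiles' requires profiles")
        feat = np.asarray(profiles, dtype=float)
    else:
        raise ValueError("features must be 'similarity_rows' or 'profiles'")

    rng = np.random.default_rng(seed)
    sil = {}
    labels_by_k = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=restarts,
                    random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(feat)
        sil[k] = float(silhouette_score(feat, lab, metric="euclidean"))
        labels_by_k[k] = lab
    sil_series = pd.Series(sil, name="silhouette")
    best = max(sil, key=lambda k: (sil[k], -k))
    lab = labels_by_k[best]
    # relabel by descending cluster size: biotype 1 = largest subgroup
    order = pd.Series(lab).value_counts().index.to_list()
    remap = {old: i + 1 for i, old in enumerate(order)}
    relabeled = np.array([remap[v] for v in lab])
    return ClusterResult(
        similarity=s,
        labels=relabeled,
        silhouette=sil_series,
        chosen_k=best,
        restarts=restarts,
        weak_structure=max(sil.values()) < WEAK_STRUCTURE_SILHOUETTE,
    )


def compare_subgroups(
    labels: np.ndarray,
    cohort: CohortData,
    variables: tuple[str, ...] = ("duration", "dose"),
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t contrasts of drug-use variables between two biotypes.

    ``labels`` aligns with the cohort's patients in order. Student's pooled
    t by default (``welch=True`` for unequal variances); two-tailed p.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly 2 subgroups required")
    patients = cohort.subjects.loc[cohort.is_patient].reset_index(drop=True)
    if len(patients) != labels.size:
        raise ValueError("labels must align with the cohort's patients")
    rows = []
    for var in variables:
        vals = patients[var].to_numpy(dtype=float)
        a = vals[(labels == groups[0]) & np.isfinite(vals)]
        b = vals[(labels == groups[1]) & np.isfinite(vals)]
        if a.size < 2 or b.size < 2:
            raise ValueError(f"subgroup with fewer than 2 values for {var!r}")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append({
            "variable": var, "t": float(t), "p": float(p),
            "mean_1": a.mean(), "sd_1": a.std(ddof=1),
            "mean_2": b.mean(), "sd_2": b.std(ddof=1),
            "n_1": a.size, "n_2": b.size,
        })
    return pd.DataFrame(rows)
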