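"""Network models of cortical alteration.

Implements the two connectome-constrained atrophy models and their
individual-level extension:

* nodal stress — weighted degree centrality (row sums of a connectome),
  spatially correlated with the thinning map;
* nodal-neighbor common atrophy — for each region, the (optionally
  connectivity-weighted) mean thinning of its structurally connected
  neighbors, T_i = sum_j w_ij t_j / sum_j w_ij over j with sc_ij > 0,
  j != i;
* network-weighted W-scores — the same neighbor aggregation applied
  row-wise to each patient's W-score map with morphological weights.

Structural neighborhoods always come from ``sc > 0``; weights may come from
the morphological (SMN) or functional (FC) matrix. With the default
``weight_sum`` normalization the aggregation is a proper weighted mean
(scale-free in the weights); ``count`` divides by the neighbor count
instead. Negative weights are clamped to zero by default (weights read as
connection strength); ``signed`` keeps them.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "build_morphological_network",
    "weighted_degree",
    "neighbor_atrophy",
    "network_weighted_wscores",
    "correlate_maps",
]

_R_CAP = 0.999999


def build_morphological_network(control_thickness: np.ndarray) -> np.ndarray:
    """Fisher-z inter-regional thickness correlation across control subjects.

    ``smn[i, j] = atanh(r_ij)`` with r the Pearson correlation of the two
    region columns over subjects; |r| is capped at 0.999999 before the
    transform so degenerate (collinear) fixtures stay finite. Diagonal is 0.
    """
    ct = np.asarray(control_thickness, dtype=float)
    if ct.ndim != 2 or ct.shape[0] < 10:
        raise ValueError("need a subjects x regions matrix with >= 10 controls")
    if np.any(ct.std(axis=0) == 0):
        raise ValueError("constant thickness column: correlation undefined")
    r = np.corrcoef(ct, rowvar=False)
    r = np.clip(r, -_R_CAP, _R_CAP)
    smn = np.arctanh(r)
    np.fill_diagonal(smn, 0.0)
    return (smn + smn.T) / 2.0


def _check_symmetric(m: np.ndarray, what: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{what} must be square")
    if np.abs(m - m.T).max(initial=0.0) > 1e-10:
        raise ValueError(f"{what} must be symmetric")
    return m


def weighted_degree(matrix: np.ndarray, modality: str = "sc") -> np.ndarray:
    """Weighted degree centrality: the signed sum of each region's connections."""
    m = _check_symmetric(matrix, "connectome")
    if np.abs(np.diag(m)).max(initial=0.0) > 0:
        raise ValueError("connectome must have zero diagonal")
    if modality not in {"sc", "smn", "fc"}:
        raise ValueError(f"unknown modality {modality!r}")
    return m.sum(axis=1)


def _neighbor_weights(
    sc: np.ndarray,
    weight_matrix: np.ndarray | None,
    normalization: str,
    negative_weights: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(weights over structural neighborhoods, denominator per region)."""
    sc = _check_symmetric(sc, "sc")
    adj = sc > 0
    np.fill_diagonal(adj, False)
    if not adj.any():
        raise ValueError("all regions are isolated: no structural neighborhoods")
    if weight_matrix is None:
        w = adj.astype(float)
    else:
        wm = _check_symmetric(np.asarray(weight_matrix, dtype=float), "weight matrix")
        if wm.shape != sc.shape:
            raise ValueError("weight matrix shape must match sc")
        if negative_weights == "clamp":
            wm = np.maximum(wm, 0.0)
        elif negative_weights != "signed":
            raise ValueError("negative_weights must be 'clamp' or 'signed'")
        w = np.where(adj, wm, 0.0)
    if normalization == "weight_sum":
        denom = w.sum(axis=1)
        if np.any(denom < 0):
            raise ValueError("negative weight sum under weight_sum normalization")
    elif normalization == "count":
        denom = adj.sum(axis=1).astype(float)
    else:
        raise ValueError("normalization must be 'weight_sum' or 'count'")
    return w, denom


def neighbor_atrophy(
    thinning: np.ndarray,
    sc: np.ndarray,
    weight_matrix: np.ndarray | None = None,
    normalization: str = "weight_sum",
    negative_weights: str = "clamp",
) -> np.ndarray:
    """Mean thinning of each region's structurally connected neighbors.

    Unweighted: T_i = (1/N_i) sum over structural neighbors of t_j.
    Weighted (SMN or FC passed as ``weight_matrix``): neighbor values are
    weighted by connectivity strength; the default divides by the weight
    sum, ``count`` by the neighbor count. Self-connections are excluded.
    Regions with no structural neighbor (or zero total weight) are NaN and
    reported with a warning.
    """
    t = np.asarray(thinning, dtype=float)
    if t.shape != (sc.shape[0],):
        raise ValueError("thinning map length must equal the number of regions")
    w, denom = _neighbor_weights(sc, weight_matrix, normalization, negative_weights)
    out = np.full(t.shape, np.nan)
    ok = denom > 0
    # centered form: exact for constant maps despite FP non-associativity
    center = np.nanmean(t)
    if normalization == "weight_sum":
        out[ok] = center + (w[ok] @ (t - center)) / denom[ok]
    else:
        out[ok] = (w[ok] @ t) / denom[ok]
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} region(s) without usable neighbors set to NaN",
            stacklevel=2,
        )
    return out


def network_weighted_wscores(
    w_matrix: np.ndarray,
    sc: np.ndarray,
    smn: np.ndarray,
    normalization: str = "weight_sum",
    negative_weights: str = "clamp",
) -> np.ndarray:
    """Individual network-weighted abnormality (patients x regions).

    For patient p and region i: SMN-W[p, i] = sum_j smn_ij W[p, j] /
    sum_j smn_ij over structural neighbors j of i — i.e.
    :func:`neighbor_atrophy` applied to each patient's W-score row with
    morphological weights.
    """
    wm = np.asarray(w_matrix, dtype=float)
    if wm.ndim != 2 or wm.shape[1] != sc.shape[0]:
        raise ValueError("w_matrix must be patients x regions on the sc frame")
    weights, denom = _neighbor_weights(sc, smn, normalization, negative_weights)
    out = np.full(wm.shape, np.nan)
    ok = denom > 0
    if normalization == "weight_sum":
        centers = wm.mean(axis=1, keepdims=True)
        out[:, ok] = centers + ((wm - centers) @ weights[ok].T) / denom[ok]
    else:
        out[:, ok] = (wm @ weights[ok].T) / denom[ok]
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} region(s) without usable neighbors set to NaN",
            stacklevel=2,
        )
    return out


def correlate_maps(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two regional maps, pairwise-complete.

    Regions missing (NaN) in either map are dropped; fewer than 3 complete
    pairs or a zero-variance map is an error.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D and of equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("fewer than 3 complete region pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map")
    am = a - a.mean()
    bm = b - b.mean()
    return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))
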