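"""Behavioral partial least squares linking brain maps to clinical scores.

The McIntosh-style behavioral PLS: z-score the patients x regions predictor
block X and the patients x measures behavior block Y, form the cross-block
correlation R = X'Y / (n - 1), and take its SVD R = U S V'. Each latent
variable (LV) pairs a brain salience (column of U) with a behavior salience
(column of V); covariance explained is sigma_l^2 / sum sigma^2; brain and
behavior scores are the projections X U and Y V. Significance is assessed
by permuting rows of Y and comparing singular values position-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSResult", "fit_pls", "pls_permutation", "behavior_loadings"]


@dataclass
class PLSResult:
    singular_values: np.ndarray          # descending, >= 0
    covariance_explained: np.ndarray     # sigma^2-normalized fractions, sums to 1
    brain_saliences: np.ndarray          # regions x LVs, unit-norm columns
    behavior_saliences: np.ndarray       # measures x LVs, unit-norm columns
    brain_scores: np.ndarray             # patients x LVs
    behavior_scores: np.ndarray          # patients x LVs
    n_used: int
    perm_p: np.ndarray | None = None
    behavior_loadings: np.ndarray | None = None


def _zscore_cols(a: np.ndarray, what: str) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"constant column in {what}")
    return (a - a.mean(axis=0)) / sd


def _complete_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1)


def fit_pls(x: np.ndarray, y: np.ndarray, sv_normalization: str = "squared") -> PLSResult:
    """SVD of the cross-block correlation between X (brain) and Y (behavior).

    Rows with any missing value in either block are dropped (listwise).
    Sign convention: each LV is flipped so its largest-|salience| behavior
    entry is positive, i.e. more severe symptoms give positive behavior
    scores. ``sv_normalization="raw"`` reports sigma / sum sigma instead of
    the default sigma^2 / sum sigma^2 covariance fractions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching rows")
    ok = _complete_rows(x, y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete rows")
    xz = _zscore_cols(x[ok], "X")
    yz = _zscore_cols(y[ok], "Y")
    n = int(ok.sum())
    r = xz.T @ yz / (n - 1)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    v = vt.T
    # sign: largest-|entry| behavior salience positive per LV
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    v = v * flip
    if sv_normalization == "squared":
        explained = s**2 / (s**2).sum()
    elif sv_normalization == "raw":
        explained = s / s.sum()
    else:
        raise ValueError("sv_normalization must be 'squared' or 'raw'")
    return PLSResult(
        singular_values=s,
        covariance_explained=explained,
        brain_saliences=u,
        behavior_saliences=v,
        brain_scores=xz @ u,
        behavior_scores=yz @ v,
        n_used=n,
    )


def pls_permutation(
    x: np.ndarray, y: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> np.ndarray:
    """Position-wise permutation p per LV by shuffling rows of Y.

    p_l = (#{sigma_null[l] >= sigma_obs[l]} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = _complete_rows(x, y)
    xz = _zscore_cols(x[ok], "X")
    yz = _zscore_cols(y[ok], "Y")
    n = int(ok.sum())
    s_obs = np.linalg.svd(xz.T @ yz / (n - 1), compute_uv=False)
    rng = np.random.default_rng(seed)
    count = np.zeros_like(s_obs)
    for _ in range(n_perm):
        yp = yz[rng.permutation(n)]
        s_null = np.linalg.svd(xz.T @ yp / (n - 1), compute_uv=False)
        count += s_null >= s_obs
    return (count + 1) / (n_perm + 1)


def behavior_loadings(y: np.ndarray, brain_scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each behavior measure with each LV's brain score."""
    y = np.asarray(y, dtype=float)
    b = np.asarray(brain_scores, dtype=float)
    if y.shape[0] != b.shape[0]:
        raise ValueError("row mismatch between behavior data and brain scores")
    if np.any(y.std(axis=0) == 0) or np.any(b.std(axis=0) == 0):
        raise ValueError("zero-variance column")
    yz = (y - y.mean(0)) / y.std(0)
    bz = (b - b.mean(0)) / b.std(0)
    return yz.T @ bz / y.shape[0]
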