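"""Rank-based disease-epicenter mapping with spin-based significance.

A region is epicenter-like when it is itself strongly thinned AND its
structurally connected neighbors are strongly thinned. Both the thinning
map and its morphology-weighted neighbor map are ranked with rank 1 = most
thinned; the mean of the two ranks is the epicenter likelihood (lower =
more epicenter-like). Significance per region comes from re-ranking under
spins of the thinning map: the spin p is the left-tail probability of a
mean rank at least as small as observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ParcellationScheme
from .networks import neighbor_atrophy
from .spin import SpinSet

__all__ = ["EpicenterResult", "epicenter_ranking", "epicenter_significance"]


@dataclass
class EpicenterResult:
    frame: ParcellationScheme | None
    own_rank: np.ndarray
    neighbor_rank: np.ndarray
    mean_rank: np.ndarray
    p_spin: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def epicenter(self) -> np.ndarray | None:
        return None if self.p_spin is None else self.p_spin < self.alpha

    def to_frame(self) -> pd.DataFrame:
        data = {
            "own_rank": self.own_rank,
            "neighbor_rank": self.neighbor_rank,
            "mean_rank": self.mean_rank,
        }
        if self.p_spin is not None:
            data["p_spin"] = self.p_spin
            data["epicenter"] = self.epicenter
        index = self.frame.names if self.frame is not None else None
        return pd.DataFrame(data, index=index)


def _rank_descending(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value; ties get the average rank."""
    return rankdata(-np.asarray(values, dtype=float), method="average")


def epicenter_ranking(
    thinning: np.ndarray,
    neighbor_map: np.ndarray,
    frame: ParcellationScheme | None = None,
) -> EpicenterResult:
    """Mean of own-thinning rank and neighbor-thinning rank per region."""
    t = np.asarray(thinning, dtype=float)
    nb = np.asarray(neighbor_map, dtype=float)
    if t.shape != nb.shape:
        raise ValueError("thinning and neighbor maps must have equal length")
    ok = np.isfinite(t) & np.isfinite(nb)
    own = np.full(t.shape, np.nan)
    nbr = np.full(t.shape, np.nan)
    own[ok] = _rank_descending(t[ok])
    nbr[ok] = _rank_descending(nb[ok])
    return EpicenterResult(
        frame=frame, own_rank=own, neighbor_rank=nbr, mean_rank=(own + nbr) / 2.0
    )


def epicenter_significance(
    thinning: np.ndarray,
    sc: np.ndarray,
    smn: np.ndarray,
    spins: SpinSet,
    normalization: str = "weight_sum",
    negative_weights: str = "clamp",
) -> EpicenterResult:
    """Spin test of the mean-rank epicenter likelihood.

    Per spin, the thinning map is rotated, the morphology-weighted neighbor
    map is recomputed on the rotated map, and the mean ranks re-derived;
    p_spin[i] = (#{null mean_rank_i <= observed_i} + 1) / (n_spins + 1).
    """
    from .networks import _neighbor_weights

    obs = epicenter_ranking(thinning, neighbor_atrophy(
        thinning, sc, smn, normalization, negative_weights), spins.scheme)
    w, denom = _neighbor_weights(sc, smn, normalization, negative_weights)
    ok = denom > 0
    spun = spins.apply(thinning)
    null_nb = np.full(spun.shape, np.nan)
    if normalization == "weight_sum":
        centers = spun.mean(axis=1, keepdims=True)
        null_nb[:, ok] = centers + ((spun - centers) @ w[ok].T) / denom[ok]
    else:
        null_nb[:, ok] = (spun @ w[ok].T) / denom[ok]
    if ok.all():
        null_own = rankdata(-spun, method="average", axis=1)
        null_nbr = rankdata(-null_nb, method="average", axis=1)
        null_mean = (null_own + null_nbr) / 2.0
    else:  # isolated regions: rank within the complete subset per spin
        null_mean = np.vstack([
            epicenter_ranking(spun[k], null_nb[k]).mean_rank
            for k in range(spins.n_spins)
        ])
    count = np.sum(null_mean <= obs.mean_rank[None, :], axis=0)
    obs.p_spin = (count + 1) / (spins.n_spins + 1)
    return obs
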