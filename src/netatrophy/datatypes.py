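"""Core in-memory containers shared by every analysis stage.

Everything downstream (thinning maps, connectomes, W-scores) is indexed by a
single :class:`ParcellationScheme`, which fixes the region order once; all
matrices and per-region vectors are stored in that order and written out with
region names so the external order is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationScheme",
    "ConnectomeSet",
    "CohortData",
    "SystemAssignment",
]

_HEMIS = ("left", "right")


@dataclass(frozen=True)
class ParcellationScheme:
    """Ordered cortical parcellation with per-hemisphere spherical centroids.

    Parameters
    ----------
    names : array of str
        Unique region names in frame order (e.g. ``"lh_superiorfrontal"``).
    hemisphere : array of str
        ``"left"`` or ``"right"`` per region; both must be present.
    centroids : (n_regions, 3) float array
        Region centroids on the unit sphere of their own hemisphere
        (FreeSurfer-style ``?h.sphere`` coordinates, unitless). Normalized
        to unit norm on construction.
    """

    names: np.ndarray
    hemisphere: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        names = np.asarray(self.names, dtype=object)
        hemi = np.asarray(self.hemisphere, dtype=object)
        cent = np.asarray(self.centroids, dtype=float)
        if len(set(names)) != names.size:
            dupes = pd.Series(names).value_counts()
            raise ValueError(
                f"duplicate region names: {list(dupes[dupes > 1].index)}"
            )
        bad = set(hemi) - set(_HEMIS)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")
        if len(set(hemi)) != 2:
            raise ValueError("both hemispheres must be represented")
        if cent.shape != (names.size, 3):
            raise ValueError("centroids must be (n_regions, 3)")
        if not np.all(np.isfinite(cent)):
            raise ValueError("non-finite centroid coordinate")
        norms = np.linalg.norm(cent, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm centroid cannot be projected to the sphere")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "centroids", cent / norms[:, None])

    @property
    def n_regions(self) -> int:
        return self.names.size

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        """Integer indices of the regions in hemisphere ``hemi``."""
        return np.flatnonzero(self.hemisphere == hemi)

    def index_of(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"region {err.args[0]!r} not in parcellation") from None


def _check_square_symmetric(m: np.ndarray, n: int, what: str, tol: float = 1e-10):
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"{what} must be {n}x{n}, got {m.shape}")
    if np.abs(m - m.T).max(initial=0.0) > tol:
        raise ValueError(f"{what} is not symmetric to {tol}")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class ConnectomeSet:
    """Normative connectomes on a shared parcellation frame.

    ``sc`` is a non-negative streamline-derived structural matrix whose
    nonzero pattern defines structural neighborhoods; ``fc`` a resting-state
    correlation matrix; ``smn`` a Fisher-z morphological covariance network
    (may be ``None`` until built from controls). All are symmetric with zero
    diagonal, in frame order.
    """

    frame: ParcellationScheme
    sc: np.ndarray
    fc: np.ndarray
    smn: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.frame.n_regions
        self.sc = _check_square_symmetric(self.sc, n, "sc")
        if np.any(self.sc < 0):
            raise ValueError("sc weights must be non-negative")
        self.fc = _check_square_symmetric(self.fc, n, "fc")
        off = ~np.eye(n, dtype=bool)
        if np.any(np.abs(self.fc[off]) > 1.0):
            raise ValueError("fc off-diagonal entries must lie in [-1, 1]")
        if self.smn is not None:
            self.smn = _check_square_symmetric(self.smn, n, "smn")

    @property
    def sc_adjacency(self) -> np.ndarray:
        """Boolean structural adjacency (``sc > 0``)."""
        return self.sc > 0


@dataclass
class CohortData:
    """Subjects x regions cortical thickness with covariates and clinical scores.

    ``thickness`` is in mm, strictly positive, columns in frame order.
    ``subjects`` carries one row per subject: ``group`` ("patient"/"control"),
    ``sex`` (0/1), ``age`` (years), ``education`` (years), ``icv`` (mm^3) and,
    for patients, clinical scores (``craving`` 0-10 VAS, ``panss``, ``hars``,
    ``hdrs``) and drug-use variables (``duration`` months, ``dose``). Missing
    values are NaN and are allowed only for controls and only in the
    clinical/drug-use columns.
    """

    frame: ParcellationScheme
    thickness: np.ndarray
    subjects: pd.DataFrame

    CLINICAL = ("craving", "panss", "hars", "hdrs")
    DRUG_USE = ("duration", "dose")
    COVARIATES = ("sex", "age", "education", "icv")

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness, dtype=float)
        if t.ndim != 2 or t.shape[1] != self.frame.n_regions:
            raise ValueError("thickness must be subjects x n_regions")
        if t.shape[0] != len(self.subjects):
            raise ValueError("thickness rows must match subject table")
        if np.any(np.isnan(t).all(axis=1)):
            raise ValueError("subject with all-missing thickness")
        with np.errstate(invalid="ignore"):
            if np.any(t <= 0):
                raise ValueError("thickness must be strictly positive (mm)")
        groups = set(self.subjects["group"])
        bad = groups - {"patient", "control"}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        for col in self.COVARIATES:
            if col not in self.subjects:
                raise ValueError(f"subject table missing covariate {col!r}")
            if self.subjects[col].isna().any():
                raise ValueError(f"missing values in covariate {col!r}")
        patients = self.subjects["group"] == "patient"
        for col in self.DRUG_USE:
            if col in self.subjects and patients.any() \
                    and self.subjects.loc[patients, col].isna().any():
                raise ValueError(f"patient with missing drug-use variable {col!r}")
        self.thickness = t

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def is_patient(self) -> np.ndarray:
        return (self.subjects["group"] == "patient").to_numpy()

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(control thickness, patient thickness) row-subsets."""
        p = self.is_patient
        return self.thickness[~p], self.thickness[p]


@dataclass
class SystemAssignment:
    """One system label per region for a named atlas (yeo7 / von_economo / custom)."""

    frame: ParcellationScheme
    labels: np.ndarray
    atlas_name: str = "custom"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if labels.size != self.frame.n_regions:
            raise ValueError("one label per region required")
        if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
            raise ValueError("unassigned region in system assignment")
        self.labels = labels

    @property
    def systems(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab))
        return list(seen)
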