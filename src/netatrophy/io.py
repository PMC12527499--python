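"""Readers and writers for the text artifacts the pipeline consumes and emits.

All tabular formats are delimited text (tab or comma accepted on input; the
writers always emit tab-delimited UTF-8 with a region-name header). Matrices
and per-region vectors are keyed by region NAME so file row order never
matters: everything is reordered to the parcellation frame on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CohortData, ConnectomeSet, ParcellationScheme, SystemAssignment

__all__ = [
    "read_parcellation",
    "write_parcellation",
    "read_square_matrix",
    "write_square_matrix",
    "read_cohort",
    "write_cohort",
    "read_system_assignment",
    "write_system_assignment",
    "read_regional_table",
    "write_regional_table",
]

_SYMMETRY_TOL = 1e-8


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_parcellation(path) -> ParcellationScheme:
    """Read a parcellation table (columns: name, hemisphere, x, y, z).

    Centroids are renormalized onto the unit sphere; file row order becomes
    the frame order. Duplicate names, non-finite coordinates and zero-norm
    centroids raise ``ValueError``.
    """
    df = _read_table(path)
    required = {"name", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation file missing columns: {sorted(missing)}")
    return ParcellationScheme(
        names=df["name"].to_numpy(dtype=object),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_parcellation(scheme: ParcellationScheme, path) -> None:
    pd.DataFrame(
        {
            "name": scheme.names,
            "hemisphere": scheme.hemisphere,
            "x": scheme.centroids[:, 0],
            "y": scheme.centroids[:, 1],
            "z": scheme.centroids[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def read_square_matrix(path, frame: ParcellationScheme) -> np.ndarray:
    """Read a square connectivity matrix, reordered to the frame.

    Accepts either a labeled matrix (region names as header row and first
    column) or a bare NxN numeric grid assumed to be in frame order already.
    Asymmetry beyond 1e-8 is an error; below it the matrix is symmetrized as
    ``(M + M.T) / 2`` and the diagonal zeroed.
    """
    n = frame.n_regions
    first = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
    try:
        labeled = not np.isfinite(float(first.iloc[0, 1]))
    except (TypeError, ValueError):
        labeled = True
    if labeled:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if set(df.index) != set(frame.names) or set(df.columns) != set(frame.names):
            raise ValueError("matrix labels do not match the parcellation frame")
        df = df.loc[frame.names, frame.names]
        m = df.to_numpy(dtype=float)
    else:
        m = pd.read_csv(path, sep=None, engine="python", header=None).to_numpy(dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} matrix, got {m.shape}")
    asym = np.abs(m - m.T).max(initial=0.0)
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds {_SYMMETRY_TOL}")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def write_square_matrix(m: np.ndarray, frame: ParcellationScheme, path) -> None:
    pd.DataFrame(m, index=frame.names, columns=frame.names).to_csv(path, sep="\t")


def read_cohort(thickness_path, subjects_path, frame: ParcellationScheme) -> CohortData:
    """Join a thickness table and a subjects table on subject id.

    The thickness table has a subject-id column (first column or ``subject``)
    plus one column per region name; the subjects table has ``subject``,
    ``group`` and the covariates, with optional clinical/drug-use columns.
    A subject present in exactly one of the two tables is an error naming
    the offending id.
    """
    thick = _read_table(thickness_path)
    subj = _read_table(subjects_path)
    id_col = "subject" if "subject" in thick.columns else thick.columns[0]
    sid_col = "subject" if "subject" in subj.columns else subj.columns[0]
    thick = thick.rename(columns={id_col: "subject"}).set_index("subject")
    subj = subj.rename(columns={sid_col: "subject"}).set_index("subject")

    missing_regions = [n for n in frame.names if n not in thick.columns]
    if missing_regions:
        raise ValueError(f"thickness table missing region column(s): {missing_regions[:5]}")
    only_thick = set(thick.index) - set(subj.index)
    only_subj = set(subj.index) - set(thick.index)
    if only_thick or only_subj:
        odd = sorted(map(str, only_thick | only_subj))
        raise ValueError(f"subject(s) present in only one table: {odd[:5]}")
    subj = subj.loc[thick.index]
    return CohortData(
        frame=frame,
        thickness=thick[list(frame.names)].to_numpy(dtype=float),
        subjects=subj.reset_index(),
    )


def write_cohort(cohort: CohortData, thickness_path, subjects_path) -> None:
    thick = pd.DataFrame(cohort.thickness, columns=cohort.frame.names)
    thick.insert(0, "subject", cohort.subjects["subject"].to_numpy())
    thick.to_csv(thickness_path, sep="\t", index=False)
    cohort.subjects.to_csv(subjects_path, sep="\t", index=False)


def read_system_assignment(path, frame: ParcellationScheme, atlas: str) -> SystemAssignment:
    """Read a region-to-system table (columns: name, <atlas> or label)."""
    df = _read_table(path).set_index("name")
    col = atlas if atlas in df.columns else "label"
    if col not in df.columns:
        raise ValueError(f"system table has no column for atlas {atlas!r}")
    missing = [n for n in frame.names if n not in df.index]
    if missing:
        raise ValueError(f"system table missing region(s): {missing[:5]}")
    return SystemAssignment(frame=frame, labels=df.loc[frame.names, col].to_numpy(dtype=object),
                            atlas_name=atlas)


def write_system_assignment(assignment: SystemAssignment, path) -> None:
    pd.DataFrame({"name": assignment.frame.names,
                  assignment.atlas_name: assignment.labels}).to_csv(path, sep="\t", index=False)


def packaged_dk_systems_path() -> str:
    """Path of the bundled Desikan-Killiany system table (name, yeo7, von_economo).

    The assignments are an approximate majority-vote lookup assembled for
    this package; for careful real-data enrichment supply your own table.
    """
    from importlib.resources import files

    return str(files("netatrophy").joinpath("data/dk_systems.tsv"))


def read_regional_table(path, frame: ParcellationScheme) -> pd.DataFrame:
    """Read a per-region table keyed by name, reordered to the frame."""
    df = _read_table(path).set_index("name")
    missing = [n for n in frame.names if n not in df.index]
    if missing:
        raise ValueError(f"regional table missing region(s): {missing[:5]}")
    return df.loc[frame.names]


def write_regional_table(df: pd.DataFrame, frame: ParcellationScheme, path) -> None:
    out = df.copy()
    out.insert(0, "name", frame.names)
    out.to_csv(path, sep="\t", index=False)
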