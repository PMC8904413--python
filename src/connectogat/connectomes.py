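"""Connectivity-matrix data model, cohort I/O, and edge-thresholding transforms.

A subject is represented by two undirected weighted graphs over the atlas
nodes — a structural connectome (SC, nonnegative probabilistic connection
weights from tractography) and a functional connectome (FC, signed
correlations between regional time series) — plus per-region morphology
(gray-matter volume, cortical thickness) and clinical variables.

The transforms here reproduce the standard connectome preprocessing chain:
absolute thresholding of SC, Fisher r-to-z normalization of FC, and
proportional (density) thresholding of FC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import AtlasParcellation

#: maximum tolerated |M - M.T| before a matrix is rejected as asymmetric
ASYMMETRY_TOL = 1e-6

CLINICAL_VARS = ("AAO", "DOI", "UPDRS_III", "HY", "MMSE", "LEDD")


class CohortLoadError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's symmetric weighted graph, tagged SC or FC.

    Invariants: square, symmetric within ``ASYMMETRY_TOL``, zero diagonal;
    SC weights nonnegative.
    """

    values: np.ndarray
    modality: str  # "SC" or "FC"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        asym = float(np.abs(v - v.T).max()) if v.size else 0.0
        if asym > ASYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL:g}"
            )
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if self.modality not in ("SC", "FC"):
            raise ValueError(f"modality must be SC or FC, got {self.modality!r}")
        if self.modality == "SC" and v.size and v.min() < 0:
            raise ValueError("SC weights must be nonnegative")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "ConnectivityMatrix":
        return replace(self, values=values)


@dataclass
class SubjectRecord:
    subject_id: str
    label: int  # 1 = patient, 0 = control
    sc: ConnectivityMatrix
    fc: ConnectivityMatrix
    morphology: np.ndarray  # n x 2: volume (mm^3), cortical thickness (mm)
    clinical: dict[str, float] = field(default_factory=dict)
    origin: str = "real"  # real | smote | synthetic

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        self.morphology = np.asarray(self.morphology, dtype=float)
        n = self.sc.n_nodes
        if self.fc.n_nodes != n:
            raise ValueError("SC and FC dimensions differ")
        if self.morphology.shape != (n, 2):
            raise ValueError(
                f"morphology must be ({n}, 2), got {self.morphology.shape}"
            )


@dataclass
class CohortDataset:
    subjects: list[SubjectRecord]
    atlas: AtlasParcellation
    provenance: str = "real"  # real | smote_augmented | synthetic

    def __post_init__(self) -> None:
        n = self.atlas.n_regions
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        for s in self.subjects:
            if s.sc.n_nodes != n:
                raise ValueError(
                    f"subject {s.subject_id}: matrix size {s.sc.n_nodes} "
                    f"does not match atlas ({n} regions)"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    def clinical_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "label": s.label, "origin": s.origin}
            for v in CLINICAL_VARS:
                row[v] = s.clinical.get(v, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return np.asarray(z[z.files[0]], dtype=float)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(path, delimiter=delimiter, dtype=float)


def load_cohort(
    manifest_path: str | Path,
    matrix_dir: str | Path,
    atlas: AtlasParcellation,
) -> CohortDataset:
    """Read a cohort from a manifest CSV plus per-subject matrix files.

    The manifest has columns ``subject_id,label,AAO,DOI,UPDRS_III,HY,MMSE,LEDD``
    (clinical cells may be empty); ``matrix_dir`` holds, per subject,
    ``<id>_SC.csv``, ``<id>_FC.csv`` and ``<id>_morph.csv``.
    """
    manifest_path = Path(manifest_path)
    matrix_dir = Path(matrix_dir)
    manifest = pd.read_csv(manifest_path)
    if "subject_id" not in manifest.columns or "label" not in manifest.columns:
        raise CohortLoadError("manifest must have subject_id and label columns")

    n = atlas.n_regions
    subjects = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        label = row["label"]
        if label not in (0, 1):
            raise CohortLoadError(f"subject {sid}: non-binary label {label!r}")
        archive = matrix_dir / "matrices.npz"
        mats = {}
        for tag in ("SC", "FC", "morph"):
            path = matrix_dir / f"{sid}_{tag}.csv"
            try:
                mats[tag] = _read_matrix(path)
            except FileNotFoundError:
                if archive.exists():  # single-archive layout fallback
                    with np.load(archive) as z:
                        key = f"{sid}_{tag}"
                        if key in z.files:
                            mats[tag] = np.asarray(z[key], dtype=float)
                            continue
                raise CohortLoadError(
                    f"subject {sid}: missing matrix file {path}"
                ) from None
        for tag in ("SC", "FC"):
            if mats[tag].shape != (n, n):
                raise CohortLoadError(
                    f"subject {sid}: {tag} matrix has shape {mats[tag].shape}, "
                    f"expected ({n}, {n})"
                )
        clinical = {
            v: float(row[v])
            for v in CLINICAL_VARS
            if v in manifest.columns and pd.notna(row[v])
        }
        origin = str(row["origin"]) if "origin" in manifest.columns else "real"
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                label=int(label),
                sc=ConnectivityMatrix(mats["SC"], "SC", sid),
                fc=ConnectivityMatrix(mats["FC"], "FC", sid),
                morphology=mats["morph"],
                clinical=clinical,
                origin=origin,
            )
        )
    return CohortDataset(subjects, atlas)


def save_cohort(
    cohort: CohortDataset, out_dir: str | Path, archive: bool = False
) -> Path:
    """Write manifest + matrix files in the layout ``load_cohort`` reads.

    ``archive=True`` additionally bundles every array into a single
    compressed ``matrices/matrices.npz`` (the loader accepts either form).
    """
    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    arrays: dict[str, np.ndarray] = {}
    for s in cohort.subjects:
        np.savetxt(mat_dir / f"{s.subject_id}_SC.csv", s.sc.values, delimiter=",")
        np.savetxt(mat_dir / f"{s.subject_id}_FC.csv", s.fc.values, delimiter=",")
        np.savetxt(mat_dir / f"{s.subject_id}_morph.csv", s.morphology, delimiter=",")
        arrays[f"{s.subject_id}_SC"] = s.sc.values
        arrays[f"{s.subject_id}_FC"] = s.fc.values
        arrays[f"{s.subject_id}_morph"] = s.morphology
        row: dict[str, object] = {
            "subject_id": s.subject_id,
            "label": s.label,
            "origin": s.origin,
        }
        for v in CLINICAL_VARS:
            row[v] = s.clinical.get(v, "")
        rows.append(row)
    if archive:
        np.savez_compressed(mat_dir / "matrices.npz", **arrays)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cohort.atlas.to_tsv(out_dir / "atlas.tsv")
    return manifest


# ---------------------------------------------------------------------------
# Thresholding / normalization transforms
# ---------------------------------------------------------------------------

def threshold_absolute(
    m: ConnectivityMatrix, t: float, strict: bool = False
) -> ConnectivityMatrix:
    """Zero every edge whose weight falls below ``t`` (values >= t kept;
    ``strict=True`` drops values equal to ``t`` as well).

    This is the sparsification applied to probabilistic-tractography SC
    matrices; the conventional cutoff for these weights is 0.1.
    """
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    v = m.values.copy()
    v[(v <= t) if strict else (v < t)] = 0.0
    return m.with_values(v)


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform, arctanh(r), applied entrywise off-diagonal."""
    if m.modality != "FC":
        raise ValueError("fisher_z applies to FC matrices")
    v = m.values.copy()
    off = ~np.eye(m.n_nodes, dtype=bool)
    bad = np.abs(v[off]) >= 1.0
    if bad.any():
        i, j = np.argwhere((np.abs(v) >= 1.0) & off)[0]
        raise ValueError(
            f"|r| >= 1 at entry ({i}, {j}): r = {v[i, j]} is outside arctanh domain"
        )
    v[off] = np.arctanh(v[off])
    return m.with_values(v)


def threshold_density(
    m: ConnectivityMatrix, density: float, ranking: str = "signed"
) -> ConnectivityMatrix:
    """Proportional threshold: keep the top ``ceil(density * E)`` undirected
    edges (E = n(n-1)/2 node pairs), ranked by edge value, zero the rest.

    Only nonzero entries count as edges, so a sparse matrix is never
    "filled in" and the transform is idempotent. ``ranking='signed'``
    retains the most-positive values (the strongest correlations after
    Fisher z); ``ranking='abs'`` ranks by magnitude. Boundary ties are
    broken by (row, col) lexicographic order.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    if ranking not in ("signed", "abs"):
        raise ValueError(f"ranking must be 'signed' or 'abs', got {ranking!r}")
    n = m.n_nodes
    iu = np.triu_indices(n, k=1)
    vals = m.values[iu]
    key = np.abs(vals) if ranking == "abs" else vals
    n_keep = math.ceil(density * len(vals))
    # only actual edges compete for the quota: zero entries are non-edges,
    # which also makes the transform idempotent for signed matrices
    candidates = np.nonzero(vals)[0]
    # stable sort on descending key; equal keys fall back to (row, col) order
    order = candidates[np.argsort(-key[candidates], kind="stable")]
    keep = order[:n_keep]
    out = np.zeros_like(m.values)
    out[iu[0][keep], iu[1][keep]] = vals[keep]
    out = out + out.T
    return m.with_values(out)


def edge_density(m: ConnectivityMatrix) -> float:
    """Fraction of the n(n-1)/2 node pairs with a nonzero edge."""
    n = m.n_nodes
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(m.values[iu])) / (n * (n - 1) // 2)


def preprocess_sc(m: ConnectivityMatrix, threshold: float = 0.1) -> ConnectivityMatrix:
    return threshold_absolute(m, threshold)


def preprocess_fc(
    m: ConnectivityMatrix, density: float = 0.5, ranking: str = "signed"
) -> ConnectivityMatrix:
    return threshold_density(fisher_z(m), density, ranking=ranking)
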