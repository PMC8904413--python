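"""Class balancing by SMOTE on flattened connectomes.

Imbalanced two-group cohorts are balanced by synthetic minority
oversampling: each subject is flattened to a vector (SC upper triangle,
FC upper triangle, morphology), new minority vectors are interpolated
between a minority subject and one of its k nearest minority neighbors,
and synthetic subjects are reconstructed as symmetric matrices so that
graph-derived node features can be recomputed on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .atlas import AtlasParcellation
from .connectomes import CohortDataset, ConnectivityMatrix, SubjectRecord


@dataclass
class FlattenedSubject:
    """A subject as one vector: SC triangle || FC triangle || morphology."""

    vector: np.ndarray
    label: int
    subject_id: str
    origin: str = "real"
    clinical: dict = field(default_factory=dict)


def vector_length(n: int) -> int:
    """2 * n(n-1)/2 triangle entries + 2n morphology values."""
    return n * (n - 1) + 2 * n


def flatten_subject(rec: SubjectRecord) -> FlattenedSubject:
    """Row-major upper triangles of SC then FC, then morphology row-major."""
    n = rec.sc.n_nodes
    iu = np.triu_indices(n, k=1)
    vec = np.concatenate(
        [rec.sc.values[iu], rec.fc.values[iu], rec.morphology.ravel()]
    )
    return FlattenedSubject(vec, rec.label, rec.subject_id, rec.origin, dict(rec.clinical))


def reconstruct_subject(flat: FlattenedSubject, n: int) -> SubjectRecord:
    ntri = n * (n - 1) // 2
    if flat.vector.shape != (vector_length(n),):
        raise ValueError(
            f"vector length {flat.vector.shape[0]} does not match "
            f"n = {n} (expected {vector_length(n)})"
        )
    iu = np.triu_indices(n, k=1)
    sc = np.zeros((n, n))
    sc[iu] = np.clip(flat.vector[:ntri], 0.0, None)  # SC must stay nonnegative
    sc = sc + sc.T
    fc = np.zeros((n, n))
    fc[iu] = flat.vector[ntri : 2 * ntri]
    fc = fc + fc.T
    morph = flat.vector[2 * ntri :].reshape(n, 2)
    return SubjectRecord(
        subject_id=flat.subject_id,
        label=flat.label,
        sc=ConnectivityMatrix(sc, "SC", flat.subject_id),
        fc=ConnectivityMatrix(fc, "FC", flat.subject_id),
        morphology=morph,
        clinical=dict(flat.clinical),
        origin=flat.origin,
    )


def smote_balance(
    subjects: list[FlattenedSubject], k_neighbors: int = 5, seed: int = 0
) -> list[FlattenedSubject]:
    """Oversample the minority class up to the majority count.

    Each synthetic vector is x + gap * (neighbor - x) for a uniformly drawn
    gap in [0, 1], where neighbor is one of the k nearest minority
    neighbors of x (Euclidean). Originals are preserved; synthetic records
    carry ``origin='smote'`` and no clinical values.
    """
    labels = np.array([s.label for s in subjects])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if counts[0] == counts[1]:
        return list(subjects)
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples but k_neighbors = {k_neighbors}; "
            f"use k_neighbors < {n_min}"
        )
    minority_subjects = [s for s in subjects if s.label == minority]
    x = np.stack([s.vector for s in minority_subjects])
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    out = list(subjects)
    for t in range(n_maj - n_min):
        i = int(rng.integers(n_min))
        j = int(idx[i, 1 + rng.integers(k_neighbors)])
        gap = float(rng.uniform())
        vec = x[i] + gap * (x[j] - x[i])
        out.append(
            FlattenedSubject(
                vector=vec,
                label=int(minority),
                subject_id=f"smote{t:04d}",
                origin="smote",
            )
        )
    return out


def reconstruct_subjects(
    flat: list[FlattenedSubject], atlas: AtlasParcellation
) -> CohortDataset:
    n = atlas.n_regions
    subjects = [reconstruct_subject(f, n) for f in flat]
    provenance = (
        "smote_augmented" if any(s.origin == "smote" for s in subjects) else "real"
    )
    return CohortDataset(subjects, atlas, provenance)


def augment_cohort(
    cohort: CohortDataset, k_neighbors: int = 5, seed: int = 0
) -> CohortDataset:
    """flatten -> SMOTE -> reconstruct, preserving subject order (originals
    first, synthetic appended)."""
    flat = [flatten_subject(s) for s in cohort.subjects]
    balanced = smote_balance(flat, k_neighbors=k_neighbors, seed=seed)
    return reconstruct_subjects(balanced, cohort.atlas)
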