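"""Synthetic two-group connectome cohorts with planted node-level effects.

The generator emulates the statistical shape of a patient/control imaging
cohort so the full pipeline (thresholding, feature extraction, SMOTE,
training, interpretability) can be exercised without any scan data:

* SC — a shared community-structured, distance-decayed template of
  nonnegative weights in [0, 1] plus subject-level multiplicative noise;
  in patients, every edge touching a planted "affected" node is scaled by
  (1 - sc_effect), mimicking focal loss of structural connectivity.
* FC — per-subject correlation matrices from a latent-factor time-series
  model that shares the SC community template (guaranteeing a valid
  correlation structure with signed entries in (-1, 1)); patients have the
  factor loading of affected nodes reduced by fc_effect.
* Morphology — volume and cortical thickness around region-typical values;
  patients lose a morph_effect fraction on affected nodes.
* Clinical variables — drawn around published-cohort-scale means
  (e.g. UPDRS-III ~ 34.5, AAO ~ 51) with optional linear coupling to a
  subject-level feature of a planted node, so correlation-recovery can be
  tested end-to-end.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasParcellation, default_atlas, make_toy_atlas
from .connectomes import CohortDataset, ConnectivityMatrix, SubjectRecord

#: clinical variable -> (mean, sd) on a plausible patient scale
CLINICAL_SCALES = {
    "AAO": (51.1, 9.1),
    "DOI": (5.9, 2.7),
    "UPDRS_III": (34.5, 8.3),
    "HY": (2.3, 0.3),
    "MMSE": (28.0, 1.6),
    "LEDD": (616.0, 277.7),
}

#: coupling channels a clinical variable can attach to
_CHANNELS = ("sc_strength", "fc_strength", "volume", "thickness")


@dataclass(frozen=True)
class ClinicalCoupling:
    """Linear link: variable = mean + slope * z(channel value at node) + noise."""

    node: int
    channel: str
    slope: float  # in units of the variable, per SD of the channel value

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 75
    n_controls: int = 34
    n_nodes: int = 86
    n_communities: int = 4
    affected_nodes: tuple[int, ...] = ()  # empty -> evenly spread default 5
    sc_effect: float = 0.3  # fractional SC weight loss at affected nodes
    fc_effect: float = 0.2  # fractional factor-loading loss at affected nodes
    morph_effect: float = 0.1  # fractional volume/thickness loss
    sc_noise_sd: float = 0.15  # lognormal sigma of subject SC noise
    fc_timepoints: int = 150  # latent time-series length
    morph_noise_sd: float = 0.05  # relative morphology noise
    clinical_noise_sd: float = 0.5  # in units of each variable's SD
    clinical_coupling: dict[str, ClinicalCoupling] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for e in (self.sc_effect, self.fc_effect, self.morph_effect):
            if not 0 <= e < 1:
                raise ValueError(f"effects must be in [0, 1), got {e}")
        for i in self.affected_nodes:
            if not 0 <= i < self.n_nodes:
                raise ValueError(
                    f"affected node index {i} out of range for {self.n_nodes} nodes"
                )

    def resolved_affected(self) -> tuple[int, ...]:
        if self.affected_nodes:
            return tuple(self.affected_nodes)
        step = max(self.n_nodes // 5, 1)
        return tuple(range(0, self.n_nodes, step))[:5]


def default_coupling(cfg: SyntheticConfig) -> dict[str, ClinicalCoupling]:
    """Negative coupling of age-at-onset to the SC strength of the first
    planted node — the kind of structure the clinical-correlation stage is
    meant to recover."""
    affected = cfg.resolved_affected()
    return {"AAO": ClinicalCoupling(affected[0], "sc_strength", -6.0)}


def _template(cfg: SyntheticConfig, rng: np.random.Generator):
    """Cohort-level SC weight template, community assignment, coordinates."""
    n = cfg.n_nodes
    comm = np.sort(rng.integers(0, cfg.n_communities, size=n))
    coords = rng.uniform(0, 1, size=(n, 3))
    d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    decay = np.exp(-d / 0.5)
    boost = np.where(comm[:, None] == comm[None, :], 1.6, 0.6)
    base = 0.35 * decay * boost * rng.uniform(0.5, 1.5, size=(n, n))
    base = (base + base.T) / 2
    np.fill_diagonal(base, 0.0)
    return np.clip(base, 0.0, 1.0), comm


def generate_cohort(cfg: SyntheticConfig) -> CohortDataset:
    """Simulate a full cohort; patients first (label 1), then controls."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    atlas = default_atlas() if n == 86 else make_toy_atlas(n)
    base, comm = _template(cfg, rng)
    affected = np.array(cfg.resolved_affected(), dtype=int)
    coupling = cfg.clinical_coupling or default_coupling(cfg)

    # region-typical morphology (template level)
    vol_mean = rng.uniform(1500, 18000, size=n)
    thick_mean = np.where(
        np.array(atlas.cortical_mask()), rng.uniform(2.0, 3.2, size=n), 0.0
    )
    loading = np.full(n, 0.75)  # FC latent-factor loading

    subjects = []
    labels = [1] * cfg.n_patients + [0] * cfg.n_controls
    for s_idx, label in enumerate(labels):
        sid = f"{'pd' if label else 'hc'}{s_idx:03d}"
        # --- SC ---
        noise = rng.lognormal(0.0, cfg.sc_noise_sd, size=(n, n))
        sc = base * (noise + noise.T) / 2
        if label:
            touch = np.zeros((n, n), dtype=bool)
            touch[affected, :] = True
            touch[:, affected] = True
            sc = np.where(touch, (1.0 - cfg.sc_effect) * sc, sc)
        sc = np.clip((sc + sc.T) / 2, 0.0, 1.0)
        np.fill_diagonal(sc, 0.0)
        # --- FC: latent community factors + node noise ---
        lam = loading.copy()
        if label:
            lam[affected] *= 1.0 - cfg.fc_effect
        t = cfg.fc_timepoints
        factors = rng.standard_normal((cfg.n_communities, t))
        series = (
            lam[:, None] * factors[comm]
            + np.sqrt(1.0 - lam**2)[:, None] * rng.standard_normal((n, t))
        )
        fc = np.corrcoef(series)
        np.fill_diagonal(fc, 0.0)
        fc = np.clip(fc, -0.999, 0.999)
        fc = (fc + fc.T) / 2
        # --- morphology ---
        vol = vol_mean * (1 + cfg.morph_noise_sd * rng.standard_normal(n))
        thick = thick_mean * (1 + cfg.morph_noise_sd * rng.standard_normal(n))
        if label:
            vol[affected] *= 1.0 - cfg.morph_effect
            thick[affected] *= 1.0 - cfg.morph_effect
        morph = np.stack([vol, np.clip(thick, 0.0, None)], axis=1)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                label=label,
                sc=ConnectivityMatrix(sc, "SC", sid),
                fc=ConnectivityMatrix(fc, "FC", sid),
                morphology=morph,
                clinical={},
                origin="real",
            )
        )

    # clinical variables (patients only): coupled channel values are
    # standardized across patients so the planted slope is on a known scale
    patients = [s for s in subjects if s.label == 1]
    channel_values = {
        "sc_strength": np.array([s.sc.values.sum(axis=1) for s in patients]),
        "fc_strength": np.array([np.abs(s.fc.values).sum(axis=1) for s in patients]),
        "volume": np.array([s.morphology[:, 0] for s in patients]),
        "thickness": np.array([s.morphology[:, 1] for s in patients]),
    }
    for var, (mean, sd) in CLINICAL_SCALES.items():
        vals = mean + sd * cfg.clinical_noise_sd * rng.standard_normal(len(patients))
        if var in coupling:
            c = coupling[var]
            ch = channel_values[c.channel][:, c.node]
            z = (ch - ch.mean()) / (ch.std() + 1e-12)
            vals = vals + c.slope * z
        for s, v in zip(patients, vals):
            s.clinical[var] = float(v)
    return CohortDataset(subjects, atlas, provenance="synthetic")


def generate_worked_micro(n_nodes: int = 6, seed: int = 0):
    """A tiny hand-checkable cohort: SC embeds a unit-weight triangle on
    nodes {0,1,2} and a star centered at node 3; FC couples two cliques.

    Returns (CohortDataset, notes) where ``notes`` records the closed-form
    values the planted motifs imply (triangle CC = 1, star-center BC =
    number of leaf pairs, leaf BC = 0).
    """
    if n_nodes < 6 or n_nodes > 6:
        raise ValueError("the worked micro-cohort is defined for 6 nodes")
    atlas = make_toy_atlas(n_nodes)
    sc = np.zeros((6, 6))
    for i, j in ((0, 1), (0, 2), (1, 2)):  # triangle
        sc[i, j] = sc[j, i] = 1.0
    for leaf in (4, 5):  # star: center 3
        sc[3, leaf] = sc[leaf, 3] = 1.0
    fc = np.zeros((6, 6))
    for grp in ((0, 1, 2), (3, 4, 5)):  # two FC cliques
        for i in grp:
            for j in grp:
                if i != j:
                    fc[i, j] = 0.8
    rng = np.random.default_rng(seed)
    subjects = []
    for k, label in enumerate((1, 0)):
        sid = f"micro{k}"
        morph = np.stack(
            [rng.uniform(1000, 2000, 6), rng.uniform(2.0, 3.0, 6)], axis=1
        )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                label=label,
                sc=ConnectivityMatrix(sc, "SC", sid),
                fc=ConnectivityMatrix(fc, "FC", sid),
                morphology=morph,
                clinical={},
            )
        )
    notes = {
        "triangle_nodes": (0, 1, 2),
        "triangle_cc": 1.0,
        "star_center": 3,
        "star_leaves": (4, 5),
        "star_center_bc": 1.0,  # one dependent leaf pair routed via the center
        "star_leaf_bc": 0.0,
    }
    return CohortDataset(subjects, atlas, provenance="synthetic"), notes
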