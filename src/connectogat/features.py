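"""Multimodal per-node feature set.

Each subject's node features combine three blocks:

* morphology — regional gray-matter volume and cortical thickness (2 columns);
* network measures of the thresholded SC and FC graphs — weighted clustering
  coefficient (CC), betweenness centrality (BC), degree (D), strength (S),
  local efficiency (LE), nodal modularity contribution (Mod) and
  participation coefficient (PC), following the Brain Connectivity Toolbox
  weighted definitions (7 columns per modality);
* statistical moments of each node's edge-weight distribution — mean, std,
  skewness, excess kurtosis (4 columns per modality).

Assembled in the order [morphology | SC network | SC statistical |
FC network | FC statistical] this yields the default 24-feature multimodal
set: 13 structural-side columns and 11 functional-side columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity
from scipy.sparse.csgraph import shortest_path
from sklearn.preprocessing import MinMaxScaler

from .connectomes import ConnectivityMatrix

NETWORK_MEASURES = ("CC", "BC", "D", "S", "LE", "Mod", "PC")
STATISTICAL_MEASURES = ("mean", "std", "skew", "kurt")
MORPHOLOGY_MEASURES = ("VOL", "CT")


@dataclass(frozen=True)
class CommunityPartition:
    """A node-to-module assignment with its Newman modularity Q."""

    assignment: np.ndarray  # length-n module ids, contiguous from 0
    modularity_q: float
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.size and sorted(set(a.tolist())) != list(range(a.max() + 1)):
            raise ValueError("module ids must be contiguous from 0")
        if not (-0.5 - 1e-9 <= self.modularity_q <= 1 + 1e-9):
            raise ValueError(f"modularity Q out of range: {self.modularity_q}")
        a.flags.writeable = False
        object.__setattr__(self, "assignment", a)

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0


@dataclass
class NodeFeatureMatrix:
    values: np.ndarray  # n x F
    feature_names: list[str]
    modality_tags: list[str]  # per column: morphological | structural | functional

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if len(self.modality_tags) != len(self.feature_names):
            raise ValueError("modality_tags length must match column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _nonneg(m: ConnectivityMatrix) -> np.ndarray:
    """Weights with negatives zeroed (needed before FC network measures)."""
    w = m.values.copy()
    w[w < 0] = 0.0
    return w


def detect_communities(m: ConnectivityMatrix, seed: int = 0) -> CommunityPartition:
    """Louvain community detection on the nonnegative weight graph.

    Deterministic for a fixed seed. An edgeless graph degenerates to one
    singleton module per node with Q = 0.
    """
    w = _nonneg(m)
    n = m.n_nodes
    g = nx.from_numpy_array(w)
    # drop zero-weight edges that from_numpy_array may keep
    g.remove_edges_from([(u, v) for u, v, d in g.edges(data=True) if d["weight"] <= 0])
    if g.number_of_edges() == 0:
        return CommunityPartition(np.arange(n), 0.0, seed)
    comms = louvain_communities(g, weight="weight", seed=seed)
    q = modularity(g, comms, weight="weight")
    # contiguous module ids, ordered by smallest member node for determinism
    comms = sorted(comms, key=min)
    assignment = np.empty(n, dtype=int)
    for mid, nodes in enumerate(comms):
        for v in nodes:
            assignment[v] = mid
    return CommunityPartition(assignment, float(q), seed)


# ---------------------------------------------------------------------------
# network measures
# ---------------------------------------------------------------------------

def _weighted_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient, weights scaled to max 1."""
    n = w.shape[0]
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(n)
    wn = np.cbrt(w / wmax)
    num = np.diag(wn @ wn @ wn)  # 2 * sum of cube-root triangle intensities
    k = (w > 0).sum(axis=1)
    cc = np.zeros(n)
    ok = k > 1
    cc[ok] = num[ok] / (k[ok] * (k[ok] - 1))
    return cc


def _betweenness(w: np.ndarray) -> np.ndarray:
    """Weighted betweenness with path length 1/weight, normalized by the
    number of ordered pairs excluding the node (standard normalization)."""
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(
        (int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)
    )
    bc = nx.betweenness_centrality(g, weight="weight", normalized=False)
    return np.array([bc[i] for i in range(n)])


def _local_efficiency(w: np.ndarray) -> np.ndarray:
    """Weighted local efficiency: for each node, mean inverse shortest-path
    length among its neighbors within the neighborhood subgraph, computed on
    cube-root-scaled weights, weighted by the cube-root intensities of the
    edges reaching the neighborhood (Brain Connectivity Toolbox form)."""
    n = w.shape[0]
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(n)
    wn = w / wmax
    le = np.zeros(n)
    with np.errstate(divide="ignore"):
        lengths = np.where(wn > 0, 1.0 / np.cbrt(wn), np.inf)
    for i in range(n):
        nb = np.nonzero(wn[i])[0]
        k = len(nb)
        if k < 2:
            continue
        sub = lengths[np.ix_(nb, nb)].copy()
        np.fill_diagonal(sub, 0.0)
        d = shortest_path(sub, method="D", directed=False)
        with np.errstate(divide="ignore"):
            e = np.where(d > 0, 1.0 / d, 0.0)
        np.fill_diagonal(e, 0.0)
        wi = np.cbrt(wn[i, nb])
        le[i] = float(wi @ e @ wi) / (k * (k - 1))
    return le


def _nodal_modularity(w: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Node i's contribution to Newman's Q:
    Mod_i = (1/2W) * sum_{j: c_j = c_i} (w_ij - s_i s_j / 2W); sums to Q."""
    s = w.sum(axis=1)
    two_w = s.sum()
    if two_w <= 0:
        return np.zeros(w.shape[0])
    same = assignment[:, None] == assignment[None, :]
    b = (w - np.outer(s, s) / two_w) * same
    return b.sum(axis=1) / two_w


def _participation(w: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """PC_i = 1 - sum_m (k_im / k_i)^2 with k taken as nodal strength."""
    n = w.shape[0]
    s = w.sum(axis=1)
    pc = np.zeros(n)
    modules = np.unique(assignment)
    km = np.stack([w[:, assignment == m].sum(axis=1) for m in modules], axis=1)
    ok = s > 0
    pc[ok] = 1.0 - ((km[ok] / s[ok, None]) ** 2).sum(axis=1)
    return pc


def compute_network_features(
    m: ConnectivityMatrix, partition: CommunityPartition | None = None, seed: int = 0
) -> np.ndarray:
    """The 7 nodal network measures, columns ordered [CC, BC, D, S, LE, Mod, PC].

    FC matrices have negative weights zeroed first; isolated nodes get 0 for
    every measure.
    """
    w = _nonneg(m)
    if partition is None:
        partition = detect_communities(m, seed=seed)
    out = np.zeros((m.n_nodes, len(NETWORK_MEASURES)))
    out[:, 0] = _weighted_clustering(w)
    out[:, 1] = _betweenness(w)
    out[:, 2] = (w > 0).sum(axis=1)  # degree
    out[:, 3] = w.sum(axis=1)  # strength
    out[:, 4] = _local_efficiency(w)
    out[:, 5] = _nodal_modularity(w, partition.assignment)
    out[:, 6] = _participation(w, partition.assignment)
    return out


def compute_statistical_features(
    m: ConnectivityMatrix, include_zeros: bool = True
) -> np.ndarray:
    """Population moments of each node's off-diagonal edge values:
    [mean, std, skew, excess kurt]. Signed FC values are used as-is.

    By default the full off-diagonal row (zeros included, post-threshold)
    forms the sample; ``include_zeros=False`` restricts to nonzero edges.
    Zero-variance rows get skew = kurt = 0 by convention.
    """
    n = m.n_nodes
    out = np.zeros((n, len(STATISTICAL_MEASURES)))
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = m.values[i][off[i]]
        if not include_zeros:
            row = row[row != 0]
        if row.size == 0:
            continue
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        sd = np.sqrt(var)
        out[i, 0] = mu
        out[i, 1] = sd
        if sd > 0:
            out[i, 2] = (((row - mu) / sd) ** 3).mean()
            out[i, 3] = (((row - mu) / sd) ** 4).mean() - 3.0
    return out


# ---------------------------------------------------------------------------
# assembly and normalization
# ---------------------------------------------------------------------------

def assemble_multimodal_features(
    morphology: np.ndarray | None,
    sc_net: np.ndarray | None,
    sc_stat: np.ndarray | None,
    fc_net: np.ndarray | None,
    fc_stat: np.ndarray | None,
) -> NodeFeatureMatrix:
    """Concatenate feature blocks into an n x F matrix with named columns.

    With all blocks present F = 24 (13 structural-side + 11 functional-side).
    Passing ``None`` for a side's blocks yields the unimodal variants
    (11 columns per modality).
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    tags: list[str] = []

    def add(block, cols, tag):
        blocks.append(np.asarray(block, dtype=float))
        names.extend(cols)
        tags.extend([tag] * len(cols))

    if morphology is not None:
        add(morphology, MORPHOLOGY_MEASURES, "morphological")
    if sc_net is not None:
        add(sc_net, [f"SC_{c}" for c in NETWORK_MEASURES], "structural")
    if sc_stat is not None:
        add(sc_stat, [f"SC_{c}" for c in STATISTICAL_MEASURES], "structural")
    if fc_net is not None:
        add(fc_net, [f"FC_{c}" for c in NETWORK_MEASURES], "functional")
    if fc_stat is not None:
        add(fc_stat, [f"FC_{c}" for c in STATISTICAL_MEASURES], "functional")
    if not blocks:
        raise ValueError("at least one feature block is required")
    n_rows = {b.shape[0] for b in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"feature blocks disagree on node count: {sorted(n_rows)}")
    widths = [b.shape[1] for b in blocks]
    mat = np.concatenate(blocks, axis=1)
    if mat.shape[1] != len(names):
        raise ValueError(f"unexpected block widths {widths}")
    return NodeFeatureMatrix(mat, names, tags)


def subject_features(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    morphology: np.ndarray | None,
    mode: str = "multimodal",
    seed: int = 0,
) -> NodeFeatureMatrix:
    """Full feature matrix for one subject from preprocessed SC/FC.

    ``mode``: 'multimodal' (24 cols), 'unimodal-sc' or 'unimodal-fc'
    (11 cols of the respective modality).
    """
    if mode == "multimodal":
        return assemble_multimodal_features(
            morphology,
            compute_network_features(sc, seed=seed),
            compute_statistical_features(sc),
            compute_network_features(fc, seed=seed),
            compute_statistical_features(fc),
        )
    if mode == "unimodal-sc":
        return assemble_multimodal_features(
            None,
            compute_network_features(sc, seed=seed),
            compute_statistical_features(sc),
            None,
            None,
        )
    if mode == "unimodal-fc":
        return assemble_multimodal_features(
            None,
            None,
            None,
            compute_network_features(fc, seed=seed),
            compute_statistical_features(fc),
        )
    raise ValueError(f"unknown feature mode {mode!r}")


class FeatureScaler:
    """Per-feature min-max scaler fitted over all nodes of the training
    subjects; constant features map to 0. Thin wrapper over sklearn."""

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(clip=False)
        self.fitted = False

    def fit(self, train: list[NodeFeatureMatrix]) -> "FeatureScaler":
        if not train:
            raise ValueError("training list must be non-empty")
        stacked = np.vstack([f.values for f in train])
        self._scaler.fit(stacked)
        # map constant columns to 0 rather than sklearn's min offset
        rng0 = self._scaler.data_range_ == 0
        self._scaler.scale_[rng0] = 1.0
        self._scaler.min_[rng0] = -self._scaler.data_min_[rng0]
        self.fitted = True
        return self

    def transform(self, feats: list[NodeFeatureMatrix]) -> list[NodeFeatureMatrix]:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return [
            NodeFeatureMatrix(
                self._scaler.transform(f.values), f.feature_names, f.modality_tags
            )
            for f in feats
        ]

    def inverse_transform(self, feats: list[NodeFeatureMatrix]) -> list[NodeFeatureMatrix]:
        return [
            NodeFeatureMatrix(
                self._scaler.inverse_transform(f.values),
                f.feature_names,
                f.modality_tags,
            )
            for f in feats
        ]


def minmax_normalize(
    train: list[NodeFeatureMatrix],
    others: list[NodeFeatureMatrix] = (),
    scope: str = "train",
) -> tuple[list[NodeFeatureMatrix], list[NodeFeatureMatrix], FeatureScaler]:
    """Fit min-max scaling on the training subjects and apply it everywhere.

    Training features land in [0, 1]; held-out features use the training
    scaler and may exceed that range. ``scope='global'`` fits the scaler on
    train and held-out subjects together — this leaks held-out ranges into
    the scaling and exists only to mirror designs that normalized before
    splitting.
    """
    if scope not in ("train", "global"):
        raise ValueError(f"scope must be 'train' or 'global', got {scope!r}")
    if not train:
        raise ValueError("training list must be non-empty")
    fit_on = list(train) + (list(others) if scope == "global" else [])
    scaler = FeatureScaler().fit(fit_on)
    return scaler.transform(list(train)), scaler.transform(list(others)), scaler
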