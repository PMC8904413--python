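"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — exhaustive simple-path enumeration
for shortest-path quantities and explicit loops for the attention
equations — so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-10


# ---------------------------------------------------------------------------
# exhaustive shortest paths
# ---------------------------------------------------------------------------

def _simple_paths(lengths: np.ndarray, s: int, t: int):
    """Yield (path, total_length) over all simple s-t paths; lengths is a
    matrix with np.inf where there is no edge."""
    n = lengths.shape[0]
    stack = [(s, (s,), 0.0)]
    while stack:
        node, path, dist = stack.pop()
        if node == t:
            yield path, dist
            continue
        for nxt in range(n):
            if np.isfinite(lengths[node, nxt]) and nxt not in path:
                stack.append((nxt, path + (nxt,), dist + lengths[node, nxt]))


def _shortest_paths(lengths: np.ndarray, s: int, t: int):
    """All shortest simple s-t paths and their common length."""
    best, paths = np.inf, []
    for path, dist in _simple_paths(lengths, s, t):
        if dist < best - TOL:
            best, paths = dist, [path]
        elif abs(dist - best) <= TOL:
            paths.append(path)
    return best, paths


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness, path length = 1/weight, summed
    over unordered pairs."""
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, np.inf)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            best, paths = _shortest_paths(lengths, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def brute_clustering(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max()
    cc = np.zeros(n)
    if wmax <= 0:
        return cc
    wn = w / wmax
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        cc[i] = total / (k * (k - 1))
    return cc


def brute_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max()
    le = np.zeros(n)
    if wmax <= 0:
        return le
    wn = w / wmax
    for i in range(n):
        nb = [j for j in range(n) if wn[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        sub = wn[np.ix_(nb, nb)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.cbrt(sub), np.inf)
        np.fill_diagonal(lengths, np.inf)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a == b:
                    continue
                d, paths = _shortest_paths(lengths, a, b)
                if paths:
                    total += (wn[i, nb[a]] * wn[i, nb[b]]) ** (1.0 / 3.0) / d
        le[i] = total / (k * (k - 1))
    return le


def brute_nodal_modularity(w: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    s = w.sum(axis=1)
    two_w = s.sum()
    out = np.zeros(n)
    if two_w <= 0:
        return out
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                out[i] += (w[i, j] - s[i] * s[j] / two_w) / two_w
    return out


def brute_participation(w: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        si = w[i].sum()
        if si <= 0:
            continue
        acc = 0.0
        for m in np.unique(assignment):
            kim = w[i, assignment == m].sum()
            acc += (kim / si) ** 2
        out[i] = 1.0 - acc
    return out


def newman_q(w: np.ndarray, assignment: np.ndarray) -> float:
    """Direct double-sum evaluation of Newman's Q."""
    return float(brute_nodal_modularity(w, assignment).sum())


# ---------------------------------------------------------------------------
# brute-force graph attention (per-element loops)
# ---------------------------------------------------------------------------

def brute_attention(h, W, a, adj, slope=0.2):
    """Row-softmax attention coefficients computed scalar by scalar."""
    n = h.shape[0]
    mask = (np.asarray(adj) != 0).astype(float)
    np.fill_diagonal(mask, 1.0)
    fp = W.shape[0]
    alpha = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in range(n) if mask[i, j]]
        es = []
        for j in neigh:
            whi = W @ h[i]
            whj = W @ h[j]
            e = float(a[:fp] @ whi + a[fp:] @ whj)
            es.append(e if e > 0 else slope * e)
        es = np.array(es)
        ex = np.exp(es - es.max())
        for j, v in zip(neigh, ex / ex.sum()):
            alpha[i, j] = v
    return alpha


def brute_layer(h, heads, adj, slope=0.2, concat=True):
    """Per-head ELU(sum_j alpha_ij W h_j), heads concatenated or averaged."""
    def elu(x):
        return np.where(x > 0, x, np.expm1(x))

    outs = []
    n = h.shape[0]
    for W, a in heads:
        alpha = brute_attention(h, W, a, adj, slope)
        o = np.zeros((n, W.shape[0]))
        for i in range(n):
            for j in range(n):
                if alpha[i, j]:
                    o[i] += alpha[i, j] * (W @ h[j])
        outs.append(o)
    if concat:
        return np.concatenate([elu(o) for o in outs], axis=1)
    return elu(np.mean(outs, axis=0))


def random_graph(rng, n, p=0.5):
    """Random symmetric binary adjacency with at least one edge."""
    while True:
        adj = (rng.uniform(size=(n, n)) < p).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        if adj.sum() > 0:
            return adj


def random_weighted_graph(rng, n, p=0.4):
    w = rng.uniform(0.2, 1.0, size=(n, n)) * (rng.uniform(size=(n, n)) < p)
    w = np.triu(w, 1)
    return w + w.T
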