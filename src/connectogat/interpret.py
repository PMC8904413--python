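"""Interpretability framework: head fidelity, gradient saliency, averaged
attention maps, and correlation of salient features with clinical scores.

* Fidelity of an attention head is the mean drop in per-graph prediction
  correctness when that head's learned attention is replaced by a
  head-agnostic mask (uniform over each node's neighborhood by default):
  F = (1/N) * sum_i [1(yhat_i = y_i) - 1(yhat_i^masked = y_i)].
* Saliency is the gradient of the predicted-class probability with respect
  to the node-by-feature input, |dy/dh| averaged over correctly predicted
  samples.
* Attention summaries average each head's coefficient matrix over
  correctly predicted samples and symmetrize it for display.
* Salient (node, feature) entries above a threshold are correlated with
  clinical variables of real patients via Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectomes import CLINICAL_VARS, CohortDataset
from .gat import GATModel
from .training import GraphSample

SALIENCY_THRESHOLD = 0.02  # default cutoff for "moderately high" saliency


@dataclass
class FidelityResult:
    scores: dict[tuple[int, int], float]  # (layer, head) -> fidelity
    baseline_accuracy: float
    mask_mode: str
    n_samples: int

    def ranked_heads(self) -> list[tuple[int, int]]:
        return sorted(self.scores, key=lambda k: (-self.scores[k], k))


@dataclass
class SaliencyMap:
    values: np.ndarray  # n x F, nonnegative (mean |gradient|)
    sample_count: int
    feature_names: list[str] = field(default_factory=list)
    node_names: list[str] = field(default_factory=list)
    threshold: float = SALIENCY_THRESHOLD


@dataclass
class AttentionSummary:
    mean: dict[tuple[int, int], np.ndarray]  # directed row-stochastic means
    symmetric: dict[tuple[int, int], np.ndarray]  # (A + A.T)/2, display-thresholded
    display_threshold: float
    n_samples: int


@dataclass
class ClinicalCorrelation:
    rows: list[dict]  # node, feature, variable, r, p, n_used, significant
    alpha: float

    def significant(self) -> list[dict]:
        return [r for r in self.rows if r["significant"]]


def _predictions(model: GATModel, samples: list[GraphSample], **kw):
    outs = [model.forward(s.features, s.adjacency, **kw) for s in samples]
    preds = np.array([o.predicted for o in outs])
    return outs, preds


def fidelity_scores(
    model: GATModel,
    samples: list[GraphSample],
    mask_mode: str = "uniform",
    layers_heads: list[tuple[int, int]] | None = None,
) -> FidelityResult:
    """Per-head fidelity on an evaluation set (typically the validation
    split): the accuracy lost when the head's attention is masked."""
    if not samples:
        raise ValueError("fidelity needs at least one evaluation sample")
    y = np.array([s.label for s in samples])
    _, base_pred = _predictions(model, samples)
    base_correct = (base_pred == y).astype(float)
    if layers_heads is None:
        layers_heads = [(0, p) for p in range(model.config.heads1)] + [(1, 0)]
    scores = {}
    for lh in layers_heads:
        _, masked_pred = _predictions(
            model, samples, mask_head=lh, mask_mode=mask_mode
        )
        masked_correct = (masked_pred == y).astype(float)
        scores[lh] = float((base_correct - masked_correct).mean())
    return FidelityResult(
        scores, float(base_correct.mean()), mask_mode, len(samples)
    )


def saliency_map(
    model: GATModel,
    samples: list[GraphSample],
    feature_names: list[str] | None = None,
    node_names: list[str] | None = None,
    signed: bool = False,
) -> SaliencyMap:
    """Mean (absolute) input gradient of the predicted-class probability
    over correctly predicted samples."""
    grads = []
    for s in samples:
        out = model.forward(s.features, s.adjacency, input_grad=True)
        if out.predicted != s.label:
            continue
        prob = out.log_probs.take_rows([out.predicted]).sum().exp()
        prob.backward()
        g = out.input_tensor.grad
        grads.append(g if signed else np.abs(g))
    if not grads:
        raise ValueError(
            f"no correctly predicted samples among {len(samples)}; "
            "saliency is undefined"
        )
    return SaliencyMap(
        np.mean(grads, axis=0),
        len(grads),
        list(feature_names or []),
        list(node_names or []),
    )


def ensemble_saliency(
    models: list[GATModel],
    samples: list[GraphSample],
    feature_names: list[str] | None = None,
    node_names: list[str] | None = None,
) -> SaliencyMap:
    """Saliency averaged over independently initialized trained models.

    Gradient attributions of a single network are initialization-dependent:
    equally accurate models can attend to different, equally predictive
    parts of the input. Averaging the per-model maps marginalizes over the
    optimization path and is the recommended protocol when saliency is
    interpreted scientifically.
    """
    if not models:
        raise ValueError("ensemble needs at least one model")
    maps = [saliency_map(m, samples) for m in models]
    return SaliencyMap(
        np.mean([s.values for s in maps], axis=0),
        min(s.sample_count for s in maps),
        list(feature_names or []),
        list(node_names or []),
    )


def select_salient(
    sal: SaliencyMap, threshold: float = SALIENCY_THRESHOLD
) -> list[tuple[int, int, float]]:
    """(node, feature, score) entries with score > threshold, descending."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    ii, jj = np.nonzero(sal.values > threshold)
    entries = [(int(i), int(j), float(sal.values[i, j])) for i, j in zip(ii, jj)]
    return sorted(entries, key=lambda e: -e[2])


def attention_summary(
    model: GATModel,
    samples: list[GraphSample],
    display_threshold: float = 0.0,
) -> AttentionSummary:
    """Per-head attention matrices averaged over correctly predicted
    samples, plus symmetrized display versions with small entries zeroed."""
    sums: dict[tuple[int, int], np.ndarray] = {}
    count = 0
    for s in samples:
        out = model.forward(s.features, s.adjacency, record_attention=True)
        if out.predicted != s.label:
            continue
        count += 1
        for key, alpha in out.attention.items():
            sums[key] = sums.get(key, 0) + alpha
    if count == 0:
        raise ValueError(
            f"no correctly predicted samples among {len(samples)}"
        )
    mean = {k: v / count for k, v in sums.items()}
    symmetric = {}
    for k, a in mean.items():
        sym = (a + a.T) / 2.0
        sym[sym < display_threshold] = 0.0
        symmetric[k] = sym
    return AttentionSummary(mean, symmetric, display_threshold, count)


def correlate_clinical(
    salient: list[tuple[int, int, float]],
    cohort: CohortDataset,
    feature_matrices: dict[str, np.ndarray],
    alpha: float = 0.005,
    variables: tuple[str, ...] = CLINICAL_VARS,
    correction: str | None = None,
) -> ClinicalCorrelation:
    """Pearson correlation of each salient node-feature with each clinical
    variable, over real patients with non-missing values (n >= 3).

    ``feature_matrices`` maps subject_id -> that subject's n x F feature
    matrix. Significance defaults to uncorrected p < alpha; zero-variance
    series yield an entry flagged undefined rather than an exception.
    ``correction``: None (default), 'bonferroni', or 'fdr_bh'
    (Benjamini-Hochberg) applied across all tested pairs.
    """
    if correction not in (None, "bonferroni", "fdr_bh"):
        raise ValueError(f"unknown correction {correction!r}")
    patients = [
        s for s in cohort.subjects if s.label == 1 and s.origin == "real"
    ]
    rows = []
    for node, feat, score in salient:
        for var in variables:
            pairs = [
                (feature_matrices[s.subject_id][node, feat], s.clinical[var])
                for s in patients
                if var in s.clinical and s.subject_id in feature_matrices
            ]
            if len(pairs) < 3:
                continue
            x = np.array([p[0] for p in pairs])
            yv = np.array([p[1] for p in pairs])
            if np.std(x) == 0 or np.std(yv) == 0:
                rows.append(
                    dict(node=node, feature=feat, variable=var, r=np.nan,
                         p=np.nan, n_used=len(pairs), significant=False,
                         undefined=True)
                )
                continue
            r, p = stats.pearsonr(x, yv)
            rows.append(
                dict(node=node, feature=feat, variable=var, r=float(r),
                     p=float(p), n_used=len(pairs),
                     significant=bool(p < alpha), undefined=False)
            )
    defined = [row for row in rows if not row["undefined"]]
    if correction == "bonferroni":
        for row in defined:
            row["significant"] = bool(row["p"] * len(defined) < alpha)
    elif correction == "fdr_bh":
        m = len(defined)
        order = np.argsort([row["p"] for row in defined])
        passed = -1
        for rank, oi in enumerate(order, start=1):
            if defined[oi]["p"] <= alpha * rank / m:
                passed = rank
        for rank, oi in enumerate(order, start=1):
            defined[oi]["significant"] = bool(rank <= passed)
    return ClinicalCorrelation(rows, alpha)
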