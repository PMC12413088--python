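"""Benchmark for the annotation-ranking methods with degree-matched negatives.

A positive is an existing direct (protein, GO term) annotation; for the
trial that scores it, that annotation edge (and any inferred ancestor
records it alone supported) is removed from the working annotation set,
so the method must rediscover it.  Each positive is paired with up to m
negative proteins that (1) lie near the positive in the interaction
graph, (2) are not annotated — directly or by inference — to the
positive's term, and (3) have approximately the same degree as the
positive.  Trials are pooled into single ROC and precision-recall
curves; because raw scores from different GO terms are not
commensurable, the default pooling converts each trial's scores to
within-trial normalized ranks first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics

from .annotation_scoring import (
    LOWER_IS_BETTER,
    ScoringMethod,
    WalkConfig,
    score_candidates,
)
from .graph_model import EdgeTypeFilter, MixedGraph
from .ontology import DIRECT, INFERRED, AnnotationSet, OntologyDag
from .subnetwork_query import traversal_view

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchingConfig:
    """Negative-sampling tolerances.

    ``degree_slack``/``degree_rel``: a negative's mixed degree must be
    within max(degree_slack, degree_rel * deg(pos)) of the positive's.
    ``radius``: initial hop radius on the interactions-only view; relaxed
    stepwise up to ``max_radius`` when fewer than m candidates exist.
    The not-annotated criterion is never relaxed.
    """
    degree_slack: int = 2
    degree_rel: float = 0.10
    radius: int = 2
    max_radius: int = 4

    def degree_tolerance(self, pos_degree: int) -> float:
        return max(self.degree_slack, self.degree_rel * pos_degree)


@dataclass
class NegativeSample:
    proteins: list[str]
    relaxation_radius: int          # radius actually used
    eligible_count: int


@dataclass
class EvalDataset:
    positives: list[tuple[str, str]]
    negatives: list[NegativeSample]  # parallel to positives
    seed: int
    skipped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class MethodCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_auc: float
    precision: np.ndarray
    recall: np.ndarray
    pr_auc: float
    labels: np.ndarray
    scores: np.ndarray
    dropped_trials: int = 0


@dataclass
class EvalCurves:
    per_method: dict[ScoringMethod, MethodCurves]
    n_trials: int
    pooling: str


def sample_positives(graph: MixedGraph, annots: AnnotationSet, n: int,
                     seed: int) -> list[tuple[str, str]]:
    """Draw n distinct direct (protein, term) records uniformly at random."""
    records = sorted((p, t) for p, t in annots.direct_pairs() if p in graph)
    if n > len(records):
        raise ValueError(
            f"requested {n} positives but only {len(records)} direct records exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in idx]


def eligible_negatives(graph: MixedGraph, annots: AnnotationSet,
                       positive: tuple[str, str], radius: int,
                       matching: MatchingConfig) -> list[str]:
    """All proteins satisfying the three criteria at a given hop radius."""
    pos, term = positive
    pos = graph.resolve(pos)
    view = traversal_view(graph, EdgeTypeFilter.MIXED)
    near = nx_ball(view, pos, radius)
    pos_deg = graph.degree(pos, EdgeTypeFilter.MIXED)
    tol = matching.degree_tolerance(pos_deg)
    member_keys = {m.lower() for m in _term_members(annots, term)}
    out = []
    for cand in sorted(near):
        if cand == pos or cand.lower() in member_keys:
            continue
        if abs(graph.degree(cand, EdgeTypeFilter.MIXED) - pos_deg) <= tol:
            out.append(cand)
    return out


def _term_members(annots: AnnotationSet, term: str) -> set[str]:
    return {r.protein for r in annots.records() if r.term == term}


def nx_ball(view, center: str, radius: int) -> set[str]:
    """Nodes within ``radius`` hops of ``center`` (center excluded)."""
    import networkx as nx
    dist = nx.single_source_shortest_path_length(view, center, cutoff=radius)
    return {n for n, d in dist.items() if 0 < d <= radius}


def sample_negatives(graph: MixedGraph, annots: AnnotationSet,
                     positive: tuple[str, str], m: int, seed: int,
                     matching: MatchingConfig = MatchingConfig()) -> NegativeSample:
    """Up to m degree-matched nearby non-members for one positive.

    The hop radius relaxes stepwise (2 -> 3 -> 4 by default) when the
    eligible pool is smaller than m; the not-annotated criterion is
    inviolable.  Returns the relaxation level used and pool size.
    """
    rng = np.random.default_rng(seed)
    radius = matching.radius
    pool = eligible_negatives(graph, annots, positive, radius, matching)
    while len(pool) < m and radius < matching.max_radius:
        radius += 1
        pool = eligible_negatives(graph, annots, positive, radius, matching)
    if not pool:
        raise ValueError(f"no eligible negatives for positive {positive}")
    take = min(m, len(pool))
    idx = rng.choice(len(pool), size=take, replace=False)
    return NegativeSample(proteins=[pool[i] for i in idx],
                          relaxation_radius=radius,
                          eligible_count=len(pool))


def build_dataset(graph: MixedGraph, annots: AnnotationSet, n_positives: int,
                  n_negatives: int, seed: int,
                  matching: MatchingConfig = MatchingConfig()) -> EvalDataset:
    positives = sample_positives(graph, annots, n_positives, seed)
    kept, negs, skipped = [], [], []
    for i, positive in enumerate(positives):
        try:
            neg = sample_negatives(graph, annots, positive, n_negatives,
                                   seed=seed + 1 + i, matching=matching)
        except ValueError:
            skipped.append(positive)
            logger.warning("positive %s skipped: no eligible negatives", positive)
            continue
        kept.append(positive)
        negs.append(neg)
    return EvalDataset(positives=kept, negatives=negs, seed=seed, skipped=skipped)


def remove_annotation(annots: AnnotationSet, protein: str, term: str,
                      dag: OntologyDag) -> AnnotationSet:
    """Copy of the annotation set with one direct record removed.

    Inferred ancestor records of the removed edge that have no other
    direct support from the same protein are removed too — an inferred
    annotation exists only by virtue of direct evidence below it.
    """
    out = annots.copy()
    out.discard(protein, term, DIRECT)
    remaining = {
        anc
        for other in out.terms_for_protein(protein, include_inferred=False)
        for anc in dag.ancestors(other) | {other}
    }
    for anc in dag.ancestors(term):
        if anc not in remaining:
            out.discard(protein, anc, INFERRED)
    return out


def _pool_scores(trial_scores: list[dict[str, float]],
                 trial_positives: list[str], method: ScoringMethod,
                 pooling: str) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-trial candidate scores into (labels, pooled scores).

    ``rank`` pooling maps each candidate to 1 - rank/(1 + n_candidates)
    using within-trial competition ranks in the method's
    better-direction, so pooled scores are always higher-is-better.
    ``raw`` pooling concatenates raw scores (sign-flipped for
    lower-is-better methods).
    """
    labels, pooled = [], []
    lower_better = ScoringMethod(method) in LOWER_IS_BETTER
    for scores, pos in zip(trial_scores, trial_positives):
        items = sorted(scores.items())
        vals = np.array([v for _, v in items])
        if pooling == "rank":
            better = vals[None, :] < vals[:, None] if lower_better \
                else vals[None, :] > vals[:, None]
            ranks = better.sum(axis=1) + 1  # competition ranks
            pool_vals = 1.0 - ranks / (1 + len(items))
        elif pooling == "raw":
            pool_vals = -vals if lower_better else vals
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        for (name, _), v in zip(items, pool_vals):
            labels.append(1 if name == pos else 0)
            pooled.append(v)
    return np.array(labels), np.array(pooled)


def roc_pr_from_table(labels: np.ndarray, scores: np.ndarray) -> MethodCurves:
    """ROC (trapezoid AUC) and PR (step-interpolated AUC) from a pooled table."""
    fpr, tpr, _ = metrics.roc_curve(labels, scores)
    roc_auc = float(metrics.auc(fpr, tpr))
    precision, recall, _ = metrics.precision_recall_curve(labels, scores)
    pr_auc = float(metrics.average_precision_score(labels, scores))
    return MethodCurves(fpr=fpr, tpr=tpr, roc_auc=roc_auc,
                        precision=precision, recall=recall, pr_auc=pr_auc,
                        labels=labels, scores=scores)


def run_benchmark(graph: MixedGraph, annots: AnnotationSet, dag: OntologyDag,
                  dataset: EvalDataset,
                  methods: list[ScoringMethod] | None = None,
                  cfg: WalkConfig = WalkConfig(),
                  pooling: str = "rank") -> EvalCurves:
    """Score every trial with every method and pool into ROC/PR curves.

    For each positive, the direct annotation edge (plus unsupported
    inferred ancestors) is removed for that trial only; the positive and
    its negatives are scored on the modified annotation set.
    """
    if methods is None:
        methods = list(ScoringMethod)
    methods = [ScoringMethod(m) for m in methods]
    per_method_scores: dict[ScoringMethod, list[dict[str, float]]] = {
        m: [] for m in methods}
    per_method_dropped = {m: 0 for m in methods}
    trial_positives: dict[ScoringMethod, list[str]] = {m: [] for m in methods}
    for positive, neg in zip(dataset.positives, dataset.negatives):
        pos_protein, term = positive
        pos_protein = graph.resolve(pos_protein)
        trial_annots = remove_annotation(annots, pos_protein, term, dag)
        candidates = [pos_protein] + list(neg.proteins)
        for method in methods:
            try:
                scores = score_candidates(graph, trial_annots, term, method,
                                          candidates, cfg, dag=dag)
            except Exception:
                per_method_dropped[method] += 1
                logger.exception("method %s failed on trial %s", method, positive)
                continue
            per_method_scores[method].append(scores)
            trial_positives[method].append(pos_protein)
    per_method: dict[ScoringMethod, MethodCurves] = {}
    for method in methods:
        labels, scores = _pool_scores(per_method_scores[method],
                                      trial_positives[method], method, pooling)
        curves = roc_pr_from_table(labels, scores)
        curves.dropped_trials = per_method_dropped[method]
        per_method[method] = curves
    return EvalCurves(per_method=per_method, n_trials=len(dataset.positives),
                      pooling=pooling)


def plot_curves(curves: EvalCurves, out_dir: str) -> list[str]:
    """One ROC and one PR figure with per-method series, AUC in the legend."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for panel in ("roc", "pr"):
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, mc in curves.per_method.items():
            if panel == "roc":
                ax.plot(mc.fpr, mc.tpr,
                        label=f"{method.value} (AUC = {mc.roc_auc:.2f})")
            else:
                ax.plot(mc.recall, mc.precision, drawstyle="steps-post",
                        label=f"{method.value} (AUC = {mc.pr_auc:.2f})")
        if panel == "roc":
            ax.plot([0, 1], [0, 1], ls=":", c="gray", lw=0.8)
            ax.set_xlabel("False positive rate")
            ax.set_ylabel("True positive rate")
        else:
            ax.set_xlabel("Recall")
            ax.set_ylabel("Precision")
        ax.legend(loc="lower right" if panel == "roc" else "upper right",
                  fontsize=8)
        fig.tight_layout()
        path = os.path.join(out_dir, f"{panel}_curves.png")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
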