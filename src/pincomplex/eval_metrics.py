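"""Evaluation machinery for predicted protein complexes.

Cluster matching uses the neighborhood affinity score
NA(A, B) = |A∩B|² / (|A|·|B|); a prediction and a benchmark complex match
when NA >= ω (0.25 conventionally).  Precision counts matched predictions,
recall matched benchmark complexes, and F is their harmonic mean.

The protein-level view builds the benchmark × prediction shared-protein
matrix T: sensitivity Sn sums row maxima over total benchmark protein
counts, positive predictive value PPV sums column maxima over column totals,
and Acc is their geometric mean.  PPV penalizes inter-complex overlap — a
benchmark with overlapping complexes does not even score PPV = 1 against
itself — which is why F is the primary metric and Acc auxiliary.

Functional homogeneity of a predicted complex is the smallest hypergeometric
enrichment p-value over all GO terms annotating its members:
P = 1 - Σ_{i<k} C(|F|,i)·C(|V|-|F|,|C|-i)/C(|V|,|C|), with k members in the
functional group F out of a universe of |V| proteins.

A five-fold protocol compares against unsupervised methods without
train/test overlap: train on four folds of the positives (plus intermediates
and fresh negatives), detect, discard predictions matching the training
complexes, pool the per-fold survivors, deduplicate, and evaluate the pool
against all positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .detect_pipeline import Candidate, PipelineParams, _rank_key, detect
from .go_semantics import AnnotationMap
from .pin_io import ComplexCatalog
from .scoring_model import build_training_set, fit

logger = logging.getLogger("pincomplex")

__all__ = [
    "EvalReport",
    "na_score",
    "precision_recall_f",
    "sn_ppv_acc",
    "overlap_matrix",
    "hypergeometric_pvalue",
    "functional_homogeneity",
    "qi_match",
    "evaluate",
    "cross_validation_eval",
]


@dataclass
class EvalReport:
    """Matching counts and metric values for one predicted-vs-benchmark comparison."""

    n_predicted: int
    n_benchmark: int
    ncp: int
    ncb: int
    precision: float
    recall: float
    f_measure: float
    sn: float = 0.0
    ppv: float = 0.0
    acc: float = 0.0
    match_threshold_omega: float = 0.25

    def as_dict(self) -> dict:
        return {
            "num": self.n_predicted,
            "ncp": self.ncp,
            "ncb": self.ncb,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
        }


def na_score(a: Iterable[str], b: Iterable[str]) -> float:
    """Neighborhood affinity |a∩b|² / (|a|·|b|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("neighborhood affinity of an empty set is undefined")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def qi_match(p: Iterable[str], b: Iterable[str]) -> bool:
    """True when the shared proteins constitute more than half of each set."""
    p, b = set(p), set(b)
    if not p or not b:
        raise ValueError("cannot match empty sets")
    inter = len(p & b)
    return inter > 0.5 * len(p) and inter > 0.5 * len(b)


def precision_recall_f(
    predicted: ComplexCatalog | Sequence[frozenset[str]],
    benchmark: ComplexCatalog | Sequence[frozenset[str]],
    omega: float = 0.25,
) -> EvalReport:
    """Match-based precision/recall/F at neighborhood affinity >= omega.

    Ncp counts predictions matching at least one benchmark complex, Ncb
    benchmark complexes matching at least one prediction.  An empty
    prediction set yields a flagged zero-precision report.
    """
    pred = [set(c) for c in predicted]
    bench = [set(c) for c in benchmark]
    if not bench:
        raise ValueError("benchmark catalog must be non-empty")
    if not pred:
        logger.warning("precision undefined for an empty prediction set; reporting 0")
        return EvalReport(0, len(bench), 0, 0, 0.0, 0.0, 0.0, match_threshold_omega=omega)
    matched_b = [False] * len(bench)
    ncp = 0
    for p in pred:
        hit = False
        for i, b in enumerate(bench):
            if na_score(p, b) >= omega:
                hit = True
                matched_b[i] = True
        if hit:
            ncp += 1
    ncb = sum(matched_b)
    precision = ncp / len(pred)
    recall = ncb / len(bench)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalReport(
        len(pred), len(bench), ncp, ncb, precision, recall, f, match_threshold_omega=omega
    )


def overlap_matrix(
    predicted: Sequence[frozenset[str]] | ComplexCatalog,
    benchmark: Sequence[frozenset[str]] | ComplexCatalog,
) -> np.ndarray:
    """T[i, j] = number of proteins shared by benchmark i and prediction j."""
    bench = [set(c) for c in benchmark]
    pred = [set(c) for c in predicted]
    t = np.zeros((len(bench), len(pred)), dtype=int)
    for i, b in enumerate(bench):
        for j, p in enumerate(pred):
            t[i, j] = len(b & p)
    return t


def sn_ppv_acc(
    predicted: ComplexCatalog | Sequence[frozenset[str]],
    benchmark: ComplexCatalog | Sequence[frozenset[str]],
) -> tuple[float, float, float]:
    """Protein-level sensitivity, positive predictive value and their geometric mean.

    Sn = Σ_i max_j T_ij / Σ_i N_i and PPV = Σ_j max_i T_ij / Σ_j T_.j;
    predictions sharing no protein with any benchmark complex (zero column
    totals) contribute 0 to both PPV sums.
    """
    bench = [set(c) for c in benchmark]
    pred = [set(c) for c in predicted]
    if not bench or not pred:
        raise ValueError("both catalogs must be non-empty")
    t = overlap_matrix(pred, bench)
    n_i = np.array([len(b) for b in bench])
    sn = float(t.max(axis=1).sum() / n_i.sum())
    col_totals = t.sum(axis=0)
    denom = col_totals.sum()
    ppv = float(t.max(axis=0).sum() / denom) if denom > 0 else 0.0
    acc = math.sqrt(sn * ppv)
    return sn, ppv, acc


def evaluate(
    predicted: ComplexCatalog | Sequence[frozenset[str]],
    benchmark: ComplexCatalog | Sequence[frozenset[str]],
    omega: float = 0.25,
) -> EvalReport:
    """Full report: NA-matched precision/recall/F plus Sn/PPV/Acc."""
    report = precision_recall_f(predicted, benchmark, omega=omega)
    if report.n_predicted:
        report.sn, report.ppv, report.acc = sn_ppv_acc(predicted, benchmark)
    return report


def hypergeometric_pvalue(k: int, f_size: int, c_size: int, v_size: int) -> float:
    """P(X >= k) for the number X of functional-group members in a complex.

    Drawing a complex of ``c_size`` proteins from a universe of ``v_size``
    containing ``f_size`` group members:
    1 - Σ_{i=0}^{k-1} C(f,i)·C(v-f,c-i)/C(v,c), evaluated in exact rational
    arithmetic.
    """
    if not (0 <= k <= c_size <= v_size) or not (0 <= f_size <= v_size):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, f={f_size}, c={c_size}, v={v_size}"
        )
    total = math.comb(v_size, c_size)
    acc = Fraction(0)
    for i in range(k):
        acc += Fraction(math.comb(f_size, i) * math.comb(v_size - f_size, c_size - i), total)
    p = 1 - acc
    return float(min(max(p, Fraction(0)), Fraction(1)))


def functional_homogeneity(
    members: Iterable[str], ann: AnnotationMap, v_size: int
) -> tuple[str | None, float]:
    """Best GO-term enrichment of a complex: the minimizing term and p-value.

    For every term annotating at least one member (propagated annotation),
    the hypergeometric p-value is computed with the term's propagated
    annotation count as the functional-group size; unannotated complexes
    return ``(None, 1.0)``.  Ties break on the smaller term ID.
    """
    if not ann.is_propagated:
        raise ValueError("functional_homogeneity requires a propagated AnnotationMap")
    members = set(members)
    c_size = len(members)
    counts: dict[str, int] = {}
    for p in members:
        for t in ann.propagated.get(p, ()):
            counts[t] = counts.get(t, 0) + 1
    best_term, best_p = None, 1.0
    for t in sorted(counts):
        f_size = min(ann.term_size[t], v_size)
        k = counts[t]
        pval = hypergeometric_pvalue(k, f_size, c_size, v_size)
        if pval < best_p:
            best_term, best_p = t, pval
    return best_term, best_p


def cross_validation_eval(
    positives: ComplexCatalog,
    intermediates: ComplexCatalog,
    gu: nx.Graph,
    gw: nx.Graph,
    params: PipelineParams,
    folds: int = 5,
    train_match: float = 0.9,
    dedup_match: float = 0.6,
    seed: int = 0,
    n_negatives: int | None = None,
    iterations: int = 500,
    eta: float = 1e-4,
    omega: float = 0.25,
) -> EvalReport:
    """Five-fold-style protocol avoiding train/test overlap.

    The positives are split into *folds* folds by seeded shuffle.  For each
    fold, a model is trained on the remaining folds (plus all intermediates
    and freshly sampled negatives, three per positive by default), detection
    runs on the full network, and predictions with NA >= *train_match*
    against any training positive are discarded.  The per-fold survivors are
    pooled, near-duplicates (NA > *dedup_match*) collapsed keeping the
    higher-scored, and the pool is evaluated against all positives.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_pos = len(positives)
    if n_pos < folds:
        raise ValueError(f"cannot split {n_pos} positives into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pos)
    assignments = [order[i::folds] for i in range(folds)]
    if n_negatives is None:
        n_negatives = 3 * n_pos
    survivors: list[Candidate] = []
    for f, test_idx in enumerate(assignments):
        train_idx = sorted(set(range(n_pos)) - set(int(i) for i in test_idx))
        if not train_idx:
            raise ValueError(f"fold {f} has no training positives")
        train_pos = ComplexCatalog([positives[i] for i in train_idx])
        fold_seed = (seed + 7919 * (f + 1)) % (2**31)
        samples = build_training_set(train_pos, intermediates, gu, gw, n_negatives, fold_seed)
        model = fit(samples, iterations=iterations, eta=eta)
        fold_params = PipelineParams(
            model=model,
            clique_min_size=params.clique_min_size,
            clique_overlap_nodes=params.clique_overlap_nodes,
            merg_thred=params.merg_thred,
            clique_overlap_strict=params.clique_overlap_strict,
            dynamic_neighborhood=params.dynamic_neighborhood,
        )
        predicted = detect(gu, gw, model, fold_params)
        kept = 0
        for members, s in zip(predicted.complexes, predicted.scores):
            if any(na_score(members, t) >= train_match for t in train_pos):
                continue
            survivors.append(Candidate(members, s if s is not None else 0.0))
            kept += 1
        logger.info("fold %d: kept %d/%d predictions after training-match removal", f, kept, len(predicted))
    # pool and collapse near-duplicates, keeping the higher-scored candidate
    survivors.sort(key=_rank_key)
    final: list[Candidate] = []
    for cand in survivors:
        if any(na_score(cand.members, k.members) > dedup_match for k in final):
            continue
        final.append(cand)
    report = evaluate([c.members for c in final], positives, omega=omega) if final else EvalReport(
        0, n_pos, 0, 0, 0.0, 0.0, 0.0, match_threshold_omega=omega
    )
    return report
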