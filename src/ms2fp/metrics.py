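"""Multi-task classification metrics, candidate ranking and diagnostics.

Per fingerprint bit (task) the usual confusion counts give sensitivity and
specificity; their mean is the per-task non-error rate NER_t, and the
overall NER is the mean of NER_t over tasks where both classes were
observed (a random classifier scores 0.5, a perfect one 1.0).  Set-level
similarity is summarised by the mean Jaccard–Tanimoto index between true
and predicted fingerprints.

For structure annotation, a predicted fingerprint is matched against a
candidate library and candidates ranked by descending JT.  Chemical-space
diagnostics embed fingerprints in two dimensions with classical (Torgerson)
multidimensional scaling on the distance 1 - JT, and relate per-compound
accuracy to the fraction of active bits in the true fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .fingerprints import jt, jt_matrix


@dataclass(frozen=True)
class TaskConfusion:
    """Confusion counts for one task (fingerprint bit)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def ner(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def confusion(pred: np.ndarray, truth: np.ndarray) -> list[TaskConfusion]:
    """Per-column confusion counts between binary matrices of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not np.isin(pred, (0, 1)).all() or not np.isin(truth, (0, 1)).all():
        raise ValueError("entries must be binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    out = []
    for j in range(p.shape[1]):
        out.append(
            TaskConfusion(
                tp=int((p[:, j] & t[:, j]).sum()),
                tn=int((~p[:, j] & ~t[:, j]).sum()),
                fp=int((p[:, j] & ~t[:, j]).sum()),
                fn=int((~p[:, j] & t[:, j]).sum()),
            )
        )
    return out


def ner(confusions: Sequence[TaskConfusion]) -> tuple[float, np.ndarray, list[int]]:
    """Overall NER (mean over defined tasks), per-task NER_t, excluded tasks.

    Tasks where only one class was observed have undefined sensitivity or
    specificity; they are excluded from the mean and their indices reported.
    """
    per_task = np.array([c.ner for c in confusions])
    defined = np.isfinite(per_task)
    excluded = [int(i) for i in np.nonzero(~defined)[0]]
    if not defined.any():
        raise ValueError("no task with both classes present")
    return float(per_task[defined].mean()), per_task, excluded


@dataclass
class EvaluationReport:
    """Metrics of one prediction set: per-task rates and JT summaries."""

    confusions: list[TaskConfusion]
    ner_overall: float
    ner_per_task: np.ndarray
    excluded_tasks: list[int]
    jt_per_spectrum: np.ndarray
    jt_mean: float

    def to_task_tsv(self) -> str:
        lines = ["task\ttp\ttn\tfp\tfn\tsn\tsp\tner"]
        for i, c in enumerate(self.confusions):
            lines.append(
                f"{i+1}\t{c.tp}\t{c.tn}\t{c.fp}\t{c.fn}"
                f"\t{c.sensitivity:.6g}\t{c.specificity:.6g}\t{c.ner:.6g}"
            )
        return "\n".join(lines) + "\n"


def evaluate_predictions(pred: np.ndarray, truth: np.ndarray) -> EvaluationReport:
    """Full multi-task report: confusion counts, NER and JT summaries."""
    conf = confusion(pred, truth)
    overall, per_task, excluded = ner(conf)
    jts = jt_matrix(truth, pred)
    return EvaluationReport(
        confusions=conf,
        ner_overall=overall,
        ner_per_task=per_task,
        excluded_tasks=excluded,
        jt_per_spectrum=jts,
        jt_mean=float(jts.mean()),
    )


# --------------------------------------------------------------------------
# candidate ranking


def rank_candidates(
    fp_pred: np.ndarray,
    library: Sequence[tuple[str, np.ndarray]],
    true_compound_id: Optional[str] = None,
) -> tuple[list[tuple[str, float, int]], Optional[int]]:
    """Rank a candidate library by JT to the predicted fingerprint.

    Descending JT; exact ties break by lexicographic compound id, making the
    ranking deterministic.  Returns (ranked list of (compound_id, jt, rank),
    rank of ``true_compound_id`` if present in the library).
    """
    if not library:
        raise ValueError("candidate library is empty")
    scored = sorted(
        ((cid, jt(fp, fp_pred)) for cid, fp in library),
        key=lambda x: (-x[1], x[0]),
    )
    ranked = [(cid, score, i + 1) for i, (cid, score) in enumerate(scored)]
    true_rank = None
    if true_compound_id is not None:
        for cid, _, rank in ranked:
            if cid == true_compound_id:
                true_rank = rank
                break
    return ranked, true_rank


# --------------------------------------------------------------------------
# classical MDS


def mds_embed(
    fingerprints: Sequence[np.ndarray] | np.ndarray, n_dims: int = 2
) -> np.ndarray:
    """Classical (Torgerson) MDS of fingerprints on the distance 1 - JT.

    Double-centres the squared-distance matrix, eigendecomposes, and returns
    the top ``n_dims`` coordinates (descending eigenvalue order).  The
    orientation is fixed deterministically: in each dimension the
    largest-magnitude coordinate is made positive.  If fewer than ``n_dims``
    positive eigenvalues exist, fewer columns are returned with a warning.
    """
    fps = np.asarray(fingerprints)
    m = fps.shape[0]
    if m < 3:
        raise ValueError("need at least 3 fingerprints")
    D = np.zeros((m, m))
    for i in range(m):
        for k in range(i + 1, m):
            D[i, k] = D[k, i] = 1.0 - jt(fps[i], fps[k])
    return mds_from_distances(D, n_dims=n_dims)


def mds_from_distances(D: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson MDS from a symmetric distance matrix."""
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(1e-10, 1e-10 * abs(evals[0]))
    n_pos = int(positive.sum())
    if n_pos < n_dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} dimensions",
            stacklevel=2,
        )
        n_dims = n_pos
    coords = evecs[:, :n_dims] * np.sqrt(evals[:n_dims])
    for j in range(n_dims):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def mds_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Sum of squared residuals between input and embedded distances."""
    from scipy.spatial.distance import squareform, pdist

    D_hat = squareform(pdist(coords))
    return float(((np.asarray(D) - D_hat) ** 2).sum())


# --------------------------------------------------------------------------
# active-bit diagnostics


def active_bit_analysis(
    mean_jt_per_compound: Mapping[str, float],
    true_fingerprints: Mapping[str, np.ndarray],
    threshold_low: float = 0.25,
    threshold_high: float = 0.75,
) -> dict[str, Optional[dict[str, float]]]:
    """Compare active-bit fractions of well- and poorly-predicted compounds.

    Compounds are grouped by mean JT between predicted and true fingerprints
    (low: < ``threshold_low``; high: > ``threshold_high``) and the
    distribution (n, median, quartiles) of the percentage of active bits in
    each group's *true* fingerprints is returned.  An empty group maps to
    None (flagged as undefined).
    """
    groups: dict[str, list[float]] = {"low": [], "high": []}
    for cid, mjt in mean_jt_per_compound.items():
        fp = np.asarray(true_fingerprints[cid])
        pct_active = 100.0 * fp.sum() / fp.size
        if mjt < threshold_low:
            groups["low"].append(pct_active)
        elif mjt > threshold_high:
            groups["high"].append(pct_active)
    out: dict[str, Optional[dict[str, float]]] = {}
    for name, vals in groups.items():
        if not vals:
            out[name] = None
            continue
        arr = np.array(vals)
        out[name] = {
            "n": float(len(arr)),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }
    return out
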