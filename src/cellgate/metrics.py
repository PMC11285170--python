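"""Open-set evaluation metrics.

Annotation with rejection is scored along two axes: did the classifier keep
truly-known cells inside the known vocabulary while pushing truly-novel
cells to "unknown" (effective assignment score, EAS), and did it also name
the correct type (the stricter EAS_M)? Both are differences of rates,

    EAS   = N_k^k / N_k  -  N_u^k / N_u
    EAS_M = N_k^true / N_k  -  N_u^k / N_u

where N_k / N_u count truly known / truly unknown cells, N_k^k and N_u^k
count those predicted as any known type, and N_k^true counts known cells
predicted as their own type. Cohen's kappa, computed over the K+1 classes
(all novel truth types pooled into one "unknown"), adds a chance-corrected
view that is sensitive to minor types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNKNOWN = "unknown"


@dataclass
class OpenSetEval:
    """Counts, metrics and the (K+1)-class confusion matrix of one run."""

    known_types: list
    n_k: int
    n_u: int
    n_k_k: int
    n_u_k: int
    n_k_true: int
    eas: float
    eas_m: float
    kappa: float
    confusion: np.ndarray
    class_order: list
    partial: bool = False  # set when one side (known/unknown) is empty

    def as_dict(self) -> dict:
        return {
            "known_types": list(self.known_types),
            "n_k": self.n_k, "n_u": self.n_u, "n_k_k": self.n_k_k,
            "n_u_k": self.n_u_k, "n_k_true": self.n_k_true,
            "eas": self.eas, "eas_m": self.eas_m, "kappa": self.kappa,
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "partial": self.partial,
        }


def effective_assignment(y_true, y_pred, known_types):
    """EAS and EAS_M with their underlying counts.

    A true label is "known" iff it is in ``known_types``; any other truth
    label counts as unknown. Predictions must be a known type or
    ``"unknown"``. If a side is empty (no truly-unknown or no truly-known
    cells) the corresponding rate is dropped and the result flagged partial.

    Returns (eas, eas_m, counts) where counts is a dict with keys
    n_k, n_u, n_k_k, n_u_k, n_k_true, partial.
    """
    y_true = [str(t).strip() for t in y_true]
    y_pred = [str(p).strip() for p in y_pred]
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    known = {str(t).strip() for t in known_types}
    bad = {p for p in y_pred if p not in known and p != UNKNOWN}
    if bad:
        raise ValueError(f"predicted labels outside vocabulary: {sorted(bad)}")

    n_k = n_u = n_k_k = n_u_k = n_k_true = 0
    for t, p in zip(y_true, y_pred):
        if t in known:
            n_k += 1
            if p in known:
                n_k_k += 1
                if p == t:
                    n_k_true += 1
        else:
            n_u += 1
            if p in known:
                n_u_k += 1

    known_rate = n_k_k / n_k if n_k else 0.0
    true_rate = n_k_true / n_k if n_k else 0.0
    unk_rate = n_u_k / n_u if n_u else 0.0
    counts = {"n_k": n_k, "n_u": n_u, "n_k_k": n_k_k, "n_u_k": n_u_k,
              "n_k_true": n_k_true, "partial": n_k == 0 or n_u == 0}
    return known_rate - unk_rate, true_rate - unk_rate, counts


def confusion_matrix(y_true, y_pred, class_order) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    mat = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return mat


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement from the confusion matrix over the union
    of the two label vocabularies."""
    y_true, y_pred = list(y_true), list(y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    mat = confusion_matrix(y_true, y_pred, classes)
    return kappa_from_confusion(mat)


def kappa_from_confusion(mat: np.ndarray) -> float:
    mat = np.asarray(mat, dtype=np.float64)
    total = mat.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(mat) / total
    p_e = float((mat.sum(axis=1) * mat.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        # degenerate single-class agreement
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def evaluate(pred, truth_labels, known_types) -> OpenSetEval:
    """Full open-set evaluation of a prediction against ground truth.

    ``pred`` is either a PredictionSet (cell ids are checked against
    ``truth_labels`` keys if a mapping is given) or a plain label sequence.
    All novel truth types are pooled into a single "unknown" class for the
    confusion matrix and kappa.
    """
    if hasattr(pred, "labels"):
        y_pred = list(pred.labels)
        cell_ids = list(getattr(pred, "cell_ids", []))
        if isinstance(truth_labels, dict):
            missing = [c for c in cell_ids if c not in truth_labels]
            if missing:
                raise ValueError(f"truth labels missing for cells: {missing[:5]}")
            truth_labels = [truth_labels[c] for c in cell_ids]
    else:
        y_pred = list(pred)
    y_true = [str(t).strip() for t in truth_labels]
    y_pred = [str(p).strip() for p in y_pred]
    known = [str(t).strip() for t in known_types]

    eas, eas_m, counts = effective_assignment(y_true, y_pred, known)
    class_order = list(known) + [UNKNOWN]
    pooled_true = [t if t in set(known) else UNKNOWN for t in y_true]
    mat = confusion_matrix(pooled_true, y_pred, class_order)
    kappa = kappa_from_confusion(mat)
    result = OpenSetEval(
        known_types=known, eas=eas, eas_m=eas_m, kappa=kappa,
        confusion=mat, class_order=class_order, partial=counts["partial"],
        n_k=counts["n_k"], n_u=counts["n_u"], n_k_k=counts["n_k_k"],
        n_u_k=counts["n_u_k"], n_k_true=counts["n_k_true"],
    )
    assert result.eas_m <= result.eas + 1e-12
    return result
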