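"""Two-class Fisher linear discriminant in closed form.

Fisher's criterion seeks the projection direction w maximizing the
between-class distance over the within-class spread,

    J(w) = (w^T (mu0 - mu1))^2 / (w^T S0 w + w^T S1 w),

where mu_j are the class means and S_j the *un-normalized* within-class
scatter matrices (sums of outer products of deviations).  The maximizer has
the closed form

    w* proportional to (S0 + S1)^(-1) (mu0 - mu1),

returned here with unit norm.  No intercept falls out of the criterion; the
decision threshold is the midpoint projection ``w^T (mu0 + mu1) / 2``
(the equal-prior rule, appropriate for balanced designs).  Using covariance
instead of raw scatter would only rescale w, which normalization removes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = ["LDAModel", "lda_fit", "lda_predict", "fisher_ratio", "save_lda_model", "load_lda_model"]


@dataclasses.dataclass
class LDAModel:
    """Fitted Fisher discriminant.

    ``class_labels`` holds the two labels in the order (class 0, class 1)
    used during fitting; predictions are reported in these labels.
    """

    w: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    S0: np.ndarray
    S1: np.ndarray
    threshold: float
    class_labels: tuple = (0, 1)

    def __post_init__(self) -> None:
        if np.allclose(self.w, 0):
            raise ValueError("weight vector must be nonzero")


def _class_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    dev = x - mu
    return mu, dev.T @ dev  # un-normalized scatter


def lda_fit(
    features: np.ndarray,
    labels: np.ndarray,
    ridge: float | None = None,
) -> LDAModel:
    """Fit the closed-form Fisher discriminant.

    Parameters
    ----------
    features : ndarray (n_samples x n_features)
    labels : ndarray
        Exactly two distinct values; the smaller sorts as class 0.
    ridge : float, optional
        Added to the diagonal of ``S0 + S1`` before solving.  ``None``
        (default) uses a tiny trace-scaled value, ``1e-10 * tr(S)/d``, for
        numerical safety; pass 0 for the exact unregularized solve.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("features must be 2-d (samples x features)")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required; got {classes}")
    x0, x1 = x[y == classes[0]], x[y == classes[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each class needs at least 2 samples")

    mu0, s0 = _class_stats(x0)
    mu1, s1 = _class_stats(x1)
    s = s0 + s1
    d = x.shape[1]
    if ridge is None:
        ridge = 1e-10 * np.trace(s) / d
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")

    diff = mu0 - mu1
    if np.allclose(diff, 0):
        raise ValueError("identical class means; Fisher direction undefined")
    try:
        w = np.linalg.solve(s + ridge * np.eye(d), diff)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular within-class scatter; pass ridge > 0 to regularize"
        ) from err
    norm = np.linalg.norm(w)
    if norm == 0 or not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "within-class scatter is singular along the mean difference; "
            "pass ridge > 0 to regularize"
        )
    w = w / norm
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return LDAModel(
        w=w,
        mu0=mu0,
        mu1=mu1,
        S0=s0,
        S1=s1,
        threshold=threshold,
        class_labels=tuple(classes.tolist()),
    )


def lda_predict(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Classify feature vectors by which side of the threshold they project.

    A point projecting exactly onto the threshold is assigned to class 0
    (documented tie rule).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != len(model.w):
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model dimension {len(model.w)}"
        )
    side0 = np.sign(model.w @ model.mu0 - model.threshold)
    if side0 == 0:  # degenerate: means project to the same point
        side0 = 1.0
    score = (x @ model.w - model.threshold) * side0
    labels = np.where(score >= 0, model.class_labels[0], model.class_labels[1])
    return labels


def fisher_ratio(model: LDAModel, w_test: np.ndarray) -> float:
    """Fisher criterion G2/G1 evaluated at an arbitrary direction.

    Scale-invariant in ``w_test``; the fitted ``model.w`` maximizes it.
    """
    w = np.asarray(w_test, dtype=float)
    if w.shape != model.w.shape:
        raise ValueError("w_test dimension does not match model")
    g1 = float(w @ model.S0 @ w + w @ model.S1 @ w)
    if g1 <= 0:
        raise ValueError("within-class spread along w_test is not positive")
    g2 = float(w @ (model.mu0 - model.mu1)) ** 2
    return g2 / g1


def save_lda_model(model: LDAModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "w": model.w.tolist(),
        "mu0": model.mu0.tolist(),
        "mu1": model.mu1.tolist(),
        "S0": model.S0.tolist(),
        "S1": model.S1.tolist(),
        "threshold": model.threshold,
        "class_labels": list(model.class_labels),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_lda_model(path: str | Path) -> LDAModel:
    payload = json.loads(Path(path).read_text())
    return LDAModel(
        w=np.asarray(payload["w"], dtype=float),
        mu0=np.asarray(payload["mu0"], dtype=float),
        mu1=np.asarray(payload["mu1"], dtype=float),
        S0=np.asarray(payload["S0"], dtype=float),
        S1=np.asarray(payload["S1"], dtype=float),
        threshold=float(payload["threshold"]),
        class_labels=tuple(payload["class_labels"]),
    )
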