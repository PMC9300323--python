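"""Two-class Common Spatial Patterns by the whitening path.

CSP finds linear channel combinations (spatial filters) whose output
variance is maximal for one class and minimal for the other.  The procedure
implemented here is the classical whitening construction:

1. per-trial covariance ``R = X X^T / tr(X X^T)`` (trace-normalized, so
   trials contribute equally regardless of overall amplitude);
2. class-average covariances ``R1_bar``, ``R2_bar`` and their sum ``R``;
3. eigendecompose ``R = U diag(lam) U^T`` with ``lam`` descending and form
   the whitening transform ``P = diag(lam)^(-1/2) U^T``;
4. eigendecompose the whitened class-1 covariance ``P R1_bar P^T = B D B^T``;
   the projection matrix is ``W = B^T P`` with rows ordered by descending D.

Because whitening makes ``R1_bar + R2_bar`` the identity, the whitened
class eigenvalues are complementary (``d + (1 - d) = 1``): a filter that
maximizes class-1 variance simultaneously minimizes class-2 variance.
Features are the normalized variances of the top/bottom filtered components
(``f_i = var(Z_i) / sum_j var(Z_j)``).

Spatial *filters* are rows of ``W``; spatial *patterns* (interpretable
topographies, comparable to a forward-model mixing column) are columns of
``W^-1``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .dataset import MIEEGDataset

__all__ = [
    "CSPModel",
    "normalized_covariance",
    "average_covariance",
    "csp_fit",
    "csp_features",
    "save_csp_model",
    "load_csp_model",
]


@dataclasses.dataclass
class CSPModel:
    """Fitted CSP projection.

    Attributes
    ----------
    W : ndarray (channels x channels)
        Full projection matrix; rows are spatial filters ordered by
        descending class-1 whitened eigenvalue.
    P : ndarray
        Whitening matrix of the composite covariance.
    eigvals : ndarray
        Class-1 whitened eigenvalues, descending, each in [0, 1]; the
        class-2 eigenvalue of the same component is ``1 - eigval``.
    R1_bar, R2_bar : ndarray
        Average class covariances (trace 1 each).
    n_pairs : int
        Number of top/bottom filter pairs retained for features.
    log_variance : bool
        If True, features are log of the normalized variance share.
    """

    W: np.ndarray
    P: np.ndarray
    eigvals: np.ndarray
    R1_bar: np.ndarray
    R2_bar: np.ndarray
    n_pairs: int
    log_variance: bool = False

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    @property
    def patterns(self) -> np.ndarray:
        """Spatial patterns: columns of W^-1, aligned with W's rows."""
        return np.linalg.inv(self.W)

    @property
    def selected_rows(self) -> np.ndarray:
        """Row indices of the retained top/bottom filters."""
        n = self.W.shape[0]
        return np.r_[0 : self.n_pairs, n - self.n_pairs : n]


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance ``X X^T / tr(X X^T)`` of one trial.

    Symmetric, positive semi-definite, trace exactly 1.  The trial is not
    mean-centered: the raw outer product is used, as is conventional for
    band-passed (zero-mean) EEG.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError(f"trial must be 2-d (channels x samples); got shape {trial.shape}")
    n, t = trial.shape
    if n >= t:
        raise ValueError(f"need fewer channels than samples; got {n} x {t}")
    if not np.all(np.isfinite(trial)):
        raise ValueError("trial contains non-finite values")
    outer = trial @ trial.T
    tr = np.trace(outer)
    if tr <= 0:
        raise ValueError("trial has zero total energy; covariance undefined")
    cov = outer / tr
    return 0.5 * (cov + cov.T)  # exact symmetry against rounding


def average_covariance(trials: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of per-trial trace-normalized covariances."""
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    covs = [normalized_covariance(t) for t in trials]
    shapes = {c.shape for c in covs}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent channel counts across trials: {sorted(shapes)}")
    return np.mean(covs, axis=0)


def _default_n_pairs(n_channels: int) -> int:
    return 3 if n_channels >= 6 else n_channels // 2


def csp_fit(
    dataset: MIEEGDataset,
    n_pairs: int | None = None,
    shrinkage: float = 0.0,
) -> CSPModel:
    """Fit CSP on a labeled dataset (class 1 vs class 2).

    Parameters
    ----------
    n_pairs : int, optional
        Top/bottom filter pairs kept for features.  Default 3, or
        ``channels // 2`` for montages with fewer than 6 channels.
    shrinkage : float in [0, 1]
        Convex shrinkage of each class covariance toward a trace-matched
        identity; 0 by default.  Needed when the composite covariance is
        rank deficient (e.g. fewer trials*samples than channels, or
        linearly dependent channels).
    """
    dataset.require_two_classes()
    n_ch = dataset.n_channels
    if n_pairs is None:
        n_pairs = _default_n_pairs(n_ch)
    if not 1 <= 2 * n_pairs <= n_ch:
        raise ValueError(f"need 1 <= 2*n_pairs <= {n_ch}; got n_pairs={n_pairs}")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")

    R1 = average_covariance(dataset.class_trials(1))
    R2 = average_covariance(dataset.class_trials(2))
    if shrinkage > 0:
        eye = np.eye(n_ch)
        R1 = (1 - shrinkage) * R1 + shrinkage * (np.trace(R1) / n_ch) * eye
        R2 = (1 - shrinkage) * R2 + shrinkage * (np.trace(R2) / n_ch) * eye

    R = R1 + R2
    lam, U = np.linalg.eigh(R)
    lam, U = lam[::-1], U[:, ::-1]  # descending
    tol = lam[0] * n_ch * np.finfo(float).eps * 10
    if lam[-1] <= tol:
        raise np.linalg.LinAlgError(
            "composite covariance is rank deficient; pass shrinkage > 0 "
            "(e.g. shrinkage=1e-6) to regularize"
        )
    P = (U / np.sqrt(lam)).T  # diag(lam^-1/2) U^T

    S1 = P @ R1 @ P.T
    S1 = 0.5 * (S1 + S1.T)
    D, B = np.linalg.eigh(S1)
    D, B = D[::-1], B[:, ::-1]
    W = B.T @ P

    # sign convention: largest-magnitude entry of each filter positive
    signs = np.sign(W[np.arange(n_ch), np.abs(W).argmax(axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]

    return CSPModel(
        W=W,
        P=P,
        eigvals=np.clip(D, 0.0, 1.0),
        R1_bar=R1,
        R2_bar=R2,
        n_pairs=n_pairs,
    )


def csp_features(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Normalized-variance feature vector of length ``2 * n_pairs``.

    ``Z = W_sel X`` with the top/bottom ``n_pairs`` filters;
    ``f_i = var(Z_i) / sum_j var(Z_j)`` over the selected components, so the
    features are nonnegative and sum to one, and are invariant to positive
    rescaling of the trial.  With ``log_variance`` set on the model the log
    of each share is returned instead (a common variance-stabilizing
    variant; off by default).
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] != model.n_channels:
        raise ValueError(
            f"trial shape {trial.shape} incompatible with model ({model.n_channels} channels)"
        )
    z = model.W[model.selected_rows] @ trial
    variances = z.var(axis=1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("zero total variance after projection; cannot normalize features")
    f = variances / total
    return np.log(f) if model.log_variance else f


# ---------------------------------------------------------------------------
# serialization: JSON manifest + matrix CSVs
# ---------------------------------------------------------------------------

def save_csp_model(model: CSPModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("W", "P", "R1_bar", "R2_bar"):
        np.savetxt(out / f"{name}.csv", getattr(model, name), delimiter=",")
    manifest = {
        "eigvals": model.eigvals.tolist(),
        "n_pairs": model.n_pairs,
        "log_variance": model.log_variance,
    }
    (out / "csp_model.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_csp_model(in_dir: str | Path) -> CSPModel:
    src = Path(in_dir)
    manifest = json.loads((src / "csp_model.json").read_text())
    mats = {
        name: np.atleast_2d(np.loadtxt(src / f"{name}.csv", delimiter=","))
        for name in ("W", "P", "R1_bar", "R2_bar")
    }
    return CSPModel(
        W=mats["W"],
        P=mats["P"],
        eigvals=np.asarray(manifest["eigvals"], dtype=float),
        R1_bar=mats["R1_bar"],
        R2_bar=mats["R2_bar"],
        n_pairs=int(manifest["n_pairs"]),
        log_variance=bool(manifest["log_variance"]),
    )
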