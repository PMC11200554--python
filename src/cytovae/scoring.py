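"""Normal-class latent Gaussian and abnormality scoring.

After one-class training, the latent means of held-out normal crops are
summarized by a full multivariate normal N(mu_hat, V_hat). A sample's
abnormality score is its negative log-likelihood under that density,

    s(z) = 0.5 * [ (z - mu_hat)^T V_hat^{-1} (z - mu_hat) + log det(2 pi V_hat) ],

in nats: the Mahalanobis departure from normality plus the normalization.
AUROC treats abnormal as the positive class; thresholded metrics use a
configurable rule (Youden's J on a validation split, or a quantile of the
normal-class scores, the natural one-class rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn import metrics as _skm

from .synthetic import LatentPosterior

__all__ = [
    "GaussianDensity",
    "ScoreReport",
    "fit_gaussian",
    "abnormality_score",
    "roc_auc",
    "classwise_metrics",
    "crossval_occ",
]


@dataclass(frozen=True)
class GaussianDensity:
    """A full multivariate normal used as a fitted density or CRSD argument."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64)
        cov = np.asarray(self.covariance, dtype=np.float64)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        d = mean.shape[0]
        if mean.ndim != 1 or cov.shape != (d, d):
            raise ValueError("mean must be (d,), covariance (d, d)")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @classmethod
    def from_posterior(cls, p: LatentPosterior) -> "GaussianDensity":
        return cls(mean=p.mean, covariance=np.diag(p.stddev**2))


def fit_gaussian(latent_means: np.ndarray, ridge: float | None = None) -> GaussianDensity:
    """Sample mean and unbiased (n-1) covariance plus a ridge on the diagonal.

    ridge=None uses the default 1e-6 * trace(S)/d; ridge=0 disables it and
    raises if the covariance is singular. With fewer than d+1 samples the
    estimate falls back to the diagonal of S (plus ridge), since the full
    matrix would be rank-deficient.
    """
    x = np.asarray(latent_means, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("latent_means must be (n, d)")
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1).reshape(d, d)
    if n < d + 1:
        cov = np.diag(np.diag(cov))
    if ridge is None:
        ridge = 1e-6 * np.trace(cov) / d
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    cov = cov + ridge * np.eye(d)
    try:
        linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            "covariance is singular; pass a positive ridge to regularize"
        ) from err
    return GaussianDensity(mean=mean, covariance=cov)


def abnormality_score(z: np.ndarray, density: GaussianDensity) -> float | np.ndarray:
    """Negative log-likelihood of z under the fitted normal-class Gaussian.

    Accepts a single vector (d,) or a batch (n, d); returns nats.
    """
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    zz = np.atleast_2d(z)
    if zz.shape[1] != density.dim:
        raise ValueError(f"latent dim {zz.shape[1]} != density dim {density.dim}")
    chol = linalg.cholesky(density.covariance, lower=True)
    diff = zz - density.mean
    sol = linalg.solve_triangular(chol, diff.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    s = 0.5 * (maha + logdet + density.dim * np.log(2.0 * np.pi))
    return float(s[0]) if single else s


def roc_auc(scores_normal, scores_abnormal) -> float:
    """AUROC with abnormal as the positive class; ties by midrank."""
    sn = np.asarray(scores_normal, dtype=np.float64)
    sa = np.asarray(scores_abnormal, dtype=np.float64)
    if sn.size == 0 or sa.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.zeros(sn.size), np.ones(sa.size)])
    return float(_skm.roc_auc_score(y, np.concatenate([sn, sa])))


@dataclass
class ScoreReport:
    """Per-sample scores plus thresholded and threshold-free metrics."""

    scores: np.ndarray
    labels: np.ndarray  # 0 = normal, 1 = abnormal
    threshold: float
    accuracy: float
    auroc: float
    f1: float
    sensitivity: float
    specificity: float

    def metric_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def classwise_metrics(
    scores,
    labels,
    threshold_rule: str | float = "youden",
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    normal_quantile: float = 0.95,
) -> ScoreReport:
    """Binary metrics at a threshold; abnormal (label 1) is positive.

    threshold_rule:
      * a float — used directly;
      * "youden" — maximize sensitivity + specificity - 1 on `validation`
        (scores, labels) if given, else on the scored data itself (flagged
        for quick looks only; prefer an independent validation split);
      * "normal-quantile" — the `normal_quantile` quantile of the normal
        scores in `validation` (or the scored data), a one-class rule that
        needs no abnormal examples.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0 (normal) / 1 (abnormal)")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes for threshold-dependent metrics")

    if isinstance(threshold_rule, (int, float)) and not isinstance(threshold_rule, bool):
        thr = float(threshold_rule)
    else:
        vs, vl = validation if validation is not None else (scores, labels)
        vs, vl = np.asarray(vs, float), np.asarray(vl)
        if threshold_rule == "youden":
            thr = _youden_threshold(vs, vl)
        elif threshold_rule == "normal-quantile":
            thr = float(np.quantile(vs[vl == 0], normal_quantile))
        else:
            raise ValueError(f"unknown threshold rule: {threshold_rule!r}")

    pred = (scores >= thr).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / labels.size
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    auroc = float(_skm.roc_auc_score(labels, scores))
    return ScoreReport(
        scores=scores, labels=labels, threshold=thr,
        accuracy=acc, auroc=auroc, f1=f1, sensitivity=sens, specificity=spec,
    )


def crossval_occ(
    normal_latents: np.ndarray,
    abnormal_latents: np.ndarray,
    k: int = 5,
    seed: int = 0,
    ridge: float | None = None,
    threshold_rule: str | float = "youden",
) -> dict:
    """k-fold one-class evaluation at the latent level.

    Normal latents are split into k folds: each round fits the normal-class
    Gaussian on the other k-1 folds (held out from scoring, mirroring the
    protocol of estimating the density on normals unseen in training) and
    scores the remaining normal fold against one of k abnormal folds. Half
    of each evaluation fold serves as the validation split for the threshold
    rule; metrics are computed on the other half, AUROC on the full fold.

    Returns {"folds": [ScoreReport...], "mean": {...}, "std": {...}}.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    xn = np.asarray(normal_latents, dtype=np.float64)
    xa = np.asarray(abnormal_latents, dtype=np.float64)
    if len(xn) < 2 * k or len(xa) < k:
        raise ValueError("not enough samples for the requested number of folds")
    rng = np.random.default_rng(seed)
    folds_n = np.array_split(rng.permutation(len(xn)), k)
    folds_a = np.array_split(rng.permutation(len(xa)), k)

    reports: list[ScoreReport] = []
    for i in range(k):
        fit_idx = np.concatenate([folds_n[j] for j in range(k) if j != i])
        density = fit_gaussian(xn[fit_idx], ridge=ridge)
        s_n = np.atleast_1d(abnormality_score(xn[folds_n[i]], density))
        s_a = np.atleast_1d(abnormality_score(xa[folds_a[i]], density))
        scores = np.concatenate([s_n, s_a])
        labels = np.concatenate([np.zeros(len(s_n), int), np.ones(len(s_a), int)])
        # split the fold into validation (threshold) and test halves
        val_mask = np.zeros(len(scores), dtype=bool)
        val_mask[rng.permutation(len(scores))[: len(scores) // 2]] = True
        if len(np.unique(labels[val_mask])) < 2 or len(np.unique(labels[~val_mask])) < 2:
            val_mask = np.arange(len(scores)) % 2 == 0  # deterministic fallback
        rep = classwise_metrics(
            scores[~val_mask], labels[~val_mask],
            threshold_rule=threshold_rule,
            validation=(scores[val_mask], labels[val_mask]),
        )
        # report AUROC on the full fold (threshold-free)
        rep.auroc = roc_auc(s_n, s_a)
        rep.scores, rep.labels = scores, labels
        reports.append(rep)

    keys = reports[0].metric_dict().keys()
    mean = {k_: float(np.mean([r.metric_dict()[k_] for r in reports])) for k_ in keys}
    std = {k_: float(np.std([r.metric_dict()[k_] for r in reports])) for k_ in keys}
    return {"folds": reports, "mean": mean, "std": std}
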