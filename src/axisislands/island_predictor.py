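"""Logistic prediction of island/desert identity from coding density.

Each 5-kb genome bin carries a coding density x in [0, 1] and a label
y in {island = 1, desert = 0} taken from a region partition. A
single-feature logistic regression P(island | x) = 1/(1 + exp(-(b0 +
b1 x))) is fit by maximum likelihood on a random 80% training split and
evaluated on the held-out 20% (accuracy at a 0.5 probability cutoff,
ROC curve, AUC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve

from .genome_model import GenomicInterval
from .island_calling import ISLAND, RegionPartition, assign_regions


@dataclass
class LabeledBins:
    """Per-bin coding density and island/desert label."""

    df: pd.DataFrame  # columns: chrom, start, end, coding_density, label

    REQUIRED = ("chrom", "start", "end", "coding_density", "label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"LabeledBins missing columns {missing}")
        x = self.df["coding_density"].to_numpy()
        if np.any((x < 0) | (x > 1)):
            raise ValueError("coding density outside [0, 1]")
        y = self.df["label"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be 0 (desert) or 1 (island)")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["coding_density"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    def exclude_chroms(self, chroms) -> "LabeledBins":
        return LabeledBins(self.df[~self.df["chrom"].isin(set(chroms))].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabeledBins":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class LogisticModel:
    intercept: float
    slope: float
    converged: bool
    n_iter: int
    se_slope: float
    wald_p: float

    def predict_proba(self, x) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return expit(z)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                    "se_slope": self.se_slope,
                    "wald_p": self.wald_p,
                },
                fh,
                indent=2,
            )


@dataclass
class EvalReport:
    accuracy: float
    roc: np.ndarray | None  # (n_points, 2) columns fpr, tpr
    auc: float | None
    prob_threshold: float
    n_test: int
    note: str = ""


def label_bins(
    partition: RegionPartition,
    bins: list[GenomicInterval],
    density: np.ndarray,
) -> LabeledBins:
    """Attach island/desert labels (bin-midpoint rule) to per-bin densities."""
    density = np.asarray(density, dtype=float)
    if len(bins) != len(density):
        raise ValueError(
            f"bin/density count mismatch ({len(bins)} vs {len(density)})"
        )
    labels = assign_regions(bins, partition)
    return LabeledBins(
        pd.DataFrame(
            {
                "chrom": [b.chrom for b in bins],
                "start": [b.start for b in bins],
                "end": [b.end for b in bins],
                "coding_density": density,
                "label": [1 if l == ISLAND else 0 for l in labels],
            }
        )
    )


def split_bins(
    data: LabeledBins,
    train_fraction: float = 0.8,
    seed: int | None = None,
    stratified: bool = True,
) -> tuple[LabeledBins, LabeledBins]:
    """Disjoint, exhaustive train/test split; stratified by label by default."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(data) < 5:
        raise ValueError("need at least 5 records to split")
    rng = np.random.default_rng(seed)
    y = data.y
    train_idx: list[np.ndarray] = []
    if stratified:
        if len(np.unique(y)) < 2:
            raise ValueError("stratified split requires both classes present")
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_train = int(round(train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else n_train
            train_idx.append(idx[:n_train])
    else:
        idx = rng.permutation(len(data))
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
    train_mask = np.zeros(len(data), dtype=bool)
    train_mask[np.concatenate(train_idx)] = True
    return (
        LabeledBins(data.df[train_mask].reset_index(drop=True)),
        LabeledBins(data.df[~train_mask].reset_index(drop=True)),
    )


def _loglik(x: np.ndarray, y: np.ndarray, b0: float, b1: float) -> float:
    z = b0 + b1 * x
    # log(1 + e^z) computed stably
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def fit_logistic(
    train: LabeledBins,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence is declared when the log-likelihood change drops below
    ``tol``. Under perfect separation the likelihood has no maximum; the
    fit then stops at ``max_iter`` with ``converged=False`` and a
    warning (coefficients are at whatever magnitude the iteration
    reached — effectively capped). An optional ridge penalty (``ridge``
    > 0) regularizes; it is off by default.
    """
    x, y = train.x, train.y.astype(float)
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data must contain both classes")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _loglik(x, y, *beta)
    converged = False
    n_iter = 0
    pen = ridge * np.eye(2)
    for n_iter in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1 - p)
        H = (X.T * W) @ X + pen
        g = X.T @ (y - p) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        new_ll = _loglik(x, y, *beta) - 0.5 * ridge * float(beta @ beta)
        if abs(new_ll - ll) < tol:
            converged = True
            ll = new_ll
            break
        ll = new_ll
    # a saturated likelihood (every probability within ~1e-8 of its label)
    # means the data are perfectly separated and the MLE does not exist
    if converged and ridge == 0 and _loglik(x, y, *beta) > -1e-6:
        converged = False
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible perfect separation); "
            "coefficients capped at the last iterate",
            stacklevel=2,
        )
    p = expit(X @ beta)
    W = p * (1 - p)
    H = (X.T * W) @ X + pen
    try:
        cov = np.linalg.inv(H)
        se1 = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se1 = float("inf")
    wald_p = float(2 * stats.norm.sf(abs(beta[1]) / se1)) if se1 > 0 else 0.0
    return LogisticModel(float(beta[0]), float(beta[1]), converged, n_iter, se1, wald_p)


def evaluate(
    model: LogisticModel, test: LabeledBins, prob_threshold: float = 0.5
) -> EvalReport:
    """Held-out accuracy, ROC and AUC.

    Predicted class is 1 iff predicted probability >= threshold. The ROC
    sweeps the threshold over all distinct scores; AUC is the
    trapezoidal area, which equals the pair-concordance (ties counting
    one half). With a single class in the test set, accuracy is still
    defined but the ROC/AUC are flagged undefined.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(test.x)
    y = test.y
    preds = (probs >= prob_threshold).astype(int)
    accuracy = float((preds == y).mean())
    if len(np.unique(y)) < 2:
        return EvalReport(
            accuracy, None, None, prob_threshold, len(test), "single-class test set: AUC undefined"
        )
    fpr, tpr, _ = roc_curve(y, probs, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(accuracy, np.column_stack([fpr, tpr]), auc, prob_threshold, len(test))


def train_and_evaluate(
    data: LabeledBins,
    train_fraction: float = 0.8,
    seed: int | None = None,
    stratified: bool = True,
    prob_threshold: float = 0.5,
    exclude_chroms=(),
) -> tuple[LogisticModel, EvalReport]:
    """The full predictor pipeline: split, fit, evaluate."""
    if exclude_chroms:
        data = data.exclude_chroms(exclude_chroms)
    train, test = split_bins(data, train_fraction, seed, stratified)
    model = fit_logistic(train)
    return model, evaluate(model, test, prob_threshold)
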