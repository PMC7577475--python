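"""Logistic-regression head combining the DCA score and the filter score.

The classifier is P(contact | x) = sigma(w0 + w1*x1 + w2*x2'), with x2'
the filter score rescaled by the training-set extremes,

    x2' = (x2 - min_train) / (max_train - min_train),

fitted with L2-regularized logistic regression (liblinear).  Training is
restricted to pairs with DCA score x1 > 0; prediction ranks all pairs.
Models are trained per effective-sequence-number bin and refuse to score a
family from a different bin unless forced.

Regularization convention: ``l2_strength`` is the penalty weight (larger =
stronger penalty); it maps to sklearn's C as C = 1 / l2_strength.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "LogisticModel",
    "SplitPlan",
    "scale_x2",
    "fit",
    "predict_proba",
    "predict_table",
    "decision_boundary",
    "split_families",
]


@dataclass
class LogisticModel:
    w0: float
    w1: float
    w2: float
    x2_min: float
    x2_max: float
    l2_strength: float = 1.0
    k: int | None = None
    meff_bin: str | None = None
    seed: int | None = None
    fitted: bool = True

    def __post_init__(self) -> None:
        if self.x2_min >= self.x2_max:
            raise ValueError("scaling bounds must satisfy min < max")

    def to_json(self, path) -> None:
        payload = {
            "w0": self.w0, "w1": self.w1, "w2": self.w2,
            "x2_min": self.x2_min, "x2_max": self.x2_max,
            "l2_strength": self.l2_strength,
            "k": self.k, "meff_bin": self.meff_bin, "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SplitPlan:
    """Family-level train/test assignment."""

    train: list
    test: list
    fraction: float
    seed: int

    def side(self, family) -> str:
        if family in self._train_set:
            return "train"
        if family in self._test_set:
            return "test"
        raise KeyError(f"family {family!r} not in split plan")

    def __post_init__(self) -> None:
        self._train_set = set(self.train)
        self._test_set = set(self.test)
        if self._train_set & self._test_set:
            raise ValueError("train and test sides overlap")


def scale_x2(x2, bounds: tuple) -> np.ndarray | float:
    """Affine rescaling by training extremes; no clamping outside [0, 1]."""
    lo, hi = bounds
    if lo >= hi:
        raise ValueError(f"invalid scaling bounds: min={lo} >= max={hi}")
    return (np.asarray(x2, dtype=float) - lo) / (hi - lo) if np.ndim(x2) else (float(x2) - lo) / (hi - lo)


def fit(
    features: pd.DataFrame,
    l2_strength: float = 1.0,
    seed: int = 0,
    k: int | None = None,
    meff_bin: str | None = None,
) -> LogisticModel:
    """Fit the logistic head on labeled training features.

    The training set is restricted to rows with x1 > 0 before computing the
    x2 scaling bounds and fitting.  Raises if only one class survives the
    restriction.
    """
    if l2_strength <= 0:
        raise ValueError("l2_strength must be positive")
    labeled = features[features["label"].isin((0, 1))]
    train = labeled[labeled["x1"] > 0]
    if train.empty or train["label"].nunique() < 2:
        raise ValueError("training set has fewer than 2 classes after the x1 > 0 restriction")
    x2_min = float(train["x2"].min())
    x2_max = float(train["x2"].max())
    if x2_min >= x2_max:
        raise ValueError("degenerate filter-score range in training set")
    x = np.column_stack(
        [train["x1"].to_numpy(float), scale_x2(train["x2"].to_numpy(float), (x2_min, x2_max))]
    )
    y = train["label"].to_numpy(int)
    lr = LogisticRegression(
        C=1.0 / l2_strength,
        solver="liblinear",
        random_state=seed,
        tol=1e-8,
        max_iter=1000,
    )
    lr.fit(x, y)
    return LogisticModel(
        w0=float(lr.intercept_[0]),
        w1=float(lr.coef_[0, 0]),
        w2=float(lr.coef_[0, 1]),
        x2_min=x2_min,
        x2_max=x2_max,
        l2_strength=l2_strength,
        k=k,
        meff_bin=meff_bin,
        seed=seed,
    )


def predict_proba(model: LogisticModel, x1, x2_raw) -> np.ndarray | float:
    """Contact probability P(+|x) for raw features (x2 is rescaled first)."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    z = model.w0 + model.w1 * np.asarray(x1, dtype=float) + model.w2 * np.asarray(
        scale_x2(x2_raw, (model.x2_min, model.x2_max))
    )
    p = expit(z)
    return p if np.ndim(p) else float(p)


def predict_table(
    model: LogisticModel,
    features: pd.DataFrame,
    family_bin: str | None = None,
    force: bool = False,
) -> pd.DataFrame:
    """Score a family's feature table; adds ``p`` and a deterministic ``rank``.

    Ties are broken by (-p, i, j).  Refuses to score a family whose M_eff bin
    differs from the model's training bin unless ``force`` is set.
    """
    if model.meff_bin is not None and family_bin is not None and family_bin != model.meff_bin:
        if not force:
            raise ValueError(
                f"model trained for bin {model.meff_bin!r} cannot score a "
                f"{family_bin!r} family (pass force=True to override)"
            )
        warnings.warn(
            f"scoring a {family_bin!r} family with a {model.meff_bin!r}-bin model",
            stacklevel=2,
        )
    out = features.copy()
    out["p"] = predict_proba(model, out["x1"].to_numpy(float), out["x2"].to_numpy(float))
    out = out.sort_values(["p", "i", "j"], ascending=[False, True, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def decision_boundary(model: LogisticModel):
    """The P = 1/2 locus as x1 = slope * x2_raw + intercept.

    Returns ``("line", slope, intercept)`` in the (x2_raw, x1) plane, or
    ``("vertical", x2_raw)`` when w1 = 0 (and w2 != 0).
    """
    span = model.x2_max - model.x2_min
    if model.w1 == 0:
        if model.w2 == 0:
            raise ValueError("degenerate model: w1 = w2 = 0 has no boundary")
        scaled = -model.w0 / model.w2
        return ("vertical", scaled * span + model.x2_min)
    slope = -(model.w2 / model.w1) / span
    intercept = -(model.w0 + model.w2 * (-model.x2_min / span)) / model.w1
    return ("line", slope, intercept)


def split_families(families, fraction: float = 0.5, seed: int = 0) -> SplitPlan:
    """Random family-level split; every family lands on exactly one side."""
    families = list(dict.fromkeys(families))  # dedupe, keep order
    if len(families) < 2:
        raise ValueError(f"need at least 2 families to split, got {len(families)}")
    if not (0 < fraction < 1):
        raise ValueError("split fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(families))
    n_train = int(round(fraction * len(families)))
    n_train = min(max(n_train, 1), len(families) - 1)
    train = sorted(families[i] for i in order[:n_train])
    test = sorted(families[i] for i in order[n_train:])
    return SplitPlan(train=train, test=test, fraction=fraction, seed=seed)
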