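"""From-scratch k-nearest-neighbor detector.

k-NN is a lazy learner: "fitting" stores the min-max normalization bounds
learned from the training table and the normalized reference points, nothing
else.  Prediction computes the Euclidean distance from a query to every
reference point (brute force -- the reference path any accelerated search
must agree with exactly), lets the k closest vote, and reports the fraction
of Y votes as a score in [0, 1]; with k odd the majority label is Y exactly
when the score exceeds 1/2.  Distance ties at the k-th neighbor are broken
by reference-row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .features import TARGET_COLUMN
from .metrics import ConfusionMatrix


class Prediction(NamedTuple):
    label: str  # "Y" / "N"
    score: float  # fraction of the k neighbors labeled Y


@dataclass
class KnnModel:
    """Stored state of a fitted k-NN detector."""

    k: int
    feature_names: list[str]
    lo: np.ndarray  # per-feature training minima
    hi: np.ndarray  # per-feature training maxima
    reference: np.ndarray  # normalized training points, row order preserved
    reference_labels: np.ndarray  # bool, True = Y
    ir_tag: float | None = None  # imbalance ratio of the training set

    # ------------------------------------------------------------------ fit

    @classmethod
    def fit(cls, train: pd.DataFrame, k: int, ir_tag: float | None = None) -> "KnnModel":
        """Store normalization bounds and the normalized reference set.

        ``k`` must be odd (so majority votes are never tied) and at most the
        training-set size; both classes must be present.
        """
        if train.empty:
            raise ValueError("training table is empty")
        if k < 1 or k % 2 == 0:
            raise ValueError(f"k must be an odd positive integer, got {k}")
        if k > len(train):
            raise ValueError(f"k={k} exceeds training-set size {len(train)}")
        if TARGET_COLUMN not in train.columns:
            raise ValueError(f"training table lacks {TARGET_COLUMN!r}")
        labels = (train[TARGET_COLUMN].to_numpy() == "Y")
        if labels.all() or not labels.any():
            raise ValueError("training set must contain both classes")
        feats = train.drop(columns=[TARGET_COLUMN])
        x = feats.to_numpy(dtype=float)
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        return cls(
            k=int(k),
            feature_names=list(feats.columns),
            lo=lo,
            hi=hi,
            reference=cls._normalize_raw(x, lo, hi),
            reference_labels=labels,
            ir_tag=ir_tag,
        )

    # ------------------------------------------------------------- predict

    @staticmethod
    def _normalize_raw(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        out = (x - lo) / safe
        out[:, span == 0] = 0.0
        return np.clip(out, 0.0, 1.0)

    def _query_matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise KeyError(f"query table lacks feature columns: {missing[:5]}")
        x = table[self.feature_names].to_numpy(dtype=float)
        return self._normalize_raw(x, self.lo, self.hi)

    def _scores(self, queries: np.ndarray, chunk: int = 256) -> np.ndarray:
        scores = np.empty(queries.shape[0])
        for start in range(0, queries.shape[0], chunk):
            q = queries[start : start + chunk]
            d2 = ((q[:, None, :] - self.reference[None, :, :]) ** 2).sum(axis=2)
            order = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
            scores[start : start + chunk] = self.reference_labels[order].mean(axis=1)
        return scores

    def predict(self, row: pd.Series | pd.DataFrame) -> Prediction:
        """Classify a single feature row by majority vote of the k closest."""
        frame = row.to_frame().T if isinstance(row, pd.Series) else row
        score = float(self._scores(self._query_matrix(frame))[0])
        return Prediction(label="Y" if score > 0.5 else "N", score=score)

    def predict_batch(
        self, table: pd.DataFrame
    ) -> tuple[pd.DataFrame, ConfusionMatrix | None]:
        """Row-wise prediction; confusion matrix if the table is labeled."""
        if table.empty:
            empty = pd.DataFrame(columns=["label", "score"], index=table.index)
            return empty, None
        scores = self._scores(self._query_matrix(table))
        labels = np.where(scores > 0.5, "Y", "N")
        preds = pd.DataFrame({"label": labels, "score": scores}, index=table.index)
        cm = None
        if TARGET_COLUMN in table.columns:
            actual = table[TARGET_COLUMN].to_numpy() == "Y"
            predicted = scores > 0.5
            cm = ConfusionMatrix(
                tp=int((predicted & actual).sum()),
                tn=int((~predicted & ~actual).sum()),
                fp=int((predicted & ~actual).sum()),
                fn=int((~predicted & actual).sum()),
            )
        return preds, cm

    # --------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ref = pd.DataFrame(self.reference, columns=self.feature_names)
        ref[TARGET_COLUMN] = np.where(self.reference_labels, "Y", "N")
        ref.to_csv(directory / "reference.csv", index=False)
        meta = {
            "k": self.k,
            "ir_tag": self.ir_tag,
            "feature_names": self.feature_names,
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "KnnModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        ref = pd.read_csv(directory / "reference.csv")
        labels = ref[TARGET_COLUMN].to_numpy() == "Y"
        return cls(
            k=meta["k"],
            feature_names=meta["feature_names"],
            lo=np.asarray(meta["lo"], dtype=float),
            hi=np.asarray(meta["hi"], dtype=float),
            reference=ref[meta["feature_names"]].to_numpy(dtype=float),
            reference_labels=labels,
            ir_tag=meta["ir_tag"],
        )
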