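"""Optimized Matthews Undersampling (OMU).

Seizure feature tables are extremely imbalanced (hundreds of ictal windows
against ~10^5 interictal ones).  OMU tames this by random undersampling
under an imbalance-ratio (IR) constraint, repeated n times per IR: each
resample keeps every minority (Y) row and draws ``round(minority * IR)``
majority rows uniformly without replacement; the resample whose 1-NN
achieves the highest stratified-CV Matthews correlation is selected.
Repeating the draw and keeping the Matthews-best set limits the information
lost from the majority class compared with a single blind undersample.

Seeding uses a ladder: the master seed spawns one independent stream per
(IR, resample), keyed by the IR value itself, so extending the IR list
never perturbs the draws of existing IRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import stratified_kfold_cv
from .features import TARGET_COLUMN
from .metrics import mcc_score

DEFAULT_IR_VALUES = (1.0, 2.0, 5.0, 10.0, 20.0, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class OmuConfig:
    ir_values: tuple[float, ...] = DEFAULT_IR_VALUES
    n_resamples: int = 10
    cv_folds: int = 10
    include_original: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(ir < 1 for ir in self.ir_values):
            raise ValueError("imbalance ratios must be >= 1")
        if self.n_resamples < 1:
            raise ValueError("need at least one resample")


def _split_classes(table: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    labels = table[TARGET_COLUMN].to_numpy()
    y_mask = labels == "Y"
    n_y, n_n = int(y_mask.sum()), int((~y_mask).sum())
    if n_y == 0 or n_n == 0:
        raise ValueError("table must contain both classes")
    minority_is_y = n_y <= n_n
    minority = table.index[y_mask if minority_is_y else ~y_mask]
    majority = table.index[~y_mask if minority_is_y else y_mask]
    return minority, majority


def undersample(table: pd.DataFrame, ir: float, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """IR-constrained random undersample of the majority class.

    Keeps every minority row and exactly ``round(n_minority * ir)`` majority
    rows drawn uniformly without replacement; original row order (and row
    identifiers) are preserved.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    minority, majority = _split_classes(table)
    n_keep = int(round(len(minority) * ir))
    if n_keep > len(majority):
        raise ValueError(
            f"IR={ir} needs {n_keep} majority rows but only {len(majority)} available"
        )
    chosen = rng.choice(len(majority), size=n_keep, replace=False)
    keep = set(minority) | set(majority[np.sort(chosen)])
    return table.loc[[i for i in table.index if i in keep]]


@dataclass
class OmuResult:
    """Per-IR resample scores and the selected training sets."""

    mccs: dict[float, list[float]]  # per IR, the per-resample CV MCCs
    best_index: dict[float, int]  # argmax resample per IR (ties -> lowest)
    selected: dict[float, pd.DataFrame]  # per IR, the chosen training set
    original: pd.DataFrame | None = None
    original_ir: float | None = None
    original_mcc: float | None = None
    config: OmuConfig = field(default_factory=OmuConfig)

    def train_sets(self) -> dict[float, pd.DataFrame]:
        """Selected sets keyed by IR, plus the untouched original set."""
        out = dict(self.selected)
        if self.original is not None:
            out[self.original_ir] = self.original
        return out

    def selected_row_ids(self, ir: float) -> list:
        return list(self.selected[ir].index)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"ir": ir, "best_index": self.best_index[ir], "best_mcc": max(m), "mccs": m}
            for ir, m in self.mccs.items()
        ]
        if self.original_mcc is not None:
            rows.append(
                {"ir": self.original_ir, "best_index": -1, "best_mcc": self.original_mcc,
                 "mccs": [self.original_mcc]}
            )
        return pd.DataFrame(rows)


def _stream_seed(master: int, ir: float, resample: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master), int(round(ir * 1000)), int(resample)))


def omu_select(table: pd.DataFrame, config: OmuConfig = OmuConfig()) -> OmuResult:
    """Run OMU: per IR, score ``n_resamples`` undersamples by 1-NN CV MCC.

    The selected set per IR is the argmax resample (ties to the lowest
    index).  When ``include_original`` is set, the untouched input table and
    its own 1-NN CV MCC are reported under the table's native IR.
    """
    minority, majority = _split_classes(table)
    mccs: dict[float, list[float]] = {}
    best_index: dict[float, int] = {}
    selected: dict[float, pd.DataFrame] = {}
    for ir in config.ir_values:
        scores = []
        candidates = []
        for j in range(config.n_resamples):
            ss = _stream_seed(config.seed, ir, j)
            sub = undersample(table, ir, np.random.default_rng(ss))
            cv_seed = int(ss.generate_state(1)[0] % (2**31))
            cm, _ = stratified_kfold_cv(sub, k=1, n_folds=config.cv_folds, seed=cv_seed)
            scores.append(mcc_score(cm))
            candidates.append(sub)
        mccs[ir] = scores
        best = int(np.argmax(scores))
        best_index[ir] = best
        selected[ir] = candidates[best]

    original = original_ir = original_mcc = None
    if config.include_original:
        original = table
        original_ir = round(len(majority) / len(minority), 1)
        cm, _ = stratified_kfold_cv(
            table, k=1, n_folds=config.cv_folds,
            seed=int(_stream_seed(config.seed, 0, 0).generate_state(1)[0] % (2**31)),
        )
        original_mcc = mcc_score(cm)
    return OmuResult(
        mccs=mccs,
        best_index=best_index,
        selected=selected,
        original=original,
        original_ir=original_ir,
        original_mcc=original_mcc,
        config=config,
    )
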