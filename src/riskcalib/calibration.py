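"""Goodness-of-fit by decile of predicted cost.

Patients are ranked on model-predicted cost and split into ten near-equal
groups; within each decile the mean predicted ("expected") cost is compared
with the mean observed cost. The gap is expected minus actual, so negative
values mean the model underestimates. Subgroup tables restrict to the
subgroup FIRST and re-decile within it, which is what gives subgroup tables
their own expected-cost ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .hcc_engine import HCCProfile
from .psycms_grouper import PsyCMSProfile

N_DECILES = 10


class CohortMismatchError(ValueError):
    """Prediction sets do not refer to the same cohort."""


@dataclass(frozen=True)
class SubgroupDef:
    """A deterministic predicate over (HCC profile, psychiatric profile)."""

    name: str
    predicate: Callable[[HCCProfile, PsyCMSProfile], bool]

    def mask(
        self, hcc_profiles: Sequence[HCCProfile], psycms_profiles: Sequence[PsyCMSProfile]
    ) -> np.ndarray:
        return np.array(
            [self.predicate(h, p) for h, p in zip(hcc_profiles, psycms_profiles)], dtype=bool
        )


@dataclass
class CalibrationTable:
    """Per-decile expected mean, actual mean, dollar gap, integer percent gap.

    Gap = expected - actual (positive = overestimate); percent gap uses the
    expected mean as denominator and rounds to the nearest integer, half away
    from zero. Means and gaps are kept unrounded; rounding is a display rule.
    """

    label: str
    n: int
    decile_n: np.ndarray
    expected_mean: np.ndarray
    actual_mean: np.ndarray

    @property
    def gap(self) -> np.ndarray:
        return self.expected_mean - self.actual_mean

    @property
    def percent_gap(self) -> np.ndarray:
        return np.array(
            [round_half_away(100.0 * g / e) for g, e in zip(self.gap, self.expected_mean)],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "decile": np.arange(1, N_DECILES + 1),
                "n": self.decile_n,
                "expected_mean": self.expected_mean,
                "actual_mean": self.actual_mean,
                "gap": self.gap,
                "percent_gap": self.percent_gap,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "cohort", self.label)
        df.to_csv(path, index=False)


def decile_gap(expected_mean: float, actual_mean: float) -> tuple[float, int]:
    """Dollar gap and integer percent gap for one decile row.

    The same arithmetic the table applies: gap = expected - actual; percent =
    100*gap/expected rounded to the nearest integer, half away from zero.
    Usable directly on printed table means.
    """
    gap = expected_mean - actual_mean
    return gap, int(round_half_away(100.0 * gap / expected_mean))


def assign_deciles(predictions: np.ndarray, patient_ids: Sequence[str]) -> np.ndarray:
    """Decile label (1..10) per patient.

    Patients are sorted by (prediction, patient_id) ascending — the id
    tie-break makes assignment deterministic — and split into ten contiguous
    groups with sizes as equal as possible; the first n mod 10 groups take
    the extra patient.
    """
    predictions = np.asarray(predictions, dtype=float)
    n = len(predictions)
    if n < N_DECILES:
        raise ValueError(f"need at least {N_DECILES} patients to form deciles, got {n}")
    if len(patient_ids) != n:
        raise ValueError("patient_ids must match predictions")
    order = np.lexsort((np.asarray(patient_ids), predictions))
    base, extra = divmod(n, N_DECILES)
    sizes = np.array([base + 1 if d < extra else base for d in range(N_DECILES)])
    labels_sorted = np.repeat(np.arange(1, N_DECILES + 1), sizes)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def calibration_table(
    y: np.ndarray,
    predictions: np.ndarray,
    patient_ids: Sequence[str],
    label: str = "all",
    subgroup_mask: np.ndarray | None = None,
) -> CalibrationTable:
    """Decile calibration table for a cohort or a subgroup.

    With a subgroup mask, the cohort is restricted FIRST and deciles are
    recomputed within the subgroup. Expected and actual decile means are
    unweighted.
    """
    y = np.asarray(y, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    ids = np.asarray(patient_ids)
    if not (len(y) == len(predictions) == len(ids)):
        raise CohortMismatchError("y, predictions and patient_ids must align")
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        if len(mask) != len(y):
            raise CohortMismatchError("subgroup mask must align with the cohort")
        y, predictions, ids = y[mask], predictions[mask], ids[mask]
    if len(y) < N_DECILES:
        raise ValueError(f"subgroup {label!r} has fewer than {N_DECILES} patients")

    deciles = assign_deciles(predictions, ids)
    decile_n = np.zeros(N_DECILES, dtype=int)
    expected = np.zeros(N_DECILES)
    actual = np.zeros(N_DECILES)
    for d in range(1, N_DECILES + 1):
        sel = deciles == d
        decile_n[d - 1] = int(sel.sum())
        expected[d - 1] = predictions[sel].mean()
        actual[d - 1] = y[sel].mean()
    return CalibrationTable(
        label=label, n=len(y), decile_n=decile_n, expected_mean=expected, actual_mean=actual
    )


@dataclass
class ImprovementSeries:
    """Aligned per-decile gaps for a base and an augmented prediction set."""

    gap_base: np.ndarray
    gap_augmented: np.ndarray
    reduction: float  # mean |gap| base - mean |gap| augmented (positive = improvement)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "decile": np.arange(1, N_DECILES + 1),
                "gap_base": self.gap_base,
                "gap_augmented": self.gap_augmented,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def improvement_series(
    y: np.ndarray,
    predictions_base: np.ndarray,
    predictions_augmented: np.ndarray,
    patient_ids: Sequence[str],
    subgroup_mask: np.ndarray | None = None,
) -> ImprovementSeries:
    """Per-decile mean gap under each model, each on its own deciles of
    predicted cost, aligned by decile index."""
    if len(predictions_base) != len(predictions_augmented) or len(predictions_base) != len(y):
        raise CohortMismatchError("prediction sets must cover the same cohort")
    t_base = calibration_table(y, predictions_base, patient_ids, "base", subgroup_mask)
    t_aug = calibration_table(y, predictions_augmented, patient_ids, "augmented", subgroup_mask)
    reduction = float(np.mean(np.abs(t_base.gap)) - np.mean(np.abs(t_aug.gap)))
    return ImprovementSeries(gap_base=t_base.gap, gap_augmented=t_aug.gap, reduction=reduction)
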