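"""Screening validation statistics on labeled actives/decoys.

The six standard virtual-screening statistics computed from a confusion
matrix over labeled libraries:

    sensitivity (TPR) = TP / n_actives
    specificity       = TN / n_decoys
    FPR               = FP / n_decoys
    accuracy          = (TP + TN) / (n_actives + n_decoys)
    PPV               = TP / (TP + FP)
    NPV               = TN / (TN + FN)

Fractions are exposed raw and formatted as percentages to 2 decimal
places.  A metric whose denominator is zero (e.g. specificity of an
internal validation that has no decoys) is reported as undefined rather
than silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

__all__ = ["ConfusionCounts", "ValidationMetrics", "counts_from_screen",
           "metrics_from_counts", "metrics_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Screening outcome counts over a labeled library."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_actives(self) -> int:
        return self.tp + self.fn

    @property
    def n_decoys(self) -> int:
        return self.fp + self.tn

    @property
    def n_total(self) -> int:
        return self.n_actives + self.n_decoys


@dataclass(frozen=True)
class ValidationMetrics:
    """The six statistics as raw fractions; ``None`` marks undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    false_positive_rate: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_percent(self) -> Dict[str, Optional[float]]:
        """Each metric as a percentage rounded to 2 dp (None if undefined)."""
        return {
            k: (None if v is None else round(100.0 * v, 2))
            for k, v in self.__dict__.items()
        }

    def format(self) -> Dict[str, str]:
        return {
            k: ("undefined" if v is None else f"{v:.2f}%")
            for k, v in self.as_percent().items()
        }


def counts_from_screen(labels: Dict[str, str], table: pd.DataFrame) -> ConfusionCounts:
    """Confusion counts from a screening table and an id -> label map.

    Labels are "active" / "decoy".  Error rows (unreadable records) count
    as non-hits.  Unlabeled ids raise, listing every offender.
    """
    ids = list(table["molecule_id"])
    unlabeled = sorted(set(ids) - set(labels))
    if unlabeled:
        raise KeyError(f"unlabeled molecule ids: {unlabeled}")
    bad = sorted({v for v in labels.values() if v not in ("active", "decoy")})
    if bad:
        raise ValueError(f"labels must be 'active' or 'decoy', got {bad}")
    tp = fn = fp = tn = 0
    for _, row in table.iterrows():
        hit = row["hit"] == 1
        if labels[row["molecule_id"]] == "active":
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics_from_counts(c: ConfusionCounts) -> ValidationMetrics:
    """The six validation statistics from confusion counts."""
    return ValidationMetrics(
        sensitivity=_ratio(c.tp, c.n_actives),
        specificity=_ratio(c.tn, c.n_decoys),
        false_positive_rate=_ratio(c.fp, c.n_decoys),
        accuracy=_ratio(c.tp + c.tn, c.n_total),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def metrics_table(c: ConfusionCounts) -> pd.DataFrame:
    """Counts + formatted metrics as a two-column report table."""
    m = metrics_from_counts(c)
    rows = [
        ("true_positives", c.tp), ("false_negatives", c.fn),
        ("false_positives", c.fp), ("true_negatives", c.tn),
        ("n_actives", c.n_actives), ("n_decoys", c.n_decoys),
    ]
    rows += list(m.format().items())
    return pd.DataFrame(rows, columns=["metric", "value"])
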