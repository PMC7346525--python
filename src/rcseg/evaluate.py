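"""Region-level evaluation and the case-scenario training/testing grid.

Segmentation quality is scored at the level of k-means color regions: a
confusion matrix between manually derived and predicted region labels,
summarized by the overall accuracy

    A = (TP + TN) / (TP + FP + TN + FN)  in [0, 1].

Region-level counting is more sensitive to classification failures than
whole-mask Dice (one wrong region is one error regardless of its pixel
area); a pixel Dice coefficient is still reported for context.

The scenario grid trains one eight-member ensemble per (scenario,
stage-combination) on the union of the training tables of the included
developmental stages, then evaluates every member on the training table
itself (test set "0") and on held-out test tables of the juvenile (I),
mid-stage (II) and adult (III) samples - four records per trained
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import MEMBER_ACRONYMS, train_ensemble
from .colorspace import RegionPartition
from .errors import ConfigurationError, ValidationError
from .io import BinaryMask

STAGES = ("I", "II", "III")
#: Stage combinations of the full grid.
STAGE_COMBOS = (
    ("I",), ("II",), ("III",),
    ("I", "II"), ("I", "III"), ("II", "III"),
    ("I", "II", "III"),
)
TEST_SETS = ("0", "I", "II", "III")


@dataclass
class ConfusionMatrix:
    """Region-level TP/FP/FN/TN counts (plant is the positive class)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def accuracy(confusion: ConfusionMatrix) -> float:
    """Overall accuracy ``(TP + TN) / (TP + FP + TN + FN)``."""
    if confusion.total < 1:
        raise ValidationError("accuracy undefined for an empty confusion matrix")
    return (confusion.tp + confusion.tn) / confusion.total


def region_confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count region-level confusion between binary label vectors."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if t.size != p.size:
        raise ValidationError("label vectors must have equal length")
    if not (set(np.unique(t)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValidationError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def region_truth_labels(
    partition: RegionPartition, truth_mask: BinaryMask
) -> np.ndarray:
    """Derive region ground truth from a pixel ground-truth mask.

    A region is plant when more than half of its pixels are plant in the
    reference mask; an exact 50% tie also counts as plant (consistent
    with the other tie rules in this package).
    """
    if partition.labels.shape != truth_mask.shape:
        raise ValidationError("partition and truth mask shapes differ")
    sel = partition.labels >= 0
    lab = partition.labels[sel]
    plant = truth_mask.pixels[sel].astype(np.float64)
    total = np.bincount(lab, minlength=partition.n_reg)
    pos = np.bincount(lab, weights=plant, minlength=partition.n_reg)
    return (2 * pos >= total).astype(np.intp)


def pixel_dice(a: BinaryMask, b: BinaryMask) -> float:
    """Pixel-level Dice similarity coefficient between two masks."""
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a.pixels, b.pixels).sum()) / (na + nb)


@dataclass
class RegionSample:
    """The region table of one image pair: AC-KMR features and truth labels."""

    x: np.ndarray
    y: np.ndarray


@dataclass
class EvaluationRecord:
    """One (scenario, classifier, test set) accuracy measurement."""

    scenario: dict
    classifier: str
    test_set: str
    confusion: ConfusionMatrix
    accuracy: float
    seed: int = 0


def _concat(samples: list[RegionSample]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.concatenate([s.x for s in samples]),
        np.concatenate([s.y for s in samples]),
    )


def run_scenario_grid(
    samples: dict,
    archetypes: list[str],
    stage_combos=STAGE_COMBOS,
    seed: int = 0,
    net_hidden: int = 10,
    modality: str = "VIS",
) -> list[EvaluationRecord]:
    """Train and 4-way test the ensemble over a case-scenario grid.

    ``samples`` maps ``(archetype, stage)`` to ``{"train": [RegionSample],
    "test": [RegionSample]}``.  For each archetype and stage combination
    one ensemble is trained on the union of the training tables; each of
    its eight members is then evaluated on test sets 0 (the training
    table), I, II and III.  Deterministic given ``seed``.
    """
    for arch in archetypes:
        for stage in STAGES:
            if (arch, stage) not in samples:
                raise ConfigurationError(
                    f"grid references missing dataset ({arch}, {stage})"
                )
    records: list[EvaluationRecord] = []
    for arch in archetypes:
        for combo in stage_combos:
            train_parts = [s for st in combo for s in samples[(arch, st)]["train"]]
            x_train, y_train = _concat(train_parts)
            ens = train_ensemble(x_train, y_train, net_hidden=net_hidden, seed=seed)
            eval_sets = {"0": (x_train, y_train)}
            for st in STAGES:
                eval_sets[st] = _concat(samples[(arch, st)]["test"])
            scenario = {
                "archetype": arch,
                "modality": modality,
                "stages": "+".join(combo),
            }
            for acronym in MEMBER_ACRONYMS:
                for test_set, (x, y) in eval_sets.items():
                    pred = ens.predict_single(acronym, x)
                    cm = region_confusion(y, pred)
                    records.append(
                        EvaluationRecord(
                            scenario=dict(scenario),
                            classifier=acronym,
                            test_set=test_set,
                            confusion=cm,
                            accuracy=accuracy(cm),
                            seed=seed,
                        )
                    )
    return records


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Flatten evaluation records into a DataFrame (one row per record)."""
    rows = []
    for r in records:
        rows.append(
            {
                **{f"scenario_{k}": v for k, v in r.scenario.items()},
                "classifier": r.classifier,
                "test_set": r.test_set,
                "tp": r.confusion.tp,
                "fp": r.confusion.fp,
                "fn": r.confusion.fn,
                "tn": r.confusion.tn,
                "accuracy": r.accuracy,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def summarize(records: list[EvaluationRecord]) -> dict:
    """Mean / median / SD / min / max accuracy over a set of records."""
    acc = np.array([r.accuracy for r in records])
    return {
        "mean": float(acc.mean()),
        "median": float(np.median(acc)),
        "sd": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        "min": float(acc.min()),
        "max": float(acc.max()),
        "n_records": int(acc.size),
    }
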