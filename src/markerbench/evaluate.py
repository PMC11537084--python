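"""Per-genus classification metrics, confusion estimation, paired tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassificationResult

__all__ = ["GenusMetrics", "ConfusionMatrix", "genus_metrics",
           "estimate_confusion", "paired_marker_test"]


@dataclass(frozen=True)
class GenusMetrics:
    """Accuracy plus macro-averaged one-vs-rest precision/sensitivity.

    Accuracy is correct calls over all genomes of the genus.  Precision
    and sensitivity are computed one-vs-rest per species and macro-averaged
    over species present in truth; a species never predicted is skipped
    from the precision average (its precision is undefined).  With
    ``micro=True`` the micro averages are used instead, which for a
    single-label problem both equal accuracy.
    """

    genus: str
    region: str
    method: str
    accuracy: float
    precision: float
    sensitivity: float
    n_samples: int


def genus_metrics(results: Sequence[ClassificationResult],
                  genus: str = "", region: str = "",
                  micro: bool = False) -> GenusMetrics:
    if not results:
        raise ValueError("empty results")
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ValueError("mixed methods in one metrics group")
    n = len(results)
    n_correct = sum(r.correct for r in results)
    accuracy = n_correct / n
    if micro:
        precision = sensitivity = accuracy
    else:
        truth_species = sorted({r.true_species for r in results})
        precisions, sensitivities = [], []
        for sp in truth_species:
            tp = sum(r.correct for r in results if r.true_species == sp)
            fn = sum(not r.correct for r in results if r.true_species == sp)
            predicted = sum(r.predicted_species == sp for r in results)
            sensitivities.append(tp / (tp + fn))
            if predicted > 0:
                precisions.append(tp / predicted)
        precision = float(np.mean(precisions)) if precisions else 0.0
        sensitivity = float(np.mean(sensitivities))
    return GenusMetrics(genus, region, methods.pop(), accuracy,
                        precision, sensitivity, n)


@dataclass
class ConfusionMatrix:
    """Row-stochastic species x species matrix: C[i, j] = P(pred j | true i)."""

    species: list[str]
    matrix: np.ndarray
    region: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("entries outside [0, 1]")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")

    @classmethod
    def identity(cls, species: Sequence[str], **kw) -> "ConfusionMatrix":
        return cls(list(species), np.eye(len(species)), **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species,
                            columns=self.species)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, **kw) -> "ConfusionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), **kw)


def estimate_confusion(results: Sequence[ClassificationResult],
                       species: Sequence[str] | None = None,
                       region: str = "", method: str = "") -> ConfusionMatrix:
    """Estimate P(predicted | true) from classification outcomes.

    Every species in ``species`` (default: those observed in truth) must
    occur at least once as truth.  Unclassified results (no prediction at
    all) are excluded from their row with a warning; the row is normalized
    over classified outcomes.
    """
    if not results:
        raise ValueError("empty results")
    if species is None:
        species = sorted({r.true_species for r in results})
    idx = {sp: i for i, sp in enumerate(species)}
    n = len(species)
    counts = np.zeros((n, n))
    n_unclassified = 0
    for r in results:
        if r.true_species not in idx:
            raise ValueError(f"unexpected true species {r.true_species}")
        if r.predicted_species is None:
            n_unclassified += 1
            continue
        counts[idx[r.true_species], idx[r.predicted_species]] += 1
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        missing = [sp for sp, s in zip(species, row_sums) if s == 0]
        raise ValueError(f"species with zero classified truth "
                         f"occurrences: {missing}")
    if n_unclassified:
        warnings.warn(f"{n_unclassified} unclassified results excluded "
                      "from confusion estimation")
    return ConfusionMatrix(list(species), counts / row_sums[:, None],
                           region, method)


def paired_marker_test(
    acc_marker1: Mapping[str, float],
    acc_marker2: Mapping[str, float],
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on per-genus accuracies.

    Zero differences are dropped (standard convention); if every
    difference is zero the test is undefined and (nan, 1.0) is returned
    with a warning.  Exact null distribution for n <= 25 without ties,
    normal approximation otherwise (scipy's "auto" policy).
    """
    if set(acc_marker1) != set(acc_marker2):
        raise ValueError("mismatched genus sets")
    genera = sorted(acc_marker1)
    if len(genera) < 6:
        raise ValueError("need >= 6 genera for a meaningful paired test")
    d = np.array([acc_marker1[g] - acc_marker2[g] for g in genera])
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; test undefined, "
                      "reporting p=1")
        return float("nan"), 1.0
    stat, p = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return float(stat), float(p)


def metrics_to_frame(metrics: Sequence[GenusMetrics]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in metrics])
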