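"""Two-group differential abundance on proportion tables.

The minimal core of the common microbiome workflow: total-sum scaling to
proportions, arcsine-square-root variance stabilization, then an ordinary
least-squares fit per species of the transformed abundance on a binary
group indicator (case = 1).  Species with a two-sided slope p-value below
alpha (default 0.05, no multiplicity correction) are called significant.

Agreement between a predicted and a reference significant set is scored
with Venn semantics: the false negative rate is the fraction of
reference-significant species missed, and the false discovery rate is the
fraction of predicted-significant species absent from the reference set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["tss", "ast", "fit_group_models", "AgreementReport",
           "agreement", "coefficient_table"]


def tss(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: divide each sample column by its sum."""
    sums = table.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"all-zero samples: {bad}")
    if (table < 0).to_numpy().any():
        raise ValueError("negative abundances")
    return table / sums


def ast(x):
    """Arcsine square-root transform, arcsin(sqrt(x)), for x in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("input outside [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(x) else out


def fit_group_models(
    profile_table: pd.DataFrame,
    group_labels: Sequence[str] | Mapping[str, str],
    alpha: float = 0.05,
    case_label: str = "case",
) -> pd.DataFrame:
    """Per-species linear model of AST(TSS proportion) on the group.

    ``group_labels`` gives each sample's group (sequence aligned with the
    table's columns, or a mapping column -> label); the label equal to
    ``case_label`` codes 1.  Returns a DataFrame with columns species,
    coefficient, p_value, significant.  A species with constant response
    gets coefficient 0 and p-value 1.
    """
    if isinstance(group_labels, Mapping):
        labels = [group_labels[c] for c in profile_table.columns]
    else:
        labels = list(group_labels)
    if len(labels) != profile_table.shape[1]:
        raise ValueError("group_labels length mismatch")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    x = np.array([1.0 if lab == case_label else 0.0 for lab in labels])
    if x.sum() == 0:
        raise ValueError(f"case label {case_label!r} not present")
    for g in groups:
        if labels.count(g) < 3:
            raise ValueError(f"group {g!r} has < 3 samples")

    y_all = ast(tss(profile_table).to_numpy())
    design = sm.add_constant(x)
    rows = []
    for i, species in enumerate(profile_table.index):
        y = y_all[i]
        if np.ptp(y) == 0:
            coef, p = 0.0, 1.0
        else:
            fit = sm.OLS(y, design).fit()
            coef, p = float(fit.params[1]), float(fit.pvalues[1])
            if np.isnan(p):  # group-wise constant response
                p = 1.0
        rows.append((species, coef, p, p < alpha))
    return pd.DataFrame(rows, columns=["species", "coefficient",
                                       "p_value", "significant"])


@dataclass(frozen=True)
class AgreementReport:
    n_reference_significant: int
    n_predicted_significant: int
    n_overlap: int
    false_negative_rate: float
    false_discovery_rate: float

    @classmethod
    def from_sets(cls, reference: set, predicted: set) -> "AgreementReport":
        overlap = len(reference & predicted)
        if not reference:
            warnings.warn("empty reference significant set; FNR reported as 0")
            fnr = 0.0
        else:
            fnr = (len(reference) - overlap) / len(reference)
        if not predicted:
            warnings.warn("empty predicted significant set; FDR reported as 0")
            fdr = 0.0
        else:
            fdr = (len(predicted) - overlap) / len(predicted)
        return cls(len(reference), len(predicted), overlap, fnr, fdr)

    def to_dict(self) -> dict:
        return {
            "n_reference_significant": self.n_reference_significant,
            "n_predicted_significant": self.n_predicted_significant,
            "n_overlap": self.n_overlap,
            "false_negative_rate": self.false_negative_rate,
            "false_discovery_rate": self.false_discovery_rate,
        }


def _significant_set(results: pd.DataFrame) -> set:
    return set(results.loc[results["significant"], "species"])


def agreement(reference_results: pd.DataFrame,
              predicted_results: pd.DataFrame) -> AgreementReport:
    """Score a predicted significant set against the reference one."""
    ref_universe = set(reference_results["species"])
    pred_universe = set(predicted_results["species"])
    if not ref_universe & pred_universe:
        raise ValueError("disjoint species universes")
    return AgreementReport.from_sets(_significant_set(reference_results),
                                     _significant_set(predicted_results))


def coefficient_table(
    reference_results: pd.DataFrame,
    predicted_results_by_marker: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Long table of coefficients for species with any disagreement.

    A species is kept when, for at least one marker, its significance
    status or its coefficient sign differs from the reference.  Columns:
    species, source, coefficient, p_value, significant.
    """
    ref = reference_results.set_index("species")
    keep: set = set()
    for marker, res in predicted_results_by_marker.items():
        df = res.set_index("species")
        shared = ref.index.intersection(df.index)
        for sp in shared:
            if bool(ref.loc[sp, "significant"]) != bool(df.loc[sp, "significant"]):
                keep.add(sp)
            elif np.sign(ref.loc[sp, "coefficient"]) != np.sign(
                    df.loc[sp, "coefficient"]):
                keep.add(sp)
    rows = []
    sources = {"reference": reference_results,
               **predicted_results_by_marker}
    for source, res in sources.items():
        sub = res[res["species"].isin(keep)]
        for r in sub.itertuples(index=False):
            rows.append((r.species, source, r.coefficient, r.p_value,
                         bool(r.significant)))
    return pd.DataFrame(rows, columns=["species", "source", "coefficient",
                                       "p_value", "significant"]
                        ).sort_values(["species", "source"],
                                      ignore_index=True)
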