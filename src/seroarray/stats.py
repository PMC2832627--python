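"""Profile statistics: quantile normalization and per-antigen ROC AUC.

A screened serum yields one profile of per-antigen intensities; stacking
sera gives the profile matrix all downstream statistics operate on.
Inter-array intensity effects (membrane batch, serum dilution, scanner
gain) are removed by quantile normalization; each antigen's power to
separate two serum groups is summarized by the area under the ROC curve
obtained by sweeping a decision threshold over the observed intensities.
An antigen is called informative when its AUC leaves the [0.3, 0.7] band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("seroarray")

__all__ = [
    "ProfileMatrix",
    "AntigenScore",
    "fit_quantile_reference",
    "apply_quantile_reference",
    "quantile_normalize",
    "antigen_auc",
    "flag_informative",
    "score_antigens",
]

INFORMATIVE_LOW = 0.3
INFORMATIVE_HIGH = 0.7


@dataclass
class ProfileMatrix:
    """Sera x antigens intensity matrix with serum group labels.

    ``values``: DataFrame, rows = sera (index of serum ids), columns =
    antigen ids; integer after quantification, real after normalization.
    ``groups``: Series mapping serum id -> group label, aligned to rows.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate serum ids in profile matrix")
        if self.values.isna().any().any():
            raise ValueError("profile matrix must have no missing cells")
        if not self.values.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.index)
            if self.groups.isna().any():
                missing = self.values.index[self.groups.isna()].tolist()
                raise ValueError(f"sera without group label: {missing}")

    @property
    def n_sera(self) -> int:
        return self.values.shape[0]

    @property
    def n_antigens(self) -> int:
        return self.values.shape[1]

    def task_subset(self, group1: str, group2: str) -> "ProfileMatrix":
        """Restrict to the sera of a two-group classification task."""
        mask = self.groups.isin([group1, group2])
        if not mask.any():
            raise ValueError(f"no sera in groups {group1!r}/{group2!r}")
        return ProfileMatrix(self.values.loc[mask], self.groups.loc[mask])


@dataclass
class AntigenScore:
    antigen_id: str
    auc: float
    informative: bool


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def fit_quantile_reference(X: np.ndarray) -> np.ndarray:
    """Reference distribution: column-wise mean of the sorted sample rows."""
    X = np.asarray(X, dtype=float)
    return np.sort(X, axis=1).mean(axis=0)


def apply_quantile_reference(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map each row onto the reference distribution by rank.

    The value at sorted position ``i`` of a row becomes ``reference[i]``.
    Tied values within a row receive the mean of the reference quantiles
    they span, so the within-row rank order is preserved up to ties --
    integer grayscale profiles are heavily tied, and splitting a tie would
    invent order that is not in the data.
    """
    X = np.asarray(X, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if X.shape[1] != reference.shape[0]:
        raise ValueError("reference length must equal the number of antigens")
    out = np.empty_like(X)
    for i, row in enumerate(X):
        order = np.argsort(row, kind="stable")
        sv = row[order]
        starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        counts = np.diff(np.r_[starts, len(sv)])
        group_means = np.add.reduceat(reference, starts) / counts
        out[i, order] = np.repeat(group_means, counts)
    return out


def quantile_normalize(matrix: ProfileMatrix) -> ProfileMatrix:
    """Quantile-normalize a profile matrix across sera.

    After normalization every serum shares (up to ties) the common
    reference distribution, the mean of the sorted per-serum vectors. A
    single-serum matrix is returned unchanged with a warning -- there is
    nothing to normalize against.
    """
    if matrix.n_sera < 2:
        logger.warning("quantile_normalize: single serum, returning input unchanged")
        return matrix
    X = matrix.values.to_numpy(dtype=float)
    ref = fit_quantile_reference(X)
    normalized = apply_quantile_reference(X, ref)
    frame = pd.DataFrame(
        normalized, index=matrix.values.index, columns=matrix.values.columns
    )
    return ProfileMatrix(values=frame, groups=matrix.groups.copy())


# ---------------------------------------------------------------------------
# Threshold-sweep AUC
# ---------------------------------------------------------------------------


def antigen_auc(values_group1, values_group2) -> float:
    """Area under the ROC curve separating two groups of intensities.

    Every observed intensity serves as a decision threshold; at each
    threshold ``t`` group-2 sera above ``t`` count as true positives and
    group-1 sera above ``t`` as false positives, giving one
    (1-specificity, sensitivity) point. The area under the resulting
    staircase (trapezoidal, so between-group ties contribute one half) is
    returned.

    Orientation: AUC > 0.5 means group 2 runs higher, AUC < 0.5 means
    group 1 runs higher; ``antigen_auc(a, b) == 1 - antigen_auc(b, a)``.
    An AUC of 0.5 means the two intensity distributions cannot be told
    apart; 0 and 1 are perfect separation.
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both serum groups must be non-empty")
    thresholds = np.unique(np.concatenate([g1, g2]))
    # fraction of each group strictly above every threshold
    tpr = 1.0 - np.searchsorted(np.sort(g2), thresholds, side="right") / g2.size
    fpr = 1.0 - np.searchsorted(np.sort(g1), thresholds, side="right") / g1.size
    # prepend the all-positive operating point (threshold below every value)
    tpr = np.concatenate([[1.0], tpr])
    fpr = np.concatenate([[1.0], fpr])
    return float(-np.trapezoid(tpr, fpr))  # fpr is decreasing


def flag_informative(auc: float) -> bool:
    """Informative antigen rule: AUC strictly below 0.3 or strictly above 0.7."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    return auc < INFORMATIVE_LOW or auc > INFORMATIVE_HIGH


def score_antigens(
    matrix: ProfileMatrix, group1: str, group2: str
) -> pd.DataFrame:
    """Per-antigen AUC and informativeness for one two-group task.

    Expects normalized intensities (AUC is rank-based, so normalization
    matters only through its tie handling). Returns a DataFrame with
    columns ``antigen_id``, ``auc``, ``informative``.
    """
    sub = matrix.task_subset(group1, group2)
    m1 = (sub.groups == group1).to_numpy()
    m2 = (sub.groups == group2).to_numpy()
    X = sub.values.to_numpy(dtype=float)
    records = []
    for j, antigen in enumerate(sub.values.columns):
        auc = antigen_auc(X[m1, j], X[m2, j])
        records.append(
            {"antigen_id": antigen, "auc": auc, "informative": flag_informative(auc)}
        )
    return pd.DataFrame.from_records(records)
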