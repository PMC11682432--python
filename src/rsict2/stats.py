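"""Group comparisons of compartmental T2 summaries.

Three analyses, all two-sample t-tests at alpha = 0.05 on per-patient
median T2 values:

* compartment vs compartment within the whole prostate (6 pairs),
* lesion tissue vs non-lesion tissue (lesion medians of csPCa patients
  against prostate-minus-lesion medians of csPCa patients pooled with
  whole-prostate medians of non-csPCa patients),
* csPCa patients vs non-csPCa patients on whole-prostate medians.

Welch's unequal-variance test is the default; a pooled-variance option is
available.  No multiple-testing correction is applied (each test is read
at alpha per comparison).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .volumes import N_COMPARTMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "two_sample_test",
    "compare_compartments",
    "lesion_vs_rest",
    "patient_level_comparison",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sample comparison; ``significant`` iff ``p < alpha``."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_difference: float
    t: float
    p: float
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or math.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)

    def as_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_difference": self.mean_difference,
            "t": self.t,
            "p": self.p,
            "significant": self.significant,
        }


def two_sample_test(
    a,
    b,
    group_a: str = "A",
    group_b: str = "B",
    equal_var: bool = False,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-sample t-test (Welch by default) with a zero-variance guard.

    NaNs are dropped.  If both groups are constant the t statistic is
    degenerate; the guard reports p = 1 when the means agree and p = 0
    otherwise, and logs the event.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two finite observations")
    diff = float(a.mean() - b.mean())
    if np.var(a) == 0 and np.var(b) == 0:
        equal_means = np.isclose(a.mean(), b.mean())
        logger.warning("zero-variance groups in %s vs %s", group_a, group_b)
        return ComparisonResult(
            group_a, group_b, a.size, b.size,
            mean_difference=diff,
            t=0.0 if equal_means else math.inf,
            p=1.0 if equal_means else 0.0,
            alpha=alpha,
        )
    t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        group_a, group_b, a.size, b.size,
        mean_difference=diff, t=float(t), p=float(p), alpha=alpha,
    )


def _col(summaries: pd.DataFrame, i: int, mask: str) -> pd.Series:
    name = f"t2_c{i}_{mask}"
    if name not in summaries.columns:
        raise KeyError(f"summary table lacks column {name!r}")
    return summaries[name]


def compare_compartments(
    summaries: pd.DataFrame,
    mask: str = "prostate",
    equal_var: bool = False,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """All six pairwise compartment comparisons of whole-prostate median T2."""
    if len(summaries) < 2:
        raise ValueError("need at least two patients")
    results = []
    for i, j in itertools.combinations(range(1, N_COMPARTMENTS + 1), 2):
        results.append(
            two_sample_test(
                _col(summaries, i, mask),
                _col(summaries, j, mask),
                group_a=f"C{i}",
                group_b=f"C{j}",
                equal_var=equal_var,
                alpha=alpha,
            )
        )
    return results


def lesion_vs_rest(
    summaries: pd.DataFrame,
    equal_var: bool = False,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Lesion-tissue vs non-lesion-tissue T2, one comparison per compartment.

    Group A: per-patient lesion-mask medians (csPCa patients).  Group B:
    per-patient prostate-minus-lesion medians of csPCa patients pooled with
    whole-prostate medians of non-csPCa patients.  Patients whose lesion
    median is undefined for a compartment are skipped with a log entry.
    """
    if "label" not in summaries.columns:
        raise KeyError("summary table needs a boolean 'label' column")
    pos = summaries[summaries["label"].astype(bool)]
    neg = summaries[~summaries["label"].astype(bool)]
    if len(pos) == 0:
        raise ValueError("no csPCa patients with lesion masks in the table")
    results = []
    for i in range(1, N_COMPARTMENTS + 1):
        lesion_vals = _col(pos, i, "lesion")
        n_missing = int(lesion_vals.isna().sum())
        if n_missing:
            logger.info(
                "compartment %d: %d csPCa patients without valid lesion voxels",
                i, n_missing,
            )
        rest = np.concatenate(
            [_col(pos, i, "rest").to_numpy(), _col(neg, i, "prostate").to_numpy()]
        )
        results.append(
            two_sample_test(
                lesion_vals.to_numpy(),
                rest,
                group_a=f"C{i} lesion",
                group_b=f"C{i} non-lesion",
                equal_var=equal_var,
                alpha=alpha,
            )
        )
    return results


def patient_level_comparison(
    summaries: pd.DataFrame,
    equal_var: bool = False,
    alpha: float = ALPHA,
) -> tuple[list[ComparisonResult], list[int]]:
    """csPCa vs non-csPCa whole-prostate median T2 per compartment.

    Returns the four comparisons and the list of compartment indices with a
    significant difference (candidates for inclusion in the classifier).
    """
    if "label" not in summaries.columns:
        raise KeyError("summary table needs a boolean 'label' column")
    labels = summaries["label"].astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both csPCa and non-csPCa patients are required")
    results = []
    flagged = []
    for i in range(1, N_COMPARTMENTS + 1):
        res = two_sample_test(
            _col(summaries[labels], i, "prostate"),
            _col(summaries[~labels], i, "prostate"),
            group_a=f"C{i} csPCa",
            group_b=f"C{i} no csPCa",
            equal_var=equal_var,
            alpha=alpha,
        )
        results.append(res)
        if res.significant:
            flagged.append(i)
    return results, flagged
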