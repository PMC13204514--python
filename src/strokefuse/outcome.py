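"""Biomarker-vs-recovery association analyses.

Two families of simple linear regressions relate the spectral biomarker to
longitudinal change in three assessment scores (FIM Walk, word
comprehension, Posner cueing reaction time):

* family 1 ("prognostic"): assessment change ~ subacute biomarker level;
* family 2 ("longitudinal-change"): assessment change ~ biomarker change.

Each family's family-wise error rate is controlled at 0.05 with the
Holm-Bonferroni step-down procedure (thresholds alpha/(m-i+1) for the i-th
smallest p-value).  The per-subject biomarker level at a visit is the mean
per-scan Fisher score of the chosen feature over that visit's runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct

from .evaluation import PairedTResult, paired_t_test

ASSESSMENTS = ("fim_walk", "word_comprehension", "posner_ms")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p: float
    r2: float
    n: int


def simple_regression(x, y) -> RegressionResult:
    """OLS slope with its two-sided t-test p-value and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero variance in the regressor")
    res = sct.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            p=float(res.pvalue),
                            r2=float(res.rvalue ** 2), n=x.size)


def holm_thresholds(m: int, alpha: float = 0.05) -> np.ndarray:
    """Step-wise thresholds alpha/(m-i+1) for the i-th smallest p, i=1..m."""
    if m < 1 or not 0 < alpha < 1:
        raise ValueError("need m >= 1 and 0 < alpha < 1")
    return alpha / (m - np.arange(m))


def holm_flags(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni significance flags, in input order."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    thr = holm_thresholds(p.size, alpha)
    flags = np.zeros(p.size, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= thr[rank]:
            flags[idx] = True
        else:
            break
    return flags


@dataclass
class FamilyReport:
    label: str
    table: pd.DataFrame       # test, slope, p, r2, n, flagged
    thresholds: np.ndarray
    alpha: float = 0.05

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table.flagged, "test"])


def _family(label: str, x: np.ndarray, ys: dict, alpha: float) -> FamilyReport:
    rows = []
    for name, y in ys.items():
        r = simple_regression(x, y)
        rows.append({"test": name, "slope": r.slope, "p": r.p,
                     "r2": r.r2, "n": r.n})
    table = pd.DataFrame(rows)
    table["flagged"] = holm_flags(table.p.to_numpy(), alpha)
    return FamilyReport(label=label, table=table,
                        thresholds=holm_thresholds(len(rows), alpha),
                        alpha=alpha)


def run_families(amplitude_summary: pd.DataFrame,
                 assessments: pd.DataFrame,
                 alpha: float = 0.05) -> tuple[FamilyReport, FamilyReport]:
    """The two Holm-controlled test families on the completer subjects.

    ``amplitude_summary``: columns subject_id / visit / amplitude (the
    per-subject biomarker level per visit).  ``assessments``: columns
    subject_id / visit / fim_walk / word_comprehension / posner_ms.  Only
    subjects with both visits in both tables enter; fewer than 3 completers
    is an error.
    """
    amp = amplitude_summary.pivot(index="subject_id", columns="visit",
                                  values="amplitude")
    scores = assessments.pivot(index="subject_id", columns="visit",
                               values=list(ASSESSMENTS))
    both = amp.dropna().index.intersection(scores.dropna().index)
    if len(both) < 3:
        raise ValueError(f"need >= 3 completers, have {len(both)}")
    amp = amp.loc[both]
    scores = scores.loc[both]

    x1 = amp["subacute"].to_numpy()
    x2 = (amp["chronic"] - amp["subacute"]).to_numpy()
    ys = {f"change_in_{name}":
          (scores[(name, "chronic")] - scores[(name, "subacute")]).to_numpy()
          for name in ASSESSMENTS}
    fam1 = _family("prognostic", x1, ys, alpha)
    fam2 = _family("longitudinal-change", x2, ys, alpha)
    return fam1, fam2


def amplitude_decline_test(subacute_scores, chronic_scores) -> PairedTResult:
    """Paired t-test for the subacute-to-chronic decline of the per-subject
    biomarker level (paired per subject)."""
    return paired_t_test(subacute_scores, chronic_scores)
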