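"""Observer/classifier agreement and normality-gated group comparisons.

Frame agreement is a 2x2 confusion between two label series over their
jointly annotated frames.  Group comparisons follow the conventional gated
procedure: a normality test per group (D'Agostino-Pearson by default,
Shapiro-Wilk for paired pharmacology designs) decides between the parametric
branch (t test / paired t) and the rank branch (Mann-Whitney / Wilcoxon
signed-rank).  Rank-test nulls are enumerated exactly when the combined
sample is small; larger samples use the normal approximation with
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .labels import POSITIVE, LabelSeries

EXACT_RANK_MAX_N = 12  # combined n at or below this enumerates the exact null


@dataclass
class AgreementReport:
    """Frame-level 2x2 confusion between series a (observer) and b (reference)."""

    n_match_pos: int
    n_match_neg: int
    n_obs_pos_clf_neg: int
    n_obs_neg_clf_pos: int
    normalized_positive_ratio: float

    @property
    def n_frames(self) -> int:
        return (
            self.n_match_pos
            + self.n_match_neg
            + self.n_obs_pos_clf_neg
            + self.n_obs_neg_clf_pos
        )

    def fractions(self) -> dict:
        n = self.n_frames
        return {
            "match_pos": self.n_match_pos / n,
            "match_neg": self.n_match_neg / n,
            "obs_pos_clf_neg": self.n_obs_pos_clf_neg / n,
            "obs_neg_clf_pos": self.n_obs_neg_clf_pos / n,
        }

    def to_dict(self) -> dict:
        return {
            "n_match_pos": self.n_match_pos,
            "n_match_neg": self.n_match_neg,
            "n_obs_pos_clf_neg": self.n_obs_pos_clf_neg,
            "n_obs_neg_clf_pos": self.n_obs_neg_clf_pos,
            "normalized_positive_ratio": self.normalized_positive_ratio,
            "fractions": self.fractions(),
        }


@dataclass
class ComparisonResult:
    test_name: str  # t, mann_whitney, paired_t, wilcoxon
    statistic: float
    p_value: float
    tails: int
    normality_p: tuple[float, float]
    normality_test: str
    alternative: str

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "tails": self.tails,
            "normality_p": list(self.normality_p),
            "normality_test": self.normality_test,
            "alternative": self.alternative,
        }


def frame_agreement(a: LabelSeries, b: LabelSeries) -> AgreementReport:
    """Quadrant counts between two label series on jointly annotated frames.

    ``normalized_positive_ratio`` is positives(a) / positives(b): how many
    frames the observer called burying relative to the reference.
    """
    if len(a) != len(b):
        raise ValueError("label series lengths differ")
    both = a.annotated & b.annotated
    if not both.any():
        raise ValueError("no jointly annotated frames")
    pa = a.label[both] == POSITIVE
    pb = b.label[both] == POSITIVE
    n_pos_b = int(pb.sum())
    ratio = float(pa.sum() / n_pos_b) if n_pos_b else np.inf
    return AgreementReport(
        n_match_pos=int(np.sum(pa & pb)),
        n_match_neg=int(np.sum(~pa & ~pb)),
        n_obs_pos_clf_neg=int(np.sum(pa & ~pb)),
        n_obs_neg_clf_pos=int(np.sum(~pa & pb)),
        normalized_positive_ratio=ratio,
    )


def _normality_p(x: np.ndarray, test: str) -> float:
    """Normality p-value; NaN when the sample is too small for the test
    (D'Agostino-Pearson needs n >= 8), which the gate treats as not normal."""
    if test == "dagostino_pearson":
        if len(x) < 8:
            return float("nan")
        return float(sps.normaltest(x).pvalue)
    if test == "shapiro_wilk":
        return float(sps.shapiro(x).pvalue)
    raise ValueError(f"unknown normality test: {test}")


def group_compare(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    tails: int = 2,
    normality_test: str = "dagostino_pearson",
    alternative: str | None = None,
    alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Both groups must pass the normality test at ``alpha_normality`` for the
    parametric branch (t test; paired t for paired designs); otherwise the
    rank branch is used (Mann-Whitney U; Wilcoxon signed-rank for paired).
    One- vs two-tailed is always the caller's decision; for one-tailed tests
    ``alternative`` ('greater' or 'less', referring to x relative to y)
    defaults to 'greater'.

    Rank tests enumerate the exact null when the combined sample size is at
    most 12; above that the normal approximation with continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 3:
        raise ValueError("need n >= 3 per group")
    if paired and len(x) != len(y):
        raise ValueError("paired comparison needs equal-length groups")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if tails == 2:
        alt = "two-sided"
    else:
        alt = alternative or "greater"
        if alt not in ("greater", "less"):
            raise ValueError("one-tailed alternative must be 'greater' or 'less'")

    if paired:
        px = _normality_p(x - y, normality_test)
        norm_p = (px, px)  # the paired branch tests the differences
        normal_ok = bool(px >= alpha_normality)
    else:
        px = _normality_p(x, normality_test)
        py = _normality_p(y, normality_test)
        norm_p = (px, py)
        normal_ok = bool(px >= alpha_normality) and bool(py >= alpha_normality)

    exact = len(x) + len(y) <= EXACT_RANK_MAX_N
    if paired:
        if normal_ok:
            res = sps.ttest_rel(x, y, alternative=alt)
            name = "paired_t"
        else:
            if exact:
                res = sps.wilcoxon(x, y, alternative=alt, method="exact")
            else:
                res = sps.wilcoxon(x, y, alternative=alt, method="approx", correction=True)
            name = "wilcoxon"
    else:
        if normal_ok:
            res = sps.ttest_ind(x, y, alternative=alt)
            name = "t"
        else:
            res = sps.mannwhitneyu(
                x,
                y,
                alternative=alt,
                method="exact" if exact else "asymptotic",
                use_continuity=True,
            )
            name = "mann_whitney"

    return ComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tails=tails,
        normality_p=norm_p,
        normality_test=normality_test,
        alternative=alt,
    )
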