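"""Group-comparison statistics for phantom image-quality studies.

Three procedures cover the study designs used here:

* :func:`tukey_kramer` — all pairwise mean comparisons across conditions
  with studentised-range adjusted p-values and simultaneous CIs
  (Tukey–Kramer HSD, delegated to statsmodels);
* :func:`equivalence_test` — paired TOST against a symmetric margin
  (e.g. CT value within +/- 2 HU of the reference);
* :func:`noninferiority_test` — one-sided test that a treatment is no worse
  than a reference by more than a margin (e.g. CNR margin 0.1,
  MTF10% margin 0.05 cycles/mm, noise-SD margin 1 HU).

Confidence intervals use the t distribution (Welch correction for unpaired
unequal-variance comparisons).  Verdict rules follow the CI conventions:
*equivalent* iff the two-sided 95% CI lies strictly inside (-margin, margin);
*non-inferior* iff the CI lower bound exceeds -margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatResult",
    "tukey_kramer",
    "equivalence_test",
    "noninferiority_test",
]


@dataclass
class StatResult:
    """Outcome of one comparison: estimate, 95% CI, margin, p, verdict."""

    comparison: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    verdict: str
    margin: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if self.verdict not in ("significant", "equivalent", "non_inferior", "fail"):
            raise ValueError(f"unknown verdict {self.verdict!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def tukey_kramer(groups: Sequence[tuple[str, Sequence[float]]],
                 alpha: float = 0.05) -> list[StatResult]:
    """Tukey–Kramer HSD over all pairs of groups.

    Each group is ``(label, samples)`` with at least 2 samples; the pooled
    variance comes from the one-way ANOVA across groups.  Verdict is
    ``significant`` when the adjusted p-value is below *alpha*, else
    ``fail``; the estimate is mean(second) - mean(first) in label order.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels, data = [], []
    for label, samples in groups:
        arr = np.asarray(samples, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs at least 2 samples")
        labels.extend([str(label)] * arr.size)
        data.append(arr)
    means = [a.mean() for a in data]
    pooled_ss = sum(((a - a.mean()) ** 2).sum() for a in data)
    if pooled_ss == 0:
        raise ValueError("zero pooled variance; Tukey-Kramer undefined"
                         if len(set(means)) > 1 else
                         "zero pooled variance and identical means; nothing to test")

    res = pairwise_tukeyhsd(np.concatenate(data), np.asarray(labels), alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    out = []
    for (g1, g2), diff, (lo, hi), p in zip(pairs, res.meandiffs, res.confint, res.pvalues):
        out.append(StatResult(
            comparison=f"{g2} - {g1}",
            estimate=float(diff),
            ci_low=float(lo),
            ci_high=float(hi),
            p_value=float(p),
            verdict="significant" if p < alpha else "fail",
        ))
    return out


def _mean_se_df(x: np.ndarray) -> tuple[float, float, float]:
    n = x.size
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(n)), float(n - 1)


def equivalence_test(paired_diffs: Sequence[float], margin: float,
                     alpha: float = 0.05, comparison: str = "equivalence") -> StatResult:
    """Two one-sided tests (TOST) that a mean paired difference is within
    ``(-margin, +margin)``.

    The reported p-value is the larger of the two one-sided p-values;
    verdict ``equivalent`` iff the two-sided 95% CI of the mean difference
    lies strictly inside the margin interval.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    d = np.asarray(paired_diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    mean, se, df = _mean_se_df(d)

    if se == 0:  # degenerate CI {mean}
        inside = abs(mean) < margin
        p = 0.0 if inside else 1.0
        ci_lo = ci_hi = mean
    else:
        t_lo = (mean + margin) / se   # H1: mean > -margin
        t_hi = (margin - mean) / se   # H1: mean < +margin
        p = float(max(sps.t.sf(t_lo, df), sps.t.sf(t_hi, df)))
        half = sps.t.ppf(1 - alpha / 2, df) * se
        ci_lo, ci_hi = mean - half, mean + half
        inside = (-margin < ci_lo) and (ci_hi < margin)

    return StatResult(comparison=comparison, estimate=mean,
                      ci_low=ci_lo, ci_high=ci_hi, p_value=p,
                      verdict="equivalent" if inside else "fail", margin=margin)


def noninferiority_test(treatment: Sequence[float], reference: Sequence[float],
                        margin: float, paired: bool = True, alpha: float = 0.05,
                        lower_is_better: bool = False,
                        comparison: str = "non-inferiority") -> StatResult:
    """One-sided test that mean(treatment - reference) > -margin.

    For higher-is-better metrics (CNR, MTF10%) non-inferiority means the
    treatment deficit does not exceed the margin.  For lower-is-better
    metrics (noise SD) set ``lower_is_better=True``; the difference sign is
    flipped before testing.  Verdict ``non_inferior`` iff the two-sided 95%
    CI lower bound of the (oriented) difference exceeds -margin.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    t_arr = np.asarray(treatment, dtype=float)
    r_arr = np.asarray(reference, dtype=float)

    if paired:
        if t_arr.size != r_arr.size:
            raise ValueError("paired samples must have equal size")
        d = t_arr - r_arr
        if lower_is_better:
            d = -d
        if d.size < 2:
            raise ValueError("need at least 2 pairs")
        mean, se, df = _mean_se_df(d)
    else:
        if t_arr.size < 2 or r_arr.size < 2:
            raise ValueError("each sample needs at least 2 values")
        sign = -1.0 if lower_is_better else 1.0
        mean = sign * float(t_arr.mean() - r_arr.mean())
        v_t, v_r = t_arr.var(ddof=1), r_arr.var(ddof=1)
        a, b = v_t / t_arr.size, v_r / r_arr.size
        se = math.sqrt(a + b)
        if se > 0:  # Welch-Satterthwaite
            df = (a + b) ** 2 / (a * a / (t_arr.size - 1) + b * b / (r_arr.size - 1))
        else:
            df = t_arr.size + r_arr.size - 2

    if se == 0:
        non_inf = mean > -margin
        p = 0.0 if non_inf else 1.0
        ci_lo, ci_hi = mean, mean
    else:
        p = float(sps.t.sf((mean + margin) / se, df))
        half = sps.t.ppf(1 - alpha / 2, df) * se
        ci_lo, ci_hi = mean - half, mean + half
        non_inf = ci_lo > -margin

    return StatResult(comparison=comparison, estimate=mean,
                      ci_low=ci_lo, ci_high=ci_hi, p_value=p,
                      verdict="non_inferior" if non_inf else "fail", margin=margin)
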