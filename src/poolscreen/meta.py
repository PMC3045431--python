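"""DerSimonian-Laird random-effects meta-analysis of odds ratios.

Studies are supplied as (OR, 95% CI) as published.  Each is converted to a
log odds ratio theta = ln OR with standard error SE = (ln hi - ln lo)/3.92
(the CI inversion uses the conventional multiplier 1.96 exactly, which is
what reproduces published pooled values from published intervals).

The between-study variance tau^2 is the DerSimonian-Laird method-of-moments
estimate from Cochran's Q, truncated at zero:

    w_i   = 1/SE_i^2                       (fixed-effect weights)
    Q     = sum w_i (theta_i - theta_fixed)^2
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1/(SE_i^2 + tau^2)             (random-effects weights)

The pooled log OR is the w*-weighted mean, with SE* = 1/sqrt(sum w*),
z = theta*/SE* and a two-sided normal p-value.  When Q <= k-1 the estimate
collapses to fixed-effect inverse-variance pooling.  Cochran's Q and
I^2 = max(0, (Q - df)/Q) are reported as heterogeneity summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.96
CI_LOG_WIDTH = 2 * Z_95  # 3.92


@dataclass(frozen=True)
class StudyEffect:
    """One study's odds ratio with its 95% confidence interval."""

    label: str
    or_: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_lo <= self.or_ <= self.ci_hi):
            raise ValueError(
                f"{self.label}: need 0 < ci_lo <= OR <= ci_hi, got "
                f"({self.ci_lo}, {self.or_}, {self.ci_hi})"
            )
        if self.ci_lo == self.ci_hi:
            raise ValueError(f"{self.label}: degenerate CI gives SE = 0")

    @property
    def theta(self) -> float:
        return math.log(self.or_)

    @property
    def se(self) -> float:
        return (math.log(self.ci_hi) - math.log(self.ci_lo)) / CI_LOG_WIDTH


def se_from_ci(or_: float, ci_lo: float, ci_hi: float) -> tuple[float, float]:
    """(theta, SE) from a published OR and 95% CI.

    theta = ln OR; SE = (ln hi - ln lo)/3.92.  Rejects non-positive or
    degenerate inputs.
    """
    eff = StudyEffect("", or_, ci_lo, ci_hi)
    return (eff.theta, eff.se)


@dataclass
class MetaResult:
    """Pooled random-effects estimate with heterogeneity summaries."""

    studies: list[StudyEffect]
    q_stat: float
    tau2: float
    i2: float
    theta: float
    se: float
    or_: float
    ci_lo: float
    ci_hi: float
    z: float
    p: float
    weights_pct: np.ndarray  # per-study random-effects weights, percent

    def to_frame(self) -> pd.DataFrame:
        """Per-study table plus the pooled row, mirroring a forest-plot table."""
        rows = [
            {
                "study": s.label,
                "odds_ratio": s.or_,
                "ci_lo": s.ci_lo,
                "ci_hi": s.ci_hi,
                "weight_pct": w,
            }
            for s, w in zip(self.studies, self.weights_pct)
        ]
        rows.append(
            {
                "study": "D+L pooled",
                "odds_ratio": self.or_,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "weight_pct": 100.0,
            }
        )
        return pd.DataFrame(rows)


def dl_meta(effects: Sequence[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of >= 2 study effects."""
    if len(effects) < 2:
        raise ValueError(f"meta-analysis needs >= 2 studies, got {len(effects)}")
    theta = np.array([e.theta for e in effects])
    var = np.array([e.se**2 for e in effects])
    w = 1.0 / var
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    k = len(effects)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (var + tau2)
    theta_star = float(np.sum(w_star * theta) / np.sum(w_star))
    se_star = float(1.0 / math.sqrt(np.sum(w_star)))
    z = theta_star / se_star
    p = float(2 * stats.norm.sf(abs(z)))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return MetaResult(
        studies=list(effects),
        q_stat=q,
        tau2=tau2,
        i2=i2,
        theta=theta_star,
        se=se_star,
        or_=math.exp(theta_star),
        ci_lo=math.exp(theta_star - Z_95 * se_star),
        ci_hi=math.exp(theta_star + Z_95 * se_star),
        z=z,
        p=p,
        weights_pct=100.0 * w_star / np.sum(w_star),
    )


def read_effects(path: Union[str, Path]) -> list[StudyEffect]:
    """Read a study-effects TSV with columns study, or, ci_lo, ci_hi.

    Column aliases ``odds_ratio`` (for ``or``) and ``label`` (for ``study``)
    are accepted.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    label_col = cols.get("study") or cols.get("label")
    or_col = cols.get("or") or cols.get("odds_ratio")
    if not (label_col and or_col and "ci_lo" in cols and "ci_hi" in cols):
        raise ValueError(
            f"{path}: expected columns study/label, or/odds_ratio, ci_lo, ci_hi"
        )
    return [
        StudyEffect(
            str(r[label_col]),
            float(r[or_col]),
            float(r[cols["ci_lo"]]),
            float(r[cols["ci_hi"]]),
        )
        for _, r in df.iterrows()
    ]
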