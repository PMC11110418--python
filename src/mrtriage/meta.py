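"""Multi-cohort meta-analysis with heterogeneity-driven model choice.

Per-cohort log-OR estimates (possibly reconstructed from published
``OR (95% CI)`` cells) are pooled with a fixed-effect inverse-variance
model; when between-cohort heterogeneity I² exceeds 50% the
DerSimonian–Laird random-effects model is used instead.  A protein
replicates when the pooled estimate is significant and sign-concordant
with discovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_io import beta_from_or_ci
from .mr_estimators import MREstimate

I2_RANDOM_THRESHOLD = 50.0  # percent; strict inequality switches models


@dataclass(frozen=True)
class CohortEstimate:
    """One cohort's log-OR and SE for a protein–outcome pair."""

    cohort_label: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")

    @classmethod
    def from_or_ci(cls, cohort_label: str, or_: float, lower: float,
                   upper: float, level: float = 0.95) -> "CohortEstimate":
        beta, se = beta_from_or_ci(or_, lower, upper, level)
        return cls(cohort_label=cohort_label, beta=beta, se=se)


@dataclass(frozen=True)
class MetaResult:
    pooled_beta: float
    pooled_se: float
    pvalue: float
    q_stat: float
    df: int
    i2: float  # percent
    tau2: float
    model: str  # "fixed" or "random"
    k: int

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_beta)


def _pool(betas: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    sw = float(np.sum(weights))
    return float(np.sum(weights * betas) / sw), 1.0 / math.sqrt(sw)


def meta_fixed(estimates: list[CohortEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling."""
    if not estimates:
        raise ValueError("need at least one cohort estimate")
    b = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled, se = _pool(b, w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(estimates) - 1
    return MetaResult(
        pooled_beta=pooled, pooled_se=se,
        pvalue=float(2.0 * stats.norm.sf(abs(pooled / se))),
        q_stat=q, df=df, i2=i_squared(q, df) if df >= 1 else 0.0,
        tau2=0.0, model="fixed", k=len(estimates))


def meta_random_dl(estimates: list[CohortEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    ``τ² = max(0, (Q − df) / (Σw − Σw²/Σw))`` from the fixed-effect Q;
    cohort weights are then ``1/(se² + τ²)``.
    """
    if len(estimates) < 2:
        raise ValueError("random-effects pooling needs at least two cohorts")
    fixed = meta_fixed(estimates)
    b = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (fixed.q_stat - fixed.df) / c) if c > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in estimates]) + tau2)
    pooled, se = _pool(b, w_star)
    return MetaResult(
        pooled_beta=pooled, pooled_se=se,
        pvalue=float(2.0 * stats.norm.sf(abs(pooled / se))),
        q_stat=fixed.q_stat, df=fixed.df, i2=fixed.i2,
        tau2=tau2, model="random", k=len(estimates))


def i_squared(q_stat: float, df: int) -> float:
    """Higgins I² in percent: ``max(0, (Q − df)/Q)·100``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if q_stat <= 0:
        return 0.0
    return max(0.0, (q_stat - df) / q_stat) * 100.0


def select_model(i2: float) -> str:
    """Random effects strictly above 50% heterogeneity, fixed otherwise."""
    return "random" if i2 > I2_RANDOM_THRESHOLD else "fixed"


def pool_cohorts(estimates: list[CohortEstimate]) -> MetaResult:
    """Pool with the model chosen by the I²>50% rule."""
    fixed = meta_fixed(estimates)
    if len(estimates) >= 2 and select_model(fixed.i2) == "random":
        return meta_random_dl(estimates)
    return fixed


def replication_verdict(meta: MetaResult, discovery: MREstimate,
                        alpha: float = 0.05) -> str:
    """``"pass"`` when the pooled estimate is significant and its sign agrees
    with the discovery estimate, else ``"fail"``."""
    same_sign = math.copysign(1.0, meta.pooled_beta) == math.copysign(1.0, discovery.beta)
    return "pass" if (meta.pvalue < alpha and same_sign) else "fail"
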