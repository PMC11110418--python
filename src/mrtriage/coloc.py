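"""Single-causal-variant Bayesian colocalization via approximate Bayes factors.

For a region covered by two traits' summary statistics, each SNP gets a
Wakefield approximate Bayes factor per trait; combining them under the
single-causal-variant assumption yields posterior probabilities for five
hypotheses — H0 no causal variant, H1/H2 a causal variant for one trait
only, H3 distinct causal variants, H4 a shared causal variant.  All
accumulation is in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .summary_io import SummaryDataset

PPH4_THRESHOLD = 0.8

#: Conventional prior SD of the true effect at a causal SNP, per trait type.
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2


@dataclass(frozen=True)
class ColocConfig:
    """Priors: p1/p2 — a SNP is causal for trait 1/2 only; p12 — for both."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = PRIOR_SD_QUANTITATIVE
    prior_sd_binary: float = PRIOR_SD_BINARY

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2, self.p12):
            if not (0.0 < p < 1.0):
                raise ValueError("priors must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")

    def prior_sd(self, trait_type: str) -> float:
        return self.prior_sd_binary if trait_type == "binary" else self.prior_sd_quant


@dataclass(frozen=True)
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int

    @property
    def pp(self) -> tuple[float, ...]:
        return (self.pp0, self.pp1, self.pp2, self.pp3, self.pp4)


def abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for association at one SNP.

    With V = se², W = prior_sd², z = beta/se:
    ``log ABF = ½·log(V/(V+W)) + z²·W / (2(V+W))``.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    V = se * se
    W = prior_sd * prior_sd
    z = beta / se
    return 0.5 * math.log(V / (V + W)) + z * z * W / (2.0 * (V + W))


def coloc_abf(ds1: SummaryDataset, ds2: SummaryDataset,
              config: ColocConfig | None = None) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Only variants present in both datasets enter.  The per-trait prior
    effect SD follows each dataset's trait type.
    """
    config = config or ColocConfig()
    shared = sorted(set(ds1.records) & set(ds2.records))
    if len(shared) < 1:
        raise ValueError("no shared variants between the two datasets")
    sd1 = config.prior_sd(ds1.study.trait_type)
    sd2 = config.prior_sd(ds2.study.trait_type)
    l1 = np.array([abf(ds1.records[v].beta, ds1.records[v].se, sd1) for v in shared])
    l2 = np.array([abf(ds2.records[v].beta, ds2.records[v].se, sd2) for v in shared])

    lsum1 = float(logsumexp(l1))          # log Σ B1_j
    lsum2 = float(logsumexp(l2))          # log Σ B2_j
    lsum12 = float(logsumexp(l1 + l2))    # log Σ B1_j·B2_j
    # log(Σ_j Σ_{k≠j} B1_j B2_k) = log(ΣB1·ΣB2 − ΣB1B2), guarded in log space
    both = lsum1 + lsum2
    if len(shared) == 1 or both <= lsum12:
        lh3 = -math.inf
    else:
        lh3 = both + math.log1p(-math.exp(lsum12 - both))

    lp = [
        0.0,
        math.log(config.p1) + lsum1,
        math.log(config.p2) + lsum2,
        math.log(config.p1) + math.log(config.p2) + lh3 if math.isfinite(lh3) else -math.inf,
        math.log(config.p12) + lsum12,
    ]
    norm = logsumexp(lp)
    pp = np.exp(np.array(lp) - norm)
    return ColocResult(pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
                       pp3=float(pp[3]), pp4=float(pp[4]), n_snps=len(shared))


def coloc_pass(result: ColocResult, threshold: float = PPH4_THRESHOLD) -> bool:
    """Shared-causal-variant verdict: PPH4 strictly above the threshold."""
    return result.pp4 > threshold
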