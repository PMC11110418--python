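"""Causal-direction checks: the Steiger test, reverse MR, and the exclusion rule.

A protein→disease estimate is trusted only when the instruments explain more
variance in the protein than in the disease (Steiger) and the disease does
not show an MR effect on the protein in the reverse direction.  A protein is
excluded only when BOTH checks point the wrong way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .summary_io import SummaryDataset
from .instruments import HarmonizedInstrument, harmonize
from .mr_estimators import (
    MREstimate, choose_estimate, egger, ivw, mr_presso, mr_raps,
    wald_ratio, weighted_median, InsufficientInstrumentsError, EstimationError,
)

GENOME_WIDE_P = 5e-8
REVERSE_ALPHA = 0.01  # Bonferroni-style threshold for reverse-direction MR


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    z_stat: float
    pvalue: float
    direction_ok: bool


@dataclass(frozen=True)
class ReverseMRResult:
    estimate: MREstimate | None
    significant: bool
    status: str  # "tested" or "untestable"


def snp_r2(beta: float, se: float, n: int) -> float:
    """Variance in a trait explained by one variant, from its z-statistic.

    ``r² = z² / (z² + n − 2)`` — usable for binary traits where allele
    frequencies may be missing.
    """
    if n <= 2:
        raise ValueError("n must exceed 2")
    if se <= 0:
        raise ValueError("se must be > 0")
    z2 = (beta / se) ** 2
    return z2 / (z2 + n - 2)


def instruments_r2(instr: list[HarmonizedInstrument], n_exp: int,
                   n_out: int) -> tuple[float, float]:
    """Summed per-instrument r² on each side, assuming post-clumping
    independence."""
    r2x = sum(snp_r2(i.bx, i.sx, n_exp) for i in instr)
    r2y = sum(snp_r2(i.by, i.sy, n_out) for i in instr)
    return min(r2x, 1.0 - 1e-12), min(r2y, 1.0 - 1e-12)


def steiger_test(r2_exp: float, r2_out: float, n_exp: int, n_out: int,
                 alpha: float = 0.05) -> SteigerResult:
    """Compare variance explained in exposure vs outcome via Fisher's z.

    ``direction_ok`` requires both the correct ordering (more variance in
    the exposure) and a significant difference.
    """
    for r2 in (r2_exp, r2_out):
        if not (0.0 <= r2 < 1.0):
            raise ValueError("r² must lie in [0, 1)")
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3")
    zx = math.atanh(math.sqrt(r2_exp))
    zy = math.atanh(math.sqrt(r2_out))
    se = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (zx - zy) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(r2_exposure=r2_exp, r2_outcome=r2_out, z_stat=z,
                         pvalue=p, direction_ok=(r2_exp > r2_out and p < alpha))


def run_estimator_suite(instr: list[HarmonizedInstrument], seed: int = 0,
                        n_boot: int = 1000, n_sim: int = 1000) -> dict[str, MREstimate]:
    """Run every estimator the instrument count allows; keys are method names."""
    out: dict[str, MREstimate] = {}
    if len(instr) == 0:
        return out
    if len(instr) == 1:
        out["wald_ratio"] = wald_ratio(instr[0])
        return out
    out["ivw"] = ivw(instr)
    try:
        out["mr_raps"] = mr_raps(instr)
    except EstimationError:
        pass
    if len(instr) >= 3:
        out["egger"] = egger(instr)
        out["weighted_median"] = weighted_median(instr, n_boot=n_boot, seed=seed)
    if len(instr) >= 4:
        try:
            out["mr_presso"] = mr_presso(instr, n_sim=n_sim, seed=seed)
        except EstimationError:
            pass
    return out


def reverse_mr(outcome_as_exposure: SummaryDataset,
               protein_as_outcome: SummaryDataset,
               p_max: float = GENOME_WIDE_P,
               alpha: float = REVERSE_ALPHA,
               seed: int = 0) -> ReverseMRResult:
    """MR in the disease→protein direction.

    Instruments are the disease GWAS's genome-wide-significant variants;
    the selected estimate is called significant below ``alpha`` (a
    multiple-comparison-corrected threshold).  With no usable instruments
    the protein is 'untestable' and counts as not significant.
    """
    sig = outcome_as_exposure.subset(
        v for v, r in outcome_as_exposure.records.items() if r.pvalue < p_max)
    if len(sig) == 0:
        return ReverseMRResult(estimate=None, significant=False, status="untestable")
    harm, _ = harmonize(sig, protein_as_outcome)
    if len(harm) == 0:
        return ReverseMRResult(estimate=None, significant=False, status="untestable")
    suite = run_estimator_suite(harm, seed=seed)
    est = choose_estimate(suite)
    return ReverseMRResult(estimate=est, significant=bool(est.pvalue < alpha),
                           status="tested")


def exclusion_rule(steiger: SteigerResult, reverse_significant: bool) -> str:
    """Reverse-causality exclusion: drop a protein only when the Steiger test
    fails AND reverse MR is significant.  Returns ``"keep"`` or ``"excluded"``.
    """
    if (not steiger.direction_ok) and reverse_significant:
        return "excluded"
    return "keep"
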