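"""Two-sample MR estimators, the estimator-preference policy and FDR control.

The suite covers the Wald ratio (single instrument), multiplicative
random-effects IVW, MR-Egger regression, the weighted median, MR-PRESSO
outlier detection with outlier-corrected re-estimation, and the robust
adjusted profile score (RAPS).  ``choose_estimate`` encodes the preference
policy: IVW by default; Egger when the Egger intercept signals directional
pleiotropy; the MR-PRESSO-corrected estimate when the global test finds
outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .summary_io import ci_from_beta
from .instruments import HarmonizedInstrument


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class EstimationError(RuntimeError):
    """The estimator could not produce a usable estimate."""


@dataclass
class MREstimate:
    """A causal-effect estimate (log-OR per SD of exposure) with diagnostics."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    outlier_ids: tuple[str, ...] | None = None
    fdr_q: float | None = None
    selection_reason: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def or_ci(self, level: float = 0.95) -> tuple[float, float, float]:
        return ci_from_beta(self.beta, self.se, level)


def _two_sided_p(z: float) -> float:
    # floor guards against underflow to exactly 0 at extreme z
    return float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))


def _arrays(instr: list[HarmonizedInstrument]):
    bx = np.array([i.bx for i in instr], dtype=float)
    sx = np.array([i.sx for i in instr], dtype=float)
    by = np.array([i.by for i in instr], dtype=float)
    sy = np.array([i.sy for i in instr], dtype=float)
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate ``by / bx``.

    First-order SE ``sy/|bx|`` by default; ``second_order`` adds the
    delta-method term for uncertainty in the exposure effect.
    """
    if inst.bx == 0:
        raise ValueError("wald ratio undefined for bx = 0")
    beta = inst.by / inst.bx
    if second_order:
        se = math.sqrt(inst.sy**2 / inst.bx**2
                       + inst.by**2 * inst.sx**2 / inst.bx**4)
    else:
        se = inst.sy / abs(inst.bx)
    return MREstimate(method="wald_ratio", beta=beta, se=se,
                      pvalue=_two_sided_p(beta / se), n_snp=1)


def ivw(instr: list[HarmonizedInstrument],
        scale_overdispersion: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of by on bx
    through the origin with weights ``1/sy²``.

    With ``scale_overdispersion`` the SE is inflated by
    ``max(1, √(Q/(J−1)))`` — the multiplicative random-effects model.
    """
    if len(instr) < 2:
        raise InsufficientInstrumentsError("IVW needs ≥2 instruments")
    bx, _, by, sy = _arrays(instr)
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w) / denom)
    se = 1.0 / math.sqrt(denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = len(instr) - 1
    if scale_overdispersion:
        se *= max(1.0, math.sqrt(q / df))
    return MREstimate(method="ivw", beta=beta, se=se,
                      pvalue=_two_sided_p(beta / se), n_snp=len(instr),
                      q_stat=q, q_pvalue=float(stats.chi2.sf(q, df)))


def egger(instr: list[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Instruments are first oriented so every bx ≥ 0 (both signs flipped);
    the slope is the pleiotropy-adjusted causal estimate, the intercept
    estimates the average directional pleiotropic effect.
    """
    if len(instr) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs ≥3 instruments")
    bx, _, by, sy = _arrays(instr)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x, y = bx * flip, by * flip
    w = 1.0 / sy**2
    # closed-form weighted least squares for [intercept, slope]
    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("degenerate design in Egger regression")
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = y - a - b * x
    df = len(instr) - 2
    q = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q / df))  # multiplicative overdispersion
    se_a = math.sqrt(swxx / det) * scale
    se_b = math.sqrt(sw / det) * scale
    return MREstimate(
        method="egger", beta=float(b), se=float(se_b),
        pvalue=_two_sided_p(b / se_b), n_snp=len(instr),
        q_stat=q, q_pvalue=float(stats.chi2.sf(q, df)),
        egger_intercept=float(a), egger_intercept_se=float(se_a),
        egger_intercept_p=_two_sided_p(a / se_a))


def weighted_median(instr: list[HarmonizedInstrument], n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of the per-instrument Wald ratios.

    Consistent when instruments carrying ≥50% of the weight are valid.
    The SE comes from a seeded parametric bootstrap (``n_boot`` draws of
    (bx, by) from their sampling normals); ``n_boot=0`` skips it and
    reports NaN SE/p, which is useful in large bias simulations.
    """
    if len(instr) < 3:
        raise InsufficientInstrumentsError("weighted median needs ≥3 instruments")
    bx, sx, by, sy = _arrays(instr)
    est = _wmedian_point(bx, by, sy)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for r in range(n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            reps[r] = _wmedian_point(bxs, bys, sy)
        se = float(np.std(reps, ddof=1))
        p = _two_sided_p(est / se) if se > 0 else float("nan")
    else:
        se, p = float("nan"), float("nan")
    return MREstimate(method="weighted_median", beta=est, se=se, pvalue=p,
                      n_snp=len(instr))


def _wmedian_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    ratios = by / bx
    w = bx**2 / sy**2
    order = np.argsort(ratios)
    ratios, w = ratios[order], w[order]
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, ratios))


def mr_presso(instr: list[HarmonizedInstrument], n_sim: int = 1000,
              seed: int = 0, outlier_alpha: float = 0.05) -> MREstimate:
    """MR-PRESSO: simulation-based residual-sum-of-squares outlier test.

    Observed RSS uses leave-one-out IVW predictions; the null distribution
    comes from ``n_sim`` parametric draws.  Per-instrument outlier p-values
    are Bonferroni-corrected; the returned estimate is IVW on the
    non-outliers (the uncorrected IVW when no outliers are found).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if len(instr) < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs ≥4 instruments")
    bx, sx, by, sy = _arrays(instr)
    J = len(instr)
    w = 1.0 / sy**2
    # leave-one-out IVW slopes
    num, den = np.sum(bx * by * w), np.sum(bx**2 * w)
    beta_loo = (num - bx * by * w) / (den - bx**2 * w)
    yhat = beta_loo * bx
    obs_res = w * (by - yhat) ** 2
    rss_obs = float(np.sum(obs_res))

    rng = np.random.default_rng(seed)
    by_star = rng.normal(yhat, sy, size=(n_sim, J))
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    # recompute the leave-one-out statistic on every simulated dataset so the
    # null distribution mirrors the observed one
    num_s = np.sum(bx_star * by_star * w, axis=1, keepdims=True)
    den_s = np.sum(bx_star**2 * w, axis=1, keepdims=True)
    beta_loo_s = (num_s - bx_star * by_star * w) / (den_s - bx_star**2 * w)
    sim_res = w * (by_star - beta_loo_s * bx_star) ** 2
    rss_star = sim_res.sum(axis=1)
    global_p = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)

    per_snp_p = (1.0 + (sim_res >= obs_res).sum(axis=0)) / (n_sim + 1.0)
    corrected = np.minimum(per_snp_p * J, 1.0)  # Bonferroni
    out_mask = corrected < outlier_alpha
    outlier_ids = tuple(instr[j].variant_id for j in np.flatnonzero(out_mask))
    keep = [inst for inst, o in zip(instr, out_mask) if not o]
    if len(keep) == 0:
        raise EstimationError("MR-PRESSO flagged every instrument as an outlier")
    if len(keep) >= 2:
        base = ivw(keep)
    else:
        base = wald_ratio(keep[0])
    return replace(base, method="mr_presso", presso_global_p=global_p,
                   outlier_ids=outlier_ids)


def mr_raps(instr: list[HarmonizedInstrument],
            overdispersion: bool = False) -> MREstimate:
    """Adjusted profile score estimate.

    Solves the profile-likelihood score equation
    ``Σ (by − θ·bx)·(bx·sy² + θ·by·sx²) / (sy² + θ²·sx²)² = 0``
    by bracketed root search on [−10, 10].  The score is unbiased under
    exposure-side measurement error (the source of weak-instrument dilution
    in IVW) and reduces to the IVW normal equation when sx → 0.  The SE is
    the observed-information value ``1/√(−ψ'(θ̂))``, which likewise reduces
    to the fixed-effect IVW SE in that limit.
    """
    if len(instr) < 2:
        raise InsufficientInstrumentsError("RAPS needs ≥2 instruments")
    bx, sx, by, sy = _arrays(instr)

    def psi(theta: float) -> float:
        v = sy**2 + theta**2 * sx**2
        return float(np.sum((by - theta * bx) * (bx * sy**2 + theta * by * sx**2) / v**2))

    def dpsi(theta: float, h: float = 1e-6) -> float:
        return (psi(theta + h) - psi(theta - h)) / (2.0 * h)

    # bracket around the IVW solution (the score decays at large |θ|, so a
    # fixed wide bracket can miss the sign change)
    t0 = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    lo = hi = t0
    step = 0.1
    while psi(lo) * psi(hi) >= 0 and step < 20.0:
        lo, hi = max(t0 - step, -10.0), min(t0 + step, 10.0)
        step *= 2.0
    if psi(lo) * psi(hi) > 0:
        raise EstimationError("profile score has no sign change on [-10, 10]")
    theta = float(optimize.brentq(psi, lo, hi, xtol=1e-12))
    info = -dpsi(theta)
    if info <= 0:
        raise EstimationError("non-positive observed information")
    se = 1.0 / math.sqrt(info)
    if overdispersion:
        v = sy**2 + theta**2 * sx**2
        resid2 = (by - theta * bx) ** 2 / v
        scale = max(1.0, float(np.mean(resid2)))
        se *= math.sqrt(scale)
    return MREstimate(method="mr_raps", beta=theta, se=se,
                      pvalue=_two_sided_p(theta / se), n_snp=len(instr))


# ---------------------------------------------------------------------------
# Policy, multiplicity, reporting scale
# ---------------------------------------------------------------------------

def choose_estimate(candidates: dict[str, MREstimate],
                    alpha: float = 0.05) -> MREstimate:
    """Estimator-preference policy.

    MR-PRESSO-corrected when the global test is significant and outliers
    were found; otherwise Egger when its intercept indicates directional
    pleiotropy; otherwise IVW (or the Wald ratio for single-instrument
    proteins).  The selection reason is recorded on the returned estimate.
    """
    presso = candidates.get("mr_presso")
    if (presso is not None and presso.presso_global_p is not None
            and presso.presso_global_p < alpha and presso.outlier_ids):
        return replace(presso, selection_reason="presso_global_significant")
    eg = candidates.get("egger")
    if (eg is not None and eg.egger_intercept_p is not None
            and eg.egger_intercept_p < alpha):
        return replace(eg, selection_reason="egger_intercept_significant")
    if "ivw" in candidates:
        return replace(candidates["ivw"], selection_reason="default_ivw")
    if "wald_ratio" in candidates:
        return replace(candidates["wald_ratio"], selection_reason="single_instrument_wald")
    raise ValueError("no IVW or Wald estimate among candidates")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg q-values (step-up FDR adjustment)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def beta_to_or(estimate: MREstimate, level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-OR estimate to ``(OR, lower, upper)``."""
    return estimate.or_ci(level)
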