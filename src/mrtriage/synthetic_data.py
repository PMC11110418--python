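"""Seeded generators of GWAS summary statistics with known ground truth.

These emulate the statistical structure of the real inputs a proteome-wide
MR triage consumes — cis-pQTL exposure panels, binary-outcome GWAS,
multi-cohort replication series, colocalization regions, TWAS weight sets
and PPI graphs — so every pipeline stage can be exercised against a known
truth.  Standard errors follow the usual GWAS approximations:
``sx = 1/√(2f(1−f)·N)`` for a standardized quantitative trait and
``sy = 1/√(2f(1−f)·N·v)`` for a binary trait with case-balance variance
factor v (0.25 for a balanced design).

Every generator is a pure function of its config, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import StudyMeta, SummaryDataset, VariantAssoc

#: z a variant needs for genome-wide significance (p < 5e-8 two-sided).
GENOME_WIDE_Z = 5.451652

#: Balanced case/control variance factor n_case·n_control/n².
BINARY_VARIANCE_FACTOR = 0.25

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for instrument / cohort simulations.

    Defaults mirror a well-powered plasma-pQTL discovery setting: tens of
    strong cis instruments measured in a proteomics cohort of several
    thousand and a disease GWAS of hundreds of thousands.
    """

    theta: float = 0.0               # true causal log-OR per SD of protein
    n_instruments: int = 50
    gamma_sd: float = 0.05           # spread of true instrument effects (SD units)
    eaf_range: tuple[float, float] = (0.1, 0.9)
    n_exposure: int = 7000
    n_outcome: int = 450000
    pleiotropy_frac: float = 0.0     # fraction of invalid instruments
    alpha_mean: float = 0.0          # directional pleiotropy mean
    alpha_sd: float = 0.0
    n_cohorts: int = 4
    tau: float = 0.0                 # between-cohort SD of the causal effect
    seed: int = 0
    target_z: float = 8.0            # expected exposure z of a simulated pQTL
    positive_gamma: bool = False     # orient all true effects positive
    # (directional pleiotropy is sign-coupled to the variant coding; a mix of
    # effect signs cancels it after Egger orientation, so recovery studies
    # simulate positively oriented instruments)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0,1]")
        if self.n_instruments < 1:
            raise ValueError("need at least one instrument")
        for s in (self.gamma_sd, self.alpha_sd, self.tau):
            if s < 0:
                raise ValueError("SD parameters must be >= 0")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("eaf_range must lie within (0,1)")


@dataclass(frozen=True)
class ColocScenarioConfig:
    """One colocalization scenario: which hypothesis holds and how strongly."""

    scenario: str = "H4"             # H0..H4
    n_snps_region: int = 100
    causal_z: float = 8.0            # marginal z at the causal SNP
    ld_rho: float = 0.0              # AR(1) LD decay
    n1: int = 7000
    n2: int = 450000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValueError(f"unknown scenario {self.scenario}")
        if self.scenario == "H3" and self.n_snps_region < 2:
            raise ValueError("H3 needs at least 2 SNPs")
        if self.causal_z < 0:
            raise ValueError("causal_z must be >= 0")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0,1)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    theta_true: float = 0.0
    invalid_instrument_ids: tuple[str, ...] = ()
    theta_per_cohort: tuple[float, ...] = ()
    causal_snp_ids: dict = field(default_factory=dict)


def _draw_alleles(rng: np.random.Generator, n: int,
                  allow_palindromic: bool = False) -> tuple[np.ndarray, np.ndarray]:
    ea = _BASES[rng.integers(0, 4, size=n)]
    oa = np.empty(n, dtype=ea.dtype)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for i, a in enumerate(ea):
        choices = [b for b in "ACGT" if b != a]
        if not allow_palindromic:
            choices = [b for b in choices if b != comp[a]]
        oa[i] = choices[rng.integers(0, len(choices))]
    return ea, oa


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def simulate_instruments(
    config: SimulationConfig,
    protein_id: str = "PROT",
    outcome_id: str = "DISEASE",
    chrom: str = "1",
    pos_start: int = 1_000_000,
    include_decoys: bool = False,
) -> tuple[SummaryDataset, SummaryDataset, TruthRecord]:
    """Simulate exposure (pQTL) and outcome GWAS records for one protein.

    True instrument effects γ_j are drawn with random sign and magnitude
    ``|γ_j| ~ N(μ, gamma_sd²)`` where μ is set so the expected exposure z
    (``γ/sx``) reaches ``target_z`` for every instrument — i.e. instruments
    arrive pre-selected at genome-wide significance.  An invalid fraction
    receives a direct (pleiotropic) outcome effect α_j ~ N(alpha_mean,
    alpha_sd²); outcome effects are ``θ·γ_j + α_j`` plus sampling noise.

    ``include_decoys`` appends an equal number of null sub-threshold
    variants for filter testing.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_instruments
    lo, hi = config.eaf_range
    eaf = rng.uniform(lo, hi, size=J)
    sx = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    sy = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome
                       * BINARY_VARIANCE_FACTOR)
    # magnitude floor so every instrument is genome-wide significant in expectation
    mu = max(3.0 * config.gamma_sd, config.target_z * float(np.max(sx)))
    sign = np.ones(J) if config.positive_gamma else rng.choice([-1.0, 1.0], size=J)
    gamma = sign * np.abs(rng.normal(mu, config.gamma_sd, size=J))

    n_invalid = int(round(config.pleiotropy_frac * J))
    invalid_idx = rng.choice(J, size=n_invalid, replace=False) if n_invalid else np.array([], dtype=int)
    alpha = np.zeros(J)
    if n_invalid:
        alpha[invalid_idx] = rng.normal(config.alpha_mean, config.alpha_sd, size=n_invalid)

    bx = rng.normal(gamma, sx)
    by = rng.normal(config.theta * gamma + alpha, sy)

    ea, oa = _draw_alleles(rng, J)
    ids = [f"{protein_id}_snp{j}" for j in range(J)]
    pos = pos_start + np.arange(J) * 5000

    exp = SummaryDataset(study=StudyMeta(
        trait_id=protein_id, trait_type="quantitative",
        cohort_label="sim_pqtl", n=config.n_exposure))
    out = SummaryDataset(study=StudyMeta(
        trait_id=outcome_id, trait_type="binary",
        cohort_label="sim_gwas", n=config.n_outcome))
    px = _two_sided_p(bx / sx)
    py = _two_sided_p(by / sy)
    for j in range(J):
        exp.add(VariantAssoc(
            variant_id=ids[j], chrom=chrom, pos=int(pos[j]),
            effect_allele=str(ea[j]), other_allele=str(oa[j]),
            eaf=float(eaf[j]), beta=float(bx[j]), se=float(sx[j]),
            pvalue=float(px[j]), n=config.n_exposure))
        out.add(VariantAssoc(
            variant_id=ids[j], chrom=chrom, pos=int(pos[j]),
            effect_allele=str(ea[j]), other_allele=str(oa[j]),
            eaf=float(eaf[j]), beta=float(by[j]), se=float(sy[j]),
            pvalue=float(py[j]), n=config.n_outcome))

    if include_decoys:
        eafd = rng.uniform(lo, hi, size=J)
        sxd = 1.0 / np.sqrt(2.0 * eafd * (1.0 - eafd) * config.n_exposure)
        syd = 1.0 / np.sqrt(2.0 * eafd * (1.0 - eafd) * config.n_outcome
                            * BINARY_VARIANCE_FACTOR)
        bxd = rng.normal(0.0, sxd)
        byd = rng.normal(0.0, syd)
        ead, oad = _draw_alleles(rng, J)
        for j in range(J):
            vid = f"{protein_id}_decoy{j}"
            p = int(pos_start + (J + j) * 5000)
            exp.add(VariantAssoc(
                variant_id=vid, chrom=chrom, pos=p,
                effect_allele=str(ead[j]), other_allele=str(oad[j]),
                eaf=float(eafd[j]), beta=float(bxd[j]), se=float(sxd[j]),
                pvalue=float(_two_sided_p(np.array([bxd[j] / sxd[j]]))[0]),
                n=config.n_exposure))
            out.add(VariantAssoc(
                variant_id=vid, chrom=chrom, pos=p,
                effect_allele=str(ead[j]), other_allele=str(oad[j]),
                eaf=float(eafd[j]), beta=float(byd[j]), se=float(syd[j]),
                pvalue=float(_two_sided_p(np.array([byd[j] / syd[j]]))[0]),
                n=config.n_outcome))

    truth = TruthRecord(theta_true=config.theta,
                        invalid_instrument_ids=tuple(ids[j] for j in sorted(invalid_idx)))
    return exp, out, truth


def simulate_cohorts(
    config: SimulationConfig,
    protein_id: str = "PROT",
    outcome_id: str = "DISEASE",
) -> tuple[list[tuple[SummaryDataset, SummaryDataset]], TruthRecord]:
    """Multi-cohort replication series with between-cohort heterogeneity.

    Cohort k draws its causal effect θ_k ~ N(theta, tau²); true instrument
    effects γ_j are shared across cohorts while sampling noise is
    independent.
    """
    if config.n_cohorts < 1:
        raise ValueError("need at least one cohort")
    rng = np.random.default_rng(config.seed)
    thetas = rng.normal(config.theta, config.tau, size=config.n_cohorts) \
        if config.tau > 0 else np.full(config.n_cohorts, config.theta)
    # shared instrument structure: derive per-cohort seeds from the master rng
    sub_seeds = rng.integers(0, 2**31 - 1, size=config.n_cohorts)
    base = replace(config, seed=int(sub_seeds[0]))
    pairs = []
    # draw the shared gammas once using the base config's rng stream
    rng0 = np.random.default_rng(base.seed)
    lo, hi = config.eaf_range
    J = config.n_instruments
    eaf = rng0.uniform(lo, hi, size=J)
    sx = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    sy = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome
                       * BINARY_VARIANCE_FACTOR)
    mu = max(3.0 * config.gamma_sd, config.target_z * float(np.max(sx)))
    sign = rng0.choice([-1.0, 1.0], size=J)
    gamma = sign * np.abs(rng0.normal(mu, config.gamma_sd, size=J))
    ea, oa = _draw_alleles(rng0, J)
    ids = [f"{protein_id}_snp{j}" for j in range(J)]

    for k in range(config.n_cohorts):
        rngk = np.random.default_rng(int(sub_seeds[k]) + 10**6)
        bx = rngk.normal(gamma, sx)
        by = rngk.normal(thetas[k] * gamma, sy)
        exp = SummaryDataset(study=StudyMeta(
            trait_id=protein_id, trait_type="quantitative",
            cohort_label=f"cohort{k}_pqtl", n=config.n_exposure))
        out = SummaryDataset(study=StudyMeta(
            trait_id=outcome_id, trait_type="binary",
            cohort_label=f"cohort{k}_gwas", n=config.n_outcome))
        px = _two_sided_p(bx / sx)
        py = _two_sided_p(by / sy)
        for j in range(J):
            common = dict(variant_id=ids[j], chrom="1", pos=1_000_000 + j * 5000,
                          effect_allele=str(ea[j]), other_allele=str(oa[j]),
                          eaf=float(eaf[j]))
            exp.add(VariantAssoc(beta=float(bx[j]), se=float(sx[j]),
                                 pvalue=float(px[j]), n=config.n_exposure, **common))
            out.add(VariantAssoc(beta=float(by[j]), se=float(sy[j]),
                                 pvalue=float(py[j]), n=config.n_outcome, **common))
        pairs.append((exp, out))

    truth = TruthRecord(theta_true=config.theta,
                        theta_per_cohort=tuple(float(t) for t in thetas))
    return pairs, truth


def simulate_coloc_region(
    config: ColocScenarioConfig,
    trait1_id: str = "PROT",
    trait2_id: str = "DISEASE",
) -> tuple[SummaryDataset, SummaryDataset, TruthRecord]:
    """A regional dataset pair under one colocalization hypothesis.

    LD is AR(1) with parameter ``ld_rho``; the marginal z-score mean is
    ``Σ·λ`` with λ placing ``causal_z`` at the causal index (shared for H4,
    distinct for H3, single-trait for H1/H2, absent for H0); observed
    z ~ MVN(mean, Σ); ``beta = z·se`` with ``se = 1/√n``.
    """
    rng = np.random.default_rng(config.seed)
    M = config.n_snps_region
    idx = np.arange(M)
    sigma = config.ld_rho ** np.abs(idx[:, None] - idx[None, :])

    causal: dict[str, list[str]] = {trait1_id: [], trait2_id: []}
    lam1 = np.zeros(M)
    lam2 = np.zeros(M)
    ids = [f"region_snp{j}" for j in range(M)]
    if config.scenario in ("H1", "H3", "H4"):
        c1 = int(rng.integers(0, M))
        lam1[c1] = config.causal_z
        causal[trait1_id].append(ids[c1])
    if config.scenario in ("H2", "H4"):
        c2 = c1 if config.scenario == "H4" else int(rng.integers(0, M))
        lam2[c2] = config.causal_z
        causal[trait2_id].append(ids[c2])
    if config.scenario == "H3":
        c2 = int(rng.integers(0, M - 1))
        if c2 >= c1:
            c2 += 1  # distinct from trait 1's causal SNP
        lam2[c2] = config.causal_z
        causal[trait2_id].append(ids[c2])

    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(M))
    z1 = sigma @ lam1 + chol @ rng.standard_normal(M)
    z2 = sigma @ lam2 + chol @ rng.standard_normal(M)
    se1 = 1.0 / np.sqrt(config.n1)
    se2 = 1.0 / np.sqrt(config.n2)

    ea, oa = _draw_alleles(rng, M)
    ds1 = SummaryDataset(study=StudyMeta(
        trait_id=trait1_id, trait_type="quantitative", cohort_label="sim", n=config.n1))
    ds2 = SummaryDataset(study=StudyMeta(
        trait_id=trait2_id, trait_type="binary", cohort_label="sim", n=config.n2))
    p1 = _two_sided_p(z1)
    p2 = _two_sided_p(z2)
    for j in range(M):
        common = dict(variant_id=ids[j], chrom="1", pos=2_000_000 + j * 1000,
                      effect_allele=str(ea[j]), other_allele=str(oa[j]),
                      eaf=0.5)
        ds1.add(VariantAssoc(beta=float(z1[j] * se1), se=float(se1),
                             pvalue=float(p1[j]), n=config.n1, **common))
        ds2.add(VariantAssoc(beta=float(z2[j] * se2), se=float(se2),
                             pvalue=float(p2[j]), n=config.n2, **common))
    return ds1, ds2, TruthRecord(causal_snp_ids=causal)


def simulate_twas_weights(
    M: int,
    h2: float = 0.1,
    causal: bool = True,
    seed: int = 0,
    effect: float = 8.0,
    sparsity: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prediction weights, GWAS z-scores and an LD matrix for one gene.

    A sparse weight vector (about ``sparsity·M`` non-zero entries scaled to
    total weight variance ``h2``) and GWAS z drawn around ``Σ·w·effect``
    when the gene truly affects the trait, around 0 otherwise.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.zeros(M)
    nz = max(1, int(round(sparsity * M)))
    pick = rng.choice(M, size=nz, replace=False)
    w[pick] = rng.normal(0.0, 1.0, size=nz)
    w *= np.sqrt(h2 / np.sum(w**2))
    ld = np.eye(M)
    mean = ld @ w * effect if causal else np.zeros(M)
    z = mean + rng.standard_normal(M)
    return w, z, ld


def simulate_ppi_graph(
    n_nodes: int,
    n_drug_targets: int,
    edge_density: float,
    seed: int = 0,
    score_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[pd.DataFrame, set[str]]:
    """Random scored PPI edge list plus the drug-target node subset.

    Node labels are ``prot0..`` with the first ``n_drug_targets`` designated
    drug targets; each unordered pair carries an edge with probability
    ``edge_density`` and a Uniform(score_range) interaction score.
    """
    if n_drug_targets > n_nodes:
        raise ValueError("more drug targets than nodes")
    if not (0.0 <= edge_density <= 1.0):
        raise ValueError("edge_density must be in [0,1]")
    rng = np.random.default_rng(seed)
    nodes = [f"prot{i}" for i in range(n_nodes)]
    targets = set(nodes[:n_drug_targets])
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_density:
                rows.append((nodes[i], nodes[j],
                             float(rng.uniform(*score_range))))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"]), targets
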