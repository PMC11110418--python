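"""End-to-end orchestration: discovery → direction checks → replication
meta-analysis → colocalization → external validation → PPI → tier grading.

`run_discovery` screens a panel of proteins against one outcome with the
full estimator suite and per-outcome FDR control; `run_full` carries the
FDR-significant set through every evidence layer and grades it.
`build_synthetic_study` assembles a complete simulated study with planted
ground truth for end-to-end testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .summary_io import SummaryDataset
from .instruments import (GeneLocus, HarmonizedInstrument, harmonize,
                          ld_clump, select_instruments)
from .mr_estimators import MREstimate, bh_fdr, choose_estimate
from .directionality import (ReverseMRResult, exclusion_rule, instruments_r2,
                             reverse_mr, run_estimator_suite, steiger_test)
from .meta import CohortEstimate, MetaResult, pool_cohorts, replication_verdict
from .coloc import ColocConfig, coloc_abf
from .tiering import (EvidenceProfile, ExternalValidation, assign_tier,
                      external_validation_verdict, ppi_linked, twas_assoc)
from . import synthetic_data as sim

logger = logging.getLogger("mrtriage")


@dataclass(frozen=True)
class RunParams:
    """Thresholds and knobs for a full run; defaults are the study settings."""

    p_max: float = 5e-8
    cis_window: int = 1_000_000
    r2_max: float = 0.001
    palindrome_eaf_margin: float = 0.42
    fdr_alpha: float = 0.05
    policy_alpha: float = 0.05
    reverse_alpha: float = 0.01
    meta_alpha: float = 0.05
    pph4_threshold: float = 0.8
    external_q_max: float = 0.05
    ias_min_score: float = 0.4
    n_boot: int = 200
    n_sim: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ProteinInput:
    """Discovery-side inputs for one protein."""

    protein_id: str
    exposure: SummaryDataset
    locus: GeneLocus
    ld: pd.DataFrame | None = None


@dataclass
class StudyData:
    """Everything a full triage run consumes."""

    proteins: list[ProteinInput]
    outcome: SummaryDataset
    outcome_id: str
    replication: dict = field(default_factory=dict)   # protein -> [(exp, out)] per cohort
    coloc_regions: dict = field(default_factory=dict)  # protein -> (ds1, ds2)
    twas: dict = field(default_factory=dict)           # protein -> (weights, z, ld)
    reverse: dict = field(default_factory=dict)        # protein -> (disease_exp, protein_out)
    ppi_edges: pd.DataFrame | None = None
    drug_targets: set = field(default_factory=set)


def run_discovery(
    proteins: list[ProteinInput],
    outcome: SummaryDataset,
    params: RunParams = RunParams(),
) -> tuple[pd.DataFrame, dict[str, list[HarmonizedInstrument]], dict[str, str]]:
    """Screen a protein panel against one outcome.

    Per protein: instrument filters → LD clumping → harmonization → full
    estimator suite → preference policy; then BH-FDR across proteins for
    this outcome.  Returns the results table, the harmonized instruments
    per protein (reused by the Steiger step), and an audit of skipped
    proteins.
    """
    rows = []
    instruments: dict[str, list[HarmonizedInstrument]] = {}
    skipped: dict[str, str] = {}
    for pin in proteins:
        sel, audit = select_instruments(pin.exposure, pin.locus,
                                        p_max=params.p_max,
                                        cis_window=params.cis_window)
        sel = ld_clump(sel, pin.ld, r2_max=params.r2_max)
        harm, _ = harmonize(sel, outcome,
                            palindrome_eaf_margin=params.palindrome_eaf_margin)
        if len(harm) == 0:
            skipped[pin.protein_id] = "no_instruments"
            continue
        suite = run_estimator_suite(harm, seed=params.seed,
                                    n_boot=params.n_boot, n_sim=params.n_sim)
        est = choose_estimate(suite, alpha=params.policy_alpha)
        instruments[pin.protein_id] = harm
        or_, lo, hi = est.or_ci()
        rows.append({
            "protein": pin.protein_id,
            "outcome": outcome.study.trait_id,
            "n_snp": est.n_snp,
            "method": est.method,
            "selection_reason": est.selection_reason,
            "beta": est.beta, "se": est.se, "pvalue": est.pvalue,
            "or": or_, "or_lower": lo, "or_upper": hi,
            "q_stat": est.q_stat,
            "egger_intercept_p": suite.get("egger").egger_intercept_p if "egger" in suite else np.nan,
            "presso_global_p": suite.get("mr_presso").presso_global_p if "mr_presso" in suite else np.nan,
            "audit_cis": audit["cis"], "audit_significance": audit["significance"],
            "audit_mhc": audit["mhc"],
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr_q"] = bh_fdr(df["pvalue"])
        df["significant"] = df["fdr_q"] < params.fdr_alpha
        df = df.sort_values("protein", kind="stable").reset_index(drop=True)
    else:
        logger.warning("discovery produced an empty results table")
    return df, instruments, skipped


def run_full(
    study: StudyData,
    params: RunParams = RunParams(),
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full evidence triage of one outcome's protein panel.

    Returns ``(evidence profile table, tier table)`` and, when ``out_dir``
    is given, writes discovery/meta/tier TSVs plus plot-ready tables.
    """
    discovery, instruments, skipped = run_discovery(
        study.proteins, study.outcome, params)
    profiles = []
    if discovery.empty:
        return pd.DataFrame(), pd.DataFrame()
    sig = discovery[discovery["significant"]]

    # external validation q-values are FDR-adjusted jointly across proteins
    twas_stats: dict[str, tuple[float, float]] = {}
    for pid, (w, z, ld) in study.twas.items():
        try:
            twas_stats[pid] = twas_assoc(w, z, ld)
        except ValueError:
            continue
    twas_prots = sorted(twas_stats)
    if twas_prots:
        qs = bh_fdr([twas_stats[p][1] for p in twas_prots])
        twas_q = dict(zip(twas_prots, qs))
    else:
        twas_q = {}

    for _, row in sig.iterrows():
        pid = row["protein"]
        harm = instruments[pid]
        pin = next(p for p in study.proteins if p.protein_id == pid)

        r2x, r2y = instruments_r2(harm, pin.exposure.study.n, study.outcome.study.n)
        steiger = steiger_test(r2x, r2y, pin.exposure.study.n, study.outcome.study.n)
        if pid in study.reverse:
            rev = reverse_mr(*study.reverse[pid], alpha=params.reverse_alpha,
                             seed=params.seed)
        else:
            rev = ReverseMRResult(estimate=None, significant=False,
                                  status="untestable")
        keep = exclusion_rule(steiger, rev.significant) == "keep"

        disc_est = MREstimate(method=row["method"], beta=row["beta"],
                              se=row["se"], pvalue=row["pvalue"],
                              n_snp=int(row["n_snp"]))
        meta_res: MetaResult | None = None
        repl = "fail"
        if pid in study.replication and len(study.replication[pid]) >= 1:
            cohort_estimates = []
            for k, (exp_k, out_k) in enumerate(study.replication[pid]):
                harm_k, _ = harmonize(exp_k, out_k,
                                      palindrome_eaf_margin=params.palindrome_eaf_margin)
                if not harm_k:
                    continue
                suite_k = run_estimator_suite(harm_k, seed=params.seed,
                                              n_boot=0, n_sim=params.n_sim)
                est_k = choose_estimate(suite_k, alpha=params.policy_alpha)
                cohort_estimates.append(CohortEstimate(
                    cohort_label=exp_k.study.cohort_label,
                    beta=est_k.beta, se=est_k.se))
            if cohort_estimates:
                meta_res = pool_cohorts(cohort_estimates)
                repl = replication_verdict(meta_res, disc_est,
                                           alpha=params.meta_alpha)

        pph4 = 0.0
        if pid in study.coloc_regions:
            ds1, ds2 = study.coloc_regions[pid]
            pph4 = coloc_abf(ds1, ds2).pp4

        if pid in twas_q:
            ev = ExternalValidation(twas_z=twas_stats[pid][0],
                                    twas_q=float(twas_q[pid]))
        else:
            ev = ExternalValidation()
        ext = external_validation_verdict(ev, q_max=params.external_q_max)

        linked = False
        if study.ppi_edges is not None and len(study.ppi_edges):
            linked = ppi_linked(study.ppi_edges, pid, study.drug_targets,
                                min_score=params.ias_min_score)

        profiles.append({
            "protein": pid, "outcome": study.outcome_id,
            "beta": row["beta"], "fdr_q": row["fdr_q"],
            "steiger_p": steiger.pvalue, "steiger_keep": keep,
            "reverse_status": rev.status,
            "replication_pass": repl == "pass",
            "meta_or": meta_res.pooled_or if meta_res else np.nan,
            "meta_p": meta_res.pvalue if meta_res else np.nan,
            "meta_i2": meta_res.i2 if meta_res else np.nan,
            "meta_model": meta_res.model if meta_res else "NA",
            "coloc_pph4": pph4,
            "twas_z": twas_stats.get(pid, (np.nan, np.nan))[0],
            "twas_q": float(twas_q[pid]) if pid in twas_q else np.nan,
            "external_pass": ext == "pass",
            "ppi_linked": linked,
        })

    prof_df = pd.DataFrame(profiles)
    tier_rows = []
    for _, r in prof_df.iterrows():
        profile = EvidenceProfile(
            protein_id=r["protein"], outcome_id=r["outcome"],
            steiger_keep=bool(r["steiger_keep"]),
            replication_pass=bool(r["replication_pass"]),
            coloc_pph4=float(r["coloc_pph4"]),
            external_pass=bool(r["external_pass"]),
            ppi_linked=bool(r["ppi_linked"]),
            discovery_beta=float(r["beta"]), discovery_fdr_q=float(r["fdr_q"]))
        ta = assign_tier(profile, pph4_threshold=params.pph4_threshold)
        tier_rows.append({"protein": r["protein"], "outcome": r["outcome"],
                          "tier": ta.tier, "rationale": "; ".join(ta.rationale)})
    tier_df = pd.DataFrame(tier_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g")
        discovery.to_csv(out / "discovery.tsv", **kw)
        prof_df.to_csv(out / "evidence_profiles.tsv", **kw)
        tier_df.to_csv(out / "tiers.tsv", **kw)
        if not discovery.empty:
            volcano = discovery[["protein", "beta", "pvalue", "fdr_q"]]
            volcano.to_csv(out / "volcano.tsv", **kw)
    return prof_df, tier_df


# ---------------------------------------------------------------------------
# Synthetic full-study scenario
# ---------------------------------------------------------------------------

def build_synthetic_study(
    n_proteins: int = 20,
    planted: dict[str, float] | None = None,
    seed: int = 0,
    n_instruments: int = 12,
    n_cohorts: int = 4,
    planted_ppi: bool = True,
    planted_twas_effect: float = 20.0,
    outcome_id: str = "DISEASE",
) -> tuple[StudyData, dict]:
    """A complete synthetic study with planted causal targets.

    ``planted`` maps protein ids (``prot0..``) to true causal effects; all
    other proteins are null.  Planted proteins get a shared-causal-variant
    (H4) colocalization region, a truly associated TWAS gene, replication
    cohorts with the same causal effect, and (optionally) a strong PPI edge
    to a known drug target; null proteins get H0 regions, null TWAS and no
    planted edge.
    """
    planted = planted or {}
    rng = np.random.default_rng(seed)
    proteins: list[ProteinInput] = []
    outcome = None
    study = StudyData(proteins=proteins, outcome=None, outcome_id=outcome_id)
    merged_outcome_records = {}

    for i in range(n_proteins):
        pid = f"prot{i}"
        theta = planted.get(pid, 0.0)
        cfg = sim.SimulationConfig(theta=theta, n_instruments=n_instruments,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        pos0 = 1_000_000 + i * 10_000_000
        exp, out, _ = sim.simulate_instruments(cfg, protein_id=pid,
                                               outcome_id=outcome_id,
                                               chrom="1", pos_start=pos0)
        locus = GeneLocus(gene_id=pid, chrom="1", start=pos0,
                          end=pos0 + (n_instruments - 1) * 5000)
        proteins.append(ProteinInput(protein_id=pid, exposure=exp, locus=locus))
        merged_outcome_records.update(out.records)
        if i == 0:
            outcome = out

        # replication cohorts (same causal effect, fresh noise)
        ccfg = sim.SimulationConfig(theta=theta, n_instruments=n_instruments,
                                    n_cohorts=n_cohorts,
                                    seed=int(rng.integers(0, 2**31 - 1)))
        pairs, _ = sim.simulate_cohorts(ccfg, protein_id=pid, outcome_id=outcome_id)
        study.replication[pid] = pairs

        scen = "H4" if pid in planted else "H0"
        rcfg = sim.ColocScenarioConfig(
            scenario=scen, n_snps_region=60,
            causal_z=8.0 if pid in planted else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)))
        ds1, ds2, _ = sim.simulate_coloc_region(rcfg, trait1_id=pid,
                                                trait2_id=outcome_id)
        study.coloc_regions[pid] = (ds1, ds2)

        w, z, ld = sim.simulate_twas_weights(
            M=50, h2=0.2, causal=pid in planted,
            seed=int(rng.integers(0, 2**31 - 1)),
            effect=planted_twas_effect)
        study.twas[pid] = (w, z, ld)

    outcome = SummaryDataset(study=outcome.study, records=merged_outcome_records)
    study.outcome = outcome

    # PPI graph: drug targets drug0/drug1; planted proteins get a strong edge
    edges = [("drug0", "drug1", 0.9)]
    for pid in planted:
        if planted_ppi:
            edges.append((pid, "drug0", 0.9))
    for i in range(n_proteins):
        pid = f"prot{i}"
        if pid not in planted:
            edges.append((pid, f"prot{(i + 1) % n_proteins}", 0.2))
    study.ppi_edges = pd.DataFrame(edges, columns=["node_a", "node_b", "score"])
    study.drug_targets = {"drug0", "drug1"}

    truth = {"planted": dict(planted), "n_proteins": n_proteins}
    return study, truth
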