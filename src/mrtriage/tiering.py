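"""External validation (TWAS/PWAS), PPI drug-target linkage, and evidence tiers.

Each protein–outcome pair accumulates an evidence profile — discovery MR,
direction checks, replication meta-analysis, colocalization, external
TWAS/PWAS validation, and direct PPI linkage to known drug targets — and
is graded:

* Tier 1: colocalizes (PPH4 > 0.8), replicates, AND passes external
  TWAS/PWAS validation.
* Tier 2: directly linked to a known drug target in the PPI network AND
  validated by replication or external validation.
* Tier 3: colocalizes AND has any one of replication / external
  validation / PPI linkage.
* Tier 4: everything else.  Proteins failing the reverse-causality
  exclusion rule are 'excluded' before grading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coloc import PPH4_THRESHOLD

logger = logging.getLogger("mrtriage")

IAS_THRESHOLD = 0.4
EXTERNAL_Q_MAX = 0.05


@dataclass(frozen=True)
class ExternalValidation:
    """TWAS (tissue-level) and PWAS (protein-level) association evidence."""

    twas_z: float | None = None
    twas_q: float | None = None
    pwas_z: float | None = None
    pwas_q: float | None = None
    direction_concordant_twas: bool | None = None
    direction_concordant_pwas: bool | None = None

    def __post_init__(self) -> None:
        for q in (self.twas_q, self.pwas_q):
            if q is not None and not (0.0 < q <= 1.0):
                raise ValueError("q-values must lie in (0, 1]")


@dataclass(frozen=True)
class EvidenceProfile:
    """The complete per-protein dossier entering tier assignment.

    Missing evidence must be encoded as an explicit fail (False) — never
    None — so grading is total.
    """

    protein_id: str
    outcome_id: str
    steiger_keep: bool
    replication_pass: bool
    coloc_pph4: float
    external_pass: bool
    ppi_linked: bool
    discovery_beta: float | None = None
    discovery_fdr_q: float | None = None

    def validate(self) -> None:
        missing = [f for f in ("steiger_keep", "replication_pass",
                               "external_pass", "ppi_linked")
                   if getattr(self, f) is None]
        if self.coloc_pph4 is None or not (0.0 <= self.coloc_pph4 <= 1.0):
            missing.append("coloc_pph4")
        if missing:
            raise ValueError(f"incomplete evidence profile: missing {missing}")


@dataclass(frozen=True)
class TierAssignment:
    tier: str  # "1".."4" or "excluded"
    rationale: tuple[str, ...]


# ---------------------------------------------------------------------------
# TWAS / PWAS weighted-score association
# ---------------------------------------------------------------------------

def twas_assoc(weights: np.ndarray, gwas_z: np.ndarray,
               ld: np.ndarray) -> tuple[float, float]:
    """Weighted-score association: ``z = wᵀz / √(wᵀ·LD·w)``.

    The z of a predicted expression/protein score against the GWAS trait,
    built from prediction weights and SNP-level GWAS z-scores.
    Returns ``(z, two-sided p)``.
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    R = np.asarray(ld, dtype=float)
    if w.shape != z.shape or R.shape != (w.size, w.size):
        raise ValueError("dimension mismatch between weights, z and LD")
    denom2 = float(w @ R @ w)
    if denom2 <= 0:
        raise ValueError("degenerate weights: wᵀ·LD·w must be positive")
    zs = float(w @ z) / math.sqrt(denom2)
    return zs, float(2.0 * stats.norm.sf(abs(zs)))


def external_validation_verdict(ev: ExternalValidation,
                                q_max: float = EXTERNAL_Q_MAX,
                                require_direction: bool = False) -> str:
    """``"pass"`` when TWAS or PWAS is FDR-significant (optionally also
    direction-concordant); an absent study fails its branch."""
    def branch(q: float | None, concordant: bool | None) -> bool:
        if q is None or not (q < q_max):
            return False
        if require_direction and not bool(concordant):
            return False
        return True

    ok = branch(ev.twas_q, ev.direction_concordant_twas) or \
        branch(ev.pwas_q, ev.direction_concordant_pwas)
    return "pass" if ok else "fail"


# ---------------------------------------------------------------------------
# PPI linkage
# ---------------------------------------------------------------------------

def read_ppi_edges(path) -> pd.DataFrame:
    """3-column TSV: node, node, interaction score in [0,1]."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["node_a", "node_b", "score"])
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("PPI scores must lie in [0, 1]")
    return df


def ppi_linked(edges: pd.DataFrame, protein_id: str, drug_targets: set[str],
               min_score: float = IAS_THRESHOLD,
               allow_paths: bool = False) -> bool:
    """Is the protein connected to any known drug target?

    Default: a direct edge with interaction score ≥ ``min_score``.
    ``allow_paths`` accepts any path through edges above the threshold
    (non-default; tier definitions ask for direct linkage).
    """
    strong = edges[edges["score"] >= min_score]
    nodes = set(edges["node_a"]) | set(edges["node_b"])
    if protein_id not in nodes:
        logger.warning("protein %s absent from PPI graph", protein_id)
        return False
    if allow_paths:
        g = nx.Graph()
        g.add_edges_from(zip(strong["node_a"], strong["node_b"]))
        if protein_id not in g:
            return False
        reachable = nx.node_connected_component(g, protein_id)
        return bool(reachable & drug_targets - {protein_id})
    direct = strong[(strong["node_a"] == protein_id) |
                    (strong["node_b"] == protein_id)]
    partners = (set(direct["node_a"]) | set(direct["node_b"])) - {protein_id}
    return bool(partners & drug_targets)


# ---------------------------------------------------------------------------
# Tier assignment
# ---------------------------------------------------------------------------

def assign_tier(profile: EvidenceProfile,
                pph4_threshold: float = PPH4_THRESHOLD,
                tier3_requires_coloc: bool = True) -> TierAssignment:
    """Grade one protein–outcome profile into excluded / Tier 1–4.

    Rules are evaluated in order and the first match wins.  With
    ``tier3_requires_coloc`` (default) Tier 3 reads as PPH4 > threshold AND
    (replication OR external OR PPI); the alternative disjunctive reading
    additionally admits PPI-only proteins without colocalization.
    """
    profile.validate()
    coloc_ok = profile.coloc_pph4 > pph4_threshold
    rationale = [
        f"steiger_keep={profile.steiger_keep}",
        f"coloc_pass={coloc_ok} (pph4={profile.coloc_pph4:.4g})",
        f"replication_pass={profile.replication_pass}",
        f"external_pass={profile.external_pass}",
        f"ppi_linked={profile.ppi_linked}",
    ]
    if not profile.steiger_keep:
        return TierAssignment(tier="excluded", rationale=tuple(rationale + ["rule=excluded"]))
    if coloc_ok and profile.replication_pass and profile.external_pass:
        return TierAssignment(tier="1", rationale=tuple(rationale + ["rule=tier1"]))
    if profile.ppi_linked and (profile.replication_pass or profile.external_pass):
        return TierAssignment(tier="2", rationale=tuple(rationale + ["rule=tier2"]))
    any_support = profile.replication_pass or profile.external_pass or profile.ppi_linked
    if coloc_ok and any_support:
        return TierAssignment(tier="3", rationale=tuple(rationale + ["rule=tier3"]))
    if not tier3_requires_coloc and profile.ppi_linked:
        return TierAssignment(tier="3", rationale=tuple(rationale + ["rule=tier3_ppi_only"]))
    return TierAssignment(tier="4", rationale=tuple(rationale + ["rule=tier4_default"]))
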