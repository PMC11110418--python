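"""GWAS summary-statistic data model and TSV input/output.

Every downstream stage (instrument selection, MR estimation, colocalization)
operates on :class:`SummaryDataset` objects — collections of per-variant
association records for one trait in one cohort.  Effect sizes are log
odds ratios for binary traits and SD units for quantitative traits;
odds-ratio / confidence-interval conversions used to reconstruct standard
errors from published tables live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrtriage")

#: z quantile for a 95% interval, fixed to the conventional rounded value used
#: in published tables so CI reconstructions are stable.
Z_95 = 1.959964

VALID_ALLELES = frozenset("ACGT")

#: Default column names for summary TSVs written by this package.
DEFAULT_COLUMNS = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait.

    ``beta`` is on the log-odds scale for binary traits and in SD units for
    quantitative traits; ``pos`` is 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int
    eaf: float | None = None
    n_case: int | None = None
    n_control: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not (self.se > 0):
            problems.append("se must be > 0")
        if self.pos < 1:
            problems.append("pos must be >= 1")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append("eaf outside [0,1]")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        for a in (self.effect_allele, self.other_allele):
            if a not in VALID_ALLELES:
                problems.append(f"allele {a!r} not a single ACGT base")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append("pvalue outside (0,1]")
        return problems

    def pvalue_consistent(self, rtol: float = 1e-6) -> bool:
        """Check p against the two-sided normal p implied by beta/se.

        Published tables round, so callers treat a mismatch as a warning,
        never a rejection.
        """
        if self.se <= 0:
            return False
        implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if implied == 0.0:
            return self.pvalue <= 1e-300
        return math.isclose(self.pvalue, implied, rel_tol=rtol)


@dataclass(frozen=True)
class StudyMeta:
    """Identity of one summary-statistics study (trait + cohort)."""

    trait_id: str
    trait_type: str  # "quantitative" or "binary"
    cohort_label: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")


@dataclass
class SummaryDataset:
    """Summary statistics for one study: records keyed by variant id."""

    study: StudyMeta
    records: dict[str, VariantAssoc] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def add(self, rec: VariantAssoc) -> None:
        if rec.variant_id in self.records:
            raise ValueError(f"duplicate variant_id {rec.variant_id}")
        self.records[rec.variant_id] = rec

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        keep = {v: self.records[v] for v in variant_ids if v in self.records}
        return SummaryDataset(study=self.study, records=keep)

    def to_frame(self) -> pd.DataFrame:
        cols = list(DEFAULT_COLUMNS) + ["n_case", "n_control"]
        rows = [
            {c: getattr(r, c) for c in cols}
            for r in sorted(self.records.values(), key=lambda r: (r.chrom, r.pos, r.variant_id))
        ]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# TSV ingest / emit
# ---------------------------------------------------------------------------

def read_summary_table(
    path,
    study: StudyMeta,
    column_map: Mapping[str, str] | None = None,
) -> tuple[SummaryDataset, dict[str, int]]:
    """Read a summary-statistics TSV into a :class:`SummaryDataset`.

    ``column_map`` maps canonical field names (keys of ``DEFAULT_COLUMNS``)
    to the file's column names.  Rows violating record invariants are
    dropped and counted in the returned audit dict.

    Returns ``(dataset, audit)`` where ``audit`` holds per-reason drop counts.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype={cmap["chrom"]: str})
    audit: dict[str, int] = {"invalid": 0, "duplicate": 0, "inconsistent_p": 0}
    ds = SummaryDataset(study=study)
    if df.empty:
        logger.warning("empty summary table: %s", path)
        return ds, audit

    required = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "se", "pvalue", "n"]
    for canon in required:
        if cmap[canon] not in df.columns:
            raise ConfigurationError(
                f"column {cmap[canon]!r} (for {canon}) missing from {path}")

    has_eaf = cmap["eaf"] in df.columns
    has_ncase = cmap.get("n_case", "n_case") in df.columns
    has_nctrl = cmap.get("n_control", "n_control") in df.columns

    for _, row in df.iterrows():
        eaf = float(row[cmap["eaf"]]) if has_eaf and pd.notna(row[cmap["eaf"]]) else None
        rec = VariantAssoc(
            variant_id=str(row[cmap["variant_id"]]),
            chrom=str(row[cmap["chrom"]]),
            pos=int(row[cmap["pos"]]),
            effect_allele=str(row[cmap["effect_allele"]]).upper(),
            other_allele=str(row[cmap["other_allele"]]).upper(),
            beta=float(row[cmap["beta"]]),
            se=float(row[cmap["se"]]),
            pvalue=float(row[cmap["pvalue"]]),
            n=int(row[cmap["n"]]),
            eaf=eaf,
            n_case=int(row["n_case"]) if has_ncase and pd.notna(row.get("n_case")) else None,
            n_control=int(row["n_control"]) if has_nctrl and pd.notna(row.get("n_control")) else None,
        )
        problems = rec.validate()
        if problems:
            audit["invalid"] += 1
            logger.info("dropped %s: %s", rec.variant_id, "; ".join(problems))
            continue
        if rec.variant_id in ds.records:
            audit["duplicate"] += 1
            continue
        if not rec.pvalue_consistent():
            audit["inconsistent_p"] += 1  # warning only; record kept
        ds.add(rec)
    return ds, audit


def write_summary_table(ds: SummaryDataset, path) -> None:
    """Write a dataset as a TSV round-trippable by :func:`read_summary_table`.

    Floats are written with 17 significant digits so the round trip is
    lossless to 1e-12 relative tolerance.
    """
    df = ds.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# OR / CI <-> beta / SE conversions
# ---------------------------------------------------------------------------

def _z_quantile(level: float) -> float:
    if not (0.5 < level < 1.0):
        raise ValueError(f"confidence level must be in (0.5, 1): {level}")
    if level == 0.95:
        return Z_95
    return float(stats.norm.ppf(0.5 + level / 2.0))


def se_from_ci(lower_or: float, upper_or: float, level: float = 0.95) -> float:
    """Standard error of a log odds ratio from a published OR confidence interval.

    ``se = (ln upper − ln lower) / (2 z)``.
    """
    if lower_or <= 0 or upper_or <= 0:
        raise ValueError("CI bounds must be positive")
    if lower_or > upper_or:
        raise ValueError("lower bound exceeds upper bound")
    z = _z_quantile(level)
    return (math.log(upper_or) - math.log(lower_or)) / (2.0 * z)


def ci_from_beta(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with confidence bounds from a log-OR and its SE.

    Inverse of :func:`se_from_ci` on the SE.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    z = _z_quantile(level)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def beta_from_or_ci(or_: float, lower: float, upper: float,
                    level: float = 0.95) -> tuple[float, float]:
    """(log-OR, SE) reconstructed from a printed ``OR (lower, upper)`` cell."""
    if or_ <= 0:
        raise ValueError("OR must be positive")
    return math.log(or_), se_from_ci(lower, upper, level)
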