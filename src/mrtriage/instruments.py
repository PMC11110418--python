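"""cis-pQTL instrument selection, LD clumping and cross-dataset harmonization.

Instrument selection applies the standard cis-MR filters in order:
(1) cis window — within 1 Mb of the gene body; (2) genome-wide significance
p < 5e-8; (3) MHC exclusion (chr6:26–34 Mb); LD pruning to pairwise
r² < 0.001 is a separate greedy step.  Harmonization aligns outcome effects
to the exposure effect allele, resolving strand flips and dropping
ambiguous palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summary_io import SummaryDataset, VariantAssoc

logger = logging.getLogger("mrtriage")

GENOME_WIDE_P = 5e-8
CIS_WINDOW = 1_000_000
MHC_CHROM = "6"
MHC_START = 26_000_000
MHC_END = 34_000_000

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GeneLocus:
    """Gene body coordinates, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome-aligned instrument: the (bx, by) pair entering MR."""

    variant_id: str
    bx: float
    sx: float
    by: float
    sy: float
    effect_allele: str
    eaf: float | None = None
    flipped: bool = False


def read_loci(path) -> list[GeneLocus]:
    """Read gene loci from a BED-like TSV (0-based half-open start converted
    to 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"],
                     dtype={"chrom": str})
    return [
        GeneLocus(gene_id=str(r.gene_id), chrom=_norm_chrom(r.chrom),
                  start=int(r.start) + 1, end=int(r.end))
        for r in df.itertuples()
    ]


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def select_instruments(
    ds: SummaryDataset,
    locus: GeneLocus,
    p_max: float = GENOME_WIDE_P,
    cis_window: int = CIS_WINDOW,
    mhc: tuple[str, int, int] = (MHC_CHROM, MHC_START, MHC_END),
) -> tuple[SummaryDataset, dict[str, int]]:
    """Apply the cis / significance / MHC instrument filters in order.

    Returns the surviving subset and an audit dict counting records removed
    by each filter.  The cis interval is ``[start − cis_window,
    end + cis_window]`` closed; the MHC interval is closed; a record failing
    an earlier filter is not re-counted by later ones.
    """
    mhc_chrom, mhc_lo, mhc_hi = _norm_chrom(mhc[0]), mhc[1], mhc[2]
    lchrom = _norm_chrom(locus.chrom)
    lo = locus.start - cis_window
    hi = locus.end + cis_window
    audit = {"cis": 0, "significance": 0, "mhc": 0}
    keep: dict[str, VariantAssoc] = {}
    for rec in ds:
        if _norm_chrom(rec.chrom) != lchrom or not (lo <= rec.pos <= hi):
            audit["cis"] += 1
            continue
        if not (rec.pvalue < p_max):
            audit["significance"] += 1
            continue
        if _norm_chrom(rec.chrom) == mhc_chrom and mhc_lo <= rec.pos <= mhc_hi:
            audit["mhc"] += 1
            continue
        keep[rec.variant_id] = rec
    return SummaryDataset(study=ds.study, records=keep), audit


def ld_clump(
    subset: SummaryDataset,
    ld: pd.DataFrame | None,
    r2_max: float = 0.001,
) -> SummaryDataset:
    """Greedy LD pruning to pairwise r² < ``r2_max``.

    Variants are visited in ascending p-value (ties broken lexicographically
    by variant id); a variant is accepted iff its squared correlation with
    every already-accepted variant is below the threshold.  ``ld`` is a
    square correlation (r) matrix indexed by variant id; ``None`` treats all
    variants as independent.
    """
    if ld is None:
        return SummaryDataset(study=subset.study, records=dict(subset.records))
    missing = [v for v in subset.records if v not in ld.index]
    if missing:
        raise KeyError(f"variants missing from LD matrix: {missing}")
    order = sorted(subset.records.values(), key=lambda r: (r.pvalue, r.variant_id))
    accepted: list[str] = []
    for rec in order:
        r = ld.loc[rec.variant_id, accepted].to_numpy(dtype=float) if accepted else np.array([])
        if np.all(r ** 2 < r2_max):
            accepted.append(rec.variant_id)
    return subset.subset(accepted)


def read_ld_matrix(matrix_path, variants_path) -> pd.DataFrame:
    """Load a plain numeric LD (r) matrix with a sidecar one-id-per-line
    variant list."""
    with open(variants_path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    mat = np.loadtxt(matrix_path)
    mat = np.atleast_2d(mat)
    if mat.shape != (len(ids), len(ids)):
        raise ValueError("LD matrix shape does not match variant list")
    return pd.DataFrame(mat, index=ids, columns=ids)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exp: SummaryDataset,
    out: SummaryDataset,
    palindrome_eaf_margin: float = 0.42,
) -> tuple[list[HarmonizedInstrument], dict[str, int]]:
    """Align outcome records to exposure effect alleles.

    Matching is by variant id.  If the outcome's effect allele equals the
    exposure's other allele (directly or after strand complement) the
    outcome beta and EAF are flipped.  Palindromic variants (A/T or C/G)
    are kept only when their exposure EAF is far from 0.5 — i.e. dropped
    when ``eaf ∈ (margin, 1−margin)`` or when EAF is unavailable — and
    strand is then inferred from EAF concordance.
    """
    audit = {"unmatched": 0, "palindromic": 0, "irreconcilable": 0}
    res: list[HarmonizedInstrument] = []
    for vid, ex in exp.records.items():
        ou = out.records.get(vid)
        if ou is None:
            audit["unmatched"] += 1
            continue
        ea, oa = ex.effect_allele, ex.other_allele
        if _is_palindromic(ea, oa):
            if ex.eaf is None or ou.eaf is None:
                audit["palindromic"] += 1
                continue
            if palindrome_eaf_margin < ex.eaf < 1.0 - palindrome_eaf_margin:
                audit["palindromic"] += 1
                continue
            if {ou.effect_allele, ou.other_allele} != {ea, oa}:
                audit["irreconcilable"] += 1
                continue
            # allele letters are strand-ambiguous; align on allele frequency
            flip = (ex.eaf < 0.5) != (ou.eaf < 0.5)
        else:
            oe, oo = ou.effect_allele, ou.other_allele
            if (oe, oo) == (ea, oa):
                flip = False
            elif (oe, oo) == (oa, ea):
                flip = True
            elif (oe, oo) == (_COMPLEMENT[ea], _COMPLEMENT[oa]):
                flip = False
            elif (oe, oo) == (_COMPLEMENT[oa], _COMPLEMENT[ea]):
                flip = True
            else:
                audit["irreconcilable"] += 1
                continue
        by = -ou.beta if flip else ou.beta
        res.append(HarmonizedInstrument(
            variant_id=vid, bx=ex.beta, sx=ex.se, by=by, sy=ou.se,
            effect_allele=ea, eaf=ex.eaf, flipped=flip))
    return res, audit
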