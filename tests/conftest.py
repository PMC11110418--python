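import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mrtriage.instruments import HarmonizedInstrument
from mrtriage.summary_io import StudyMeta, SummaryDataset, VariantAssoc


def make_instruments(bx, by, sy, sx=None, ids=None):
    """Build harmonized instruments from plain arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.zeros_like(bx) if sx is None else np.asarray(sx, dtype=float)
    ids = ids or [f"rs{i}" for i in range(len(bx))]
    return [
        HarmonizedInstrument(variant_id=ids[j], bx=bx[j], sx=sx[j],
                             by=by[j], sy=sy[j], effect_allele="A")
        for j in range(len(bx))
    ]


def make_dataset(rows, trait_id="trait", trait_type="quantitative",
                 cohort="test", n=10000):
    """Build a SummaryDataset from (id, chrom, pos, ea, oa, eaf, beta, se, p) rows."""
    ds = SummaryDataset(study=StudyMeta(trait_id=trait_id,
                                        trait_type=trait_type,
                                        cohort_label=cohort, n=n))
    for vid, chrom, pos, ea, oa, eaf, beta, se, p in rows:
        ds.add(VariantAssoc(variant_id=vid, chrom=chrom, pos=pos,
                            effect_allele=ea, other_allele=oa, eaf=eaf,
                            beta=beta, se=se, pvalue=p, n=n))
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
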