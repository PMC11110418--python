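import numpy as np
import pandas as pd
import pytest

from mrtriage.instruments import (
    GeneLocus, harmonize, ld_clump, select_instruments,
)
from mrtriage.summary_io import StudyMeta, SummaryDataset

from conftest import make_dataset


LOCUS_CHR6 = GeneLocus(gene_id="G", chrom="6", start=33_800_000, end=33_900_000)


class TestSelectInstruments:
    def test_toy_table_filter_audit(self):
        # gene near the MHC edge: 2 trans, 1 non-significant, 1 in the MHC,
        # 1 survivor beyond 34 Mb
        ds = make_dataset([
            ("trans1", "1", 500, "A", "G", 0.3, 0.2, 0.02, 1e-20),
            ("trans2", "6", 50_000_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
            ("weak", "6", 34_500_000, "A", "G", 0.3, 0.05, 0.02, 1e-6),
            ("mhc", "6", 33_000_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
            ("good", "6", 34_200_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
        ])
        sel, audit = select_instruments(ds, LOCUS_CHR6)
        assert set(sel.records) == {"good"}
        assert (audit["cis"], audit["significance"], audit["mhc"]) == (2, 1, 1)

    def test_mhc_overlap_excluded_for_gene_inside_mhc(self):
        # a gene inside the MHC keeps nothing cis to it
        locus = GeneLocus(gene_id="G", chrom="6", start=29_000_000, end=29_050_000)
        ds = make_dataset([
            ("inside", "6", 29_500_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
        ])
        sel, audit = select_instruments(ds, locus)
        assert len(sel) == 0 and audit["mhc"] == 1

    def test_cis_window_boundary_is_closed(self):
        locus = GeneLocus(gene_id="G", chrom="1", start=2_000_000, end=2_100_000)
        ds = make_dataset([
            ("edge", "1", 1_000_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
            ("out", "1", 999_999, "A", "G", 0.3, 0.2, 0.02, 1e-20),
        ])
        sel, audit = select_instruments(ds, locus)
        assert set(sel.records) == {"edge"}

    def test_empty_dataset(self):
        ds = make_dataset([])
        sel, audit = select_instruments(ds, LOCUS_CHR6)
        assert len(sel) == 0 and sum(audit.values()) == 0

    def test_filters_are_order_independent_of_rows(self):
        rows = [
            ("a", "6", 28_500_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
            ("b", "6", 30_000_000, "A", "G", 0.3, 0.2, 0.02, 1e-20),
            ("c", "1", 500, "A", "G", 0.3, 0.2, 0.02, 1e-20),
        ]
        s1, a1 = select_instruments(make_dataset(rows), LOCUS_CHR6)
        s2, a2 = select_instruments(make_dataset(rows[::-1]), LOCUS_CHR6)
        assert set(s1.records) == set(s2.records) and a1 == a2


class TestLdClump:
    @staticmethod
    def _ld(ids, r):
        m = pd.DataFrame(r, index=ids, columns=ids)
        return m

    def test_correlated_pair_keeps_smaller_p(self):
        ds = make_dataset([
            ("rsA", "1", 100, "A", "G", 0.3, 0.2, 0.02, 1e-10),
            ("rsB", "1", 200, "A", "G", 0.3, 0.2, 0.02, 1e-9),
        ])
        ld = self._ld(["rsA", "rsB"], [[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        out = ld_clump(ds, ld, r2_max=0.001)
        assert set(out.records) == {"rsA"}

    def test_identity_ld_retains_all(self):
        ds = make_dataset([
            (f"rs{i}", "1", 100 + i, "A", "G", 0.3, 0.2, 0.02, 1e-10)
            for i in range(5)
        ])
        out = ld_clump(ds, self._ld(list(ds.records), np.eye(5)))
        assert set(out.records) == set(ds.records)

    def test_missing_variant_raises_naming_it(self):
        ds = make_dataset([
            ("rsA", "1", 100, "A", "G", 0.3, 0.2, 0.02, 1e-10),
        ])
        with pytest.raises(KeyError, match="rsA"):
            ld_clump(ds, self._ld(["other"], [[1.0]]))

    def test_matches_bruteforce_selection(self, rng):
        n = 20
        ids = [f"rs{i:02d}" for i in range(n)]
        a = rng.normal(size=(n, n))
        corr = np.corrcoef(a @ a.T)
        ld = self._ld(ids, corr)
        pvals = rng.uniform(1e-20, 1e-8, size=n)
        ds = make_dataset([
            (ids[i], "1", 100 + i, "A", "G", 0.3, 0.2, 0.02, pvals[i])
            for i in range(n)
        ])
        r2max = 0.05
        # independent re-derivation: walk p-sorted list, pairwise check
        order = sorted(range(n), key=lambda i: (pvals[i], ids[i]))
        expect = []
        for i in order:
            if all(corr[i, j] ** 2 < r2max for j in expect):
                expect.append(i)
        out = ld_clump(ds, ld, r2_max=r2max)
        assert set(out.records) == {ids[i] for i in expect}

    def test_input_order_invariance(self, rng):
        ids = [f"rs{i}" for i in range(8)]
        corr = np.eye(8)
        corr[0, 1] = corr[1, 0] = 0.9
        ld = self._ld(ids, corr)
        rows = [(ids[i], "1", 100 + i, "A", "G", 0.3, 0.2, 0.02, 1e-10)
                for i in range(8)]  # all tie on p; lexicographic break
        o1 = ld_clump(make_dataset(rows), ld, r2_max=0.5)
        o2 = ld_clump(make_dataset(rows[::-1]), ld, r2_max=0.5)
        assert set(o1.records) == set(o2.records)
        assert "rs0" in o1.records and "rs1" not in o1.records


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        out = make_dataset([("rs1", "1", 100, "G", "A", 0.7, -0.05, 0.01, 1e-6)],
                           trait_type="binary")
        harm, audit = harmonize(exp, out)
        assert len(harm) == 1
        assert harm[0].by == pytest.approx(0.05)
        assert harm[0].flipped

    def test_strand_complement_alignment(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        out = make_dataset([("rs1", "1", 100, "T", "C", 0.3, 0.05, 0.01, 1e-6)],
                           trait_type="binary")
        harm, _ = harmonize(exp, out)
        assert harm[0].by == pytest.approx(0.05) and not harm[0].flipped

    def test_palindromic_midfrequency_dropped(self):
        exp = make_dataset([("rs1", "1", 100, "A", "T", 0.50, 0.1, 0.02, 1e-9)])
        out = make_dataset([("rs1", "1", 100, "A", "T", 0.50, 0.05, 0.01, 1e-6)])
        harm, audit = harmonize(exp, out)
        assert harm == [] and audit["palindromic"] == 1

    def test_palindromic_extreme_frequency_kept(self):
        exp = make_dataset([("rs1", "1", 100, "A", "T", 0.10, 0.1, 0.02, 1e-9)])
        out = make_dataset([("rs1", "1", 100, "A", "T", 0.12, 0.05, 0.01, 1e-6)])
        harm, _ = harmonize(exp, out)
        assert len(harm) == 1 and harm[0].by == pytest.approx(0.05)

    def test_irreconcilable_alleles_audited(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        out = make_dataset([("rs1", "1", 100, "A", "C", 0.3, 0.05, 0.01, 1e-6)])
        harm, audit = harmonize(exp, out)
        assert harm == [] and audit["irreconcilable"] == 1

    def test_self_harmonization_identity(self):
        exp = make_dataset([
            ("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9),
            ("rs2", "1", 200, "C", "T", 0.6, -0.2, 0.03, 1e-11),
        ])
        harm, _ = harmonize(exp, exp)
        assert all(h.by == h.bx and not h.flipped for h in harm)

    def test_unmatched_variants_audited(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        out = make_dataset([("rs9", "1", 900, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        harm, audit = harmonize(exp, out)
        assert harm == [] and audit["unmatched"] == 1
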