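import numpy as np
import pandas as pd
import pytest

from ervkit.architecture import (
    annotate_cgi_promoters,
    assess_spreading,
    classify_cgi_promoter,
    compare_ltr_methylation,
    filter_copies,
    orientation_cgi_table,
    proximal_ltr,
)
from ervkit.methylation import MethylationCall
from ervkit.model import CgiInterval, ErvRecord, GeneRecord
from tests.conftest import make_clone_set


def make_full_length(erv_id, chrom, start, end, strand, ltr=400):
    left = (start, start + ltr)
    right = (end - ltr, end)
    ltr5, ltr3 = (left, right) if strand == "+" else (right, left)
    return ErvRecord(erv_id, "IAP", "full_length", chrom, start, end, strand,
                     ltr5=ltr5, ltr3=ltr3)


class TestClassifyCgiPromoter:
    def test_cgi_covering_tss(self):
        gene = GeneRecord("g", "chr1", "+", 10_000, 20_000)
        assert classify_cgi_promoter(gene, [CgiInterval("chr1", 9_500, 10_500)])

    def test_cgi_just_beyond_window(self):
        gene = GeneRecord("g", "chr1", "+", 10_000, 20_000)
        assert not classify_cgi_promoter(gene, [CgiInterval("chr1", 11_501, 11_600)])

    def test_cgi_ending_exactly_at_window_start(self):
        gene = GeneRecord("g", "chr1", "+", 10_000, 20_000)
        assert not classify_cgi_promoter(gene, [CgiInterval("chr1", 8_000, 8_500)])
        # one base inside the half-open window counts
        assert classify_cgi_promoter(gene, [CgiInterval("chr1", 8_000, 8_501)])

    def test_wrong_chromosome(self):
        gene = GeneRecord("g", "chr1", "+", 10_000, 20_000)
        assert not classify_cgi_promoter(gene, [CgiInterval("chr2", 9_500, 10_500)])

    def test_annotate_helper(self):
        genes = [GeneRecord("g1", "chr1", "+", 10_000, 20_000),
                 GeneRecord("g2", "chr1", "+", 50_000, 60_000)]
        annotated = annotate_cgi_promoters(genes, [CgiInterval("chr1", 9_900, 10_100)])
        assert annotated[0].promoter_is_cgi is True
        assert annotated[1].promoter_is_cgi is False


class TestProximalLtr:
    def test_plus_erv_left_of_gene_gives_3prime(self):
        erv = make_full_length("e", "chr1", 10_000, 15_000, "+")
        gene = GeneRecord("g", "chr1", "+", 16_000, 26_000)
        call = proximal_ltr(erv, gene)
        assert call.proximal_ltr == "3prime"
        assert call.distance_to_tss == 1000
        assert not call.tie

    def test_minus_erv_left_of_gene_gives_5prime(self):
        erv = make_full_length("e", "chr1", 10_000, 15_000, "-")
        gene = GeneRecord("g", "chr1", "+", 16_000, 26_000)
        assert proximal_ltr(erv, gene).proximal_ltr == "5prime"

    def test_equidistant_tie_goes_to_5prime_with_flag(self):
        erv = make_full_length("e", "chr1", 10_000, 15_000, "+")
        gene = GeneRecord("g", "chr1", "+", 12_500, 22_500)  # centered on the ERV
        call = proximal_ltr(erv, gene)
        assert call.proximal_ltr == "5prime"
        assert call.tie

    def test_solo_inapplicable(self, solo_erv, plus_gene):
        with pytest.raises(ValueError, match="solo"):
            proximal_ltr(solo_erv, plus_gene)

    def test_mirror_invariance(self):
        # mirroring all coordinates and flipping all strands preserves the call
        C = 1_000_000
        erv = make_full_length("e", "chr1", 10_000, 15_000, "+")
        gene = GeneRecord("g", "chr1", "+", 16_000, 26_000)
        m_erv = make_full_length("e", "chr1", C - 15_000, C - 10_000, "-")
        m_gene = GeneRecord("g", "chr1", "-", C - 16_000, C - 26_000)
        assert proximal_ltr(erv, gene).proximal_ltr == \
            proximal_ltr(m_erv, m_gene).proximal_ltr


def table1_fixture():
    """Constructed ERV/gene set reproducing the published screen counts:
    56 full-length copies, 25 with the 5' LTR proximal (20 CGI promoters),
    31 with the 3' LTR proximal (15 CGI promoters)."""
    calls = []
    genes = []
    ervs = []
    k = 0
    for n, which, n_cgi in ((25, "5prime", 20), (31, "3prime", 15)):
        for i in range(n):
            base = 100_000 * (k + 1)
            # gene to the right of the ERV; strand of the ERV decides which
            # LTR faces the gene
            strand = "-" if which == "5prime" else "+"
            erv = make_full_length(f"e{k}", "chr1", base, base + 5_000, strand)
            gene = GeneRecord(f"g{k}", "chr1", "+", base + 6_000, base + 16_000,
                              promoter_is_cgi=i < n_cgi)
            ervs.append(erv)
            genes.append(gene)
            calls.append(proximal_ltr(erv, gene))
            k += 1
    return calls


class TestOrientationCgiTable:
    def test_reproduces_published_counts_and_pvalues(self):
        calls = table1_fixture()
        summary = orientation_cgi_table(calls)
        assert (summary.n_5prime, summary.n_3prime) == (25, 31)
        assert (summary.cgi_5prime, summary.cgi_3prime) == (20, 15)
        assert round(summary.association_test.p_value, 4) == 0.0314
        assert round(summary.orientation_test.p_value, 1) == 0.5

    def test_all_one_class_degenerate(self):
        calls = [c for c in table1_fixture() if c.proximal_ltr == "5prime"]
        summary = orientation_cgi_table(calls)
        assert "degenerate_orientation" in summary.flags
        assert "degenerate_association" in summary.flags
        assert summary.association_test is None

    def test_symmetric_cgi_fractions_give_p_one(self):
        calls = table1_fixture()
        # rebuild with equal CGI fractions in both classes
        from dataclasses import replace
        adjusted = []
        for c in calls:
            idx = sum(1 for a in adjusted if a.proximal_ltr == c.proximal_ltr)
            n_class = 25 if c.proximal_ltr == "5prime" else 31
            n_cgi = round(0.6 * n_class)
            adjusted.append(replace(c, promoter_is_cgi=idx < n_cgi))
        summary = orientation_cgi_table(adjusted)
        assert summary.association_test.p_value > 0.5

    def test_empty_calls(self):
        with pytest.raises(ValueError):
            orientation_cgi_table([])


class TestCompareLtrMethylation:
    def test_fully_separated(self):
        s5 = make_clone_set([1.0] * 8, region_id="ltr5")
        s3 = make_clone_set([0.0] * 8, region_id="ltr3")
        res = compare_ltr_methylation(s5, s3)
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_identical_sets(self):
        fractions = [0.5, 0.6, 0.7, 0.8]
        res = compare_ltr_methylation(make_clone_set(fractions),
                                      make_clone_set(fractions))
        assert res.p_value > 0.9

    def test_empty_side_error(self):
        with pytest.raises(ValueError):
            compare_ltr_methylation(make_clone_set([]), make_clone_set([0.5]))

    def test_equal_level_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 100
        for _ in range(n_sims):
            a = [float(np.mean(rng.random(20) < 0.8)) for _ in range(8)]
            b = [float(np.mean(rng.random(20) < 0.8)) for _ in range(8)]
            res = compare_ltr_methylation(make_clone_set(a), make_clone_set(b))
            rejections += res.p_value < 0.05
        assert rejections / n_sims <= 0.12  # ~nominal 5%, 3-sigma slack


class TestAssessSpreading:
    def _erv_call(self, fraction, tissue="liver"):
        call = "methylated" if fraction >= 0.2 else "unmethylated"
        return MethylationCall("erv1", tissue, fraction, call, "bisulfite",
                               fraction=fraction)

    def test_methylated_erv_clean_promoter(self):
        promoter = make_clone_set([0.0] * 9 + [0.1], n_cpgs=10, region_id="prom")
        res = assess_spreading(self._erv_call(0.95), promoter, 973, True)
        assert not res.spreading_call
        assert res.promoter_methylation == pytest.approx(0.01)

    def test_spreading_case(self):
        promoter = make_clone_set([0.3] * 10, n_cpgs=10, region_id="prom")
        res = assess_spreading(self._erv_call(0.84), promoter, 368, True)
        assert res.spreading_call

    def test_boundary_inclusive(self):
        promoter = make_clone_set([0.1] * 10, n_cpgs=10)
        assert assess_spreading(self._erv_call(0.9), promoter, 500, True).spreading_call

    def test_unmethylated_erv_never_spreads(self):
        promoter = make_clone_set([0.9] * 10, n_cpgs=10)
        assert not assess_spreading(self._erv_call(0.1), promoter, 500, True).spreading_call

    def test_monotone_in_promoter_fraction(self):
        low = make_clone_set([0.05] * 10, n_cpgs=20)
        high = make_clone_set([0.5] * 10, n_cpgs=20)
        r_low = assess_spreading(self._erv_call(0.9), low, 500, True)
        r_high = assess_spreading(self._erv_call(0.9), high, 500, True)
        assert (not r_low.spreading_call) and r_high.spreading_call

    def test_tissue_mismatch(self):
        promoter = make_clone_set([0.0] * 5, tissue="brain")
        with pytest.raises(ValueError, match="tissue"):
            assess_spreading(self._erv_call(0.9, tissue="liver"), promoter, 500, True)


class TestFilterCopies:
    def _evidence(self, **overrides):
        row = {"erv_id": "e1", "est_or_expression_available": True,
               "gene_annotation_ok": True, "tss_count": 1,
               "inside_upstream_gene": False}
        row.update(overrides)
        return pd.DataFrame([row])

    def test_clean_copy_passes(self):
        report = filter_copies(self._evidence())
        assert report.rows[0].passed
        assert report.rows[0].reasons == ()

    def test_inside_upstream_gene(self):
        report = filter_copies(self._evidence(inside_upstream_gene=True))
        assert report.rows[0].reasons == ("inside_upstream_gene",)

    def test_too_many_tss(self):
        report = filter_copies(self._evidence(tss_count=4))
        assert report.rows[0].reasons == ("too_many_tss",)
        assert filter_copies(self._evidence(tss_count=3)).rows[0].passed

    def test_multiple_reasons(self):
        report = filter_copies(self._evidence(est_or_expression_available=False,
                                              gene_annotation_ok=False))
        assert set(report.rows[0].reasons) == {"no_est_or_expression_data",
                                               "gene_misannotated"}

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="tss_count"):
            filter_copies(self._evidence().drop(columns=["tss_count"]))

    def test_rerun_on_passed_subset_excludes_nothing(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "erv_id": [f"e{i}" for i in range(50)],
            "est_or_expression_available": rng.random(50) < 0.8,
            "gene_annotation_ok": rng.random(50) < 0.8,
            "tss_count": rng.integers(1, 6, 50),
            "inside_upstream_gene": rng.random(50) < 0.2,
        })
        report = filter_copies(df)
        passed = df[df["erv_id"].isin(report.passed_ids)]
        rerun = filter_copies(passed)
        assert all(r.passed for r in rerun.rows)
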