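"""VCF and genetic-map I/O: parsing, alignment, round trips."""

import numpy as np
import pytest

from conftest import panel_from_haplotypes, params_for
from lsimpute import inference, panel_io
from lsimpute.panel_io import GeneticMap, LikelihoodMatrix

PANEL_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=20>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(path, header, rows):
    path.write_text(header + "".join(r + "\n" for r in rows))
    return str(path)


@pytest.fixture
def panel_vcf(tmp_path):
    rows = [
        "20\t100\t.\tA\tC\t.\t.\t.\tGT\t0|0\t0|1\t1|1",
        "20\t200\t.\tG\tT\t.\t.\t.\tGT\t0|1\t1|1\t0|0",
        "20\t300\t.\tT\tA\t.\t.\t.\tGT\t1|0\t0|0\t0|1",
        "20\t400\t.\tC\tG\t.\t.\t.\tGT\t0|0\t0|0\t1|0",
        "20\t500\t.\tA\tG\t.\t.\t.\tGT\t1|1\t0|1\t0|0",
    ]
    return write_vcf(tmp_path / "panel.vcf", PANEL_HEADER, rows)


class TestReadReferencePanel:
    def test_counts_haplotypes_and_sites(self, panel_vcf):
        panel = panel_io.read_reference_panel(panel_vcf)
        assert panel.n_haplotypes == 6
        assert panel.n_sites == 5
        np.testing.assert_array_equal(panel.positions, [100, 200, 300, 400, 500])
        np.testing.assert_array_equal(panel.haplotypes[:, 0], [0, 0, 0, 1, 1, 1])

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        rows = [
            "20\t100\t.\tA\tC\t.\t.\t.\tGT\t0|0\t0|1\t1|1",
            "20\t150\t.\tA\tC,G\t.\t.\t.\tGT\t0|0\t0|1\t1|2",
            "20\t200\t.\tG\tT\t.\t.\t.\tGT\t0|1\t1|1\t0|0",
            "20\t250\t.\tGA\tG\t.\t.\t.\tGT\t0|0\t0|1\t1|1",
            "20\t300\t.\tT\tA\t.\t.\t.\tGT\t1|0\t0|0\t0|1",
        ]
        panel = panel_io.read_reference_panel(write_vcf(tmp_path / "p.vcf", PANEL_HEADER, rows))
        assert panel.n_sites == 3
        assert panel.skipped == {"multiallelic": 1, "indel_or_non_snp": 1}

    def test_unphased_genotype_is_hard_error(self, tmp_path):
        rows = ["20\t100\t.\tA\tC\t.\t.\t.\tGT\t0|0\t0/1\t1|1"]
        with pytest.raises(ValueError, match="unphased"):
            panel_io.read_reference_panel(write_vcf(tmp_path / "p.vcf", PANEL_HEADER, rows))

    def test_region_restriction(self, panel_vcf):
        panel = panel_io.read_reference_panel(panel_vcf, region="20:150-350")
        assert panel.n_sites == 2
        with pytest.raises(ValueError):
            panel_io.read_reference_panel(panel_vcf, region="21")

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            panel_io.read_reference_panel(str(tmp_path / "absent.vcf"))


TARGET_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=20>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1
"""

GL_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=20>
##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 likelihoods">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1
"""


class TestReadTargetLikelihoods:
    def test_pl_conversion_and_alignment(self, panel_vcf, tmp_path):
        panel = panel_io.read_reference_panel(panel_vcf)
        rows = [
            "20\t100\t.\tA\tC\t.\t.\t.\tPL\t0,30,60",
            "20\t300\t.\tA\tT\t.\t.\t.\tPL\t0,10,20",  # swapped ref/alt: dropped
            "20\t400\t.\tC\tG\t.\t.\t.\tPL\t.",  # missing value: uniform
            "20\t999\t.\tA\tC\t.\t.\t.\tPL\t0,5,10",  # not a panel site: dropped
        ]
        lik = panel_io.read_target_likelihoods(
            write_vcf(tmp_path / "t.vcf", TARGET_HEADER, rows), "NA1", panel
        )
        assert lik.n_sites == panel.n_sites
        np.testing.assert_allclose(lik.likelihoods[0], [1.0, 1e-3, 1e-6], rtol=1e-9)
        assert lik.observed.tolist() == [True, False, False, False, False]
        np.testing.assert_array_equal(lik.likelihoods[1], [1.0, 1.0, 1.0])
        assert lik.n_unmatched_target_records == 2

    def test_gl_conversion(self, panel_vcf, tmp_path):
        panel = panel_io.read_reference_panel(panel_vcf)
        rows = ["20\t200\t.\tG\tT\t.\t.\t.\tGL\t-0.1,-1.0,-2.0"]
        lik = panel_io.read_target_likelihoods(
            write_vcf(tmp_path / "t.vcf", GL_HEADER, rows), "NA1", panel
        )
        row = lik.likelihoods[1]
        expect = 10.0 ** np.array([-0.1, -1.0, -2.0])
        np.testing.assert_allclose(row, expect / expect.max(), rtol=1e-6)

    def test_unknown_sample_or_missing_format_rejected(self, panel_vcf, tmp_path):
        panel = panel_io.read_reference_panel(panel_vcf)
        target = write_vcf(
            tmp_path / "t.vcf", TARGET_HEADER, ["20\t100\t.\tA\tC\t.\t.\t.\tPL\t0,30,60"]
        )
        with pytest.raises(KeyError):
            panel_io.read_target_likelihoods(target, "NOPE", panel)
        gt_only = write_vcf(
            tmp_path / "gt.vcf",
            PANEL_HEADER.replace("\tS1\tS2\tS3", "\tNA1"),
            ["20\t100\t.\tA\tC\t.\t.\t.\tGT\t0|1"],
        )
        with pytest.raises(ValueError, match="neither GL nor PL"):
            panel_io.read_target_likelihoods(gt_only, "NA1", panel)

    def test_row_scaling_does_not_change_posteriors(self, rng):
        """End-to-end scale invariance of likelihood rows."""
        hap = rng.integers(0, 2, size=(4, 8))
        lik = rng.uniform(0.05, 1.0, size=(8, 3))
        params = params_for(hap, rng.uniform(0, 0.3, size=7), 0.02)
        panel = panel_from_haplotypes(hap)
        base = inference.run_forward_backward(panel, lik, params)
        rescaled = LikelihoodMatrix(lik, np.ones(8, bool)).rescaled()
        res = inference.run_forward_backward(panel, rescaled, params)
        np.testing.assert_allclose(res.gp, base.gp, atol=1e-12)


class TestGeneticMap:
    def test_interpolation_identity_and_midpoint(self):
        gmap = GeneticMap([1000, 2000, 3000], [1.0, 2.0, 4.0])
        assert gmap.interpolate(2000) == pytest.approx(2.0)
        assert gmap.interpolate(1500) == pytest.approx(1.5)
        assert gmap.interpolate(2500) == pytest.approx(3.0)

    def test_extrapolation_at_flanking_rate(self):
        gmap = GeneticMap([1000, 2000, 3000], [1.0, 2.0, 4.0])
        assert gmap.interpolate(500) == pytest.approx(0.5)
        assert gmap.interpolate(3500) == pytest.approx(5.0)

    def test_monotone_output(self, rng):
        gmap = GeneticMap([1000, 2000, 3000, 4000], [0.0, 0.0, 1.0, 1.5])
        q = np.sort(rng.integers(0, 5000, size=50))
        out = gmap.interpolate(q)
        assert np.all(np.diff(out) >= 0)

    def test_hapmap_and_plink_dialects(self, tmp_path):
        hap_style = tmp_path / "hapmap.txt"
        hap_style.write_text(
            "position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n"
            "1000 1.0 0.0\n2000 1.0 0.001\n3000 1.0 0.002\n"
        )
        plink_style = tmp_path / "plink.txt"
        plink_style.write_text(
            "20 rs1 0.0 1000\n20 rs2 0.001 2000\n20 rs3 0.002 3000\n"
        )
        for path in (hap_style, plink_style):
            gmap = panel_io.read_genetic_map(path)
            np.testing.assert_array_equal(gmap.positions, [1000, 2000, 3000])
            np.testing.assert_allclose(gmap.cumulative_cm, [0.0, 0.001, 0.002])

    def test_map_write_read_round_trip(self, tmp_path):
        path = tmp_path / "map.txt"
        panel_io.write_genetic_map(path, [1000, 2000, 5000], [0.0, 0.5, 0.8])
        gmap = panel_io.read_genetic_map(path)
        np.testing.assert_allclose(gmap.cumulative_cm, [0.0, 0.5, 0.8], atol=1e-8)

    def test_degenerate_maps_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            GeneticMap([1000], [0.0])
        empty = tmp_path / "empty.txt"
        empty.write_text("")
        with pytest.raises((ValueError, Exception)):
            panel_io.read_genetic_map(empty)


class TestWriteImputedVcf:
    def _result(self, panel, rng):
        lik = rng.uniform(0.05, 1.0, size=(panel.n_sites, 3))
        params = params_for(panel.haplotypes, rng.uniform(0, 0.3, size=panel.n_sites - 1), 0.02)
        return inference.run_forward_backward(panel, lik, params)

    def test_round_trip_gt_exact_gp_within_rounding(self, tmp_path, rng):
        panel = panel_from_haplotypes(rng.integers(0, 2, size=(6, 20)))
        res = self._result(panel, rng)
        out = tmp_path / "imputed.vcf"
        panel_io.write_imputed_vcf(res, panel, "NA1", out)
        import pysam

        gts, gps, dss = [], [], []
        with pysam.VariantFile(str(out)) as vcf:
            for rec in vcf:
                call = rec.samples["NA1"]
                assert call.phased
                gts.append(call["GT"])
                gps.append(list(call["GP"]))
                dss.append(float(np.atleast_1d(call["DS"])[0]))
        np.testing.assert_array_equal(
            np.array(gts).T, res.haplotypes
        )
        gps = np.array(gps)
        # one unit in the last printed place is the exact bound for
        # sum-constrained 3-decimal rounding
        np.testing.assert_allclose(gps, res.gp, atol=1e-3)
        np.testing.assert_allclose(gps.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(
            np.array(dss), gps[:, 1] + 2 * gps[:, 2], atol=1e-6
        )

    def test_rounded_gp_rows_sum_to_one(self):
        gp = np.array([[0.3333, 0.3333, 0.3334], [0.0004, 0.0004, 0.9992]])
        rounded = panel_io.round_genotype_posteriors(gp)
        np.testing.assert_allclose(rounded.sum(axis=1), 1.0, atol=1e-12)

    def test_dosage_definition(self, tmp_path, rng):
        panel = panel_from_haplotypes(rng.integers(0, 2, size=(4, 12)))
        res = self._result(panel, rng)
        out = tmp_path / "imp.vcf"
        panel_io.write_imputed_vcf(res, panel, "NA1", out)
        text = out.read_text()
        assert "GT:GP:DS" in text

    def test_size_mismatch_rejected(self, tmp_path, rng):
        panel = panel_from_haplotypes(rng.integers(0, 2, size=(4, 12)))
        res = self._result(panel, rng)
        small = panel_from_haplotypes(rng.integers(0, 2, size=(4, 10)))
        with pytest.raises(ValueError):
            panel_io.write_imputed_vcf(res, small, "NA1", tmp_path / "x.vcf")
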