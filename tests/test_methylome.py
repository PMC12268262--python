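import math

import numpy as np
import pandas as pd
import pytest

from allometh._errors import FormatError, ParameterError, RowError
from allometh import methylome as m
from allometh.synthetic_data import find_cytosines

from conftest import make_calls


def _write(tmp_path, text, name="calls.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "chrom\tpos\tstrand\tcontext\tratio\teff_CT\tC_count\tCT_count\n"


class TestReadMethratio:
    def test_direct_parse(self, tmp_path):
        p = _write(tmp_path, HEADER + "chr1\t100\t+\tCG\t0.3\t10\t3\t10\n")
        sample = m.read_methratio(p)
        row = sample.calls.iloc[0]
        assert (row["c_count"], row["ct_count"], row["context"]) == (3, 10, "CG")
        assert row["pos"] == 100

    def test_empty_file_with_header(self, tmp_path):
        sample = m.read_methratio(_write(tmp_path, HEADER))
        assert sample.calls.empty

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "chrom\tpos\tstrand\n")
        with pytest.raises(FormatError, match="context"):
            m.read_methratio(p)

    def test_count_exceeding_coverage_names_line(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER + "chr1\t100\t+\tCG\t0.3\t10\t3\t10\nchr1\t101\t+\tCG\t1.1\t10\t11\t10\n",
        )
        with pytest.raises(RowError, match="line 3"):
            m.read_methratio(p)

    def test_extra_columns_ignored(self, tmp_path):
        p = _write(
            tmp_path,
            "chrom\tpos\tstrand\tcontext\tratio\teff_CT\tC_count\tCT_count\textra\n"
            "chr1\t5\t-\tCHH\t0\t4\t0\t4\tjunk\n",
        )
        assert len(m.read_methratio(p).calls) == 1

    def test_roundtrip_through_writer(self, tmp_path):
        calls = make_calls([("chr1", 10, "+", "CG", 3, 9), ("chr1", 22, "-", "CHH", 0, 5)])
        m.write_methratio(calls, tmp_path / "out.tsv")
        back = m.read_methratio(tmp_path / "out.tsv").calls
        pd.testing.assert_frame_equal(back, calls)


class TestCallContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 2, "+", "CG"),
            ("ACTGA", 2, "+", "CHG"),
            ("ACTTA", 2, "+", "CHH"),
            ("ACGT", 1, "+", None),  # not a C
            ("ACGT", 4, "+", None),  # context runs off the end
            ("ACG", 3, "-", "CG"),  # G on + means C on -, next base complement G
            ("CAGT", 3, "-", "CHG"),
            ("TTGA", 3, "-", "CHH"),
            ("GAT", 1, "-", None),  # context runs off the start
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert m.call_context(seq, pos, strand) == expected

    def test_agrees_with_vectorized_enumeration(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        enumerated = find_cytosines(seq, "c")
        table = {(r.pos, r.strand): r.context for r in enumerated.itertuples()}
        for pos in range(1, len(seq) + 1):
            for strand in "+-":
                assert m.call_context(seq, pos, strand) == table.get((pos, strand))


class TestWeightedMethylation:
    def test_single_site(self):
        assert m.weighted_methylation(make_calls([("c", 1, "+", "CG", 3, 10)])) == 0.3

    def test_pooled_not_mean_of_ratios(self):
        calls = make_calls([("c", 1, "+", "CG", 2, 4), ("c", 2, "+", "CG", 1, 6)])
        level = m.weighted_methylation(calls)
        assert level == pytest.approx(0.3)
        assert level != pytest.approx((2 / 4 + 1 / 6) / 2)

    def test_empty_selection_is_missing(self):
        calls = make_calls([("c", 1, "+", "CG", 2, 4)])
        assert math.isnan(m.weighted_methylation(calls, ("c", 100, 200)))
        assert math.isnan(m.weighted_methylation(calls, context="CHH"))

    def test_region_selection_is_half_open(self):
        calls = make_calls([("c", 10, "+", "CG", 1, 1), ("c", 11, "+", "CG", 0, 1)])
        # 1-based pos 10 has 0-based coordinate 9: region [9, 10) selects only it
        assert m.weighted_methylation(calls, ("c", 9, 10)) == 1.0

    def test_pooling_identity_over_disjoint_regions(self, rng):
        """Union level equals pooled counts of the union, never mean of region levels."""
        n = 300
        calls = make_calls(
            [
                ("c", int(p), "+", "CG", int(c), int(ct))
                for p, (c, ct) in zip(
                    rng.choice(np.arange(1, 5000), size=n, replace=False),
                    zip(rng.integers(0, 5, n), rng.integers(5, 30, n)),
                )
            ]
        )
        cuts = [0, 1000, 2500, 5000]
        total_c = total_ct = 0
        for lo, hi in zip(cuts, cuts[1:]):
            sub = calls[(calls["pos"] > lo) & (calls["pos"] <= hi)]
            total_c += sub["c_count"].sum()
            total_ct += sub["ct_count"].sum()
        assert m.weighted_methylation(calls) == pytest.approx(total_c / total_ct)


class TestConversionRate:
    def test_examples(self):
        assert m.conversion_rate(make_calls([("p", 1, "+", "CHH", 7, 1000)])) == pytest.approx(0.993)
        assert m.conversion_rate(make_calls([("p", 1, "+", "CHH", 0, 50)])) == 1.0
        assert m.conversion_rate(make_calls([("p", 1, "+", "CHH", 50, 100)])) == 0.5

    def test_zero_coverage_is_error(self):
        with pytest.raises(ParameterError):
            m.conversion_rate(make_calls([("p", 1, "+", "CHH", 0, 0)]))


class TestMethylcytosineCalling:
    def test_zero_count_never_called(self):
        s = m.MethylomeSample("s", calls=make_calls([("c", 1, "+", "CG", 0, 30)]))
        assert m.call_methylcytosines(s, 0.007) == set()

    def test_saturated_site_called(self):
        # P(X >= 10 | n=10, p=0.007) = 0.007^10 ~ 2.8e-22
        s = m.MethylomeSample("s", calls=make_calls([("c", 5, "+", "CG", 10, 10)]))
        assert m.call_methylcytosines(s, 0.007) == {("c", 5, "+")}

    def test_single_hit_in_deep_site_not_called(self):
        # P(X >= 1 | n=100, p=0.007) = 1 - 0.993^100 ~ 0.504
        s = m.MethylomeSample("s", calls=make_calls([("c", 5, "+", "CG", 1, 100)]))
        assert m.call_methylcytosines(s, 0.007) == set()

    def test_error_rate_range_enforced(self):
        s = m.MethylomeSample("s", calls=make_calls([("c", 1, "+", "CG", 1, 10)]))
        for bad in (0.0, 0.5, 0.9):
            with pytest.raises(ParameterError):
                m.call_methylcytosines(s, bad)

    def test_coverage_floor_excludes_shallow_sites(self):
        s = m.MethylomeSample(
            "s", calls=make_calls([("c", 1, "+", "CG", 3, 3), ("c", 2, "+", "CG", 10, 10)])
        )
        assert m.call_methylcytosines(s, 0.007, min_coverage=4) == {("c", 2, "+")}


class TestTracks:
    def test_uniform_sites_give_uniform_windows(self):
        calls = make_calls([("c", p, "+", "CG", 1, 2) for p in range(1, 1001, 10)])
        s = m.MethylomeSample("s", calls=calls)
        track = m.chromosome_track(s, 100, "CG")
        assert (track["level"] == 0.5).all()

    def test_empty_window_flagged_missing(self):
        calls = make_calls([("c", 1, "+", "CG", 1, 2), ("c", 500, "+", "CG", 1, 2)])
        s = m.MethylomeSample("s", calls=calls)
        track = m.chromosome_track(s, 100, "CG", chrom_lengths={"c": 500})
        assert track["level"].isna().sum() == 3

    def test_single_window_equals_global_level(self, meth_study):
        _, _, samples, _, _ = meth_study
        s = list(samples.values())[0]
        chrom = s.calls["chrom"].iloc[0]
        length = int(s.calls["pos"].max())
        track = m.chromosome_track(s, length, "CG", chrom_lengths={chrom: length})
        assert len(track) == 1
        assert track["level"].iloc[0] == pytest.approx(m.global_level(s, "CG"))

    def test_window_floor(self, meth_study):
        _, _, samples, _, _ = meth_study
        with pytest.raises(ParameterError):
            m.chromosome_track(list(samples.values())[0], 50, "CG")


def _step_function_sample(gene_start=1000, gene_end=2000, strand="+"):
    """Methylation 0.8 inside the gene body, 0.2 outside (every 10 bp, CG)."""
    rows = []
    for pos0 in range(0, 4000, 10):
        inside = gene_start <= pos0 < gene_end
        rows.append(("c", pos0 + 1, "+", "CG", 8 if inside else 2, 10))
    return m.MethylomeSample("s", calls=make_calls(rows))


class TestMetaprofile:
    def test_bin_count_and_layout(self):
        prof = m.metaprofile(
            _step_function_sample(),
            pd.DataFrame([{"chrom": "c", "start": 1000, "end": 2000, "strand": "+"}]),
            flank_bp=1000, n_bins_body=10, n_bins_flank=5,
        )
        assert prof.n_bins == 20
        assert set(prof.table["bin_index"]) == set(range(20))

    def test_step_function_recovered(self):
        prof = m.metaprofile(
            _step_function_sample(),
            pd.DataFrame([{"chrom": "c", "start": 1000, "end": 2000, "strand": "+"}]),
            flank_bp=1000, n_bins_body=10, n_bins_flank=5, contexts=("CG",),
        )
        tab = prof.table.set_index("bin_index")["level"]
        # interior bins away from the boundary
        assert all(tab[b] == pytest.approx(0.2) for b in range(0, 4))
        assert all(tab[b] == pytest.approx(0.8) for b in range(6, 14))
        assert all(tab[b] == pytest.approx(0.2) for b in range(16, 20))

    def test_minus_strand_mirrors_plus(self):
        sample = _step_function_sample()
        kwargs = dict(flank_bp=1000, n_bins_body=10, n_bins_flank=5, contexts=("CG",))
        plus = m.metaprofile(
            sample, pd.DataFrame([{"chrom": "c", "start": 1000, "end": 2000, "strand": "+"}]),
            **kwargs,
        ).table.set_index("bin_index")["level"]
        minus = m.metaprofile(
            sample, pd.DataFrame([{"chrom": "c", "start": 1000, "end": 2000, "strand": "-"}]),
            **kwargs,
        ).table.set_index("bin_index")["level"]
        np.testing.assert_allclose(plus.to_numpy(), minus.to_numpy()[::-1])


class TestSampleInvariants:
    def test_duplicate_site_keys_rejected(self):
        calls = make_calls([("c", 1, "+", "CG", 1, 2), ("c", 1, "+", "CHG", 1, 2)])
        with pytest.raises(RowError):
            m.MethylomeSample("s", calls=calls)

    def test_conversion_rate_range(self):
        with pytest.raises(ParameterError):
            m.MethylomeSample("s", conversion_rate=0.4)

    def test_pool_replicates_sums_counts(self):
        a = make_calls([("c", 1, "+", "CG", 1, 4)])
        b = make_calls([("c", 1, "+", "CG", 2, 6), ("c", 9, "-", "CHH", 0, 3)])
        pooled = m.pool_replicates([a, b])
        assert len(pooled) == 2
        row = pooled[pooled["pos"] == 1].iloc[0]
        assert (row["c_count"], row["ct_count"]) == (3, 10)
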