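from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from fruitmethyl.dmr_calling import (
    DmrParams,
    bh_qvalues,
    bin_windows,
    call_dmrs,
    fisher_window_test,
    genome_dmr_coverage,
    read_dmr_bed,
    shared_dmrs,
    write_dmr_bed,
)

from conftest import make_records


def fisher_oracle(c_a, n_a, c_b, n_b):
    """Exact rational two-sided Fisher p by full hypergeometric enumeration."""
    k = c_a + c_b
    denom = comb(n_a + n_b, k)
    probs = {
        x: Fraction(comb(n_a, x) * comb(n_b, k - x), denom)
        for x in range(max(0, k - n_b), min(n_a, k) + 1)
    }
    p_obs = probs[c_a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestBinWindows:
    sizes = {"chr1": 450}

    def test_tiling_with_truncated_tail(self):
        a = make_records([("chr1", 1, "+", "CHH", 0, 10)])
        b = make_records([("chr1", 1, "+", "CHH", 0, 10)])
        w = bin_windows(a, b, self.sizes, contexts=("CHH",))
        assert list(w[["start", "end"]].itertuples(index=False, name=None)) == [
            (0, 200), (200, 400), (400, 450)
        ]
        assert list(w["truncated"]) == [False, False, True]

    def test_counts_and_levels(self):
        a = make_records([("chr1", 50, "+", "CHH", 2, 10)])
        b = make_records([("chr1", 50, "+", "CHH", 8, 10)])
        w = bin_windows(a, b, self.sizes, contexts=("CHH",)).iloc[0]
        assert (w["c_a"], w["n_a"], w["c_b"], w["n_b"]) == (2, 10, 8, 10)
        assert (w["level_a"], w["level_b"]) == (0.2, 0.8)
        assert not w["testable"]  # one site < min_sites default of 3

    def test_zero_coverage_untestable(self):
        a = make_records([("chr1", p, "+", "CHH", 0, 0) for p in (10, 20, 30)])
        b = make_records([("chr1", p, "+", "CHH", 3, 10) for p in (10, 20, 30)])
        w = bin_windows(a, b, self.sizes, contexts=("CHH",))
        assert not w.iloc[0]["testable"]

    def test_mismatched_chromosomes_listed(self):
        a = make_records([("chr1", 10, "+", "CHH", 1, 10)])
        b = make_records([("chr2", 10, "+", "CHH", 1, 10)])
        with pytest.raises(ValueError, match="chr2"):
            bin_windows(a, b, {"chr1": 450, "chr2": 450})


class TestFisher:
    def test_extreme_table(self):
        # [[10,0],[0,10]]: only the two extreme tables are as improbable
        assert fisher_window_test(10, 10, 0, 10) == pytest.approx(
            2 / comb(20, 10), abs=1e-15
        )

    def test_identical_counts(self):
        assert fisher_window_test(5, 10, 5, 10) == 1.0

    def test_degenerate_margin(self):
        assert fisher_window_test(0, 10, 0, 10) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_window_test(0, 0, 5, 10)

    def test_matches_enumeration_oracle_spot(self):
        for args in [(3, 9, 7, 11), (1, 12, 6, 8), (0, 5, 5, 5), (4, 4, 0, 7)]:
            assert fisher_window_test(*args) == pytest.approx(
                fisher_oracle(*args), abs=1e-12
            )


class TestCallDmrs:
    def test_bh_step_up(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_delta_below_threshold_not_dmr(self):
        # CHH delta 0.09 with overwhelming significance is still not a DMR
        a = make_records([("chr1", p, "+", "CHH", 100, 1000) for p in (10, 20, 30)])
        b = make_records([("chr1", p, "+", "CHH", 190, 1000) for p in (10, 20, 30)])
        w = bin_windows(a, b, {"chr1": 200}, contexts=("CHH",))
        res = call_dmrs(w)
        row = res.tested.iloc[0]
        assert row["p_value"] < 1e-6
        assert row["delta"] == pytest.approx(0.09)
        assert not row["is_dmr"]

    def test_antisymmetry_under_sample_swap(self, recovery_run):
        tables = recovery_run["tables"]
        spec = recovery_run["spec"]
        sizes = recovery_run["sizes"]
        a = tables["YF"]
        b = tables["EF"]
        a = a[(a["chrom"] == "chr1") & (a["pos"] <= 50_000)]
        b = b[(b["chrom"] == "chr1") & (b["pos"] <= 50_000)]
        small = {"chr1": 50_000}
        fwd = call_dmrs(bin_windows(a, b, small, contexts=("CHH",))).dmrs
        rev = call_dmrs(bin_windows(b, a, small, contexts=("CHH",))).dmrs
        key = ["chrom", "start", "end", "context"]
        pd.testing.assert_frame_equal(
            fwd[key].reset_index(drop=True), rev[key].reset_index(drop=True)
        )
        flipped = rev["direction"].map({"hyper": "hypo", "hypo": "hyper"})
        assert list(fwd["direction"]) == list(flipped)

    def test_no_testable_windows_warns_empty(self):
        a = make_records([("chr1", 10, "+", "CHH", 0, 1)])
        b = make_records([("chr1", 10, "+", "CHH", 0, 1)])
        w = bin_windows(a, b, {"chr1": 200}, contexts=("CHH",))
        with pytest.warns(UserWarning, match="no testable"):
            res = call_dmrs(w)
        assert len(res.dmrs) == 0


class TestSharedDmrs:
    def _dmrs(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "context", "direction"]
        )

    def test_disjoint_sets(self):
        d1 = self._dmrs([("chr1", 0, 200, "CHH", "hyper")])
        d2 = self._dmrs([("chr1", 200, 400, "CHH", "hyper")])
        rep = shared_dmrs(d1, d2).set_index("context")
        assert rep.loc["CHH", "n_shared"] == 0
        assert np.isnan(rep.loc["CHH", "concordance"])

    def test_identical_sets(self):
        d = self._dmrs(
            [("chr1", 0, 200, "CHH", "hyper"), ("chr1", 400, 600, "CG", "hypo")]
        )
        rep = shared_dmrs(d, d).set_index("context")
        assert rep.loc["CHH", "concordance"] == 1.0
        assert rep.loc["CG", "concordance"] == 1.0

    def test_window_size_mismatch_rejected(self):
        d1 = self._dmrs([("chr1", 0, 200, "CHH", "hyper")])
        d2 = self._dmrs([("chr1", 0, 100, "CHH", "hyper")])
        with pytest.raises(ValueError, match="window sizes"):
            shared_dmrs(d1, d2)


class TestGenomeCoverage:
    def test_no_dmrs(self):
        d = pd.DataFrame(columns=["chrom", "start", "end", "context"])
        assert genome_dmr_coverage(d, {"chr1": 1000}) == 0.0

    def test_adjacent_windows_union(self):
        d = pd.DataFrame(
            [("chr1", 0, 200), ("chr1", 200, 400)], columns=["chrom", "start", "end"]
        )
        assert genome_dmr_coverage(d, {"chr1": 1000}) == pytest.approx(0.4)

    def test_full_tiling(self):
        d = pd.DataFrame(
            [("chr1", s, s + 200) for s in range(0, 1000, 200)],
            columns=["chrom", "start", "end"],
        )
        assert genome_dmr_coverage(d, {"chr1": 1000}) == 1.0

    def test_control_excluded_from_denominator(self):
        d = pd.DataFrame([("chr1", 0, 200)], columns=["chrom", "start", "end"])
        cov = genome_dmr_coverage(d, {"chr1": 1000, "lambda_control": 9000},
                                  exclude=("lambda_control",))
        assert cov == pytest.approx(0.2)


def test_dmr_bed_round_trip(tmp_path, recovery_run):
    dmrs = recovery_run["dmrs_ef"].dmrs
    path = tmp_path / "d.bed"
    write_dmr_bed(dmrs, path)
    back = read_dmr_bed(path)
    assert len(back) == len(dmrs)
    for col in ("chrom", "start", "end", "context", "direction"):
        assert list(back[col]) == list(dmrs[col])
    assert back["q_value"].to_numpy() == pytest.approx(
        dmrs["q_value"].to_numpy(), abs=1e-12
    )
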