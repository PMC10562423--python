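"""1-D track tests: ATAC partition, RPM matrices, enhancer rules, H3K9me3
bin calls and expression-in-loop summaries, against set-algebra oracles."""

import numpy as np
import pandas as pd
import pytest

from loopshift.contactio import GenomeLayout, Loop, PeakSet, SignalTrack
from loopshift.tracks import (FragmentTable, classify_enhancers,
                              differential_enhancers, expression_in_loops,
                              h3k9me3_bin_calls, h3k9me3_differential_bins,
                              rpm_bin_matrix, shift_and_partition_atac)


def frag_df(rows):
    return FragmentTable(pd.DataFrame(rows,
                                      columns=["chrom", "start", "end", "strand"]))


def peaks_of(rows, name="x"):
    return PeakSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestAtacPartition:
    def test_length_gates(self):
        # post-shift lengths 100 -> TF, 200 -> Nuc, 150 -> discarded
        ft = frag_df([("chr1", 1000, 1096, "+"),     # 96-4 = wait: shift +4 start
                      ("chr1", 2000, 2205, "-"),
                      ("chr1", 3000, 3155, "-")])
        part = shift_and_partition_atac(ft)
        assert len(part.tf) == 1 and len(part.nuc) == 1
        assert part.n_discarded == 1

    def test_shift_directions(self):
        ft = frag_df([("chr1", 100, 200, "+"), ("chr1", 100, 200, "-")])
        part = shift_and_partition_atac(ft)
        rows = pd.concat([part.tf.frags, part.nuc.frags])
        plus = rows[rows["strand"] == "+"].iloc[0]
        minus = rows[rows["strand"] == "-"].iloc[0]
        assert (plus["start"], plus["end"]) == (104, 200)     # len 96 -> TF
        assert (minus["start"], minus["end"]) == (100, 195)   # len 95 -> TF

    def test_boundaries_inclusive(self):
        # lengths exactly 50, 115, 180, 247 after shift (use - strand, end-5)
        rows = [("chr1", 0, l + 5, "-") for l in (50, 115, 180, 247, 49, 116,
                                                  179, 248)]
        part = shift_and_partition_atac(frag_df(rows))
        assert len(part.tf) == 2 and len(part.nuc) == 2
        assert part.n_discarded == 4

    def test_partition_complete_and_disjoint(self, rng):
        lengths = rng.integers(20, 300, 500)
        strands = np.where(rng.random(500) < 0.5, "+", "-")
        rows = [("chr1", 10_000, 10_000 + int(l), s)
                for l, s in zip(lengths, strands)]
        ft = frag_df(rows)
        part = shift_and_partition_atac(ft)
        assert len(part.tf) + len(part.nuc) + part.n_discarded == len(ft)
        # oracle on shifted lengths
        shifted = np.where(strands == "+", lengths - 4, lengths - 5)
        assert len(part.tf) == int(((shifted >= 50) & (shifted <= 115)).sum())
        assert len(part.nuc) == int(((shifted >= 180) & (shifted <= 247)).sum())

    def test_negative_start_clipped(self):
        part = shift_and_partition_atac(frag_df([("chr1", 0, 100, "-")]))
        assert (part.tf.frags["start"] >= 0).all()


class TestRpmBinMatrix:
    layout = GenomeLayout.from_dict({"chr1": 1_000_000}, 10_000)

    def anchors(self, centers):
        return pd.DataFrame({"chrom": "chr1",
                             "start": [c - 50 for c in centers],
                             "end": [c + 50 for c in centers]})

    def test_uniform_reads_library_scaling(self):
        # one read entirely inside every 100-bp bin of the window
        reads = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(499_000, 501_000, 100) + 10,
                              "end": np.arange(499_000, 501_000, 100) + 60})
        bm = rpm_bin_matrix(reads, self.anchors([500_000]), self.layout,
                            flank=1000, bin_width=100, library_size=1e6)
        assert np.allclose(bm.matrix, 1.0)
        bm2 = rpm_bin_matrix(reads, self.anchors([500_000]), self.layout,
                             flank=1000, bin_width=100, library_size=2e6)
        assert np.allclose(bm2.matrix, 0.5)

    def test_against_counting_oracle(self, rng):
        starts = rng.integers(480_000, 520_000, 200)
        reads = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(30, 200, 200)})
        bm = rpm_bin_matrix(reads, self.anchors([500_000]), self.layout,
                            flank=2000, bin_width=500, library_size=1e6)
        for b in range(8):
            b0 = 498_000 + b * 500
            want = int(((reads["start"] < b0 + 500) & (reads["end"] > b0)).sum())
            assert bm.matrix[0, b] == want

    def test_strand_flip_reverses_row(self, rng):
        starts = rng.integers(480_000, 520_000, 100)
        reads = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 80})
        anc = self.anchors([500_000, 500_000])
        anc["strand"] = ["+", "-"]
        bm = rpm_bin_matrix(reads, anc, self.layout, flank=2000, bin_width=500,
                            library_size=1e6, strand_aware=True)
        assert np.array_equal(bm.matrix[1], bm.matrix[0][::-1])

    def test_edge_anchor_masked(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        bm = rpm_bin_matrix(reads, self.anchors([500]), self.layout,
                            flank=2000, bin_width=500, library_size=1e6)
        assert bm.masked[0] and np.isnan(bm.matrix[0]).all()


class TestEnhancers:
    tss = peaks_of([("chr1", 50_000, 50_001)], "tss")

    def _run(self, me1, me3=(), atac=(), ac=(), tss_pad=1000):
        return classify_enhancers(peaks_of(me1, "me1"), peaks_of(me3, "me3"),
                                  peaks_of(atac, "atac"), peaks_of(ac, "ac"),
                                  self.tss, tss_pad)

    def test_h3k4me3_excludes(self):
        iv = [("chr1", 10_000, 11_000)]
        assert self._run(iv, me3=iv, atac=iv, ac=iv) == []

    def test_enhancer_then_active_promotion(self):
        iv = [("chr1", 10_000, 11_000)]
        calls = self._run(iv, atac=iv)
        assert len(calls) == 1 and not calls[0].active
        calls = self._run(iv, atac=iv, ac=[("chr1", 10_500, 12_000)])
        assert calls[0].active

    def test_needs_atac(self):
        assert self._run([("chr1", 10_000, 11_000)]) == []

    def test_tss_pad_excludes(self):
        iv = [("chr1", 50_500, 51_500)]  # within 1 kb of the TSS at 50 kb
        assert self._run(iv, atac=iv, tss_pad=1000) == []
        assert len(self._run(iv, atac=iv, tss_pad=1)) == 1  # literal +/-1 bp

    def test_random_sets_vs_bruteforce(self, rng):
        def rand(n, w):
            s = rng.integers(0, 500_000, n)
            return [("chr1", int(x), int(x + w)) for x in s]
        me1, me3 = rand(40, 1500), rand(15, 1200)
        atac, ac = rand(30, 600), rand(20, 2000)
        calls = self._run(me1, me3=me3, atac=atac, ac=ac)
        got = {(c.start, c.end, c.active) for c in calls}
        tssiv = [(s - 1000, e + 1000) for _, s, e in
                 self.tss.intervals.itertuples(index=False)]

        def hits(iv, lst):
            return any(min(iv[2], e) > max(iv[1], s) for _, s, e in lst)

        want = set()
        for iv in me1:
            if (not hits(iv, me3) and hits(iv, atac)
                    and not any(min(iv[2], e) > max(iv[1], s) for s, e in tssiv)):
                want.add((iv[1], iv[2], hits(iv, ac)))
        assert got == want

    def test_monotone_in_h3k27ac(self, rng):
        def rand(n, w):
            s = rng.integers(0, 500_000, n)
            return [("chr1", int(x), int(x + w)) for x in s]
        me1, atac = rand(30, 1500), rand(30, 800)
        base = self._run(me1, atac=atac)
        more = self._run(me1, atac=atac, ac=rand(25, 2500))
        assert {(c.start, c.end) for c in base} == {(c.start, c.end) for c in more}
        assert sum(c.active for c in more) >= sum(c.active for c in base)


class TestDifferentialEnhancers:
    def test_identical_signal_none(self):
        c = np.full((10, 2), 30.0)
        res = differential_enhancers(c, c)
        assert not res["differential"].any()

    def test_fc_gate_blocks_under_threefold(self):
        a = np.full((5, 2), 1000.0)
        b = np.full((5, 2), 2900.0)
        res = differential_enhancers(a, b)
        assert (res["p"] < 1e-6).all()
        assert not res["differential"].any()

    def test_planted_fivefold_recovered(self, rng):
        a = rng.poisson(40, (40, 2)).astype(float)
        b = a.copy()
        b[:10] = rng.poisson(200, (10, 2))
        res = differential_enhancers(a, b)
        assert res["differential"][:10].mean() >= 0.9
        assert res["differential"][10:].mean() <= 0.1


class TestK9Bins:
    layout = GenomeLayout.from_dict({"chr1": 500_000}, 25_000)

    def _track(self, vals):
        return SignalTrack(self.layout, {"chr1": np.asarray(vals, dtype=float)})

    def test_four_times_input_all_positive(self, rng):
        # tracks pre-normalized to equal depth: boundary ratio 4 is inclusive
        inp = rng.integers(5, 40, 20).astype(float)
        calls = h3k9me3_bin_calls(self._track(4 * inp), self._track(inp),
                                  depth_match=False)
        assert calls.positive["chr1"].all()

    def test_ip_equal_input_none_positive(self, rng):
        v = rng.integers(5, 40, 20).astype(float)
        calls = h3k9me3_bin_calls(self._track(v), self._track(v))
        assert not calls.positive["chr1"].any()

    def test_depth_matching_applied(self):
        # input at half depth: scaling makes IP/input = 2, not 4
        ip = np.full(20, 40.0)
        inp = np.full(20, 10.0)
        calls = h3k9me3_bin_calls(self._track(ip), self._track(inp))
        assert not calls.positive["chr1"].any()
        assert np.allclose(calls.ratio["chr1"], 1.0)

    def test_random_vs_binned_ratio_oracle(self, rng):
        ip = rng.integers(0, 200, 20).astype(float)
        inp = rng.integers(0, 50, 20).astype(float)
        calls = h3k9me3_bin_calls(self._track(ip), self._track(inp))
        scale = ip.sum() / inp.sum()
        want = ip / np.maximum(inp * scale, 1.0) >= 4.0
        assert np.array_equal(calls.positive["chr1"], want)

    def test_differential_symmetric_under_swap(self, rng):
        a = h3k9me3_bin_calls(self._track(rng.integers(1, 300, 20)),
                              self._track(rng.integers(1, 50, 20)))
        b = h3k9me3_bin_calls(self._track(rng.integers(1, 300, 20)),
                              self._track(rng.integers(1, 50, 20)))
        ab = h3k9me3_differential_bins(a, b)
        ba = h3k9me3_differential_bins(b, a)
        assert np.array_equal(ab["chr1"], -ba["chr1"])


class TestExpressionInLoops:
    genes = pd.DataFrame({
        "gene": ["g1", "g2", "g3"],
        "chrom": ["chr1"] * 3,
        "start": [100_000, 300_000, 700_000],
        "end": [110_000, 310_000, 710_000],
    })

    def _tpm(self, vals):
        return pd.DataFrame(vals, index=["g1", "g2", "g3"])

    def test_log2fc_formula(self):
        loops = {"DE": [Loop("chr1", 90_000, 100_000, 320_000, 330_000)]}
        tpm = self._tpm({"H9": [3.0, 1.0, 9.0], "DE": [7.0, 1.0, 9.0]})
        out = expression_in_loops(loops, self.genes, tpm, {"DE": ("H9", "DE")})
        df = out["DE"]
        assert set(df["gene"]) == {"g1", "g2"}
        assert df.set_index("gene").loc["g1", "log2fc"] == pytest.approx(1.0)

    def test_equal_tpm_all_zero(self):
        loops = {"PP": [Loop("chr1", 50_000, 60_000, 800_000, 810_000)]}
        tpm = self._tpm({"PGT": [2.0, 3.0, 4.0], "PP": [2.0, 3.0, 4.0]})
        out = expression_in_loops(loops, self.genes, tpm, {"PP": ("PGT", "PP")})
        assert np.allclose(out["PP"]["log2fc"], 0.0)

    def test_geneless_loops_counted(self):
        loops = {"DE": [Loop("chr1", 400_000, 410_000, 600_000, 610_000)]}
        tpm = self._tpm({"H9": [1, 1, 1], "DE": [1, 1, 1]})
        out = expression_in_loops(loops, self.genes, tpm, {"DE": ("H9", "DE")})
        assert len(out["DE"]) == 0
        assert out["DE"].attrs["n_loops_without_genes"] == 1

    def test_random_containment_oracle(self, rng):
        genes = pd.DataFrame({
            "gene": [f"g{k}" for k in range(40)],
            "chrom": "chr1",
            "start": (st := rng.integers(0, 900_000, 40)),
            "end": st + 5000,
        })
        tpm = pd.DataFrame({"H9": rng.random(40) * 10,
                            "DE": rng.random(40) * 10},
                           index=genes["gene"])
        loops = {"DE": [Loop("chr1", int(a), int(a) + 10_000,
                             int(a) + 200_000, int(a) + 210_000)
                        for a in rng.integers(0, 700_000, 8)]}
        out = expression_in_loops(loops, genes, tpm, {"DE": ("H9", "DE")})
        mids = (genes["start"] + genes["end"]) // 2
        want = set()
        for li, lp in enumerate(loops["DE"]):
            for gi in range(40):
                if lp.start1 <= mids[gi] < lp.end2:
                    want.add((li, genes["gene"][gi]))
        assert set(zip(out["DE"]["loop"], out["DE"]["gene"])) == want
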