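import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metcensus import domain_detection as dd
from metcensus import synthetic_data as sd
from metcensus.proteome_io import ProteinRecord
from metcensus.reference_domains import REFERENCE_DOMAINS


def log_tail_oracle(n, x, p):
    """Binomial upper tail by term-wise log-space accumulation, independent
    of any library survival function."""
    if x == 0:
        return 1.0
    logs = []
    lp, lq = math.log(p), math.log1p(-p)
    for k in range(x, n + 1):
        logs.append(
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * lp + (n - k) * lq
        )
    mx = max(logs)
    return math.exp(mx) * sum(math.exp(l - mx) for l in logs)


class TestBinomialScore:
    def test_zero_hits_full_tail(self):
        assert dd.score_mr_prld(100, 0, 0.02) == 1.0

    def test_single_outcome_tail(self):
        assert dd.score_mr_prld(10, 10, 0.5) == pytest.approx(0.5**10, rel=1e-12)

    def test_reference_domain_score_against_oracle(self):
        p = dd.score_mr_prld(57, 19, 42 / 956)
        assert p == pytest.approx(log_tail_oracle(57, 19, 42 / 956), rel=1e-10)

    def test_oracle_agreement_500_triples(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(5, 400))
            x = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.005, 0.5))
            assert dd.score_mr_prld(n, x, p) == pytest.approx(
                log_tail_oracle(n, x, p), rel=1e-10
            )

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=2, max_value=200), st.data())
    def test_strictly_decreasing_in_x(self, n, data):
        x = data.draw(st.integers(min_value=1, max_value=n))
        p = 0.05
        assert dd.score_mr_prld(n, x, p) < dd.score_mr_prld(n, x - 1, p)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            dd.score_mr_prld(10, 11, 0.1)
        with pytest.raises(ValueError):
            dd.score_mr_prld(10, 1, 0.0)


class TestMetBiasRegions:
    def test_no_met_empty(self):
        assert dd.met_bias_regions("A" * 200, 0.02) == []

    def test_planted_cluster_found_within_window(self):
        rng = np.random.default_rng(5)
        body = sd._background_sequence(200, 0.0, rng)
        idx = 90 + rng.choice(30, 10, replace=False)
        body[idx] = "M"
        regions = dd.met_bias_regions("".join(body), 0.02)
        assert len(regions) == 1
        r = regions[0]
        assert 91 <= r.start and r.end <= 120 and r.met_count == 10

    def test_regions_trimmed_to_met(self):
        seq = "A" * 50 + "MAMMAMMMAM" + "A" * 50
        (r,) = dd.met_bias_regions(seq, 0.02)
        assert seq[r.start - 1] == "M" and seq[r.end - 1] == "M"

    def test_agrees_with_exhaustive_oracle(self):
        """Fast scan and O(L^2) enumeration return identical regions on
        short sequences, with and without planted clusters."""
        for s in range(12):
            seq = sd.generate_prld_segment(250, "background", seed=300 + s)
            if s % 2:
                ins = sd.generate_prld_segment(40, "prion", seed=600 + s, met_weight=0.25)
                seq = seq[:100] + ins + seq[140:]
            fast = dd.met_bias_regions(seq, 0.02)
            slow = dd.met_bias_regions_exhaustive(seq, 0.02)
            assert [(r.start, r.end, r.met_count) for r in fast] == [
                (r.start, r.end, r.met_count) for r in slow
            ]
            for a, b in zip(fast, slow):
                assert a.bias_p == pytest.approx(b.bias_p, rel=1e-12)

    def test_false_positive_rate_small(self):
        """Random 2%-Met sequence rarely contains a p < 1e-5 biased region."""
        hits = sum(
            bool(dd.met_bias_regions(sd.generate_prld_segment(300, "background", seed=s), 0.02))
            for s in range(300)
        )
        assert hits / 300 <= 0.03

    def test_invalid_background(self):
        with pytest.raises(ValueError):
            dd.met_bias_regions("MAM", 0.0)


class TestPrldPosterior:
    def test_background_sequence_low_posterior(self):
        seq = sd.generate_prld_segment(500, "background", seed=11)
        assert dd.prld_posterior(seq).mean() < 0.1

    def test_identical_tables_give_stationary(self):
        params = dd.HmmParams(
            background_table=dd.EMISSION_TABLES["background"],
            prion_table=dd.EMISSION_TABLES["background"],
        )
        post = dd.prld_posterior("ACDEFGHIKLMNPQRSTVWY" * 5, params)
        assert np.allclose(post, params.stationary[1], atol=1e-12)

    def test_posteriors_in_unit_interval_and_complementary(self):
        seq = sd.generate_prld_segment(200, "prion", seed=2)
        post = dd.prld_posterior(seq)
        assert np.all((post >= 0) & (post <= 1))

    def test_planted_segment_recovered(self):
        """background(200) + prion(80) + background(200): the >=0.9 run
        overlaps the plant midpoint in nearly every seed."""
        hits = 0
        for s in range(40):
            seq = (
                sd.generate_prld_segment(200, "background", seed=3 * s)
                + sd.generate_prld_segment(80, "prion", seed=3 * s + 1, met_weight=0.2)
                + sd.generate_prld_segment(200, "background", seed=3 * s + 2)
            )
            regions = dd.prld_regions(dd.prld_posterior(seq))
            hits += any(r.start <= 240 <= r.end for r in regions)
        assert hits / 40 > 0.95

    def test_unknown_residue_uniform_emission(self):
        post = dd.prld_posterior("MXM" + "A" * 50)
        assert np.all(np.isfinite(post))


class TestPrldRegions:
    def test_all_zero_empty(self):
        assert dd.prld_regions(np.zeros(100)) == []

    def test_full_run(self):
        (r,) = dd.prld_regions(np.ones(100), min_core=60)
        assert (r.start, r.end) == (1, 100)

    def test_run_below_min_core_discarded(self):
        post = np.zeros(200)
        post[10:69] = 0.95  # run of 59
        assert dd.prld_regions(post, min_core=60) == []
        (r,) = dd.prld_regions(post, min_core=59)
        assert (r.start, r.end) == (11, 69)


class TestCallMrPrlds:
    def _record(self):
        rng = np.random.default_rng(8)
        body = sd._background_sequence(299, 0.02, rng)
        seg = sd.generate_prld_segment(60, "prion", seed=9, met_weight=0.25)
        body[100:160] = list(seg)
        return ProteinRecord("CALL1", "M" + "".join(body))

    def test_non_aggregation_protein_yields_nothing(self):
        rec = self._record()
        bias = dd.met_bias_regions(rec.sequence, 0.02)
        prlds = dd.prld_regions(dd.prld_posterior(rec.sequence))
        assert dd.call_mr_prlds(rec, bias, prlds, "dispersion") == []
        assert dd.call_mr_prlds(rec, bias, prlds, "random") == []

    def test_intersection_span_and_fields(self):
        rec = self._record()
        bias = [dd.BiasRegion(65, 121, rec.sequence[64:121].count("M"), 1e-9)]
        prld = [dd.PrldRegion(60, 130)]
        calls = dd.call_mr_prlds(rec, bias, prld, "aggregation", min_met=1)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end) == (65, 121)
        assert c.n == 57
        assert c.x == c.sequence.count("M")
        assert c.sequence == rec.sequence[64:121]

    def test_min_met_filter(self):
        rec = ProteinRecord("FEW", "M" + "A" * 40 + "MAMAMAM" + "A" * 60)
        bias = [dd.BiasRegion(42, 48, 4, 1e-9)]
        prld = [dd.PrldRegion(30, 60)]
        assert dd.call_mr_prlds(rec, bias, prld, "aggregation") == []

    def test_non_overlapping_pair_ignored(self):
        rec = self._record()
        calls = dd.call_mr_prlds(
            rec, [dd.BiasRegion(10, 20, 5, 1e-9)], [dd.PrldRegion(200, 280)], "aggregation"
        )
        assert calls == []


class TestRankCensus:
    def test_sorted_ascending(self):
        recs = [
            dd.MrPrldRecord("A", 1, 10, 10, 5, 0.02, 1e-3, "M" * 10),
            dd.MrPrldRecord("B", 1, 10, 10, 5, 0.02, 1e-13, "M" * 10),
            dd.MrPrldRecord("C", 1, 10, 10, 5, 0.02, 1e-9, "M" * 10),
        ]
        table = dd.rank_census(recs)
        assert table["p-Value"].tolist() == sorted(table["p-Value"].tolist())
        assert table.ID.tolist() == ["B", "C", "A"]

    def test_empty_input(self):
        assert dd.rank_census([]).empty

    def test_reference_domains_rank_consistently(self):
        """At any common background frequency, the (57, 19) domain outranks
        the (28, 8) one — tail comparison via the independent oracle."""
        for p_bg in (0.02, 0.035, 0.05):
            strong = dd.score_mr_prld(57, 19, p_bg)
            weak = dd.score_mr_prld(28, 8, p_bg)
            assert strong < weak
            assert log_tail_oracle(57, 19, p_bg) < log_tail_oracle(28, 8, p_bg)

    def test_reference_met_counts_recomputed(self):
        """Met counts of the six reference MR-PrLD sequences match their
        published x values via the same counting the caller uses."""
        for ref in REFERENCE_DOMAINS:
            assert ref.sequence.count("M") == ref.x
            assert len(ref.sequence) == ref.end - ref.start + 1 == ref.length


class TestAdapters:
    def test_flps_round_trip(self, tmp_path):
        f = tmp_path / "flps.txt"
        f.write_text(
            "PROT1\tMULTIPLE\t12\t65\t121\t19\t1.0e-09\t{M}\n"
            "PROT1\tMULTIPLE\t5\t10\t30\t5\t1.0e-03\t{M}\n"  # fails threshold
            "PROT2\tSINGLE\t8\t5\t60\t8\t1.0e-08\t{Q}\n"  # not Met
        )
        regions = dd.read_flps_regions(f)
        assert list(regions) == ["PROT1"]
        assert (regions["PROT1"][0].start, regions["PROT1"][0].end) == (65, 121)

    def test_plaac_round_trip(self, tmp_path):
        f = tmp_path / "plaac.txt"
        f.write_text("# header\nP1 1 0.1\nP1 2 0.95\nP1 3 0.92\n")
        post = dd.read_plaac_posteriors(f)
        assert np.allclose(post["P1"], [0.1, 0.95, 0.92])
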