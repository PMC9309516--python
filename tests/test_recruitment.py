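"""Recruitment core: best hits, sections, RSD, ANI, clouds, presence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frpipe.io import OUTFMT6_COLUMNS, annotate_alignments
from frpipe.recruitment import (
    RecruitmentProfile, ani_band, best_hits, call_presence, compute_ani,
    compute_rsd, detect_clouds, identity_histogram, relative_abundance,
    section_counts,
)


def aln_row(qseqid, genome, pident, bitscore, length=100, qlen=100,
            sstart=1):
    row = dict.fromkeys(OUTFMT6_COLUMNS, 0)
    row.update({
        "qseqid": qseqid, "sseqid": f"{genome}|c1", "pident": pident,
        "length": length, "qstart": 1, "qend": length, "sstart": sstart,
        "send": sstart + length - 1, "evalue": 1e-10, "bitscore": bitscore,
        "qlen": qlen,
    })
    return row


def frame(rows):
    return annotate_alignments(pd.DataFrame(rows, columns=OUTFMT6_COLUMNS))


class TestBestHits:
    def test_identity_below_threshold_unrecruited(self):
        best = best_hits(frame([aln_row("r1", "gA", 59.0, 180)]))
        assert best.empty

    def test_coverage_below_threshold_unrecruited(self):
        best = best_hits(frame([aln_row("r1", "gA", 95.0, 180, length=59)]))
        assert best.empty

    def test_max_bitscore_wins(self):
        best = best_hits(frame([
            aln_row("r1", "gA", 90.0, 180), aln_row("r1", "gB", 95.0, 150),
        ]))
        assert list(best["genome_id"]) == ["gA"]

    def test_tie_break_order_matches_brute_force(self):
        # enumerate all orderings of three tied/untied records; winner must be
        # the (bitscore desc, identity desc, genome asc) maximum every time
        records = [
            ("gC", 97.0, 200.0), ("gA", 92.0, 200.0), ("gB", 97.0, 200.0),
            ("gD", 99.0, 150.0),
        ]
        expect = max(records, key=lambda r: (r[2], r[1], [-ord(c) for c in r[0]]))
        for perm in itertools.permutations(records):
            best = best_hits(frame([
                aln_row("r1", g, p, b) for g, p, b in perm
            ]))
            assert best["genome_id"].iloc[0] == expect[0]

    def test_equal_bitscore_higher_identity_wins(self):
        best = best_hits(frame([
            aln_row("r1", "gA", 92.0, 200), aln_row("r1", "gB", 97.0, 200),
        ]))
        assert best["genome_id"].iloc[0] == "gB"

    def test_empty_input_empty_output(self):
        assert best_hits(frame([])).empty


class TestSectionCounts:
    def test_midpoints_fall_in_expected_sections(self):
        counts = section_counts(1000, np.array([50.0, 950.0]))
        assert counts.tolist() == [1, 0, 0, 0, 0, 0, 0, 0, 0, 1]

    def test_uniform_simulation_fills_sections_evenly(self):
        rng = np.random.default_rng(5)
        mids = rng.uniform(0, 100_000, 5000)
        counts = section_counts(100_000, mids)
        assert counts.sum() == 5000
        # multinomial 99% range around 500 per section
        margin = 3 * math.sqrt(5000 * 0.1 * 0.9)
        assert all(abs(c - 500) <= margin for c in counts)

    def test_out_of_bounds_midpoint_rejected(self):
        with pytest.raises(ValueError):
            section_counts(1000, np.array([1000.0]))

    def test_last_section_absorbs_remainder(self):
        # L=1003 -> width 100; positions 999..1002 all land in section 9
        counts = section_counts(1003, np.array([999.0, 1000.0, 1002.0]))
        assert counts[9] == 3


class TestRsd:
    def test_uniform_counts_give_zero(self):
        assert compute_rsd([100] * 10) == 0.0

    def test_single_section_pileup_gives_sqrt_ten(self):
        for n in (10, 1000, 123456):
            rsd = compute_rsd([n] + [0] * 9)
            assert rsd == pytest.approx(math.sqrt(10), rel=1e-12)

    def test_matches_two_pass_reference_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            counts = rng.integers(0, 1000, 10)
            if counts.sum() == 0:
                continue
            mean = sum(counts) / 10
            var = sum((c - mean) ** 2 for c in counts) / 9
            expect = math.sqrt(var) / mean
            assert compute_rsd(counts) == pytest.approx(expect, rel=1e-12)

    def test_zero_reads_flagged_missing(self):
        assert math.isnan(compute_rsd([0] * 10))

    def test_population_mode_switch(self):
        counts = [10] + [0] * 9
        assert compute_rsd(counts, ddof=0) == pytest.approx(3.0, rel=1e-12)


class TestAni:
    def test_mean_of_identities(self):
        assert compute_ani([90.0, 100.0]) == 95.0
        assert compute_ani([100.0] * 7) == 100.0

    def test_zero_reads_flagged_missing(self):
        assert math.isnan(compute_ani([]))

    @given(st.lists(st.floats(60, 100), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_bounded(self, ids):
        a = compute_ani(ids)
        assert compute_ani(ids[::-1]) == pytest.approx(a)
        assert min(ids) - 1e-9 <= a <= max(ids) + 1e-9


class TestDetectClouds:
    @staticmethod
    def binomial_identities(rng, divergence, n, length=200):
        return 100.0 * (length - rng.binomial(length, divergence, n)) / length

    def test_unimodal_distribution_is_one_cloud(self):
        rng = np.random.default_rng(1)
        hist = identity_histogram(self.binomial_identities(rng, 0.03, 3000))
        two, _ = detect_clouds(hist)
        assert not two

    def test_planted_bimodal_mixture_detected(self):
        rng = np.random.default_rng(2)
        ids = np.concatenate([
            self.binomial_identities(rng, 0.02, 1500),
            self.binomial_identities(rng, 0.12, 1500),
        ])
        two, sides = detect_clouds(identity_histogram(ids))
        assert two
        high = max(sides, key=lambda c: c.mean_identity)
        assert high.mean_identity == pytest.approx(98.0, abs=1.0)
        assert sum(c.n_reads for c in sides) == 3000

    def test_tiny_read_count_below_support_floor(self):
        rng = np.random.default_rng(3)
        ids = np.concatenate([
            self.binomial_identities(rng, 0.02, 5),
            self.binomial_identities(rng, 0.15, 5),
        ])
        two, sides = detect_clouds(identity_histogram(ids))
        assert not two and sides == []

    def test_empty_histogram(self):
        two, sides = detect_clouds(np.zeros(40))
        assert not two and sides == []


def profile(n_reads, rsd, ani=96.0, two_clouds=False, clouds=()):
    counts = np.zeros(10, dtype=int)
    counts[0] = n_reads
    return RecruitmentProfile(
        "g1", n_reads, ani, counts, rsd,
        identity_histogram(np.full(max(n_reads, 1), ani)), two_clouds,
        list(clouds),
    )


class TestPresenceRule:
    @pytest.mark.parametrize("n,rsd,present,reasons", [
        (1500, 0.5, True, set()),
        (999, 0.1, False, {"too_few_reads"}),
        (5000, 0.80, False, {"rsd_too_high"}),
    ])
    def test_thresholds(self, n, rsd, present, reasons):
        call = call_presence(profile(n, rsd), total_sample_reads=100_000)
        assert call.present is present
        assert set(call.fail_reasons) == reasons

    def test_band_from_ani(self):
        call = call_presence(profile(1500, 0.5, ani=96.2), 100_000)
        assert call.ani_band == "95-100"
        assert call_presence(profile(1500, 0.5, ani=91.0), 100_000).ani_band == "90-95"
        assert call_presence(profile(1500, 0.5, ani=69.9), 100_000).ani_band == "below-70"

    def test_two_cloud_band_follows_high_cloud(self):
        from frpipe.recruitment import CloudSummary

        call = call_presence(
            profile(3000, 0.4, ani=88.0, two_clouds=True,
                    clouds=[CloudSummary(1500, 82.0), CloudSummary(1500, 97.5)]),
            100_000,
        )
        assert call.ani_band == "95-100" and call.two_cloud_flag

    def test_relative_abundance(self):
        assert relative_abundance(500, 100_000) == 0.5
        assert relative_abundance(7, 7) == 100.0
        with pytest.raises(ValueError):
            relative_abundance(1, 0)

    def test_band_edges(self):
        assert ani_band(95.0) == "95-100"
        assert ani_band(94.99) == "90-95"
        assert ani_band(80.0) == "80-90"
        assert ani_band(70.0) == "70-80"
        assert ani_band(float("nan")) == "below-70"
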