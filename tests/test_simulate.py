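"""Synthetic genome / site-model / read generator tests."""

import numpy as np
import pytest
from scipy import stats

import saltosites as ss
from saltosites.simulate import _DOMAIN_SIZES

from conftest import right_end_seq


class TestHostGenome:
    def test_island_gc_and_planted_motif(self):
        g = ss.make_host_genome(50_000, 0.65,
                                low_gc_islands=((20_001, 1530, 0.42),),
                                planted_motifs=((10, "ACGT"),), seed=1)
        assert len(g) == 50_000
        island = g.seq[20_000:20_000 + 1530]
        gc = (island.count("G") + island.count("C")) / 1530
        assert abs(gc - 0.42) <= 0.03
        assert g.seq[9:13] == "ACGT"

    def test_extreme_gc(self):
        g = ss.make_host_genome(1000, 1.0, seed=2)
        assert set(g.seq) <= {"G", "C"}

    def test_rejects_bad_layout(self):
        with pytest.raises(ValueError):
            ss.make_host_genome(1000, 0.5,
                                low_gc_islands=((900, 200, 0.4),), seed=0)
        with pytest.raises(ValueError):
            ss.make_host_genome(1000, 0.5,
                                planted_motifs=((10, "ACGTACGT"),
                                                (12, "ACGT")), seed=0)


class TestPhageGenomeAndDigest:
    def test_default_layout(self, full_phage):
        assert full_phage.seq[:3] == "TGT"
        assert full_phage.seq[-3:] == "ACA"
        assert ss.find_enzyme_cut_sites(full_phage) == [6170, 37_024]
        assert ss.digest_genome(full_phage) == [6170, 30_854, 181]

    def test_digest_worked_example(self):
        assert ss.digest(37_205, [6170, 37_024]) == [6170, 30_854, 181]

    def test_digest_no_sites_and_errors(self):
        assert ss.digest(1234, []) == [1234]
        with pytest.raises(ValueError):
            ss.digest(100, [50, 30])
        with pytest.raises(ValueError):
            ss.digest(100, [100])

    def test_digest_against_subtraction_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            L = int(rng.integers(100, 10_000))
            sites = sorted(rng.choice(np.arange(1, L), size=3, replace=False))
            frags = ss.digest(L, [int(s) for s in sites])
            bounds = [0, *sites, L]
            assert frags == [b - a for a, b in zip(bounds, bounds[1:])]
            assert sum(frags) == L
            assert len(frags) == 4

    def test_no_enzyme_site_spec(self):
        spec = ss.PhageSpec(length=2000, enzyme_sites=())
        g = ss.make_phage_genome(spec, seed=3)
        assert ss.digest_genome(g) == [2000]
        assert spec.right_end_len is None

    def test_site_too_close_to_end_rejected(self):
        with pytest.raises(ValueError):
            ss.PhageSpec(length=2000, enzyme_sites=(2, 1000))


class TestSiteWeights:
    def test_uniform_genome_uniform_weights(self):
        g = ss.make_host_genome(5000, 0.65, seed=7)
        w = ss.site_weights(g, ss.SiteModel())
        assert np.allclose(w, w[0])

    def test_cold_island_weight(self):
        g = ss.make_host_genome(20_000, 0.65,
                                low_gc_islands=((8001, 2000, 0.42),), seed=8)
        model = ss.SiteModel()
        w = ss.site_weights(g, model)
        # deep inside the island the windowed GC is below threshold
        assert np.allclose(w[8500:9500], model.base_weight * model.gc_cold_factor)
        assert np.allclose(w[:7000], model.base_weight)

    def test_motif_boost_monte_carlo(self, toy_phage):
        """Empirical insertion-rate ratio (motif window vs background)
        approximates the configured boost within 3 standard errors."""
        g = ss.make_host_genome(10_000, 0.65, seed=9)
        model = ss.SiteModel(motif_positions=(5000,), immunity_leak=0.0)
        events = ss.sample_insertions(100_000, g, toy_phage, model, seed=10)
        win_lo, win_hi = 5000 - model.motif_window, 5000 + model.motif_window
        n_in = sum(1 for e in events
                   if win_lo <= e.position <= win_hi)
        n_out = len(events) - n_in
        bp_in = 2 * model.motif_window + 1
        bp_out = len(g) - bp_in
        ratio = (n_in / bp_in) / (n_out / bp_out)
        se_rel = np.sqrt(1 / n_in + 1 / n_out)
        # reverse events are offset by 5 bp, blurring the window edge a little
        assert abs(ratio - model.motif_boost) <= 3 * se_rel * model.motif_boost \
            + 0.05 * model.motif_boost

    def test_sampled_positions_follow_weights(self, toy_phage):
        """Chi-square goodness of fit on a 10-bin coarsening, alpha=0.01."""
        g = ss.make_host_genome(10_000, 0.65,
                                low_gc_islands=((2001, 2000, 0.40),), seed=14)
        model = ss.SiteModel(immunity_leak=0.0, duplication_offset=0)
        w = ss.site_weights(g, model)
        events = ss.sample_insertions(100_000, g, toy_phage, model, seed=15)
        pos = np.array([e.position - 1 for e in events])
        obs, _ = np.histogram(pos, bins=10, range=(0, len(g)))
        bins = np.array_split(w, 10)
        exp = np.array([b.sum() for b in bins]) / w.sum() * len(events)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=9)


class TestSampleInsertions:
    def test_zero_leak_means_no_phage_events(self, small_host, toy_phage):
        model = ss.SiteModel(immunity_leak=0.0)
        events = ss.sample_insertions(5000, small_host, toy_phage, model,
                                      seed=16)
        assert all(e.target == "host" for e in events)

    def test_leak_fraction_binomial(self, small_host, toy_phage):
        model = ss.SiteModel(immunity_leak=0.004)
        n = 200_000
        events = ss.sample_insertions(n, small_host, toy_phage, model, seed=17)
        k = sum(e.target == "phage" for e in events)
        se = np.sqrt(0.004 * 0.996 / n)
        assert abs(k / n - 0.004) <= 3 * se

    def test_reverse_offset_shifts_positions(self, small_host, toy_phage):
        model = ss.SiteModel(motif_positions=(25_000,), motif_window=0,
                             motif_boost=1e9, immunity_leak=0.0)
        events = ss.sample_insertions(2000, small_host, toy_phage, model,
                                      seed=18)
        fwd = {e.position for e in events if e.orientation == "forward"}
        rev = {e.position for e in events if e.orientation == "reverse"}
        assert fwd == {25_000}
        assert rev == {25_005}


class TestPackageReads:
    def test_whole_virion_left_junction_structure(self, small_host, toy_phage):
        ev = [ss.InsertionEvent("host", 10_000, "forward")]
        rs = ss.package_reads(ev, small_host, toy_phage, mode="whole-virion",
                              seed=19)
        hits = 0
        for rid, seq in rs:
            for lf in range(31, 37):
                host_part = seq[:lf]
                if (seq[lf:lf + 3] == "TGT"
                        and host_part == small_host.fetch(10_000 - lf, 10_000)
                        and seq[lf:lf + 50] == toy_phage.seq[:50]):
                    hits += 1
                    break
        assert hits >= 1

    def test_enriched_right_reads_start_with_right_end(self, enriched_readset,
                                                       toy_phage):
        _, rs = enriched_readset
        rend = right_end_seq(toy_phage)
        for rid, seq in rs.reads[:200]:
            fwd = seq.startswith(rend)
            rev = ss.revcomp(seq).startswith(rend)
            assert fwd or rev

    def test_linear_host_drops_overhanging_events(self, toy_phage):
        host = ss.make_host_genome(5000, 0.6, seed=20, circular=False)
        ev = [ss.InsertionEvent("host", 4990, "forward"),
              ss.InsertionEvent("host", 2500, "forward")]
        rs = ss.package_reads(ev, host, toy_phage, mode="enriched-right",
                              seed=21)
        assert rs.dropped == 1
        assert len(rs.truth) == 1

    def test_truth_round_trip_via_pipeline(self, enriched_readset,
                                           small_host, toy_phage):
        """Junction counting downstream matches the truth table."""
        _, rs = enriched_readset
        jr, tally = ss.filter_valid_right(rs, right_end_seq(toy_phage),
                                          min_host=12)
        n_truth = sum(1 for rid, ev in rs.truth.items())
        # every truth read has >= 170 bp of flank, so all are valid
        assert len(jr) == n_truth == tally["accepted"]


class TestDomainProfile:
    def test_stepwise_profile_and_gap(self):
        prof = ss.domain_profile(1000, (301, 701), (1.0, 5.0, 2.0),
                                 protected_gap_span=(498, 510))
        assert prof[0] == 1.0 and prof[350] == 5.0 and prof[800] == 2.0
        assert (prof[497:510] == 0).all()

    def test_scaled_profile_masses(self):
        prof = ss.scaled_domain_profile(10_000, include_gap=False,
                                        boundary_peak_rel=0.0)
        assert len(prof) == 10_000
        # relative density plateau of the central domain is the largest
        mid = prof[len(prof) // 2 - 200]
        assert mid == max(p for p in np.unique(prof))

    def test_config_round_trip(self, tmp_path):
        cfg = ss.RunConfig(seed=9, n_events=123, host_gc=0.6,
                           host_islands="100:50:0.4")
        p = tmp_path / "run.cfg"
        cfg.to_file(str(p))
        assert ss.RunConfig.from_file(str(p)) == cfg
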