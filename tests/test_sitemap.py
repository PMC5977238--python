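"""Seed index, fragment placement, site-table construction."""

import numpy as np
import pytest

import saltosites as ss
from saltosites.model import FORWARD, REVERSE


class TestSeedIndex:
    def test_linear_seed_count(self):
        g = ss.Genome("g", "ACGT" * 25, circular=False)  # 100 bp
        idx = ss.build_index(g, k=15)
        assert idx.n_seeds == 100 - 15 + 1 == 86

    def test_circular_wraparound_kmers(self):
        g = ss.make_host_genome(200, 0.5, seed=1, circular=True)
        idx = ss.build_index(g, k=15)
        assert idx.n_seeds == 200
        wrap = g.seq[-7:] + g.seq[:8]
        assert 193 in idx.lookup(wrap).tolist()

    def test_planted_unique_kmer_lookup(self):
        g = ss.make_host_genome(5000, 0.65, planted_motifs=((1001, "A" * 15),),
                                seed=2)
        idx = ss.build_index(g, k=15)
        hits = idx.lookup("A" * 15)
        assert 1000 in hits.tolist()


class TestPlaceFragment:
    def test_exact_copy_unique_forward(self, small_host):
        idx = ss.build_index(small_host)
        frag = small_host.seq[5000:5034]
        pl = ss.place_fragment(frag, idx, junction_side="start")
        assert pl.status == "unique"
        assert pl.position == 5001 and pl.orientation == FORWARD
        assert pl.mismatches == 0 and pl.gaps == 0

    def test_junction_side_and_strand_conventions(self, small_host):
        idx = ss.build_index(small_host)
        frag = small_host.seq[5000:5034]
        assert ss.place_fragment(frag, idx, junction_side="end").position == 5034
        rc = ss.revcomp(frag)
        pl = ss.place_fragment(rc, idx, junction_side="start")
        assert pl.orientation == REVERSE and pl.position == 5034
        pl = ss.place_fragment(rc, idx, junction_side="end")
        assert pl.orientation == REVERSE and pl.position == 5001

    def test_short_fragment_threshold_arithmetic(self, small_host):
        """floor(2% of 34) = 0: one substitution makes a 34-mer unmappable."""
        idx = ss.build_index(small_host)
        frag = list(small_host.seq[8000:8034])
        frag[17] = "A" if frag[17] != "A" else "C"
        pl = ss.place_fragment("".join(frag), idx)
        assert pl.status == "unmapped"

    def test_long_fragment_tolerates_threshold_mismatches(self, small_host):
        """floor(2% of 100) = 2 mismatches pass; 3 fail."""
        idx = ss.build_index(small_host)
        base = list(small_host.seq[8000:8100])
        for i in (10, 50):
            base[i] = "A" if base[i] != "A" else "C"
        pl = ss.place_fragment("".join(base), idx)
        assert pl.status == "unique" and pl.mismatches == 2
        base[80] = "A" if base[80] != "A" else "C"
        pl3 = ss.place_fragment("".join(base), idx)
        assert pl3.status == "unmapped"

    def test_gap_allowance_uses_edlib_path(self, small_host):
        """floor(3% of 100) = 3 gap bases: a 2 bp deletion still places."""
        idx = ss.build_index(small_host)
        window = small_host.seq[8000:8102]
        frag = window[:40] + window[42:]  # 100 bp with a 2 bp deletion
        pl = ss.place_fragment(frag, idx)
        assert pl.status == "unique"
        assert pl.gaps == 2 and pl.position == 8001

    def test_empty_fragment_rejected(self, small_host):
        idx = ss.build_index(small_host)
        with pytest.raises(ValueError):
            ss.place_fragment("", idx)

    def test_duplicated_fragment_ambiguous(self):
        g = ss.Genome("g", ("ACGTTGCACCGGTAAGGCCTTACGTAGCAT" * 2
                            + ss.make_host_genome(940, 0.5, seed=3).seq),
                      circular=False)
        idx = ss.build_index(g)
        pl = ss.place_fragment("ACGTTGCACCGGTAAGGCCTTACGTAGCAT", idx)
        assert pl.status == "ambiguous"

    def test_against_sliding_hamming_oracle(self):
        """200 fragments with <=1 substitution vs an exhaustive both-strand
        Hamming scan of a 20 kb genome: identical status calls and, for
        uniques, identical location."""
        g = ss.make_host_genome(20_000, 0.65, seed=4, circular=False)
        idx = ss.build_index(g)
        rng = np.random.default_rng(5)
        enc = np.frombuffer(g.seq.encode(), dtype=np.uint8)
        L = 60
        n_win = len(g) - L + 1
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)

        def oracle(frag: str):
            fa = np.frombuffer(frag.encode(), dtype=np.uint8)
            ra = np.frombuffer(ss.revcomp(frag).encode(), dtype=np.uint8)
            mm_f = (windows != fa).sum(axis=1)
            mm_r = (windows != ra).sum(axis=1)
            max_mm = int(0.02 * L)
            best = min(mm_f.min(), mm_r.min())
            if best > max_mm:
                return ("unmapped", None)
            n_best = int((mm_f == best).sum() + (mm_r == best).sum())
            if n_best > 1:
                return ("ambiguous", None)
            if (mm_f == best).any():
                return ("unique", int(np.nonzero(mm_f == best)[0][0]) + 1)
            pos0 = int(np.nonzero(mm_r == best)[0][0])
            return ("unique", pos0 + L)  # junction side start, reverse

        for i in range(200):
            p = int(rng.integers(0, n_win))
            frag = list(g.seq[p:p + L])
            if rng.random() < 0.7:
                j = int(rng.integers(0, L))
                frag[j] = "ACGT"[int(rng.integers(0, 4))]
            frag = "".join(frag)
            want_status, want_pos = oracle(frag)
            pl = ss.place_fragment(frag, idx, max_gap_frac=0.0,
                                   junction_side="start")
            assert pl.status == want_status, (i, frag)
            if want_status == "unique":
                assert pl.position == want_pos


class TestSiteTable:
    def test_build_site_table_counts(self, small_host):
        pls = [ss.Placement("a", 10, FORWARD, 0, 0, "unique"),
               ss.Placement("b", 10, FORWARD, 0, 0, "unique"),
               ss.Placement("c", 10, REVERSE, 0, 0, "unique"),
               ss.Placement("d", None, None, 0, 0, "ambiguous"),
               ss.Placement("e", None, None, 0, 0, "unmapped")]
        t = ss.build_site_table(pls, small_host)
        assert t.counts == {(10, FORWARD): 2, (10, REVERSE): 1}
        assert t.total_events == 3

    def test_empty_table(self, small_host):
        t = ss.build_site_table([], small_host)
        assert t.total_events == 0 and t.counts == {}

    def test_tsv_round_trip(self, small_host, tmp_path):
        t = ss.SiteTable(small_host.name, len(small_host),
                         {(5, FORWARD): 2, (9, REVERSE): 1})
        p = tmp_path / "sites.tsv"
        t.to_tsv(str(p))
        t2 = ss.SiteTable.from_tsv(str(p))
        assert t2.counts == t.counts and t2.length == t.length

    def test_strand_consistency_under_reference_revcomp(self):
        """Reverse-complementing the reference swaps orientations and
        mirrors junction coordinates."""
        g = ss.make_host_genome(4000, 0.6, seed=6, circular=False)
        gr = ss.Genome("rc", ss.revcomp(g.seq), circular=False)
        idx, idxr = ss.build_index(g), ss.build_index(gr)
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = int(rng.integers(0, 3900))
            frag = g.seq[p:p + 40]
            a = ss.place_fragment(frag, idx, junction_side="start")
            b = ss.place_fragment(frag, idxr, junction_side="start")
            assert a.status == b.status == "unique"
            assert a.orientation != b.orientation
            # the junction base maps to the mirrored coordinate
            assert b.position == len(g) - a.position + 1


class TestMegabaseScaleUniqueness:
    def test_short_fragments_unique_on_6mb_genome(self):
        """Error-free fragments >= 25 bp drawn from a 6 Mb random genome:
        >= 99% place uniquely and every unique call is at the truth
        position."""
        g = ss.make_host_genome(6_000_000, 0.65, seed=61, circular=False)
        idx = ss.build_index(g, k=15)
        rng = np.random.default_rng(62)
        n = uniq = at_truth = 0
        for _ in range(400):
            L = int(rng.integers(25, 70))
            p = int(rng.integers(0, len(g) - L))
            frag = g.seq[p:p + L]
            pl = ss.place_fragment(frag, idx, junction_side="start")
            n += 1
            if pl.status == "unique":
                uniq += 1
                at_truth += (pl.position == p + 1
                             and pl.orientation == "forward")
        assert uniq / n >= 0.99
        assert at_truth == uniq


class TestRoundTripOnSimulatedFragments:
    def test_error_free_fragments_unique_at_truth(self, enriched_readset,
                                                  small_host, toy_phage):
        events, rs = enriched_readset
        cut = ss.find_enzyme_cut_sites(toy_phage)[-1]
        jr, _ = ss.filter_valid_right(rs, toy_phage.seq[cut:])
        frs = [ss.trim_and_annotate(j) for j in jr]
        idx = ss.build_index(small_host)
        pidx = ss.build_index(toy_phage)
        n = ok = 0
        for fr in frs:
            ev = rs.truth[fr.read_id]
            target_idx = idx if ev.target == "host" else pidx
            pl = ss.place_fragment(fr.seq, target_idx, junction_side="start")
            n += 1
            if (pl.status == "unique" and pl.position == ev.position
                    and pl.orientation == ev.orientation):
                ok += 1
        assert n > 1500
        assert ok / n >= 0.99
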