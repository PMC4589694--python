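import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplimine import PcrParams, SequenceRecord, find_primer_sites, pair_hits, revcomp, simulate_pcr
from amplimine.pcr_engine import PrimerHit, iupac_match

from conftest import make_record, random_dna
from oracles import oracle_simulate, oracle_sites, rc as oracle_rc


class TestRevcomp:
    def test_palindrome(self):
        assert revcomp("ACGT") == "ACGT"

    def test_ambiguity_codes(self):
        assert revcomp("AAN") == "NTT"
        assert revcomp("RYSWKM") == "KMWSRY"

    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=0, max_size=60))
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40))
    def test_agrees_with_set_based_oracle(self, seq):
        assert revcomp(seq) == oracle_rc(seq)


class TestIupacMatch:
    @pytest.mark.parametrize("p,t,expected", [
        ("A", "A", True), ("A", "C", False),
        ("R", "A", True), ("R", "G", True), ("R", "C", False),
        ("N", "A", True), ("N", "T", True),
        ("A", "N", False), ("N", "N", False),  # target N never matches
        ("B", "C", True), ("B", "A", False),
        ("R", "R", True), ("R", "W", False),   # subset rule on sets
    ])
    def test_table(self, p, t, expected):
        assert iupac_match(p, t) is expected


class TestFindPrimerSites:
    def _plant(self, rng, primer, edits=0):
        """Random target with a planted copy; flanks screened clean."""
        site = list(primer)
        if edits:
            pos = rng.choice(range(2, len(primer) - 2), size=edits, replace=False)
            for p in pos:
                site[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[p]]
        from amplimine.synth_fixtures import _draw_bg
        left = _draw_bg(rng, 40, 0.5, [primer], "flank")
        right = _draw_bg(rng, 40, 0.5, [primer], "flank")
        return left + "".join(site) + right

    def test_planted_exact_site_single_hit(self, rng):
        primer = random_dna(rng, 20)
        target = make_record(self._plant(rng, primer))
        hits = find_primer_sites(target, primer, PcrParams(), "+")
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.mismatches, h.gaps) == (41, 60, 0, 0)

    def test_three_substitutions_over_budget(self, rng):
        primer = random_dna(rng, 20)
        target = make_record(self._plant(rng, primer, edits=3))
        assert find_primer_sites(target, primer, PcrParams(n_max=2), "+") == []

    def test_minus_strand_coordinates_mirror(self, rng):
        primer = random_dna(rng, 20)
        seq = self._plant(rng, primer)
        plus = find_primer_sites(make_record(seq), primer, PcrParams(), "+")
        minus = find_primer_sites(make_record(revcomp(seq)), primer, PcrParams(), "-")
        L = len(seq)
        assert [(L - h.end + 1, L - h.start + 1) for h in plus] == \
            [(h.start, h.end) for h in minus]

    def test_short_primer_rejected(self, rng):
        target = make_record(random_dna(rng, 100))
        with pytest.raises(ValueError):
            find_primer_sites(target, "ACGTACGTA", PcrParams(), "+")

    @pytest.mark.parametrize("n_max,g_max", [(0, 0), (2, 0), (0, 2), (2, 2), (1, 1)])
    def test_matches_window_dp_oracle(self, rng, n_max, g_max):
        """Hit set identical to the exhaustive per-window DP oracle."""
        params = PcrParams(n_max=n_max, g_max=g_max)
        for trial in range(4):
            primer = random_dna(rng, int(rng.integers(15, 26)))
            seq = random_dna(rng, 300, gc=0.5)
            if trial % 2 == 0:  # plant a site with random edits
                site = list(primer)
                for p in rng.choice(range(2, len(primer) - 2),
                                    size=int(rng.integers(0, 3)), replace=False):
                    site[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[p]]
                seq = seq[:150] + "".join(site) + seq[150:]
            got = find_primer_sites(make_record(seq), primer, params, "+")
            expected = oracle_sites(seq, primer, n_max, g_max)
            assert [(h.start - 1, h.end - h.start + 1, h.mismatches, h.gaps)
                    for h in got] == expected


def _hit(start, end, strand, role="forward", mm=0, gp=0):
    return PrimerHit(record_id="r", primer_role=role, strand=strand,
                     start=start, end=end, mismatches=mm, gaps=gp)


class TestPairHits:
    def test_forced_geometry(self):
        fw = _hit(101, 120, "+")
        rv = _hit(181, 200, "-", role="reverse")
        pairs = pair_hits([fw], [rv], PcrParams(d_min=50, d_max=500))
        assert pairs == [(fw, rv)]
        span = rv.end - fw.start + 1
        assert span == 100

    def test_d_min_excludes(self):
        fw = _hit(101, 120, "+")
        rv = _hit(181, 200, "-", role="reverse")
        assert pair_hits([fw], [rv], PcrParams(d_min=150, d_max=500)) == []

    def test_overlapping_footprints_excluded(self):
        fw = _hit(101, 120, "+")
        rv = _hit(115, 134, "-", role="reverse")
        assert pair_hits([fw], [rv], PcrParams(d_min=10, d_max=500)) == []

    def test_divergent_orientation_excluded(self):
        # reverse-primer match upstream of the forward match on '+' geometry
        fw = _hit(181, 200, "+")
        rv = _hit(101, 120, "-", role="reverse")
        assert pair_hits([fw], [rv], PcrParams(d_min=10, d_max=500)) == []

    def test_matches_cross_product_oracle(self, rng):
        params = PcrParams(d_min=60, d_max=200)
        fw_hits = [_hit(s, s + 19, "+") for s in (10, 80, 150, 260)]
        rv_hits = [_hit(s, s + 19, "-", role="reverse") for s in (40, 120, 200, 300)]
        got = pair_hits(fw_hits, rv_hits, params)
        expected = [
            (f, r) for f in fw_hits for r in rv_hits
            if r.start > f.end and params.d_min <= r.end - f.start + 1 <= params.d_max
        ]
        assert got == expected


class TestSimulatePcr:
    def _method(self, method_factory):
        return method_factory(probe=False)

    def test_constructed_product(self, rng, method_factory):
        m = self._method(method_factory)
        from amplimine.synth_fixtures import _draw_bg
        primers = [m.fw_primer, m.rv_primer]
        spacer = _draw_bg(rng, 64, 0.5, primers, "spacer")
        seq = m.fw_primer + spacer + revcomp(m.rv_primer)
        amps = simulate_pcr(make_record(seq), m, PcrParams())
        assert len(amps) == 1
        a = amps[0]
        assert (a.product_length, a.total_edits, a.strand) == (104, 0, "+")
        assert a.sequence == seq

    def test_strand_symmetry(self, rng, method_factory):
        m = self._method(method_factory)
        from amplimine.synth_fixtures import _draw_bg
        primers = [m.fw_primer, m.rv_primer]
        spacer = _draw_bg(rng, 64, 0.5, primers, "spacer")
        flank_l = _draw_bg(rng, 30, 0.5, primers, "f")
        flank_r = _draw_bg(rng, 50, 0.5, primers, "f")
        seq = flank_l + m.fw_primer + spacer + revcomp(m.rv_primer) + flank_r
        fwd = simulate_pcr(make_record(seq), m, PcrParams())
        bwd = simulate_pcr(make_record(revcomp(seq)), m, PcrParams())
        assert len(fwd) == len(bwd) == 1
        L = len(seq)
        assert bwd[0].strand == "-"
        assert bwd[0].sequence == fwd[0].sequence
        assert (bwd[0].start, bwd[0].end) == (L - fwd[0].end + 1, L - fwd[0].start + 1)

    def test_combined_edit_filter(self, rng, method_factory):
        """fw 2 mm + rv 1 mm: within per-primer bounds, over the summed cap."""
        m = self._method(method_factory)

        def mutate(p, k):
            s = list(p)
            for pos in range(3, 3 + 3 * k, 3):
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            return "".join(s)

        from amplimine.synth_fixtures import _draw_bg
        primers = [m.fw_primer, m.rv_primer]
        spacer = _draw_bg(rng, 64, 0.5, primers, "spacer")
        seq = mutate(m.fw_primer, 2) + spacer + revcomp(mutate(m.rv_primer, 1))
        rec = make_record(seq)
        assert simulate_pcr(rec, m, PcrParams(total_edit_max=2)) == []
        amps = simulate_pcr(rec, m, PcrParams(total_edit_max=4))
        assert len(amps) == 1 and amps[0].total_edits == 3

    def test_product_lengths_within_window(self, rng, params):
        from amplimine import FixtureSpec, generate_dataset, make_panel
        panel = make_panel(seed=5)
        bundle = generate_dataset(FixtureSpec(seed=5, n_transgenic=4, n_plant=2,
                                              n_patent_constructs=1, redundancy=2), panel)
        for recd in bundle.all_records:
            for m in panel:
                for a in simulate_pcr(recd, m, params):
                    assert params.d_min <= a.product_length <= params.d_max
                    assert a.total_edits <= params.total_edit_max
                    assert a.product_length == a.end - a.start + 1
                    assert len(a.sequence) == a.product_length

    def test_matches_brute_force_oracle(self, rng, method_factory):
        m = self._method(method_factory)
        params = PcrParams(d_min=50, d_max=300)
        spacer = random_dna(rng, 70)
        seq = (random_dna(rng, 60) + m.fw_primer + spacer
               + revcomp(m.rv_primer) + random_dna(rng, 60))
        got = simulate_pcr(make_record(seq), m, params)
        expected = oracle_simulate(seq, m.fw_primer, m.rv_primer,
                                   params.d_min, params.d_max,
                                   params.n_max, params.g_max,
                                   params.total_edit_max)
        assert [(a.start - 1, a.end, a.strand, a.fw_mismatches, a.fw_gaps,
                 a.rv_mismatches, a.rv_gaps) for a in got] == expected
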