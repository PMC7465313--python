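"""Guide scanning, specificity, orientation, SNP effects and panels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import capxcise as cx
from capxcise._dna import random_dna, revcomp
from capxcise.guides import SITE_LENGTH


def brute_force_pam_scan(sequence):
    """Independent O(n) sliding-window oracle for NGG sites on both strands."""
    seq = sequence.upper()
    found = set()
    for i in range(len(seq) - SITE_LENGTH + 1):
        site = seq[i:i + SITE_LENGTH]
        if site[21] == "G" and site[22] == "G":
            found.add((i + 1, i + SITE_LENGTH, "+"))
        rc = revcomp(site)
        if rc[21] == "G" and rc[22] == "G":
            found.add((i + 1, i + SITE_LENGTH, "-"))
    return found


class TestScanPams:
    def test_no_gg_dinucleotide_means_no_candidates(self):
        assert cx.scan_pams("ATATATATATATATATATATATATATAT") == []

    def test_single_site_input_yields_one_forward_candidate(self):
        guides = cx.scan_pams("GTCATATCTAAGGACCCGCGTGG")
        fwd = [g for g in guides if g.strand == "+"]
        assert len(fwd) == 1
        g = fwd[0]
        assert g.pam == "TGG" and (g.start, g.end) == (1, 23)
        assert g.protospacer == "GTCATATCTAAGGACCCGCG"

    @pytest.mark.parametrize("seed", [3, 17, 99])
    def test_matches_brute_force_oracle(self, seed):
        seq = random_dna(np.random.default_rng(seed), 500)
        got = {(g.start, g.end, g.strand) for g in cx.scan_pams(seq)}
        assert got == brute_force_pam_scan(seq)

    @given(st.integers(0, 10_000))
    def test_property_equals_oracle_on_random_sequences(self, seed):
        seq = random_dna(np.random.default_rng(seed), 200)
        got = {(g.start, g.end, g.strand) for g in cx.scan_pams(seq)}
        assert got == brute_force_pam_scan(seq)

    def test_roi_restricts_and_validates(self):
        seq = random_dna(np.random.default_rng(0), 300)
        inside = cx.scan_pams(seq, roi=(50, 150))
        assert all(50 <= g.start and g.end <= 150 for g in inside)
        with pytest.raises(ValueError):
            cx.scan_pams(seq, roi=(0, 500))


def _plant(genome_rng, site, positions=()):
    """A 2 kb sequence with the plus-strand 23-mer ``site`` planted at 1000,
    optionally with substitutions at given protospacer positions."""
    seq = list(random_dna(genome_rng, 2000))
    planted = list(site)
    for p in positions:
        planted[p - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[planted[p - 1]]
    seq[999:999 + 23] = planted
    return "".join(seq)


@pytest.fixture()
def planted_guide():
    rng = np.random.default_rng(8)
    proto = random_dna(rng, 20)
    site = proto + "AGG"
    return cx.Guide(name="g", protospacer=proto, pam="AGG", contig="c",
                    start=1000, end=1022, strand="+"), site, rng


class TestSpecificity:
    def test_single_planted_site_one_perfect_hit(self, planted_guide):
        guide, site, rng = planted_guide
        genome = {"c": _plant(rng, site)}
        hits = cx.specificity_search(guide, genome, max_mismatches=3)
        perfect = [h for h in hits if h.mismatches == 0]
        assert len(perfect) == 1
        assert (perfect[0].start, perfect[0].end) == (1000, 1022)

    def test_two_mismatch_secondary_site_recovered_with_positions(self, planted_guide):
        guide, site, rng = planted_guide
        seq = _plant(rng, site)
        secondary = _plant(rng, site, positions=(4, 9))
        genome = {"c": seq, "c2": secondary}
        hits = cx.specificity_search(guide, genome, max_mismatches=3)
        sec = [h for h in hits if h.contig == "c2" and h.mismatches == 2]
        assert len(sec) == 1
        assert sec[0].mismatch_positions == (4, 9)

    def test_strand_symmetry_under_reverse_complement(self, planted_guide):
        guide, site, rng = planted_guide
        seq = _plant(rng, site)
        hits = cx.specificity_search(guide, {"c": seq}, 3)
        mirrored = cx.specificity_search(guide, {"c": revcomp(seq)}, 3)
        L = len(seq)
        flipped = {(L - h.end + 1, L - h.start + 1,
                    "-" if h.strand == "+" else "+", h.mismatch_positions)
                   for h in hits}
        got = {(h.start, h.end, h.strand, h.mismatch_positions) for h in mirrored}
        assert got == flipped

    def test_score_100_iff_single_hit_and_duplicate_halves(self, planted_guide):
        guide, site, rng = planted_guide
        hits = cx.specificity_search(guide, {"c": _plant(rng, site)}, 3)
        only = [h for h in hits if h.mismatches == 0]
        assert cx.specificity_score(only) == 100.0
        dup = only + [cx.OffTargetHit("c9", 5, 27, "+", 0, ())]
        assert cx.specificity_score(dup) == pytest.approx(50.0)

    def test_score_matches_hand_summed_weight_formula(self):
        penalties = cx.load_mismatch_penalties()
        on = cx.OffTargetHit("c", 100, 122, "+", 0, ())
        off = cx.OffTargetHit("c", 500, 522, "+", 4, (3, 7, 12, 18))
        w = 1.0
        for p in (3, 7, 12, 18):
            w *= 1.0 - penalties[p - 1]
        expected = 100.0 / (1.0 + w)
        assert cx.specificity_score([on, off]) == pytest.approx(expected)

    def test_any_secondary_hit_strictly_lowers_score(self):
        on = cx.OffTargetHit("c", 100, 122, "+", 0, ())
        score = 100.0
        hits = [on]
        for mm_positions in [(1,), (1, 2), (14, 15, 16, 17)]:
            hits = hits + [cx.OffTargetHit("c", 900, 922, "-",
                                           len(mm_positions), mm_positions)]
            new = cx.specificity_score(hits)
            assert new < score
            score = new

    def test_missing_intended_site_is_error(self):
        with pytest.raises(ValueError):
            cx.specificity_score([])
        with pytest.raises(ValueError):
            cx.specificity_score([cx.OffTargetHit("c", 1, 23, "+", 1, (5,))])


def _guide(start, strand, seq="GTCATATCTAAGGACCCGCGTGG"):
    return cx.Guide("g", seq[:20], seq[20:], "c", start, start + 22, strand)


class TestOrientation:
    ROI = (5000, 8000)

    def test_forward_upstream_points_toward(self):
        assert cx.orientation(_guide(3000, "+"), self.ROI) == "toward"

    def test_forward_downstream_points_away(self):
        assert cx.orientation(_guide(9000, "+"), self.ROI) == "away"

    def test_reverse_downstream_points_toward(self):
        assert cx.orientation(_guide(9000, "-"), self.ROI) == "toward"

    def test_reverse_upstream_points_away(self):
        assert cx.orientation(_guide(3000, "-"), self.ROI) == "away"

    def test_flips_with_strand_and_with_roi_side(self):
        for start in (2000, 10_000):
            fwd = cx.orientation(_guide(start, "+"), self.ROI)
            rev = cx.orientation(_guide(start, "-"), self.ROI)
            assert {fwd, rev} == {"toward", "away"}
        assert (cx.orientation(_guide(2000, "+"), self.ROI)
                != cx.orientation(_guide(10_000, "+"), self.ROI))

    def test_guide_inside_roi_is_error(self):
        with pytest.raises(ValueError):
            cx.orientation(_guide(6000, "+"), self.ROI)


class TestSnpEffect:
    def _setup(self, mutate=None):
        rng = np.random.default_rng(21)
        proto = random_dna(rng, 20)
        guide = cx.Guide("g", proto, "TGG", "c", 501, 523, "+")
        hap = list(random_dna(rng, 1200))
        hap[500:523] = proto + "TGG"
        if mutate:
            pos, base = mutate
            hap[pos - 1] = base
        return guide, "".join(hap)

    def test_identical_site_cleaves_fully(self):
        guide, hap = self._setup()
        cls = cx.snp_effect(guide, hap)
        assert cls.kind == "full" and cls.multiplier == 1.0

    def test_pam_disruption_abolishes_cleavage(self):
        # final PAM G -> A, as in a guide whose target PAM carries a SNP
        guide, hap = self._setup(mutate=(523, "A"))
        cls = cx.snp_effect(guide, hap)
        assert cls.kind == "none"
        assert cls.multiplier <= 0.05

    def test_distal_protospacer_snp_reduces_mildly(self):
        guide, hap = self._setup()
        hap = hap[:502] + {"A": "C", "C": "G", "G": "T", "T": "A"}[hap[502]] + hap[503:]
        cls = cx.snp_effect(guide, hap)
        assert cls.kind == "reduced"
        assert cls.mismatch_positions == (3,)

    def test_seed_snp_penalised_more_than_distal(self):
        guide, hap = self._setup()
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        distal = hap[:502] + flip[hap[502]] + hap[503:]        # position 3
        seed = hap[:515] + flip[hap[515]] + hap[516:]          # position 16
        m_distal = cx.snp_effect(guide, distal).multiplier
        m_seed = cx.snp_effect(guide, seed).multiplier
        assert 0 < m_seed < m_distal < 1


@pytest.fixture(scope="module")
def chrom():
    return random_dna(np.random.default_rng(77), 60_000)


class TestPlanPanel:
    def test_excision_flanks_and_points_toward(self, chrom):
        roi = (25_000, 33_000)
        panel = cx.plan_panel(chrom, roi, "excision", guides_per_side=2)
        assert len(panel) == 4
        assert all(cx.orientation(g, roi) == "toward" for g in panel)
        cuts = sorted(cx.cut_position(g) for g in panel)
        assert cuts[1] < roi[0] and cuts[2] > roi[1]

    def test_tiling_gaps_within_band(self, chrom):
        roi = (15_000, 40_000)
        panel = cx.plan_panel(chrom, roi, "tiling")
        cuts = [cx.cut_position(g) for g in panel]
        gaps = [b - a for a, b in zip(cuts, cuts[1:])]
        assert gaps and all(5000 <= g <= 10_000 for g in gaps)
        assert cuts[0] <= roi[0] + 10_000 and cuts[-1] >= roi[1]

    def test_single_cut_reads_into_the_unknown(self, chrom):
        roi = (25_000, 33_000)
        [g] = cx.plan_panel(chrom, roi, "single_cut", known_end="left")
        assert cx.orientation(g, roi) == "toward"
        assert g.end < roi[0] and g.strand == "+"

    def test_impossible_panel_names_constraint(self):
        with pytest.raises(cx.PanelError, match="toward-oriented"):
            cx.plan_panel("AT" * 200, (150, 250), "excision")


class TestGuideIO:
    def test_tsv_round_trip(self, tmp_path):
        guides = cx.reference_guides()
        cx.guides_to_tsv(guides, tmp_path / "g.tsv")
        back = cx.guides_from_tsv(tmp_path / "g.tsv")
        assert back == guides

    def test_reference_panel_shape(self):
        guides = cx.reference_guides()
        assert len(guides) == 4
        assert all(g.pam.endswith("GG") for g in guides)
        assert [g.strand for g in guides] == ["+", "+", "-", "+"]
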