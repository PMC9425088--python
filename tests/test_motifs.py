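import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualreg.genomic import GeneModel, Interval, Peak, reverse_complement
from dualreg.motifs import (
    PWM,
    classify_binding_mode,
    iupac_to_pwm,
    log_odds_score,
    motif_similarity,
    read_jaspar_pfm,
    read_meme_motifs,
    scan,
    score_pvalue,
    write_meme_motifs,
)

NEG_INF = float("-inf")


def enumeration_pvalue(pwm: PWM, score: float, granularity: float = 1e-3) -> float:
    """Independent oracle: exhaustive 4^w enumeration in the same integer space."""
    lo = pwm.log_odds()
    ints = np.where(np.isfinite(lo), np.rint(lo / granularity), np.nan)
    bg = np.asarray(pwm.background)
    t = int(np.rint(score / granularity))
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        cols = [ints[j, b] for j, b in enumerate(word)]
        if any(np.isnan(c) for c in cols):
            continue  # -inf word can never reach a finite threshold
        if int(sum(cols)) >= t:
            total += float(np.prod(bg[list(word)]))
    return total


def random_pwm(rng, width, pseudocount_zero=False):
    cols = []
    for _ in range(width):
        if pseudocount_zero and rng.random() < 0.3:
            col = np.zeros(4)
            col[rng.integers(0, 4)] = 1.0
        else:
            col = rng.dirichlet(np.ones(4) * rng.uniform(0.3, 3.0))
        cols.append(tuple(col / col.sum()))
    return PWM(f"r{width}", tuple(cols))


class TestIupacToPwm:
    def test_w_column_definition(self):
        pwm = iupac_to_pwm("W", "rna")
        assert pwm.matrix[0] == pytest.approx((0.5, 0.0, 0.0, 0.5))

    def test_consensus_structure(self):
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        assert pwm.width == 7
        point_mass = [j for j, col in enumerate(pwm.matrix) if max(col) == 1.0]
        assert point_mass == [0, 1, 2, 5, 6]
        assert pwm.matrix[4] == pytest.approx((0.5, 0.5, 0.0, 0.0))  # M = A/C

    def test_pseudocount_keeps_columns_stochastic(self):
        pwm = iupac_to_pwm("CCAWMCC", "dna", pseudocount=0.1)
        for col in pwm.matrix:
            assert sum(col) == pytest.approx(1.0, abs=1e-9)
            assert min(col) > 0

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            iupac_to_pwm("CCAXCC", "dna")


class TestLogOddsScore:
    def test_point_mass_consensus_is_two_bits_per_column(self):
        pwm = iupac_to_pwm("CCCCCCC", "dna")
        assert log_odds_score(pwm, "CCCCCCC") == pytest.approx(14.0)

    def test_degenerate_columns_contribute_one_bit(self):
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        assert log_odds_score(pwm, "CCAACCC") == pytest.approx(12.0)

    def test_zero_probability_column_is_minus_infinity(self):
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        assert log_odds_score(pwm, "CCAAGCC") == NEG_INF

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            log_odds_score(iupac_to_pwm("CCAA", "dna"), "CCA")


class TestScorePvalue:
    def test_point_mass_max_score(self):
        pwm = iupac_to_pwm("CCCCCCC", "dna")
        assert score_pvalue(pwm, 14.0) == pytest.approx(0.25**7, rel=1e-12)

    def test_consensus_compatible_words_counted_exactly(self):
        # CCAWMCC at 12 bits: exactly the 2x2 consensus-compatible words
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        assert score_pvalue(pwm, 12.0) == pytest.approx(4 / 4**7, rel=1e-12)

    def test_minus_infinity_threshold(self):
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        assert score_pvalue(pwm, NEG_INF) == 1.0

    def test_monotone_non_increasing(self, rng):
        pwm = random_pwm(rng, 6)
        scores = np.linspace(-10, 12, 40)
        ps = [score_pvalue(pwm, s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_dp_equals_exhaustive_enumeration(self, width, rng):
        for _ in range(15):
            pwm = random_pwm(rng, width, pseudocount_zero=True)
            lo = pwm.log_odds()
            finite = lo[np.isfinite(lo)]
            for q in (0.25, 0.6, 0.95):
                t = float(np.quantile(finite, q)) * width / 2
                assert score_pvalue(pwm, t) == pytest.approx(
                    enumeration_pvalue(pwm, t), rel=1e-9, abs=1e-300
                )


class TestScan:
    def test_planted_consensus_found_once(self):
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        hits = scan("UUUCCAACCCUUU", pwm, p_thresh=2.5e-4)
        assert len(hits) == 1
        assert hits[0].offset == 3
        assert hits[0].score == pytest.approx(12.0, abs=1e-9)
        assert hits[0].p == pytest.approx(4 / 4**7, rel=1e-9)

    def test_poly_a_has_no_hits(self):
        pwm = iupac_to_pwm("CCAWMCC", "rna")
        assert scan("A" * 50, pwm, p_thresh=1e-3) == []

    def test_reverse_strand_hit_reported_on_forward_coordinates(self):
        pwm = iupac_to_pwm("CCTAGCC", "dna")
        word = "CCTAGCC"
        seq = "TTTTT" + reverse_complement(word) + "TTTTT"
        hits = scan(seq, pwm, p_thresh=1e-3, both_strands=True)
        assert [h.strand for h in hits] == ["-"]
        assert hits[0].offset == 5

    def test_strand_mirror_symmetry(self):
        pwm = iupac_to_pwm("CCTAGMC", "dna")
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 400))
        fwd = scan(seq, pwm, p_thresh=5e-3, both_strands=True)
        rev = scan(reverse_complement(seq), pwm, p_thresh=5e-3, both_strands=True)
        mirrored = sorted((len(seq) - pwm.width - h.offset,
                           "+" if h.strand == "-" else "-",
                           round(h.score, 6)) for h in rev)
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 6)) for h in fwd)

    def test_expected_hit_count_on_background(self):
        """Hits on i.i.d. background accrue at ~p_thresh per scanned word."""
        pwm = iupac_to_pwm("CCTAGMCA", "dna", pseudocount=0.25)
        rng = np.random.default_rng(12)
        p_thresh = 2e-3
        n_hits = positions = 0
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), 2000))
            hits = scan(seq, pwm, p_thresh=p_thresh, both_strands=True)
            n_hits += len(hits)
            positions += 2 * (len(seq) - pwm.width + 1)
        # exact per-word rate: P(hit) at this threshold
        rate = score_pvalue(pwm, _threshold_score(pwm, p_thresh))
        expected = positions * rate
        assert abs(n_hits - expected) <= 3 * math.sqrt(expected)


def _threshold_score(pwm, p_thresh):
    """Smallest achievable score whose p-value is still <= p_thresh."""
    lo = pwm.log_odds()
    best = None
    for scale in np.linspace(0, 2 * pwm.width, 2000):
        p = score_pvalue(pwm, scale)
        if p <= p_thresh:
            best = scale
            break
    return best


class TestClassifyBindingMode:
    def setup_case(self, embedded_word, strand="+"):
        rng = np.random.default_rng(9)
        genome_arr = rng.choice(list("ACGT"), 40_000)
        gene = GeneModel("g1", "G1", Interval("chr1", 10_000, 20_000, strand))
        center = gene.tss if strand == "+" else gene.interval.end - 1
        pos = 15_000
        word = embedded_word if strand == "+" else reverse_complement(embedded_word)
        genome_arr[pos : pos + len(word)] = list(word)
        genome = {"chr1": "".join(genome_arr)}
        peak_dna = Peak(Interval("chr1", pos - 100, pos + 100), assay="chip")
        peak_rna = Peak(Interval("chr1", pos - 30, pos + 30, strand), assay="eclip")
        return gene, genome, peak_dna, peak_rna

    self_pwm = iupac_to_pwm("CCGATMCGGA", "dna", name="self")
    partner_pwm = iupac_to_pwm("TTAGGCAWTT", "dna", name="partner")

    def test_self_motif_gives_direct(self):
        gene, genome, peak_dna, _ = self.setup_case("CCGATACGGA")
        call = classify_binding_mode(gene, [peak_dna], [self.self_pwm],
                                     [self.partner_pwm], "dna", genome)
        assert call.mode == "direct" and call.partner is None

    def test_partner_motif_gives_indirect(self):
        gene, genome, peak_dna, _ = self.setup_case("TTAGGCAATT")
        call = classify_binding_mode(gene, [peak_dna], [self.self_pwm],
                                     [self.partner_pwm], "dna", genome)
        assert call.mode == "indirect" and call.partner == "partner"

    def test_rna_layer_respects_strand(self):
        gene, genome, _, peak_rna = self.setup_case("CCGATACGGA", strand="-")
        call = classify_binding_mode(gene, [peak_rna], [self.self_pwm],
                                     [self.partner_pwm], "rna", genome)
        assert call.mode == "direct"

    def test_random_peaks_unresolved(self):
        gene, genome, peak_dna, _ = self.setup_case("AAAAAAAAAA")
        call = classify_binding_mode(gene, [peak_dna], [self.self_pwm],
                                     [self.partner_pwm], "dna", genome)
        assert call.mode == "unresolved"

    def test_no_eligible_peaks_unresolved(self):
        gene, genome, _, _ = self.setup_case("CCGATACGGA")
        far = Peak(Interval("chr1", 100, 300), assay="chip")
        gene_far = GeneModel("g2", "G2", Interval("chr1", 30_000, 39_000, "+"))
        call = classify_binding_mode(gene_far, [far], [self.self_pwm],
                                     [self.partner_pwm], "dna", genome)
        assert call.mode == "unresolved"

    def test_direct_dominates_indirect(self):
        """A self hit wins even when a stronger partner hit exists."""
        gene, genome, peak_dna, _ = self.setup_case("CCGATACGGA")
        # also embed the partner word right next to the self word
        arr = list(genome["chr1"])
        arr[15_020 : 15_030] = list("TTAGGCAATT")
        genome = {"chr1": "".join(arr)}
        call = classify_binding_mode(gene, [peak_dna], [self.self_pwm],
                                     [self.partner_pwm], "dna", genome)
        assert call.mode == "direct"


class TestMotifSimilarity:
    def test_identical_pwms(self, rng):
        pwm = random_pwm(rng, 8)
        r, offset, orient = motif_similarity(pwm, pwm)
        assert r == pytest.approx(1.0) and offset == 0 and orient == "+"

    def test_shifted_copy_found_at_offset(self, rng):
        core = [tuple(rng.dirichlet([0.3] * 4)) for _ in range(6)]
        flat = (0.25, 0.25, 0.25, 0.25)
        a = PWM("a", tuple(core + [flat, flat]))
        b = PWM("b", tuple([flat, flat] + core))
        r, offset, orient = motif_similarity(a, b, min_overlap=4)
        assert offset == -2 and r > 0.99

    def test_overlap_constraint(self, rng):
        with pytest.raises(ValueError, match="min_overlap"):
            motif_similarity(random_pwm(rng, 4), random_pwm(rng, 4), min_overlap=5)

    def test_exhaustive_offset_search(self, rng):
        a, b = random_pwm(rng, 7), random_pwm(rng, 5)
        best_r, best_off, orient = motif_similarity(a, b, min_overlap=4)
        ma = np.asarray(a.matrix)
        brute = -2.0
        for name, mb in (("+", np.asarray(b.matrix)),
                         ("-", np.asarray(b.reverse_complement().matrix))):
            for off in range(-1, 4):
                lo_a, hi_a = max(0, off), min(7, off + 5)
                if hi_a - lo_a < 4:
                    continue
                xa = ma[lo_a:hi_a].ravel()
                xb = mb[lo_a - off : hi_a - off].ravel()
                brute = max(brute, float(np.corrcoef(xa, xb)[0, 1]))
        assert best_r == pytest.approx(brute, abs=1e-12)


class TestMotifIO:
    def test_meme_round_trip(self, tmp_path, rng):
        pwms = [random_pwm(rng, 6), iupac_to_pwm("CCAWMCC", "dna", pseudocount=0.1)]
        pwms = [PWM(f"m{i}", p.matrix, "dna", p.background) for i, p in enumerate(pwms)]
        path = tmp_path / "motifs.meme"
        write_meme_motifs(pwms, path)
        back = read_meme_motifs(path)
        assert [p.name for p in back] == ["m0", "m1"]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-5)

    def test_jaspar_pfm(self, tmp_path):
        path = tmp_path / "a.pfm"
        path.write_text(
            ">MA0001 test\n"
            "A [ 0  3  0 ]\n"
            "C [ 9  0  0 ]\n"
            "G [ 0  6  9 ]\n"
            "T [ 0  0  0 ]\n"
        )
        (pwm,) = read_jaspar_pfm(path)
        assert pwm.width == 3
        assert pwm.matrix[0] == pytest.approx((0, 1, 0, 0))
        assert pwm.matrix[1] == pytest.approx((1 / 3, 0, 2 / 3, 0))
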