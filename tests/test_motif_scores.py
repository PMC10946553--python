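"""Motif scoring against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from splicepipe.motif_scores import (
    BP_SENTINEL,
    MaxEntLikeModel,
    PwmModel,
    ScoringError,
    bp_score,
    esr_delta,
    ppt_score,
    score_variant_motifs,
    ssf_score,
)
from splicepipe.reference_io import GenomicVariant, classify_region
from splicepipe.resources import BASES, BASE_INDEX

BASES4 = "ACGT"


def _random_pwm(rng, width):
    f = rng.dirichlet(np.ones(4), size=width)
    return PwmModel("donor", f)


class TestSsfScore:
    def test_argmax_sequence_scores_100(self, rng):
        m = _random_pwm(rng, 9)
        seq = "".join(BASES4[i] for i in m.freqs.argmax(axis=1))
        assert ssf_score(m, seq) == pytest.approx(100.0)

    def test_argmin_sequence_scores_0(self, rng):
        m = _random_pwm(rng, 9)
        seq = "".join(BASES4[i] for i in m.freqs.argmin(axis=1))
        assert ssf_score(m, seq) == pytest.approx(0.0)

    def test_matches_direct_formula_recomputation(self, rng):
        """Oracle: recompute 100·(Σf−Σmin)/(Σmax−Σmin) independently."""
        for _ in range(25):
            m = _random_pwm(rng, 9)
            seq = "".join(BASES4[i] for i in rng.integers(0, 4, 9))
            total = sum(m.freqs[i][BASE_INDEX[b]] for i, b in enumerate(seq))
            lo = sum(min(row) for row in m.freqs)
            hi = sum(max(row) for row in m.freqs)
            expected = 100.0 * (total - lo) / (hi - lo)
            assert ssf_score(m, seq) == pytest.approx(expected, abs=1e-9)

    def test_non_acgt_base_raises(self, rng):
        m = _random_pwm(rng, 9)
        with pytest.raises(ScoringError):
            ssf_score(m, "ACGTNACGT")


class TestMaxEntLike:
    def test_uniform_signal_equals_background_gives_zero(self):
        m = MaxEntLikeModel(
            site_kind="donor",
            width=3,
            order=0,
            log_p0=np.log2(np.full((3, 4), 0.25)),
        )
        for seq in itertools.product(BASES4, repeat=3):
            assert m.score("".join(seq)) == pytest.approx(0.0, abs=1e-12)

    def test_order1_matches_exhaustive_probability_enumeration(self, rng):
        """Oracle: enumerate all 64 3-mers; the trained model's implied
        probabilities must sum to 1 and match chain-rule products to 1e-9."""
        seqs = ["".join(BASES4[i] for i in rng.integers(0, 4, 3)) for _ in range(200)]
        m = MaxEntLikeModel.train("donor", seqs, order=1, pseudocount=0.7)
        p0 = 2.0 ** m.log_p0
        p1 = 2.0 ** m.log_p1
        total = 0.0
        for mer in itertools.product(range(4), repeat=3):
            prob = p0[0, mer[0]] * p1[0, mer[0], mer[1]] * p1[1, mer[1], mer[2]]
            bg = 0.25**3
            seq = "".join(BASES4[i] for i in mer)
            assert m.score(seq) == pytest.approx(math.log2(prob / bg), abs=1e-9)
            total += prob
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_order0_single_base_monotonicity(self, rng):
        """Replacing a base with a higher-signal-probability base never
        decreases an order-0 score."""
        seqs = ["".join(BASES4[i] for i in rng.integers(0, 4, 5)) for _ in range(300)]
        m = MaxEntLikeModel.train("donor", seqs, order=0)
        p0 = 2.0 ** m.log_p0
        for _ in range(50):
            seq = list(BASES4[i] for i in rng.integers(0, 4, 5))
            i = int(rng.integers(5))
            better = BASES4[int(np.argmax(p0[i]))]
            s1 = m.score("".join(seq))
            seq2 = list(seq)
            seq2[i] = better
            assert m.score("".join(seq2)) >= s1 - 1e-12

    def test_score_table_dialect(self):
        table = {"ACG": 1.25}
        m = MaxEntLikeModel.from_score_table("donor", 3, table)
        assert m.score("ACG") == 1.25
        with pytest.raises(ScoringError):
            m.score("TTT")


class TestEsrDelta:
    TABLE = {
        "".join(h): 0.1 * i
        for i, h in enumerate(itertools.product(BASES4, repeat=6))
    }

    def _brute(self, wt, mut, lo_wt, hi_wt, lo_mut, hi_mut):
        def windows(seq, lo, hi):
            return sum(
                self.TABLE[seq[j : j + 6]]
                for j in range(max(0, lo - 5), min(len(seq) - 5, hi))
            )

        return windows(mut, lo_mut, hi_mut) - windows(wt, lo_wt, hi_wt)

    def test_synonymous_no_change_is_zero(self):
        wt = "ACGTACGTACGT"
        assert esr_delta(self.TABLE, wt, wt, 6) == 0.0

    def test_interior_substitution_vs_hand_enumeration(self, rng):
        for _ in range(20):
            wt = "".join(BASES4[i] for i in rng.integers(0, 4, 12))
            off = int(rng.integers(5, 7))
            alt = BASES4[int(rng.integers(4))]
            mut = wt[:off] + alt + wt[off + 1 :]
            expected = self._brute(wt, mut, off, off + 1, off, off + 1)
            assert esr_delta(self.TABLE, wt, mut, off) == pytest.approx(expected, abs=1e-9)

    def test_edge_substitution_uses_truncated_windows(self):
        wt = "ACGTACGTACGT"
        off = 1  # 2 nt from the window edge: only windows 0..1 are feasible
        mut = wt[:off] + "T" + wt[off + 1 :]
        expected = self._brute(wt, mut, off, off + 1, off, off + 1)
        assert esr_delta(self.TABLE, wt, mut, off) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry(self, rng):
        wt = "".join(BASES4[i] for i in rng.integers(0, 4, 12))
        mut = wt[:6] + ("A" if wt[6] != "A" else "C") + wt[7:]
        d1 = esr_delta(self.TABLE, wt, mut, 6)
        d2 = esr_delta(self.TABLE, mut, wt, 6)
        assert d1 == pytest.approx(-d2, abs=1e-12)


class TestBranchPointAndPpt:
    def _brute_bp(self, seq, window, lam, freqs):
        near, far = window
        L = len(seq)
        best, pos = BP_SENTINEL, None
        for d in range(near, far + 1):
            i = L - d
            if seq[i] != "A":
                continue
            mer = seq[i - 3 : i + 4]
            pwm = sum(
                math.log2(freqs[k][BASE_INDEX[b]] / 0.25) for k, b in enumerate(mer)
            )
            pyr_seq = seq[i + 1 : L - 4]
            pyr = sum(b in "CT" for b in pyr_seq) / len(pyr_seq) if pyr_seq else 0.0
            s = pwm + lam * pyr
            if s > best or (s == best and pos is not None and -d > pos):
                best, pos = s, -d
        return best, pos

    def test_scan_matches_brute_force_at_every_adenosine(self, rng):
        from splicepipe.resources import branch_point_frequencies

        freqs = branch_point_frequencies()
        for _ in range(20):
            seq = "".join(BASES4[i] for i in rng.integers(0, 4, 50))
            got = bp_score(seq, lam=1.0)
            want = self._brute_bp(seq, (18, 44), 1.0, freqs)
            assert got[1] == want[1]
            if got[1] is not None:
                assert got[0] == pytest.approx(want[0], abs=1e-9)

    def test_window_without_adenosine_returns_sentinel(self):
        seq = "C" * 50
        score, pos = bp_score(seq)
        assert score == BP_SENTINEL and pos is None

    def test_removing_isolated_top_adenosine_never_improves(self, rng):
        """Destroying the top branch A removes its candidate; if no other
        candidate window overlaps the edited base, the maximum cannot rise
        (pyrimidine term off, so scores elsewhere are untouched)."""
        checked = 0
        while checked < 20:
            seq = list("".join(BASES4[i] for i in rng.integers(0, 4, 50)))
            best, pos = bp_score("".join(seq), lam=0.0)
            if pos is None:
                continue
            i = len(seq) + pos
            if any(seq[j] == "A" for j in range(i - 3, i + 4) if j != i):
                continue  # an overlapping 7-mer could legitimately improve
            seq[i] = "G"
            best2, pos2 = bp_score("".join(seq), lam=0.0)
            assert best2 <= best + 1e-12
            assert pos2 != pos
            checked += 1

    def test_short_window_raises(self):
        with pytest.raises(ScoringError):
            bp_score("A" * 50, window=(18, 22))

    def test_ppt_extremes_and_hand_count(self):
        assert ppt_score("CTCTCTCTCTCTC") == pytest.approx(1.0)
        assert ppt_score("AGAGAGAGAGAGA") == pytest.approx(0.0)
        assert ppt_score("CTAGCTAGCTAG") == pytest.approx(6 / 12)


class TestVariantMotifScoring:
    def test_deep_intronic_substitution_leaves_site_deltas_zero(
        self, small_reference, scoring_models
    ):
        r = small_reference
        for t in r.transcripts:
            introns = t.introns()
            long_introns = [iv for iv in introns if iv[1] - iv[0] > 800]
            if not long_introns:
                continue
            s, e = long_introns[0]
            mid = (s + e) // 2
            if r.excluded(t.chrom, mid):
                mid += 11
            ref_b = r.genome.fetch(t.chrom, mid, mid + 1)
            var = GenomicVariant(t.chrom, mid + 1, ref_b, "A" if ref_b != "A" else "C")
            ctx = classify_region(t, var)
            assert ctx.region == "deep_intronic"
            ms = score_variant_motifs(ctx, r.genome, scoring_models)
            assert ms.delta_ssf_donor == 0.0 and ms.delta_mes_donor == 0.0
            assert ms.delta_ssf_acceptor == 0.0 and ms.delta_mes_acceptor == 0.0
            assert ms.delta_esr == 0.0
            return
        pytest.skip("no long intron in fixture")

    def test_donor_plus1_G_to_A_strictly_lowers_both_site_scores(
        self, small_reference, scoring_models
    ):
        r = small_reference
        t = next(iter(r.transcripts))
        site = t.donor_sites()[0]
        ref_b = r.genome.fetch(t.chrom, site, site + 1)
        alt = {"G": "A", "C": "T"}[ref_b]  # sense G>A on either strand
        var = GenomicVariant(t.chrom, site + 1, ref_b, alt)
        ctx = classify_region(t, var)
        ms = score_variant_motifs(ctx, r.genome, scoring_models)
        assert ms.ssf_mut_donor < ms.ssf_wt_donor
        assert ms.mes_mut_donor < ms.mes_wt_donor

    def test_wild_type_fields_do_not_depend_on_alt(self, small_reference, scoring_models):
        r = small_reference
        t = next(iter(r.transcripts))
        site = t.donor_sites()[0]
        ref_b = r.genome.fetch(t.chrom, site + 2, site + 3)
        alts = [b for b in "ACGT" if b != ref_b]
        sets = []
        for alt in alts:
            ctx = classify_region(t, GenomicVariant(t.chrom, site + 3, ref_b, alt))
            sets.append(score_variant_motifs(ctx, r.genome, scoring_models))
        assert len({(m.ssf_wt_donor, m.mes_wt_donor) for m in sets}) == 1
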