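"""Site training sets, the logistic site-use metascore, de novo/cryptic
scanning, and the consensus alteration probability."""

import numpy as np
import pandas as pd
import pytest

from splicepipe.motif_scores import ScoringModels
from splicepipe.reference_io import Genome, GenomicVariant, Transcript, TranscriptIndex, classify_region
from splicepipe.resources import synthesize_esr_table
from splicepipe.site_metascore import (
    SiteMetascore,
    SpiceModel,
    build_site_training_set,
    calibrate_site_threshold,
    scan_for_new_sites,
    spice_like_probability,
    train_site_use_model,
    train_spice_model,
)
from splicepipe.synthetic_data import simulate_reference


class TestSiteTrainingSet:
    def test_positive_count_matches_annotated_boundaries(self, small_reference, scoring_models):
        r = small_reference
        df = build_site_training_set(r.transcripts, r.genome, scoring_models)
        n_donors = sum(t.n_introns for t in r.transcripts)
        pos = df[df.label == 1]
        assert len(pos[pos.kind == "donor"]) == n_donors
        assert len(pos[pos.kind == "acceptor"]) == n_donors

    def test_four_exon_toy_gives_three_of_each(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        g = Genome({"c": seq})
        t = Transcript(
            id="T4", chrom="c", strand="+",
            exons=((100, 300), (700, 900), (1400, 1600), (2100, 2300)),
        )
        table = synthesize_esr_table(0)
        # train site models on a generated reference; count sites on the toy
        sm = ScoringModels(
            donor_pwm=None, acceptor_pwm=None, donor_mes=None, acceptor_mes=None,
            bp_freqs=None, esr_table=table,
        )
        ref = simulate_reference(n_transcripts=2, seed=0, esr_table=table)
        sm = ScoringModels.from_reference(ref.genome, ref.transcripts, table)
        df = build_site_training_set(TranscriptIndex([t]), g, sm)
        pos = df[df.label == 1]
        assert (pos.kind == "donor").sum() == 3
        assert (pos.kind == "acceptor").sum() == 3

    def test_negatives_exclude_every_positive_position(self, small_reference, scoring_models):
        r = small_reference
        df = build_site_training_set(r.transcripts, r.genome, scoring_models)
        pos_keys = set(map(tuple, df[df.label == 1][["kind", "transcript", "pos"]].to_numpy()))
        neg_keys = set(map(tuple, df[df.label == 0][["kind", "transcript", "pos"]].to_numpy()))
        assert not pos_keys & neg_keys

    def test_ratio_subsampling_and_warning(self, small_reference, scoring_models):
        r = small_reference
        df = build_site_training_set(r.transcripts, r.genome, scoring_models, ratio=10, seed=0)
        for kind, grp in df.groupby("kind"):
            n_pos = (grp.label == 1).sum()
            assert (grp.label == 0).sum() == 10 * n_pos
        with pytest.warns(UserWarning):
            build_site_training_set(
                r.transcripts, r.genome, scoring_models, ratio=10_000, seed=0
            )


class TestSiteUseModel:
    def test_no_signal_gives_flat_coefficients(self, rng):
        n = 800
        feats = rng.normal(size=(n, 3))
        labels = rng.integers(0, 2, n)
        df = pd.DataFrame(feats, columns=["mes", "ssf", "esr"])
        df["label"] = labels
        df["kind"] = "donor"
        m, _ = train_site_use_model(df, seed=0)
        assert np.all(np.abs(m.beta[1:]) < 0.2)
        assert np.all(m.wald_p[1:] > 0.05)

    def test_planted_coefficient_recovery_within_3_se(self, rng):
        beta_true = np.array([-2.0, 1.2, 0.05, 0.8])
        n = 5000
        mes = rng.normal(0, 2, n)
        ssf = rng.normal(60, 15, n)
        esr = rng.normal(0, 1, n)
        z = beta_true[0] + beta_true[1] * mes + beta_true[2] * ssf + beta_true[3] * esr
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        df = pd.DataFrame(dict(mes=mes, ssf=ssf, esr=esr, label=y, kind="donor"))
        m, _ = train_site_use_model(df, split=1.0 - 1e-9, seed=0)
        assert not m.penalized
        for j in range(4):
            assert abs(m.beta[j] - beta_true[j]) < 3 * m.se[j]

    def test_metascore_dominates_each_component_on_synthetic_sites(self):
        """Validation AUC of the combined logistic exceeds MES, SSF and ESR
        alone — the qualitative ordering of the underlying tool comparison."""
        from sklearn.metrics import roc_auc_score

        ref = simulate_reference(n_transcripts=25, seed=42)
        sm = ScoringModels.from_reference(ref.genome, ref.transcripts, ref.esr_table)
        sites = build_site_training_set(ref.transcripts, ref.genome, sm, seed=0)
        for kind, grp in sites.groupby("kind"):
            m, valid = train_site_use_model(grp.reset_index(drop=True), seed=0)
            auc_meta = roc_auc_score(valid.label, valid.p)
            for comp in ("mes", "ssf", "esr"):
                assert auc_meta > roc_auc_score(valid.label, valid[comp]), (kind, comp)

    def test_threshold_calibration_holds_on_a_fresh_draw(self):
        """98%-specificity threshold recalibrates within ±0.5% on new sites."""
        ref_a = simulate_reference(n_transcripts=20, seed=101)
        sm = ScoringModels.from_reference(ref_a.genome, ref_a.transcripts, ref_a.esr_table)
        sites = build_site_training_set(ref_a.transcripts, ref_a.genome, sm, seed=0)
        ref_b = simulate_reference(n_transcripts=20, seed=202, esr_table=ref_a.esr_table)
        fresh = build_site_training_set(ref_b.transcripts, ref_b.genome, sm, seed=0)
        for kind, grp in sites.groupby("kind"):
            m, valid = train_site_use_model(grp.reset_index(drop=True), seed=0)
            tau = calibrate_site_threshold(m, valid, 0.98)
            f = fresh[fresh.kind == kind]
            p = m.probability(f.mes, f.ssf, f.esr)
            spec = float((p[f.label.to_numpy() == 0] < tau).mean())
            assert abs(spec - 0.98) <= 0.005


class TestScan:
    def _neutral_variant(self, ref, t):
        s, e = t.introns()[0]
        g = (s + e) // 2
        while ref.excluded(t.chrom, g):
            g += 7
        b = ref.genome.fetch(t.chrom, g, g + 1)
        return GenomicVariant(t.chrom, g + 1, b, b)

    def test_reference_identical_allele_changes_nothing(
        self, small_reference, scoring_models, metascore
    ):
        r = small_reference
        t = next(iter(r.transcripts))
        var = self._neutral_variant(r, t)
        ctx = classify_region(t, var)
        call = scan_for_new_sites(ctx, r.genome, metascore, scoring_models)
        assert call.mechanism == "none"
        for c in call.candidates:
            assert c.p_mut == pytest.approx(c.p_wt, abs=1e-12)

    def test_candidate_enumeration_matches_brute_force(
        self, small_reference, scoring_models, metascore
    ):
        """Every GT/AG anchor in the mutated window appears as a candidate."""
        r = small_reference
        t = next(iter(r.transcripts))
        lat = [l for l in r.latent_sites if l["tx"] == t.id and l["typ"] == "broken"]
        if not lat:
            pytest.skip("no broken latent on first transcript")
        g, ref_b, alt_b = lat[0]["fix"]
        var = GenomicVariant(t.chrom, g + 1, ref_b, alt_b)
        ctx = classify_region(t, var)
        call = scan_for_new_sites(ctx, r.genome, metascore, scoring_models, window=60)
        from splicepipe.motif_scores import mutated_window
        from splicepipe.reference_io import revcomp

        lo, hi = var.start - 60, var.end + 60
        wt = r.genome.fetch(t.chrom, lo, hi)
        mut = wt[: var.start - lo] + var.alt + wt[var.end - lo :]
        if t.strand == "-":
            mut = revcomp(mut)
        expected = set()
        for i in range(len(mut) - 1):
            if mut[i : i + 2] == "GT":
                expected.add("donor")
            if mut[i : i + 2] == "AG":
                expected.add("acceptor")
        got_kinds = {c.kind for c in call.candidates}
        assert got_kinds <= {"donor", "acceptor"}
        assert expected == got_kinds or expected >= got_kinds

    def test_fixing_a_broken_latent_donor_is_a_de_novo_call(
        self, small_reference, scoring_models, metascore
    ):
        r = small_reference
        hits = 0
        for lat in r.latent_sites:
            if lat["typ"] != "broken":
                continue
            t = r.transcripts[lat["tx"]]
            g, ref_b, alt_b = lat["fix"]
            if r.genome.fetch(t.chrom, g, g + 1) != ref_b:
                continue
            var = GenomicVariant(t.chrom, g + 1, ref_b, alt_b)
            ctx = classify_region(t, var)
            call = scan_for_new_sites(ctx, r.genome, metascore, scoring_models)
            if call.mechanism == "B_de_novo":
                hits += 1
        assert hits >= 3  # most strong broken contexts activate as de novo

    def test_translation_invariance(self, scoring_models, metascore):
        """Shifting genome and annotation by k shifts all candidate positions
        by k and changes nothing else."""
        rng = np.random.default_rng(9)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        k = 17
        g1 = Genome({"c": core})
        g2 = Genome({"c": "T" * k + core})
        t1 = Transcript(id="a", chrom="c", strand="+", exons=((200, 500), (1200, 1500)))
        t2 = Transcript(
            id="a", chrom="c", strand="+", exons=((200 + k, 500 + k), (1200 + k, 1500 + k))
        )
        pos = 800
        b = core[pos]
        var1 = GenomicVariant("c", pos + 1, b, "G" if b != "G" else "A")
        var2 = GenomicVariant("c", pos + k + 1, b, var1.alt)
        c1 = scan_for_new_sites(classify_region(t1, var1), g1, metascore, scoring_models)
        c2 = scan_for_new_sites(classify_region(t2, var2), g2, metascore, scoring_models)
        assert c1.mechanism == c2.mechanism
        assert [(c.kind, c.pos + k, round(c.p_mut, 12)) for c in c1.candidates] == [
            (c.kind, c.pos, round(c.p_mut, 12)) for c in c2.candidates
        ]

    def test_pseudo_exon_pair_flag_on_planted_pairs(
        self, small_reference, scoring_models, metascore
    ):
        r = small_reference
        flagged = total = 0
        for pair in r.pseudo_pairs:
            t = r.transcripts[pair["tx"]]
            g, ref_b, alt_b = pair["fix"]
            if r.genome.fetch(t.chrom, g, g + 1) != ref_b:
                continue
            var = GenomicVariant(t.chrom, g + 1, ref_b, alt_b)
            ctx = classify_region(t, var)
            if ctx.region != "deep_intronic":
                continue
            call = scan_for_new_sites(ctx, r.genome, metascore, scoring_models)
            total += 1
            flagged += call.pseudo_exon_pair
        assert total > 0 and flagged >= max(1, total // 2)


class TestSpiceLike:
    def _fit(self, rng):
        n = 600
        d_ssf = np.concatenate([rng.normal(-25, 6, n // 2), rng.normal(-1, 2, n // 2)])
        rel = np.concatenate([rng.normal(-0.8, 0.2, n // 2), rng.normal(0, 0.05, n // 2)])
        y = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
        return train_spice_model(np.column_stack([d_ssf, rel]), y)

    def test_zero_deltas_give_baseline_probability(self, rng):
        m = self._fit(rng)
        base = 1 / (1 + np.exp(-m.beta[0]))
        assert m.probability(0.0, 0.0) == pytest.approx(base)

    def test_monotone_in_mes_drop(self, rng):
        m = self._fit(rng)
        assert m.beta[2] < 0
        ps = [m.probability(-10.0, r) for r in np.linspace(0, -1.5, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_canonical_destruction_scores_high(
        self, small_reference, scoring_models, fitted
    ):
        from splicepipe.motif_scores import score_variant_motifs

        model, _ = fitted
        r = small_reference
        t = next(iter(r.transcripts))
        site = t.donor_sites()[0]
        ref_b = r.genome.fetch(t.chrom, site, site + 1)
        alt = {"G": "A", "C": "T"}[ref_b]
        var = GenomicVariant(t.chrom, site + 1, ref_b, alt)
        ctx = classify_region(t, var)
        ms = score_variant_motifs(ctx, r.genome, scoring_models)
        p = spice_like_probability(model.spice, ms, ctx.region)
        assert p > 0.9

    def test_outside_consensus_raises(self, fitted):
        from splicepipe.motif_scores import MotifScoreSet

        model, _ = fitted
        with pytest.raises(ValueError):
            spice_like_probability(model.spice, MotifScoreSet(), "deep_intronic")
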