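"""Transcript coordinate maps, HGVS/VCF parsing, and region classification."""

import numpy as np
import pytest

from splicepipe.reference_io import (
    CPos,
    CoordinateRangeError,
    Genome,
    GenomicVariant,
    NullVariantError,
    ReferenceMismatchError,
    Transcript,
    TranscriptIndex,
    UnknownTranscriptError,
    classify_position,
    classify_region,
    format_hgvs,
    map_c_to_g,
    map_g_to_c,
    normalize,
    parse_hgvs,
    read_vcf,
    revcomp,
    write_vcf,
)


def _toy_genome(seq="", name="chrT"):
    rng = np.random.default_rng(0)
    if not seq:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=6000))
    return Genome({name: seq})


def _toy_transcript(strand="+"):
    return Transcript(
        id="TOY", chrom="chrT", strand=strand, exons=((100, 200), (400, 520), (900, 1000))
    )


class TestCoordinateMaps:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_every_position_of_toy_transcript(self, strand):
        t = _toy_transcript(strand)
        lo, hi = t.span
        for g in range(lo, hi):
            assert map_c_to_g(t, map_g_to_c(t, g)) == g

    def test_first_transcribed_base_is_c1(self):
        t = _toy_transcript("+")
        assert str(map_g_to_c(t, 100)) == "1"
        tm = _toy_transcript("-")
        assert str(map_g_to_c(tm, 999)) == "1"

    def test_intronic_offset_rendering(self):
        t = _toy_transcript("+")
        # last base of exon 1 is c.100; 3 nt into the intron is c.100+3
        assert str(map_g_to_c(t, 202)) == "100+3"
        # 1 nt before exon 2 is c.101-1
        assert str(map_g_to_c(t, 399)) == "101-1"

    def test_round_trip_on_generated_transcripts(self, small_reference):
        """c->g->c identity over >=1000 positions of generated transcripts."""
        checked = 0
        for t in small_reference.transcripts:
            lo, hi = t.span
            for g in range(lo, min(hi, lo + 400)):
                assert map_c_to_g(t, map_g_to_c(t, g)) == g
                checked += 1
        assert checked >= 1000

    def test_out_of_flank_raises(self):
        t = _toy_transcript("+")
        with pytest.raises(CoordinateRangeError):
            map_c_to_g(t, CPos(1, -50_000))

    def test_intron_shorter_than_4_rejected(self):
        with pytest.raises(ValueError):
            Transcript(id="x", chrom="c", strand="+", exons=((0, 10), (12, 20)))


class TestHgvsParsing:
    def _index(self):
        # an exon ending at c.4096 followed by an intron, so that the
        # familiar NM-style +3 offset is expressible
        g = _toy_genome("A" * 10 + "ACGT" * 2000)
        t = Transcript(id="NM_007294", chrom="chrT", strand="+", exons=((10, 4106), (5000, 5200)))
        return g, TranscriptIndex([t])

    def test_intronic_substitution_example(self):
        g, idx = self._index()
        base = g.fetch("chrT", 4108, 4109)
        alt = "G" if base != "G" else "A"
        t, var, canon = parse_hgvs(f"NM_007294:c.4096+3{base}>{alt}", idx, g)
        assert var.pos == 4109 and var.ref == base and var.alt == alt
        assert canon == f"c.4096+3{base}>{alt}"
        assert format_hgvs(t, var) == f"NM_007294:c.4096+3{base}>{alt}"

    def test_null_variant_rejected(self):
        g, idx = self._index()
        base = g.fetch("chrT", 20, 21)
        with pytest.raises(NullVariantError):
            parse_hgvs(f"NM_007294:c.11{base}>{base}", idx, g)

    def test_unknown_transcript(self):
        g, idx = self._index()
        with pytest.raises(UnknownTranscriptError):
            parse_hgvs("NM_000000:c.1A>G", idx, g)

    def test_ref_mismatch_reported(self):
        g, idx = self._index()
        base = g.fetch("chrT", 20, 21)
        wrong = "A" if base != "A" else "C"
        with pytest.raises(ReferenceMismatchError):
            parse_hgvs(f"NM_007294:c.11{wrong}>T", idx, g)

    def test_minus_strand_maps_to_reverse_complement(self):
        """Against a hand-enumerated coordinate table of a 2-exon transcript."""
        #            0123456789012345678901234
        seq = "TTTTTGGCCAATTTTTTCCGGATTTTT"
        g = Genome({"chrT": seq})
        t = Transcript(id="M", chrom="chrT", strand="-", exons=((5, 11), (17, 23)))
        idx = TranscriptIndex([t])
        # transcription order: genomic 22..17 then 10..5; c.1 is genomic 22
        # sense sequence: revcomp(CCGGAT) + revcomp(GGCCAA) = ATCCGG TTGGCC
        assert str(map_g_to_c(t, 22)) == "1"
        assert str(map_g_to_c(t, 5)) == "12"
        _, var, _ = parse_hgvs("M:c.3C>A", idx, g)  # sense C at c.3 = genomic G at 20
        assert (var.pos, var.ref, var.alt) == (21, "G", "T")
        assert format_hgvs(t, var) == "M:c.3C>A"

    def test_substitution_round_trip_on_generated_collection(self, small_reference):
        from splicepipe.synthetic_data import CollectionSpec, simulate_collection

        recs = simulate_collection(
            CollectionSpec(n_curated=60, n_controls=140, prevalence=0.1, seed=3),
            small_reference,
        )
        for r in recs:
            text = f"{r.transcript_id}:{r.hgvs_c}"
            t, var, _ = parse_hgvs(text, small_reference.transcripts, small_reference.genome)
            assert format_hgvs(t, var) == text

    def test_indel_formats_are_parse_format_fixed_points(self):
        g, idx = self._index()
        for body in ("c.40_41insACGT", "c.50_52delinsTT"):
            t, var, _ = parse_hgvs(f"NM_007294:{body}", idx, g)
            again = format_hgvs(t, var)
            t2, var2, _ = parse_hgvs(again, idx, g)
            assert (var2.pos, var2.ref, var2.alt) == (var.pos, var.ref, var.alt)


class TestNormalization:
    def test_trim_and_leftalign(self):
        g = Genome({"c": "GGGAAAACCC"})
        v = normalize(GenomicVariant("c", 4, "AAAA", "AAA"), g)  # deletion of one A
        assert (v.pos, v.ref, v.alt) == (4, "A", "")
        v2 = normalize(GenomicVariant("c", 7, "A", "AA"), g)  # insertion left-aligns
        assert (v2.ref, v2.alt) == ("", "A")
        assert v2.pos == 4

    def test_ref_mismatch(self):
        g = Genome({"c": "GGGAAAACCC"})
        with pytest.raises(ReferenceMismatchError):
            normalize(GenomicVariant("c", 1, "T", "A"), g)


class TestVcf:
    def test_multiallelic_split_symbolic_skip_and_round_trip(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\tv1\tA\tG,T\t.\t.\t.\n"
            "chr1\t20\tv2\tC\t<DEL>\t.\t.\t.\n"
            "chr1\t30\tv3\tGA\tG\t.\t.\t.\n"
        )
        with pytest.warns(UserWarning):
            vs = list(read_vcf(p))
        assert [(v.pos, v.ref, v.alt) for v in vs] == [
            (10, "A", "G"),
            (10, "A", "T"),
            (30, "GA", "G"),
        ]
        out = tmp_path / "y.vcf"
        write_vcf(vs, out, contigs=["chr1"])
        back = list(read_vcf(out))
        assert [(v.chrom, v.pos, v.ref, v.alt) for v in back] == [
            (v.chrom, v.pos, v.ref, v.alt) for v in vs
        ]


class TestRegionClassification:
    def test_partition_has_no_gaps_or_overlaps(self, small_reference):
        for t in list(small_reference.transcripts)[:3]:
            lo, hi = t.span
            counts = {}
            for g in range(lo, hi):
                info = classify_position(t, g)
                counts[info["region"]] = counts.get(info["region"], 0) + 1
            assert sum(counts.values()) == hi - lo

    def test_deep_intronic_boundary_is_strict(self):
        t = Transcript(id="x", chrom="c", strand="+", exons=((0, 100), (600, 700)))
        at_150 = classify_position(t, 100 + 149)  # intron +150
        beyond = classify_position(t, 100 + 150)  # intron +151
        assert abs(at_150["dist"]) == 150 and at_150["region"] == "near_intronic"
        assert abs(beyond["dist"]) == 151 and beyond["region"] == "deep_intronic"

    def test_canonical_dinucleotide_positions(self):
        t = Transcript(id="x", chrom="c", strand="+", exons=((0, 100), (600, 700)))
        assert classify_position(t, 100)["region"] == "intronic_consensus_5ss"
        assert classify_position(t, 105)["region"] == "intronic_consensus_5ss"
        assert classify_position(t, 599)["region"] == "intronic_consensus_3ss"
        assert classify_position(t, 99)["region"] == "exonic_consensus"
        assert classify_position(t, 600)["region"] == "exonic_consensus"
        assert classify_position(t, 599 - 5)["region"] == "ppt"
        assert classify_position(t, 599 - 20)["region"] == "bp_region"

    def test_strand_symmetry(self):
        """A mirrored transcript assigns identical labels and distances."""
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        g_plus = Genome({"c": seq})
        g_minus = Genome({"c": revcomp(seq)})
        t_plus = Transcript(id="p", chrom="c", strand="+", exons=((100, 300), (800, 1100)))
        L = 2000
        exons_m = tuple(sorted((L - e, L - s) for s, e in t_plus.exons))
        t_minus = Transcript(id="m", chrom="c", strand="-", exons=exons_m)
        for g in range(100, 1100):
            a = classify_position(t_plus, g)
            b = classify_position(t_minus, L - 1 - g)
            assert a["region"] == b["region"]
            assert a["dist"] == b["dist"]
            assert a["nearest_site_kind"] == b["nearest_site_kind"]

    def test_variant_outside_flank_raises(self):
        t = _toy_transcript("+")
        g = _toy_genome()
        var = GenomicVariant("chrT", 1, g.fetch("chrT", 0, 1), "N")
        with pytest.raises(CoordinateRangeError):
            classify_region(t, var, flank=50)

    def test_indel_labeled_at_most_splice_proximal_base(self):
        t = Transcript(id="x", chrom="c", strand="+", exons=((0, 100), (600, 700)))
        g = Genome({"c": "A" * 700})
        # deletion spanning intron +4..+8: nearest affected base is +4
        var = GenomicVariant("c", 104, "AAAAA", "")
        ctx = classify_region(t, var)
        assert ctx.region == "intronic_consensus_5ss"
        assert ctx.dist_to_nearest_site == 4
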