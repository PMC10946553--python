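"""Synthetic references and labeled variant collections.

The generator emulates the statistical structure of a curated spliceogenic
variant collection embedded in a sea of presumed-neutral common variants:
a low prevalence of spliceogenic variants (default 2.08%), a defect-class
mix dominated by exon skipping, and per-class planted mechanisms (consensus
destruction, ESR hexamer damage, branch point / PPT damage, de novo or
cryptic site creation, deep-intronic paired-site creation for pseudo-exons).

True splice sites are sampled from the package's donor/acceptor frequency
models, so the site models are learnable from generated data by
construction.  Neutral control variants avoid every planted motif window,
except for a small fraction placed at low-information consensus positions
(common variants do occur there in real data, and they give the consensus
alteration model its negative class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import resources
from .reference_io import (
    Genome,
    GenomicVariant,
    Transcript,
    TranscriptIndex,
    classify_region,
    format_hgvs,
    normalize,
    revcomp,
    write_vcf,
)

DEFECT_CLASSES = ("exon_skipping", "site_shift", "pseudo_exon", "intron_retention")
DEFAULT_CATEGORY_MIX = (0.7297, 0.2136, 0.0473, 0.0094)
# sub-mechanism mix within exon skipping: consensus / ESR / BP / PPT
SKIPPING_MECH_MIX = (0.5819, 0.3868, 0.0171, 0.0142)
SHIFT_NATURAL_FRACTION = 0.4964  # natural-site shift vs de novo/cryptic
DENOVO_INTRONIC_FRACTION = 0.4928

_BG_P = np.array([0.275, 0.225, 0.225, 0.275])  # GC ≈ 0.45
BASES = "ACGT"


@dataclass
class CollectionSpec:
    """Shape of a generated variant collection."""

    n_curated: int = 4616
    n_controls: int = 95_000
    prevalence: float = 0.0208
    category_mix: tuple[float, float, float, float] = DEFAULT_CATEGORY_MIX
    seed: int = 0
    consensus_neutral_fraction: float = 0.02

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category mix must sum to 1")

    @property
    def n_total(self) -> int:
        return self.n_curated + self.n_controls


@dataclass
class LabeledVariant:
    variant: GenomicVariant
    transcript_id: str
    hgvs_c: str
    label: int  # 1 spliceogenic, 0 neutral
    defect_class: str  # exon_skipping | site_shift | pseudo_exon | intron_retention | none
    mechanism: str  # planted motif mechanism
    region: str


@dataclass
class SyntheticReference:
    """A generated genome with its annotation and planting records."""

    genome: Genome
    transcripts: TranscriptIndex
    esr_table: dict[str, float]
    ese_sites: list = field(default_factory=list)  # (tx_id, g_start) sense hexamer
    latent_sites: list = field(default_factory=list)  # dicts, see planting code
    pseudo_pairs: list = field(default_factory=list)
    bp_sites: list = field(default_factory=list)  # (tx_id, g_of_branch_A)
    exclusions: dict = field(default_factory=dict)  # chrom -> [(start, end)]
    seed: int = 0

    def excluded(self, chrom: str, g: int) -> bool:
        for s, e in self.exclusions.get(chrom, ()):
            if s <= g < e:
                return True
        return False

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(out / "genome.fa")
        self.transcripts.to_exon_table(out / "transcripts.tsv")
        resources.write_esr_tsv(self.esr_table, out / "esr_table.tsv")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.transcripts:
                lo, hi = t.span
                fh.write(
                    f"{t.chrom}\t.\tmRNA\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\tID={t.id}\n"
                )
                for i, (s, e) in enumerate(t.exons):
                    fh.write(
                        f"{t.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"ID={t.id}.e{i};Parent={t.id}\n"
                    )


def _sample_from_pwm(rng, freqs: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, p=row / row.sum())] for row in freqs)


def _sample_strong(rng, freqs: np.ndarray, boost: float = 0.85) -> str:
    """Consensus-leaning draw: used for latent cryptic/de novo contexts,
    which must be strong enough to be usable once activated."""
    out = []
    for row in freqs:
        if rng.random() < boost:
            out.append(BASES[int(np.argmax(row))])
        else:
            out.append(BASES[rng.choice(4, p=row / row.sum())])
    return "".join(out)


def _rand_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=_BG_P))


class _SenseBuilder:
    """Builds one transcript contig in transcript-sense space, then flips."""

    def __init__(self, rng, seq_len: int):
        self.seq = list(_rand_seq(rng, seq_len))

    def write(self, start: int, motif: str) -> None:
        self.seq[start : start + len(motif)] = list(motif)

    def read(self, start: int, end: int) -> str:
        return "".join(self.seq[start:end])


def simulate_reference(
    n_transcripts: int = 30,
    seed: int = 0,
    exon_range: tuple[int, int] = (90, 240),
    exons_per_transcript: tuple[int, int] = (5, 9),
    flank: int = 600,
    latent_per_intron: int = 3,
    esr_table: dict[str, float] | None = None,
) -> SyntheticReference:
    """Generate a genome (one contig per transcript) with planted splice
    biology.  Deterministic per seed."""
    if n_transcripts < 1 or exon_range[0] < 30:
        raise ValueError("infeasible reference sizes")
    rng = np.random.default_rng(seed)
    table = esr_table if esr_table is not None else resources.synthesize_esr_table(seed + 1)
    eses = resources.planted_enhancers(table)
    donor_f = resources.donor_frequencies()
    acceptor_f = resources.acceptor_frequencies()
    bp_f = resources.branch_point_frequencies()

    ref = SyntheticReference(
        genome=None, transcripts=None, esr_table=table, seed=seed
    )
    contigs, transcripts = {}, []

    for ti in range(n_transcripts):
        tx_id = f"TX{ti:03d}"
        chrom = f"chr{ti:03d}"
        strand = "+" if ti % 2 == 0 else "-"
        n_ex = int(rng.integers(exons_per_transcript[0], exons_per_transcript[1] + 1))
        ex_lens = rng.integers(exon_range[0], exon_range[1] + 1, size=n_ex)
        in_lens = []
        for _ in range(n_ex - 1):
            u = rng.random()
            if u < 0.40:
                in_lens.append(int(rng.integers(250, 800)))
            elif u < 0.75:
                in_lens.append(int(rng.integers(800, 2500)))
            else:
                in_lens.append(int(rng.integers(2500, 7000)))
        total = flank * 2 + int(ex_lens.sum()) + sum(in_lens)
        b = _SenseBuilder(rng, total)

        # sense-space exon coordinates
        exons_s = []
        pos = flank
        for i, L in enumerate(ex_lens):
            exons_s.append((pos, pos + int(L)))
            pos += int(L)
            if i < n_ex - 1:
                pos += in_lens[i]

        recs = dict(ese=[], latent=[], pairs=[], bp=[], excl=[])

        def exclude(s, e):
            recs["excl"].append((s, e))

        # exonic ESEs
        for s, e in exons_s:
            n_ese = max(1, (e - s) // 110)
            spots = rng.choice(
                np.arange(s + 8, e - 14), size=min(n_ese, e - s - 22), replace=False
            )
            for sp in sorted(int(x) for x in spots):
                hexamer = eses[int(rng.integers(len(eses)))]
                b.write(sp, hexamer)
                recs["ese"].append(sp)
                exclude(sp - 1, sp + 7)

        def plant_ese(sp: int) -> None:
            hexamer = eses[int(rng.integers(len(eses)))]
            b.write(sp, hexamer)
            recs["ese"].append(sp)
            exclude(sp - 1, sp + 7)

        # splice sites, branch points, PPT are implied by the acceptor PWM;
        # ESEs cluster in the exonic flank of each true site, which is what
        # makes the ESR context informative about site use
        for i in range(n_ex - 1):
            don_exon_end = exons_s[i][1]  # sense +1 base index
            acc_exon_start = exons_s[i + 1][0]
            plant_ese(don_exon_end - int(rng.integers(10, 22)))
            plant_ese(don_exon_end - int(rng.integers(24, 36)))
            plant_ese(don_exon_end - int(rng.integers(38, 50)))
            plant_ese(acc_exon_start + int(rng.integers(4, 16)))
            plant_ese(acc_exon_start + int(rng.integers(18, 30)))
            plant_ese(acc_exon_start + int(rng.integers(32, 44)))
            donor = list(_sample_from_pwm(rng, donor_f))
            donor[3], donor[4] = "G", "T"
            b.write(don_exon_end - 3, "".join(donor))
            exclude(don_exon_end - 4, don_exon_end + 7)
            acceptor = list(_sample_from_pwm(rng, acceptor_f))
            acceptor[18], acceptor[19] = "A", "G"
            b.write(acc_exon_start - 20, "".join(acceptor))
            exclude(acc_exon_start - 21, acc_exon_start + 4)
            # branch point 7-mer, branch A at intron -d
            d = int(rng.integers(22, 36))
            bp = list(_sample_from_pwm(rng, bp_f))
            bp[resources.BP_CENTER] = "A"
            a_idx = acc_exon_start - d  # sense index of the branch A
            b.write(a_idx - resources.BP_CENTER, "".join(bp))
            recs["bp"].append(a_idx)
            exclude(a_idx - 5, a_idx + 5)

        def overlaps_excl(s, e):
            return any(s < ee and e > ss for ss, ee in recs["excl"])

        def plant_side_eses(anchor: int, kind: str) -> None:
            """ESE support on the (pseudo-)exonic side of a latent site."""
            if kind == "donor":
                spots = [anchor - int(rng.integers(13, 27)),
                         anchor - int(rng.integers(29, 45))]
            else:
                spots = [anchor + int(rng.integers(5, 19)),
                         anchor + int(rng.integers(21, 38))]
            for sp in spots:
                if sp >= 6 and not overlaps_excl(sp - 1, sp + 7):
                    plant_ese(sp)

        # latent de novo / cryptic / decoy contexts
        for i in range(n_ex - 1):
            istart, iend = exons_s[i][1], exons_s[i + 1][0]
            ilen = iend - istart
            for _ in range(latent_per_intron):
                intronic = rng.random() < 0.55
                kind = "donor" if rng.random() < 0.5 else "acceptor"
                typ = rng.choice(["broken", "weak", "decoy"], p=[0.4, 0.35, 0.25])
                if intronic:
                    if ilen < 220:
                        continue
                    side_donor = rng.random() < 0.5
                    if side_donor:
                        anchor = istart + int(rng.integers(30, min(145, ilen - 40)))
                    else:
                        anchor = iend - int(rng.integers(60, min(145, ilen - 40)))
                else:
                    s, e = exons_s[i if rng.random() < 0.5 else i + 1]
                    # keep the candidate window clear of the exon's own
                    # consensus splice-site windows
                    anchor = int(rng.integers(s + 26, e - 12))
                span = (anchor - 3, anchor + 6) if kind == "donor" else (anchor - 19, anchor + 4)
                if overlaps_excl(*span):
                    continue
                rec = _plant_latent(b, rng, kind, typ, anchor, donor_f, acceptor_f)
                if rec is None:
                    continue
                rec.update(intronic=intronic)
                recs["latent"].append(rec)
                exclude(anchor - 24, anchor + 10)
                plant_side_eses(anchor, kind)

        # pseudo-exon pairs deep inside long introns
        for i in range(n_ex - 1):
            istart, iend = exons_s[i][1], exons_s[i + 1][0]
            ilen = iend - istart
            if ilen < 700:
                continue
            room = ilen - 170 - 190
            size = int(
                round(math.exp(rng.uniform(math.log(30), math.log(min(963, room)))))
            )
            acc_anchor = istart + int(rng.integers(170, max(171, ilen - size - 190)))
            acceptor = list(_sample_strong(rng, acceptor_f))
            acceptor[18], acceptor[19] = "A", "G"
            b.write(acc_anchor - 19, "".join(acceptor))  # -1 base at acc_anchor
            don_anchor = acc_anchor + size
            donor = list(_sample_strong(rng, donor_f))
            donor[3], donor[4] = "C", "T"  # broken +1
            b.write(don_anchor - 3, "".join(donor))
            # ESE support inside the latent pseudo-exon
            for sp in {acc_anchor + int(rng.integers(5, max(6, min(size - 8, 20)))),
                       don_anchor - int(rng.integers(13, 13 + max(1, min(size - 20, 20))))}:
                if acc_anchor + 4 <= sp and sp + 6 <= don_anchor - 8:
                    plant_ese(sp)
            recs["pairs"].append(
                dict(acc=acc_anchor, don=don_anchor, fix=(don_anchor, "C", "G"))
            )
            exclude(acc_anchor - 23, acc_anchor + 4)
            exclude(don_anchor - 4, don_anchor + 7)

        # flip to genomic space for minus-strand transcripts
        sense = "".join(b.seq)
        L = len(sense)
        if strand == "+":
            contigs[chrom] = sense
            exons_g = tuple(exons_s)
            conv = lambda s_pos: s_pos
            conv_iv = lambda s, e: (s, e)
            conv_base = lambda base: base
        else:
            contigs[chrom] = revcomp(sense)
            exons_g = tuple(sorted((L - e, L - s) for s, e in exons_s))
            conv = lambda s_pos: L - 1 - s_pos
            conv_iv = lambda s, e: (L - e, L - s)
            conv_base = lambda base: revcomp(base)

        t = Transcript(
            id=tx_id,
            chrom=chrom,
            strand=strand,
            exons=exons_g,
            cds_start=exons_g[0][0],
            cds_end=exons_g[-1][1],
        )
        transcripts.append(t)
        for sp in recs["ese"]:
            s, e = conv_iv(sp, sp + 6)
            ref.ese_sites.append((tx_id, s))
        for rec in recs["latent"]:
            g, r, a = rec["fix"]
            ref.latent_sites.append(
                dict(
                    tx=tx_id,
                    kind=rec["kind"],
                    typ=rec["typ"],
                    pos=conv(rec["anchor"]),
                    fix=(conv(g), conv_base(r), conv_base(a)),
                    intronic=rec["intronic"],
                )
            )
        for rec in recs["pairs"]:
            g, r, a = rec["fix"]
            ref.pseudo_pairs.append(
                dict(
                    tx=tx_id,
                    acc=conv(rec["acc"]),
                    don=conv(rec["don"]),
                    fix=(conv(g), conv_base(r), conv_base(a)),
                )
            )
        for a_idx in recs["bp"]:
            ref.bp_sites.append((tx_id, conv(a_idx)))
        ref.exclusions[chrom] = sorted(conv_iv(s, e) for s, e in recs["excl"])

    ref.genome = Genome(contigs)
    ref.transcripts = TranscriptIndex(transcripts)
    return ref


def _plant_latent(b, rng, kind, typ, anchor, donor_f, acceptor_f):
    """Write a latent site context in sense space; returns its record."""
    if kind == "donor":
        motif = list(_sample_strong(rng, donor_f))
        motif[4] = "T"
        if typ == "broken":
            motif[3] = "C"
            fix = (anchor, "C", "G")
        elif typ == "weak":
            motif[3] = "G"
            motif[2], motif[7] = "T", "T"  # corrupt exon -1 and intron +5
            fix = (anchor - 1, "T", "G")
        else:  # decoy: intact strong site
            motif[3] = "G"
            motif[2], motif[7] = "G", "G"
            fix = (anchor, "G", "G")
        b.write(anchor - 3, "".join(motif))
        return dict(kind=kind, typ=typ, anchor=anchor, fix=fix)
    motif = list(_sample_strong(rng, acceptor_f))
    motif[19] = "G"
    if typ == "broken":
        motif[18] = "C"
        fix = (anchor - 1, "C", "A")
    elif typ == "weak":
        motif[18] = "A"
        motif[17], motif[20] = "G", "T"  # corrupt intron -3 and exon +1
        fix = (anchor - 2, "G", "C")
    else:
        motif[18] = "A"
        motif[17], motif[20] = "C", "G"
        fix = (anchor, "A", "A")
    b.write(anchor - 19, "".join(motif))  # -1 base lands at anchor
    return dict(kind=kind, typ=typ, anchor=anchor, fix=fix)


# ---------------------------------------------------------------------------
# Collection simulation
# ---------------------------------------------------------------------------


class _Planter:
    def __init__(self, ref: SyntheticReference, rng):
        self.ref = ref
        self.rng = rng
        self.used: set = set()
        self.donor_f = resources.donor_frequencies()
        self.acceptor_f = resources.acceptor_frequencies()
        self.tx_list = list(ref.transcripts)

    def _take(self, chrom, g, ref_base, alt) -> GenomicVariant | None:
        key = (chrom, g, alt)
        if key in self.used:
            return None
        obs = self.ref.genome.fetch(chrom, g, g + 1)
        if obs != ref_base or alt == ref_base:
            return None
        self.used.add(key)
        return GenomicVariant(chrom, g + 1, ref_base, alt)

    def _sense_base(self, t: Transcript, g: int) -> str:
        base = self.ref.genome.fetch(t.chrom, g, g + 1)
        return base if t.strand == "+" else revcomp(base)

    def _sub_at_sense(self, t: Transcript, g: int, alt_sense: str):
        ref_g = self.ref.genome.fetch(t.chrom, g, g + 1)
        alt_g = alt_sense if t.strand == "+" else revcomp(alt_sense)
        return self._take(t.chrom, g, ref_g, alt_g)

    def _worst_alt(self, freqs_row: np.ndarray, ref_sense: str) -> str:
        order = np.argsort(freqs_row)
        for bi in order:
            if BASES[bi] != ref_sense:
                return BASES[bi]
        raise AssertionError

    def consensus(self, t: Transcript | None = None):
        """Damage a natural consensus site at a high-information position."""
        rng = self.rng
        t = t or self.tx_list[int(rng.integers(len(self.tx_list)))]
        donor = rng.random() < 0.5
        sites = t.donor_sites() if donor else t.acceptor_sites()
        site = sites[int(rng.integers(len(sites)))]
        d = +1 if t.strand == "+" else -1
        if donor:
            # window offsets from the +1 base, in sense: -3..-1 exonic, 0..5 intronic
            offs = [0, 1, -1, 4, 2, 3]
            probs = [0.30, 0.30, 0.12, 0.12, 0.08, 0.08]
            row_of = lambda off: self.donor_f[off + 3]
        else:
            # offsets from the -1 base: negative = deeper intronic, +1.. = exon
            offs = [0, -1, -2, 1, -3]
            probs = [0.32, 0.32, 0.16, 0.12, 0.08]
            row_of = lambda off: self.acceptor_f[off + 19]
        off = int(rng.choice(offs, p=np.array(probs) / sum(probs)))
        g = site + d * off  # sense offset mapped to genomic
        ref_sense = self._sense_base(t, g)
        alt_sense = self._worst_alt(row_of(off), ref_sense)
        v = self._sub_at_sense(t, g, alt_sense)
        return (v, t, "consensus") if v else None

    def esr(self):
        rng = self.rng
        if not self.ref.ese_sites:
            return None
        tx_id, g_start = self.ref.ese_sites[int(rng.integers(len(self.ref.ese_sites)))]
        t = self.ref.transcripts[tx_id]
        j = int(rng.integers(1, 5))  # sense offset within the planted hexamer
        g = g_start + j if t.strand == "+" else g_start + 5 - j
        if not (t.is_exonic(g_start) and t.is_exonic(g_start + 5)):
            return None  # only exonic ESR damage has a splicing read-out
        # evaluate alternates on the sense strand around the edited base
        win = self.ref.genome.fetch(t.chrom, g - 5, g + 6)
        if len(win) != 11:
            return None
        win_s = win if t.strand == "+" else revcomp(win)
        ref_s = win_s[5]
        best_alt, best_delta = None, np.inf
        for alt_s in BASES:
            if alt_s == ref_s:
                continue
            mut_s = win_s[:5] + alt_s + win_s[6:]
            delta = _hex_sum(self.ref.esr_table, mut_s) - _hex_sum(
                self.ref.esr_table, win_s
            )
            if delta < best_delta:
                best_delta, best_alt = delta, alt_s
        if best_alt is None or best_delta > -1.5:
            return None
        v = self._sub_at_sense(t, g, best_alt)
        return (v, t, "esr") if v else None

    def bp(self, mechanism: str = "bp"):
        rng = self.rng
        if not self.ref.bp_sites:
            return None
        tx_id, g = self.ref.bp_sites[int(rng.integers(len(self.ref.bp_sites)))]
        t = self.ref.transcripts[tx_id]
        alt_sense = "C" if rng.random() < 0.5 else "G"
        v = self._sub_at_sense(t, g, alt_sense)
        return (v, t, mechanism) if v else None

    def ppt(self):
        rng = self.rng
        t = self.tx_list[int(rng.integers(len(self.tx_list)))]
        sites = t.acceptor_sites()
        site = sites[int(rng.integers(len(sites)))]
        d = +1 if t.strand == "+" else -1
        for _ in range(10):
            off = int(rng.integers(5, 18))  # intron -5..-17
            g = site - d * (off - 1)
            if self._sense_base(t, g) in "CT":
                v = self._sub_at_sense(t, g, "G" if rng.random() < 0.5 else "A")
                if v:
                    return (v, t, "ppt")
        return None

    def shift_natural(self):
        """Damage a natural site that has a decoy cryptic site nearby."""
        rng = self.rng
        decoys = [l for l in self.ref.latent_sites if l["typ"] == "decoy"]
        if not decoys:
            return None
        lat = decoys[int(rng.integers(len(decoys)))]
        t = self.ref.transcripts[lat["tx"]]
        out = self.consensus(t)
        if out is None:
            return None
        return (out[0], out[1], "shift_natural")

    def denovo(self, intronic: bool):
        rng = self.rng
        pool = [
            l
            for l in self.ref.latent_sites
            if l["typ"] in ("broken", "weak") and l["intronic"] == intronic
        ]
        if not pool:
            return None
        lat = pool[int(rng.integers(len(pool)))]
        t = self.ref.transcripts[lat["tx"]]
        g, ref_g, alt_g = lat["fix"]
        v = self._take(t.chrom, g, ref_g, alt_g)
        mech = "de_novo_intronic" if intronic else "de_novo_exonic"
        return (v, t, mech) if v else None

    def pseudo(self):
        rng = self.rng
        if not self.ref.pseudo_pairs:
            return None
        pair = self.ref.pseudo_pairs[int(rng.integers(len(self.ref.pseudo_pairs)))]
        t = self.ref.transcripts[pair["tx"]]
        g, ref_g, alt_g = pair["fix"]
        v = self._take(t.chrom, g, ref_g, alt_g)
        return (v, t, "pseudo_exon") if v else None

    def control(self, consensus_neutral: bool):
        rng = self.rng
        for _ in range(50):
            t = self.tx_list[int(rng.integers(len(self.tx_list)))]
            lo, hi = t.span
            if consensus_neutral:
                donor = rng.random() < 0.5
                sites = t.donor_sites() if donor else t.acceptor_sites()
                site = sites[int(rng.integers(len(sites)))]
                d = +1 if t.strand == "+" else -1
                off = int(rng.choice([5, 3, 2, -3] if donor else [-3, 1, 2, 3]))
                g = site + d * off
                row = (
                    resources.donor_frequencies()[off + 3]
                    if donor
                    else resources.acceptor_frequencies()[off + 19]
                )
                ref_sense = self._sense_base(t, g)
                order = np.argsort(row)[::-1]  # least damaging substitutions
                mild = [BASES[bi] for bi in order if BASES[bi] != ref_sense][:2]
                alt_sense = mild[int(rng.integers(len(mild)))]
                v = self._sub_at_sense(t, g, alt_sense)
            else:
                g = int(rng.integers(max(0, lo - 200), hi + 200))
                if self.ref.excluded(t.chrom, g):
                    continue
                ref_g = self.ref.genome.fetch(t.chrom, g, g + 1)
                if not ref_g or ref_g not in BASES:
                    continue
                alt = BASES[int(rng.integers(4))]
                if alt == ref_g:
                    continue
                v = self._take(t.chrom, g, ref_g, alt)
            if v:
                return (v, t, "none")
        return None


def _hex_sum(table, seq):
    return sum(table[seq[i : i + 6]] for i in range(len(seq) - 5) if len(seq[i : i + 6]) == 6)


def simulate_collection(
    spec: CollectionSpec, reference: SyntheticReference
) -> list[LabeledVariant]:
    """Plant a labeled collection matching the requested prevalence and mix."""
    rng = np.random.default_rng(spec.seed)
    planter = _Planter(reference, rng)
    n_total = spec.n_total
    k = int(rng.binomial(n_total, spec.prevalence))
    cats = rng.multinomial(k, spec.category_mix)
    records: list[LabeledVariant] = []

    def emit(out, defect):
        v, t, mech = out
        v = normalize(v, reference.genome)
        ctx = classify_region(t, v)
        records.append(
            LabeledVariant(
                variant=v,
                transcript_id=t.id,
                hgvs_c=format_hgvs(t, v).split(":", 1)[1],
                label=0 if defect == "none" else 1,
                defect_class=defect,
                mechanism=mech,
                region=ctx.region,
            )
        )

    def plant(fn, defect, *args, retries=60):
        for _ in range(retries):
            out = fn(*args)
            if out is not None:
                emit(out, defect)
                return True
        return False

    for defect, n_cat in zip(DEFECT_CLASSES, cats):
        for _ in range(int(n_cat)):
            if defect == "exon_skipping":
                mech = ["consensus", "esr", "bp", "ppt"][
                    int(rng.choice(4, p=np.array(SKIPPING_MECH_MIX) / sum(SKIPPING_MECH_MIX)))
                ]
                fn = {
                    "consensus": planter.consensus,
                    "esr": planter.esr,
                    "bp": planter.bp,
                    "ppt": planter.ppt,
                }[mech]
                ok = plant(fn, defect)
            elif defect == "site_shift":
                if rng.random() < SHIFT_NATURAL_FRACTION:
                    ok = plant(planter.shift_natural, defect)
                else:
                    intronic = rng.random() < DENOVO_INTRONIC_FRACTION
                    ok = plant(planter.denovo, defect, intronic)
            elif defect == "pseudo_exon":
                ok = plant(planter.pseudo, defect)
            else:
                ok = plant(planter.bp, defect, "bp_retention")
            if not ok:  # inventory exhausted: fall back to consensus damage
                plant(planter.consensus, defect)

    n_neutral = n_total - k
    n_cons_neutral = int(round(spec.consensus_neutral_fraction * n_neutral))
    for i in range(n_neutral):
        ok = plant(planter.control, "none", i < n_cons_neutral, retries=60)
        if not ok:  # consensus-neutral inventory exhausted: regular control
            plant(planter.control, "none", False, retries=200)

    perm = rng.permutation(len(records))
    return [records[i] for i in perm]


def collection_frame(records: list[LabeledVariant]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            dict(
                variant_id=f"v{i:06d}",
                transcript=r.transcript_id,
                hgvs_c=r.hgvs_c,
                chrom=r.variant.chrom,
                pos=r.variant.pos,
                ref=r.variant.ref,
                alt=r.variant.alt,
                label=r.label,
                defect_class=r.defect_class,
                mechanism=r.mechanism,
                region=r.region,
            )
        )
    return pd.DataFrame(rows)


def write_collection(records: list[LabeledVariant], tsv_path, vcf_path=None) -> None:
    df = collection_frame(records)
    df.to_csv(tsv_path, sep="\t", index=False)
    if vcf_path:
        write_vcf(
            (r.variant for r in records),
            vcf_path,
            contigs=sorted({r.variant.chrom for r in records}),
        )


# ---------------------------------------------------------------------------
# Prevalence estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceEstimate:
    mean: float
    ci_low: float
    ci_high: float
    a_post: float
    b_post: float


def estimate_prevalence(
    k_spliceogenic: int,
    n_total: int,
    prior: tuple[float, float] = (0.5, 0.5),
) -> PrevalenceEstimate:
    """Beta-binomial posterior of the spliceogenic fraction.

    Default prior is Jeffreys, Beta(1/2, 1/2); returns the posterior mean and
    the equal-tailed 95% credible interval.
    """
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("prior parameters must be positive")
    if not 0 <= k_spliceogenic <= n_total:
        raise ValueError("need 0 <= k <= n")
    a_post = a + k_spliceogenic
    b_post = b + n_total - k_spliceogenic
    dist = stats.beta(a_post, b_post)
    return PrevalenceEstimate(
        mean=a_post / (a_post + b_post),
        ci_low=float(dist.ppf(0.025)),
        ci_high=float(dist.ppf(0.975)),
        a_post=a_post,
        b_post=b_post,
    )


# ---------------------------------------------------------------------------
# Collection summaries
# ---------------------------------------------------------------------------


def round_percent(count: int, denominator: int) -> float:
    """100·count/denominator with half-up rounding: 2 decimals, or 3
    significant figures for rare proportions (below 0.5%), which would lose
    their leading digits at 2 decimals."""
    if denominator == 0:
        return float("nan")
    x = Decimal(100 * count) / Decimal(denominator)
    if x != 0 and x < Decimal("0.5"):
        exp = x.adjusted()  # floor(log10 |x|)
        q = Decimal(1).scaleb(exp - 2)
        return float(x.quantize(q, rounding=ROUND_HALF_UP))
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def site_set_ratio(n_true: int, n_false: int) -> float:
    """False:true splice-site ratio of a site training set."""
    if n_true == 0:
        raise ValueError("no true sites")
    return n_false / n_true


@dataclass
class CollectionSummary:
    n_total: int
    n_spliceogenic: int
    category_counts: dict
    category_pct: dict  # % of spliceogenic variants per defect class
    region_counts: dict
    region_spliceogenic_pct: dict  # % spliceogenic per region


def summarize_collection(df: pd.DataFrame) -> CollectionSummary:
    """Per-category and per-region percentages with print-style rounding."""
    if len(df) == 0:
        return CollectionSummary(0, 0, {}, {}, {}, {})
    splice = df[df["label"] == 1]
    cat_counts = splice["defect_class"].value_counts().to_dict()
    n_s = len(splice)
    cat_pct = {c: round_percent(n, n_s) for c, n in sorted(cat_counts.items())}
    region_counts = df["region"].value_counts().to_dict()
    region_pct = {}
    for region, n in sorted(region_counts.items()):
        k = int(((df["region"] == region) & (df["label"] == 1)).sum())
        region_pct[region] = round_percent(k, n)
    return CollectionSummary(
        n_total=len(df),
        n_spliceogenic=n_s,
        category_counts=cat_counts,
        category_pct=cat_pct,
        region_counts=region_counts,
        region_spliceogenic_pct=region_pct,
    )


def summarize_counts(counts: dict[str, int]) -> dict[str, float]:
    """Percentages (half-up rounding) of a plain category→count table."""
    total = sum(counts.values())
    return {c: round_percent(n, total) for c, n in counts.items()}
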