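"""Motif-level scoring of wild-type and mutant sequence.

Four motif families feed the downstream metascores: consensus splice sites
(scored twice, by a Shapiro–Senapathy-style percent PWM and by a trained
log-odds signal model), exonic splicing regulators (hexamer score sums),
the branch point (PWM over a 7-mer centred on the branch adenosine plus a
pyrimidine-context term) and the polypyrimidine tract (weighted pyrimidine
content).  All scores are pure functions of sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import resources
from .reference_io import (
    Genome,
    GenomicVariant,
    Transcript,
    VariantContext,
    revcomp,
)
from .resources import (
    ACCEPTOR_INTRONIC,
    ACCEPTOR_WIDTH,
    BASE_INDEX,
    BP_CENTER,
    BP_WIDTH,
    DONOR_EXONIC,
    DONOR_WIDTH,
)

PYRIMIDINES = frozenset("CT")

BP_SEARCH = (18, 44)  # intron -18..-44 upstream of the acceptor
PPT_SEARCH = (5, 17)  # intron -5..-17
BP_SENTINEL = -50.0  # returned when a search window holds no adenosine


class ScoringError(ValueError):
    pass


def _check_seq(seq: str, width: int) -> None:
    if len(seq) != width:
        raise ScoringError(f"sequence length {len(seq)} != model width {width}")
    if any(b not in BASE_INDEX for b in seq):
        raise ScoringError(f"non-ACGT base in {seq!r}")


# ---------------------------------------------------------------------------
# PWM percent score (SSF-like)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PwmModel:
    """Per-position nucleotide frequencies with percent-scale scoring."""

    site_kind: str  # donor | acceptor
    freqs: np.ndarray  # (width, 4)
    pseudocount: float = 1e-3

    def __post_init__(self):
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @classmethod
    def from_sites(cls, site_kind: str, seqs: list[str], pseudocount: float = 0.5):
        width = len(seqs[0])
        counts = np.full((width, 4), pseudocount)
        for s in seqs:
            _check_seq(s, width)
            for i, b in enumerate(s):
                counts[i, BASE_INDEX[b]] += 1
        return cls(site_kind, counts / counts.sum(axis=1, keepdims=True))


def ssf_score(model: PwmModel, seq: str) -> float:
    """Percent-scale PWM score: 100·(Σf − Σmin)/(Σmax − Σmin), clamped to [0,100]."""
    _check_seq(seq, model.width)
    f = model.freqs
    total = sum(f[i, BASE_INDEX[b]] for i, b in enumerate(seq))
    lo = f.min(axis=1).sum()
    hi = f.max(axis=1).sum()
    return float(np.clip(100.0 * (total - lo) / (hi - lo), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Max-ent-like log-odds model
# ---------------------------------------------------------------------------


@dataclass
class MaxEntLikeModel:
    """Log-odds (base 2) splice-site signal model.

    ``order=0`` is a per-position product model; ``order=1`` conditions each
    position on its predecessor (position-specific first-order Markov).  The
    background is a single nucleotide distribution.  An external score table
    (sequence → score) may stand in for the trained model, for users holding
    the published maximum-entropy tables.
    """

    site_kind: str
    width: int
    order: int = 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    log_p0: np.ndarray | None = None  # (width, 4) log2 probs (order 0 / first pos)
    log_p1: np.ndarray | None = None  # (width-1, 4, 4) log2 P(x_i | x_{i-1})
    score_table: dict[str, float] | None = None

    @classmethod
    def train(
        cls,
        site_kind: str,
        seqs: list[str],
        order: int = 1,
        background: np.ndarray | None = None,
        pseudocount: float = 0.5,
    ) -> "MaxEntLikeModel":
        width = len(seqs[0])
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        c0 = np.full((width, 4), pseudocount)
        c1 = np.full((width - 1, 4, 4), pseudocount)
        for s in seqs:
            _check_seq(s, width)
            idx = [BASE_INDEX[b] for b in s]
            for i, b in enumerate(idx):
                c0[i, b] += 1
            for i in range(1, width):
                c1[i - 1, idx[i - 1], idx[i]] += 1
        p0 = c0 / c0.sum(axis=1, keepdims=True)
        p1 = c1 / c1.sum(axis=2, keepdims=True)
        return cls(
            site_kind=site_kind,
            width=width,
            order=order,
            background=bg / bg.sum(),
            log_p0=np.log2(p0),
            log_p1=np.log2(p1),
        )

    @classmethod
    def from_score_table(cls, site_kind: str, width: int, table: dict[str, float]):
        return cls(site_kind=site_kind, width=width, score_table=dict(table))

    def score(self, seq: str) -> float:
        """log2( P_signal(seq) / P_background(seq) )."""
        _check_seq(seq, self.width)
        if self.score_table is not None:
            try:
                return float(self.score_table[seq])
            except KeyError:
                raise ScoringError(f"{seq!r} absent from external score table") from None
        idx = [BASE_INDEX[b] for b in seq]
        log_bg = float(np.sum(np.log2(self.background[idx])))
        if self.order == 0:
            log_sig = float(sum(self.log_p0[i, b] for i, b in enumerate(idx)))
        else:
            log_sig = float(self.log_p0[0, idx[0]])
            for i in range(1, self.width):
                log_sig += float(self.log_p1[i - 1, idx[i - 1], idx[i]])
        return log_sig - log_bg


def maxent_score(model: MaxEntLikeModel, seq: str) -> float:
    return model.score(seq)


# ---------------------------------------------------------------------------
# ESR hexamer deltas
# ---------------------------------------------------------------------------


def _hexamer_sum(table: dict[str, float], seq: str, lo: int, hi: int) -> float:
    """Sum of scores of hexamers of ``seq`` overlapping bases [lo, hi)."""
    total = 0.0
    for j in range(max(0, lo - 5), min(len(seq) - 5, hi)):
        total += table[seq[j : j + 6]]
    return total


def esr_delta(
    table: dict[str, float],
    exon_seq_wt: str,
    exon_seq_mut: str,
    variant_offset: int,
    ref_len: int = 1,
    alt_len: int = 1,
) -> float:
    """Difference of hexamer score sums over windows touching the edited bases.

    ``variant_offset`` is the 0-based offset of the first edited base within
    the wild-type exonic window; windows are clipped at exon edges, so an
    interior substitution contributes exactly 6 hexamers per allele.
    """
    wt = _hexamer_sum(table, exon_seq_wt, variant_offset, variant_offset + max(ref_len, 1))
    mut = _hexamer_sum(
        table, exon_seq_mut, variant_offset, variant_offset + max(alt_len, 1)
    )
    return mut - wt


def esr_context_mean(table: dict[str, float], seq: str) -> float:
    """Mean hexamer score over a context window (0 when too short)."""
    if len(seq) < 6:
        return 0.0
    vals = [table[seq[j : j + 6]] for j in range(len(seq) - 5) if _is_acgt(seq[j : j + 6])]
    return float(np.mean(vals)) if vals else 0.0


def _is_acgt(s: str) -> bool:
    return all(b in BASE_INDEX for b in s)


# ---------------------------------------------------------------------------
# Branch point and polypyrimidine tract
# ---------------------------------------------------------------------------


def _pwm_log_odds(freqs: np.ndarray, seq: str) -> float:
    return float(
        sum(math.log2(freqs[i, BASE_INDEX[b]] / 0.25) for i, b in enumerate(seq))
    )


def bp_score(
    seq_3ss_upstream: str,
    window: tuple[int, int] = BP_SEARCH,
    lam: float = 1.0,
    bp_freqs: np.ndarray | None = None,
) -> tuple[float, int | None]:
    """Best branch-point score over candidate adenosines.

    ``seq_3ss_upstream`` is intronic sequence ending at intron position -1
    (its last base).  Candidates are the A's at intron positions
    -window[0] .. -window[1]; each is scored as the log-odds of the 7-mer
    centred on it plus ``lam`` times the pyrimidine fraction between the
    candidate and intron -5.  Returns (best_score, best_position) with the
    position as a negative intron offset; ties go to the most 3' candidate.
    A window without adenosine returns (sentinel, None).
    """
    near, far = window
    if far - near + 1 < BP_WIDTH:
        raise ScoringError("branch-point search window shorter than 7 nt")
    freqs = resources.branch_point_frequencies() if bp_freqs is None else bp_freqs
    L = len(seq_3ss_upstream)
    if L < far + BP_CENTER:
        raise ScoringError("sequence does not cover the branch-point search window")
    best, best_pos = BP_SENTINEL, None
    for d in range(near, far + 1):  # d = |intron offset|
        i = L - d  # index of the candidate base
        if seq_3ss_upstream[i] != "A":
            continue
        mer = seq_3ss_upstream[i - BP_CENTER : i - BP_CENTER + BP_WIDTH]
        if len(mer) != BP_WIDTH or not _is_acgt(mer):
            continue
        pyr_seq = seq_3ss_upstream[i + 1 : L - (PPT_SEARCH[0] - 1)]
        pyr = (
            sum(b in PYRIMIDINES for b in pyr_seq) / len(pyr_seq) if pyr_seq else 0.0
        )
        s = _pwm_log_odds(freqs, mer) + lam * pyr
        if s > best or (s == best and best_pos is not None and -d > best_pos):
            best, best_pos = s, -d
    return best, best_pos


def ppt_score(seq: str, t_weight: float = 1.0) -> float:
    """Weighted pyrimidine content of a PPT window, in [0, 1]."""
    if not seq:
        return 0.0
    w = {"C": 1.0, "T": t_weight, "A": 0.0, "G": 0.0}
    return sum(w.get(b, 0.0) for b in seq) / (len(seq) * max(1.0, t_weight))


# ---------------------------------------------------------------------------
# Window extraction and variant application
# ---------------------------------------------------------------------------


def shift_after_edit(g: int, var: GenomicVariant) -> int:
    """Map a 0-based genomic position through the edit (old → mutated coords)."""
    if g < var.start:
        return g
    if g < var.end:
        return var.start
    return g + (len(var.alt) - len(var.ref))


def mutated_window(
    genome: Genome, chrom: str, w_start: int, width: int, var: GenomicVariant | None
) -> str:
    """Mutated sequence of width ``width`` anchored at (the image of) ``w_start``."""
    if var is None or var.chrom != chrom:
        return genome.fetch(chrom, w_start, w_start + width)
    pad = width + len(var.ref) + len(var.alt) + 4
    lo = max(0, min(w_start, var.start) - pad)
    hi = max(w_start + width, var.end) + pad
    seq = genome.fetch(chrom, lo, hi)
    vs, ve = var.start - lo, var.end - lo
    mut = seq[:vs] + var.alt + seq[ve:]
    anchor = shift_after_edit(w_start, var) - lo
    return mut[anchor : anchor + width]


def donor_window_interval(t: Transcript, donor_g: int) -> tuple[int, int]:
    """Genomic interval of the donor 9-mer (exon -3 .. intron +6)."""
    if t.strand == "+":
        return donor_g - DONOR_EXONIC, donor_g + (DONOR_WIDTH - DONOR_EXONIC)
    return donor_g - (DONOR_WIDTH - DONOR_EXONIC) + 1, donor_g + DONOR_EXONIC + 1


def acceptor_window_interval(t: Transcript, acc_g: int) -> tuple[int, int]:
    """Genomic interval of the acceptor 23-mer (intron -20 .. exon +3)."""
    exonic = ACCEPTOR_WIDTH - ACCEPTOR_INTRONIC
    if t.strand == "+":
        return acc_g - (ACCEPTOR_INTRONIC - 1), acc_g + exonic + 1
    return acc_g - exonic, acc_g + ACCEPTOR_INTRONIC


def sense_window(
    genome: Genome,
    t: Transcript,
    interval: tuple[int, int],
    var: GenomicVariant | None = None,
) -> str:
    """Transcript-sense sequence of a genomic interval, optionally mutated.

    For minus-strand transcripts the window is anchored at its genomic *end*
    (the transcription start of the window) before reverse-complementing.
    """
    lo, hi = interval
    width = hi - lo
    if t.strand == "+":
        seq = mutated_window(genome, t.chrom, lo, width, var)
        return seq
    if var is None:
        return revcomp(genome.fetch(t.chrom, lo, hi))
    # anchor on the sense-first base: genomic position hi-1, walking down
    pad = width + len(var.ref) + len(var.alt) + 4
    glo = max(0, min(lo, var.start) - pad)
    ghi = max(hi, var.end) + pad
    seq = genome.fetch(t.chrom, glo, ghi)
    vs, ve = var.start - glo, var.end - glo
    mut = seq[:vs] + var.alt + seq[ve:]
    anchor_end = shift_after_edit(hi - 1, var) - glo
    return revcomp(mut[max(0, anchor_end - width + 1) : anchor_end + 1])


# ---------------------------------------------------------------------------
# Model bundle and per-variant scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoringModels:
    """All motif models used by the pipeline, trained from a reference."""

    donor_pwm: PwmModel
    acceptor_pwm: PwmModel
    donor_mes: MaxEntLikeModel
    acceptor_mes: MaxEntLikeModel
    bp_freqs: np.ndarray
    esr_table: dict[str, float]
    bp_lambda: float = 1.0

    @classmethod
    def from_reference(
        cls,
        genome: Genome,
        transcripts,
        esr_table: dict[str, float],
        order: int = 1,
        bp_freqs: np.ndarray | None = None,
    ) -> "ScoringModels":
        donors, acceptors = [], []
        for t in transcripts:
            for g in t.donor_sites():
                s = sense_window(genome, t, donor_window_interval(t, g))
                if len(s) == DONOR_WIDTH and _is_acgt(s):
                    donors.append(s)
            for g in t.acceptor_sites():
                s = sense_window(genome, t, acceptor_window_interval(t, g))
                if len(s) == ACCEPTOR_WIDTH and _is_acgt(s):
                    acceptors.append(s)
        if not donors or not acceptors:
            raise ValueError("reference has no usable annotated splice sites")
        return cls(
            donor_pwm=PwmModel.from_sites("donor", donors),
            acceptor_pwm=PwmModel.from_sites("acceptor", acceptors),
            donor_mes=MaxEntLikeModel.train("donor", donors, order=order),
            acceptor_mes=MaxEntLikeModel.train("acceptor", acceptors, order=order),
            bp_freqs=(
                resources.branch_point_frequencies() if bp_freqs is None else bp_freqs
            ),
            esr_table=esr_table,
        )


@dataclass
class MotifScoreSet:
    """Wild-type/mutant scores of every motif the variant can touch.

    Deltas are mut − wt exactly; an inapplicable motif keeps delta 0 and its
    mask bit off.
    """

    ssf_wt_donor: float = 0.0
    ssf_mut_donor: float = 0.0
    ssf_wt_acceptor: float = 0.0
    ssf_mut_acceptor: float = 0.0
    mes_wt_donor: float = 0.0
    mes_mut_donor: float = 0.0
    mes_wt_acceptor: float = 0.0
    mes_mut_acceptor: float = 0.0
    delta_esr: float = 0.0
    bp_wt: float = 0.0
    bp_mut: float = 0.0
    ppt_wt: float = 0.0
    ppt_mut: float = 0.0
    mask: dict = field(default_factory=dict)

    @property
    def delta_ssf_donor(self) -> float:
        return self.ssf_mut_donor - self.ssf_wt_donor

    @property
    def delta_ssf_acceptor(self) -> float:
        return self.ssf_mut_acceptor - self.ssf_wt_acceptor

    @property
    def delta_mes_donor(self) -> float:
        return self.mes_mut_donor - self.mes_wt_donor

    @property
    def delta_mes_acceptor(self) -> float:
        return self.mes_mut_acceptor - self.mes_wt_acceptor

    @property
    def delta_bp(self) -> float:
        return self.bp_mut - self.bp_wt

    @property
    def delta_ppt(self) -> float:
        return self.ppt_mut - self.ppt_wt

    def worst_site_deltas(self) -> tuple[float, float, float]:
        """(ssf_delta, mes_delta, mes_wt) of the most damaged natural site."""
        if self.delta_mes_donor <= self.delta_mes_acceptor:
            return self.delta_ssf_donor, self.delta_mes_donor, self.mes_wt_donor
        return self.delta_ssf_acceptor, self.delta_mes_acceptor, self.mes_wt_acceptor


def _nearest_flanking_sites(t: Transcript, ctx: VariantContext) -> dict:
    """Nearest donor and nearest acceptor genomic positions (may be absent)."""
    out = {}
    donors, acceptors = t.donor_sites(), t.acceptor_sites()
    g = ctx.variant.start
    if donors:
        out["donor"] = min(donors, key=lambda p: abs(p - g))
    if acceptors:
        out["acceptor"] = min(acceptors, key=lambda p: abs(p - g))
    return out


def _exon_of(t: Transcript, g: int) -> tuple[int, int] | None:
    for s, e in t.exons:
        if s <= g < e:
            return s, e
    return None


def _overlaps(iv: tuple[int, int], var: GenomicVariant) -> bool:
    lo, hi = iv
    if var.ref:
        return var.start < hi and var.end > lo
    return lo < var.start <= hi  # insertion between lo and hi


def score_variant_motifs(
    ctx: VariantContext, genome: Genome, models: ScoringModels
) -> MotifScoreSet:
    """Score every applicable motif of the variant's transcript context."""
    t, var = ctx.transcript, ctx.variant
    ms = MotifScoreSet()
    sites = _nearest_flanking_sites(t, ctx)

    if "donor" in sites:
        iv = donor_window_interval(t, sites["donor"])
        wt = sense_window(genome, t, iv)
        mut = sense_window(genome, t, iv, var)
        if len(wt) == DONOR_WIDTH and _is_acgt(wt) and _is_acgt(mut):
            ms.ssf_wt_donor = ssf_score(models.donor_pwm, wt)
            ms.mes_wt_donor = models.donor_mes.score(wt)
            if len(mut) == DONOR_WIDTH:
                ms.ssf_mut_donor = ssf_score(models.donor_pwm, mut)
                ms.mes_mut_donor = models.donor_mes.score(mut)
            else:
                ms.ssf_mut_donor, ms.mes_mut_donor = ms.ssf_wt_donor, ms.mes_wt_donor
            ms.mask["donor"] = _overlaps(iv, var)

    if "acceptor" in sites:
        acc = sites["acceptor"]
        iv = acceptor_window_interval(t, acc)
        wt = sense_window(genome, t, iv)
        mut = sense_window(genome, t, iv, var)
        if len(wt) == ACCEPTOR_WIDTH and _is_acgt(wt) and _is_acgt(mut):
            ms.ssf_wt_acceptor = ssf_score(models.acceptor_pwm, wt)
            ms.mes_wt_acceptor = models.acceptor_mes.score(wt)
            if len(mut) == ACCEPTOR_WIDTH:
                ms.ssf_mut_acceptor = ssf_score(models.acceptor_pwm, mut)
                ms.mes_mut_acceptor = models.acceptor_mes.score(mut)
            else:
                ms.ssf_mut_acceptor = ms.ssf_wt_acceptor
                ms.mes_mut_acceptor = ms.mes_wt_acceptor
            ms.mask["acceptor"] = _overlaps(iv, var)

        # branch point and PPT live upstream of this acceptor (intron side)
        up = BP_SEARCH[1] + BP_CENTER
        if t.strand == "+":
            iv_bp = (acc + 1 - up, acc + 1)
        else:
            iv_bp = (acc, acc + up)
        wt_up = sense_window(genome, t, iv_bp)
        mut_up = sense_window(genome, t, iv_bp, var)
        if len(wt_up) == up and _is_acgt(wt_up) and _is_acgt(mut_up) and len(mut_up) == up:
            ms.bp_wt, _ = bp_score(wt_up, bp_freqs=models.bp_freqs, lam=models.bp_lambda)
            ms.bp_mut, _ = bp_score(
                mut_up, bp_freqs=models.bp_freqs, lam=models.bp_lambda
            )
            ms.ppt_wt = ppt_score(wt_up[-PPT_SEARCH[1] : -(PPT_SEARCH[0] - 1) or None])
            ms.ppt_mut = ppt_score(mut_up[-PPT_SEARCH[1] : -(PPT_SEARCH[0] - 1) or None])
            d = abs(ctx.dist_to_nearest_site)
            is_acc_side = ctx.nearest_site_kind == "acceptor" and ctx.intron_size > 0
            ms.mask["bp"] = is_acc_side and BP_SEARCH[0] <= d <= BP_SEARCH[1]
            ms.mask["ppt"] = is_acc_side and PPT_SEARCH[0] <= d <= PPT_SEARCH[1]

    exon = _exon_of(t, var.start)
    if exon is not None and var.end <= exon[1]:
        s, e = exon
        # sense-space exonic window of up to 5 nt context each side
        lo = max(s, var.start - 5)
        hi = min(e, var.end + 5)
        wt_w = sense_window(genome, t, (lo, hi))
        mut_w = sense_window(genome, t, (lo, hi + (len(var.alt) - len(var.ref))), var) \
            if t.strand == "+" else None
        if t.strand == "+":
            offset = var.start - lo
        else:
            offset = hi - var.end
            mut_w = sense_window(
                genome, t, (lo - (len(var.alt) - len(var.ref)), hi), var
            )
        if _is_acgt(wt_w) and mut_w and _is_acgt(mut_w):
            ref_len = len(var.ref) if t.strand == "+" else len(var.ref)
            ms.delta_esr = esr_delta(
                models.esr_table, wt_w, mut_w, offset, ref_len, len(var.alt)
            )
            ms.mask["esr"] = True
    return ms
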