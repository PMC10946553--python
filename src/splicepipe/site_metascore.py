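"""Logistic metascore for splice-site use and de novo/cryptic site detection.

A splice-site candidate is any GT (donor) or AG (acceptor) anchored window.
Its probability of being used as a splice site is a logistic function of
three component scores: the trained log-odds model (MES-like), the percent
PWM (SSF-like) and the mean ESR hexamer score of the exonic-side context.
Scanning the wild-type and mutant sequence around a variant and comparing
candidate probabilities yields the four splice-site-shift mechanisms:

    A  natural site damaged with concomitant use of another site
    B  de novo site (no canonical dinucleotide in the wild type)
    C  cryptic site (predicted but unused in the wild type, strengthened)
    D  de novo and cryptic activation together
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_scores import (
    MotifScoreSet,
    ScoringModels,
    _is_acgt,
    acceptor_window_interval,
    donor_window_interval,
    esr_context_mean,
    sense_window,
    shift_after_edit,
    ssf_score,
)
from .reference_io import Genome, GenomicVariant, Transcript, VariantContext
from .resources import (
    ACCEPTOR_INTRONIC,
    ACCEPTOR_WIDTH,
    DONOR_EXONIC,
    DONOR_WIDTH,
)

ESR_CONTEXT = 50  # nt of exonic-side sequence feeding the ESR component
DEFAULT_SCAN_WINDOW = 100
PSEUDO_EXON_RANGE = (30, 963)  # plausible pseudo-exon sizes, nt

MECHANISMS = ("none", "A_natural_shift", "B_de_novo", "C_cryptic", "D_de_novo_plus_cryptic")


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SiteUseModel:
    """p(site used) = logistic(b0 + b1·MES + b2·SSF + b3·ESR)."""

    site_kind: str
    beta: np.ndarray  # (4,) intercept, MES, SSF, ESR
    se: np.ndarray | None = None
    wald_z: np.ndarray | None = None
    wald_p: np.ndarray | None = None
    n_true: int = 0
    n_false: int = 0
    split_seed: int = 0
    threshold: float | None = None  # calibrated decision threshold
    penalized: bool = False

    def probability(self, mes, ssf, esr):
        z = (
            self.beta[0]
            + self.beta[1] * np.asarray(mes)
            + self.beta[2] * np.asarray(ssf)
            + self.beta[3] * np.asarray(esr)
        )
        return _logistic(z)


def site_features(
    genome: Genome,
    t: Transcript,
    kind: str,
    site_g: int,
    models: ScoringModels,
    var: GenomicVariant | None = None,
) -> tuple[float, float, float] | None:
    """(mes, ssf, esr_context) of a candidate site, or None if unscorable."""
    if kind == "donor":
        iv = donor_window_interval(t, site_g)
        seq = sense_window(genome, t, iv, var)
        if len(seq) != DONOR_WIDTH or not _is_acgt(seq):
            return None
        mes = models.donor_mes.score(seq)
        ssf = ssf_score(models.donor_pwm, seq)
        # exonic side of a donor is upstream in transcript sense
        if t.strand == "+":
            ctx_iv = (site_g - DONOR_EXONIC - ESR_CONTEXT, site_g - DONOR_EXONIC)
        else:
            ctx_iv = (site_g + DONOR_EXONIC + 1, site_g + DONOR_EXONIC + 1 + ESR_CONTEXT)
    else:
        iv = acceptor_window_interval(t, site_g)
        seq = sense_window(genome, t, iv, var)
        if len(seq) != ACCEPTOR_WIDTH or not _is_acgt(seq):
            return None
        mes = models.acceptor_mes.score(seq)
        ssf = ssf_score(models.acceptor_pwm, seq)
        exonic = ACCEPTOR_WIDTH - ACCEPTOR_INTRONIC
        if t.strand == "+":
            ctx_iv = (site_g + exonic + 1, site_g + exonic + 1 + ESR_CONTEXT)
        else:
            ctx_iv = (site_g - exonic - ESR_CONTEXT, site_g - exonic)
    ctx_seq = sense_window(genome, t, ctx_iv, var)
    esr = esr_context_mean(models.esr_table, ctx_seq)
    return mes, ssf, esr


def build_site_training_set(
    transcripts,
    genome: Genome,
    models: ScoringModels,
    ratio: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Label every annotated site positive and every other GT/AG negative.

    Negatives are anchored GT/AG dinucleotides within transcript spans (in
    transcript sense), optionally subsampled to ``ratio`` negatives per
    positive; by default the natural imbalance is kept.  Columns: kind,
    transcript, pos, label, mes, ssf, esr.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in transcripts:
        annotated_d = set(t.donor_sites())
        annotated_a = set(t.acceptor_sites())
        for g in annotated_d:
            f = site_features(genome, t, "donor", g, models)
            if f:
                rows.append(("donor", t.id, g, 1, *f))
        for g in annotated_a:
            f = site_features(genome, t, "acceptor", g, models)
            if f:
                rows.append(("acceptor", t.id, g, 1, *f))
        lo, hi = t.span
        seq = genome.fetch(t.chrom, lo, hi)
        step = +1 if t.strand == "+" else -1
        for i in range(len(seq) - 1):
            pair = seq[i : i + 2]
            g1, g2 = lo + i, lo + i + 1
            if t.strand == "+":
                if pair == "GT" and g1 not in annotated_d:
                    f = site_features(genome, t, "donor", g1, models)
                    if f:
                        rows.append(("donor", t.id, g1, 0, *f))
                if pair == "AG" and g2 not in annotated_a:
                    f = site_features(genome, t, "acceptor", g2, models)
                    if f:
                        rows.append(("acceptor", t.id, g2, 0, *f))
            else:
                # sense GT on minus strand is genomic AC; site +1 base is g2
                if pair == "AC" and g2 not in annotated_d:
                    f = site_features(genome, t, "donor", g2, models)
                    if f:
                        rows.append(("donor", t.id, g2, 0, *f))
                # sense AG is genomic CT; acceptor -1 base is g1
                if pair == "CT" and g1 not in annotated_a:
                    f = site_features(genome, t, "acceptor", g1, models)
                    if f:
                        rows.append(("acceptor", t.id, g1, 0, *f))
    df = pd.DataFrame(
        rows, columns=["kind", "transcript", "pos", "label", "mes", "ssf", "esr"]
    )
    if ratio is not None:
        parts = []
        for kind, grp in df.groupby("kind"):
            pos = grp[grp.label == 1]
            neg = grp[grp.label == 0]
            want = int(round(ratio * len(pos)))
            if want > len(neg):
                warnings.warn(
                    f"{kind}: requested {want} negatives, only {len(neg)} available"
                )
                want = len(neg)
            keep = rng.choice(len(neg), size=want, replace=False)
            parts.append(pd.concat([pos, neg.iloc[np.sort(keep)]]))
        df = pd.concat(parts, ignore_index=True)
    return df.reset_index(drop=True)


def train_site_use_model(
    sites: pd.DataFrame,
    split: float = 2 / 3,
    seed: int = 0,
) -> tuple[SiteUseModel, pd.DataFrame]:
    """Fit the logistic site-use model on a training fraction of one site kind.

    Returns the fitted model and the held-out validation frame (with a ``p``
    column).  Wald z and p values per coefficient come from the maximum
    likelihood fit; perfect separation falls back to an L2-penalized refit
    (flagged on the model).
    """
    import statsmodels.api as sm

    kinds = sites["kind"].unique()
    if len(kinds) != 1:
        raise ValueError("train one site kind at a time")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(sites))
    n_train = int(round(split * len(sites)))
    train = sites.iloc[idx[:n_train]]
    valid = sites.iloc[idx[n_train:]].copy()
    if train["label"].nunique() < 2:
        raise ValueError("training fraction must contain both classes")

    X = sm.add_constant(train[["mes", "ssf", "esr"]].to_numpy(), has_constant="add")
    y = train["label"].to_numpy()
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError
        beta, se = fit.params, fit.bse
        z, p = fit.tvalues, fit.pvalues
    except Exception:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(train[["mes", "ssf", "esr"]], y)
        beta = np.concatenate([lr.intercept_, lr.coef_[0]])
        se = z = p = None
        penalized = True

    model = SiteUseModel(
        site_kind=str(kinds[0]),
        beta=np.asarray(beta, float),
        se=None if se is None else np.asarray(se, float),
        wald_z=None if z is None else np.asarray(z, float),
        wald_p=None if p is None else np.asarray(p, float),
        n_true=int(train["label"].sum()),
        n_false=int((1 - train["label"]).sum()),
        split_seed=seed,
        penalized=penalized,
    )
    valid["p"] = model.probability(valid["mes"], valid["ssf"], valid["esr"])
    return model, valid


def calibrate_site_threshold(
    model: SiteUseModel, valid: pd.DataFrame, target_specificity: float = 0.98
) -> float:
    """Smallest probability threshold reaching the target false-site specificity."""
    neg = np.sort(valid.loc[valid["label"] == 0, "p"].to_numpy())
    if len(neg) == 0:
        raise ValueError("no false sites in the validation frame")
    candidates = np.concatenate([np.unique(neg), [1.0 + 1e-12]])
    n = len(neg)
    for tau in candidates:
        spec = np.searchsorted(neg, tau, side="left") / n
        if spec >= target_specificity:
            model.threshold = float(tau)
            return float(tau)
    model.threshold = 1.0
    return 1.0


@dataclass
class SiteMetascore:
    """Donor and acceptor site-use models with calibrated decision thresholds."""

    donor: SiteUseModel
    acceptor: SiteUseModel

    def model(self, kind: str) -> SiteUseModel:
        return self.donor if kind == "donor" else self.acceptor

    @classmethod
    def fit(
        cls,
        transcripts,
        genome: Genome,
        models: ScoringModels,
        seed: int = 0,
        target_specificity: float = 0.98,
        ratio: float | None = None,
    ) -> "SiteMetascore":
        sites = build_site_training_set(transcripts, genome, models, ratio=ratio, seed=seed)
        out = {}
        for kind, grp in sites.groupby("kind"):
            m, valid = train_site_use_model(grp.reset_index(drop=True), seed=seed)
            calibrate_site_threshold(m, valid, target_specificity)
            out[kind] = m
        return cls(donor=out["donor"], acceptor=out["acceptor"])


# ---------------------------------------------------------------------------
# Scanning for created / reinforced sites
# ---------------------------------------------------------------------------


@dataclass
class SiteCandidate:
    kind: str
    pos: int  # genomic position of the +1 (donor) / -1 (acceptor) base
    p_wt: float
    p_mut: float
    anchored_wt: bool  # canonical dinucleotide present in the wild type
    annotated: bool = False

    @property
    def p_delta(self) -> float:
        return self.p_mut - self.p_wt


@dataclass
class DeNovoCall:
    mechanism: str = "none"
    best: SiteCandidate | None = None
    candidates: list = field(default_factory=list)
    D1: int | None = None  # new site ↔ natural site
    D2: int | None = None  # variant ↔ new site
    natural_damaged: bool = False
    pseudo_exon_pair: bool = False


def _anchor_positions(t: Transcript, seq: str, g_of_idx) -> list[tuple[str, int, int]]:
    """(kind, sense_index_of_anchor_base, genomic_pos) for GT/AG in sense seq."""
    out = []
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair == "GT":
            out.append(("donor", i, g_of_idx(i)))
        if pair == "AG":
            out.append(("acceptor", i + 1, g_of_idx(i + 1)))
    return out


def scan_for_new_sites(
    ctx: VariantContext,
    genome: Genome,
    metascore: SiteMetascore,
    models: ScoringModels,
    window: int = DEFAULT_SCAN_WINDOW,
    pseudo_exon_window: int = PSEUDO_EXON_RANGE[1] + DONOR_WIDTH,
) -> DeNovoCall:
    """Enumerate GT/AG candidates around the variant in both alleles.

    Candidates are paired across alleles by (edit-shifted) genomic position.
    A candidate is *created/reinforced* when its canonical dinucleotide is
    absent in the wild type, or when its use probability rises above the
    calibrated threshold.  Deep-intronic calls additionally look for a
    bracketing opposite-kind site at a pseudo-exon-compatible distance.
    """
    t, var = ctx.transcript, ctx.variant
    lo = var.start - window
    hi = var.end + window
    chrom_len = genome.contig_length(t.chrom)
    lo_c, hi_c = max(0, lo), min(chrom_len, hi)

    wt_seq = sense_window(genome, t, (lo_c, hi_c))
    if t.strand == "+":
        g_of_idx = lambda i: lo_c + i
    else:
        g_of_idx = lambda i: hi_c - 1 - i

    annotated = {("donor", g) for g in t.donor_sites()} | {
        ("acceptor", g) for g in t.acceptor_sites()
    }

    # wild-type candidates keyed by genomic anchor position
    wt_anchors = dict()
    for kind, _, g in _anchor_positions(t, wt_seq, g_of_idx):
        wt_anchors[(kind, g)] = True

    # mutant sequence over the same (shifted) span
    diff = len(var.alt) - len(var.ref)
    if t.strand == "+":
        mut_seq = sense_window(genome, t, (lo_c, hi_c + diff), var)
        g_of_idx_mut = lambda i: lo_c + i  # mutated-genome coordinate
    else:
        mut_seq = sense_window(genome, t, (lo_c - diff, hi_c), var)
        g_of_idx_mut = lambda i: hi_c - 1 + diff - i

    def unshift(g_mut: int) -> int:
        """Mutated-genome coordinate back to wild-type coordinate."""
        if g_mut < var.start:
            return g_mut
        if g_mut >= var.start + len(var.alt):
            return g_mut - diff
        return var.start  # inside the edited bases

    candidates: list[SiteCandidate] = []
    seen = set()
    for kind, _, g_mut in _anchor_positions(t, mut_seq, g_of_idx_mut):
        g = unshift(g_mut)
        if (kind, g) in seen:
            continue
        seen.add((kind, g))
        f_mut = site_features(genome, t, kind, g, models, var)
        if f_mut is None:
            continue
        p_mut = float(metascore.model(kind).probability(*f_mut))
        f_wt = site_features(genome, t, kind, g, models)
        p_wt = float(metascore.model(kind).probability(*f_wt)) if f_wt else 0.0
        candidates.append(
            SiteCandidate(
                kind=kind,
                pos=g,
                p_wt=p_wt,
                p_mut=p_mut,
                anchored_wt=(kind, g) in wt_anchors,
                annotated=(kind, g) in annotated,
            )
        )

    # natural-site damage: probability of the nearest annotated site drops
    # below threshold in the mutant
    natural_damaged = False
    nat_kind, nat_g = ctx.nearest_site_kind, ctx.nearest_site_pos
    tau_nat = metascore.model(nat_kind).threshold or 0.5
    f_nat_wt = site_features(genome, t, nat_kind, nat_g, models)
    f_nat_mut = site_features(genome, t, nat_kind, nat_g, models, var)
    if f_nat_wt and f_nat_mut:
        p_nat_wt = float(metascore.model(nat_kind).probability(*f_nat_wt))
        p_nat_mut = float(metascore.model(nat_kind).probability(*f_nat_mut))
        natural_damaged = p_nat_wt >= tau_nat > p_nat_mut

    def tau(kind):
        th = metascore.model(kind).threshold
        return 0.5 if th is None else th

    created = [
        c
        for c in candidates
        if not c.annotated
        and c.p_mut >= tau(c.kind)
        and (not c.anchored_wt or c.p_mut > c.p_wt)
    ]
    # under natural damage, a pre-existing unchanged cryptic site can take over
    shift_targets = [
        c
        for c in candidates
        if not c.annotated and c.p_mut >= tau(c.kind) and natural_damaged
    ]
    passing = created if created else (shift_targets if natural_damaged else [])

    call = DeNovoCall(candidates=candidates, natural_damaged=natural_damaged)
    if not passing:
        return call

    best = max(passing, key=lambda c: (c.p_mut, -abs(c.pos - var.start)))
    call.best = best
    call.D1 = abs(best.pos - nat_g)
    call.D2 = abs(best.pos - var.start)

    has_de_novo = any(not c.anchored_wt for c in passing)
    has_cryptic = any(
        c.anchored_wt and c.p_wt < tau(c.kind) for c in passing
    )
    if natural_damaged:
        call.mechanism = "A_natural_shift"
    elif has_de_novo and has_cryptic:
        call.mechanism = "D_de_novo_plus_cryptic"
    elif not best.anchored_wt:
        call.mechanism = "B_de_novo"
    else:
        call.mechanism = "C_cryptic"

    # pseudo-exon pairing: a passing deep-intronic site plus a strong
    # opposite-kind site bracketing a plausible exon
    if ctx.region == "deep_intronic":
        call.pseudo_exon_pair = _find_pseudo_exon_pair(
            ctx, genome, metascore, models, best, pseudo_exon_window
        )
    return call


def _find_pseudo_exon_pair(
    ctx, genome, metascore, models, best: SiteCandidate, search: int
) -> bool:
    t, var = ctx.transcript, ctx.variant
    want_kind = "acceptor" if best.kind == "donor" else "donor"
    # the partner lies on the exonic side of the new site: upstream (sense)
    # of a donor, downstream of an acceptor
    sense_up = best.kind == "donor"
    if (t.strand == "+") == sense_up:
        iv = (best.pos - search, best.pos)
    else:
        iv = (best.pos + 1, best.pos + 1 + search)
    lo_c = max(0, iv[0])
    hi_c = min(genome.contig_length(t.chrom), iv[1])
    seq = sense_window(genome, t, (lo_c, hi_c))
    g_of_idx = (lambda i: lo_c + i) if t.strand == "+" else (lambda i: hi_c - 1 - i)
    tau = metascore.model(want_kind).threshold or 0.5
    lo_sz, hi_sz = PSEUDO_EXON_RANGE
    for kind, _, g in _anchor_positions(t, seq, g_of_idx):
        if kind != want_kind:
            continue
        size = abs(best.pos - g)
        if not (lo_sz <= size <= hi_sz):
            continue
        f = site_features(genome, t, kind, g, models, var)
        if f and float(metascore.model(kind).probability(*f)) >= tau:
            return True
    return False


# ---------------------------------------------------------------------------
# SPiCE-like consensus alteration probability
# ---------------------------------------------------------------------------

CONSENSUS_REGIONS = {
    "exonic_consensus",
    "intronic_consensus_5ss",
    "intronic_consensus_3ss",
}


@dataclass
class SpiceModel:
    """Logistic P(natural-site alteration) on (ΔSSF, relative ΔMES)."""

    beta: np.ndarray  # (3,)
    threshold: float = 0.5
    n_train: int = 0

    def probability(self, delta_ssf, rel_delta_mes):
        z = self.beta[0] + self.beta[1] * delta_ssf + self.beta[2] * rel_delta_mes
        return float(_logistic(z))


def spice_features(ms: MotifScoreSet) -> tuple[float, float]:
    d_ssf, d_mes, mes_wt = ms.worst_site_deltas()
    rel = d_mes / max(abs(mes_wt), 1.0)
    return d_ssf, rel


def train_spice_model(
    feats: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> SpiceModel:
    """Fit on labeled consensus variants; features = (ΔSSF, relΔMES) rows."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=10.0, max_iter=2000)
    lr.fit(feats, labels)
    return SpiceModel(
        beta=np.concatenate([lr.intercept_, lr.coef_[0]]),
        threshold=threshold,
        n_train=len(labels),
    )


def spice_like_probability(model: SpiceModel, ms: MotifScoreSet, region: str) -> float:
    if region not in CONSENSUS_REGIONS:
        raise ValueError(f"SPiCE-like probability is defined on consensus regions, not {region}")
    return model.probability(*spice_features(ms))
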