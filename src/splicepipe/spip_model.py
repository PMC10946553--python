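"""The spliceogenicity classifier: predictor assembly, random forest,
threshold calibration, confidence-interval bins and motif interpretation.

The classifier score is the fraction of trees voting "spliceogenic", in
[0, 1] on a grid of 1/n_trees.  Sixteen candidate predictors summarise the
motif-level analysis; backward selection by permutation importance prunes
them while the validation ROC AUC holds, and the decision threshold is the
smallest score reaching a target specificity (default 99%) on validation
data.  Positive calls are annotated with the motif most probably altered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .motif_scores import MotifScoreSet, ScoringModels, score_variant_motifs
from .reference_io import Genome, REGION_CODE, VariantContext
from .site_metascore import (
    CONSENSUS_REGIONS,
    DeNovoCall,
    SiteMetascore,
    SpiceModel,
    scan_for_new_sites,
    spice_features,
    spice_like_probability,
)

FEATURE_NAMES = (
    "ssf_delta",
    "mes_delta_nat",
    "mes_wt_nat",
    "spice_probability",
    "denovo_p_mut",
    "denovo_p_delta",
    "esr_delta",
    "bp_delta",
    "ppt_delta",
    "exon_size",
    "intron_size",
    "rel_pos",
    "dist_to_nearest_site",
    "region_code",
    "D2",
    "pseudo_exon_pair_flag",
)

INTERPRETATIONS = (
    "consensus_alteration",
    "ppt_alteration",
    "bp_alteration",
    "esr_alteration",
    "new_splice_site",
    "pseudo_exon_creation",
    "complex",
    "NTR",
)


@dataclass
class InterpretThresholds:
    """Per-motif decision thresholds used for interpretation flags."""

    spice: float = 0.5
    ppt_drop: float = 0.10  # |delta_ppt| for a PPT alteration flag
    bp_drop: float = 1.5  # |delta_bp| (log-odds) for a BP alteration flag
    esr_drop: float = 2.5  # |delta_esr| for an ESR alteration flag


@dataclass
class FeatureVector:
    values: np.ndarray  # (16,), FEATURE_NAMES order
    mask: dict
    motif_scores: MotifScoreSet
    call: DeNovoCall
    spice_probability: float

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


class FeatureError(ValueError):
    pass


def extract_features(
    ctx: VariantContext,
    ms: MotifScoreSet,
    call: DeNovoCall,
    spice_p: float,
) -> FeatureVector:
    """Assemble the 16 candidate predictors, masked to 0 when inapplicable."""
    ssf_d, mes_d, mes_wt = ms.worst_site_deltas()
    best = call.best
    vals = np.array(
        [
            ssf_d,
            mes_d,
            mes_wt,
            spice_p,
            best.p_mut if best else 0.0,
            best.p_delta if best else 0.0,
            ms.delta_esr if ms.mask.get("esr") else 0.0,
            ms.delta_bp if ms.mask.get("bp") else 0.0,
            ms.delta_ppt if ms.mask.get("ppt") else 0.0,
            float(ctx.exon_size),
            float(ctx.intron_size),
            float(ctx.rel_pos),
            float(ctx.dist_to_nearest_site),
            float(REGION_CODE[ctx.region]),
            float(call.D2) if call.D2 is not None else 0.0,
            1.0 if call.pseudo_exon_pair else 0.0,
        ],
        dtype=float,
    )
    if not np.all(np.isfinite(vals)):
        bad = FEATURE_NAMES[int(np.argmin(np.isfinite(vals)))]
        raise FeatureError(f"non-finite predictor {bad}")
    return FeatureVector(
        values=vals,
        mask=dict(ms.mask),
        motif_scores=ms,
        call=call,
        spice_probability=spice_p,
    )


# ---------------------------------------------------------------------------
# Random forest with explicit tree votes
# ---------------------------------------------------------------------------


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    mtry: int = 3,
    seed: int = 0,
) -> RandomForestClassifier:
    if mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds {X.shape[1]} predictors")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
        oob_score=True,
    )
    rf.fit(X, y)
    return rf


def vote_fraction(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting class 1: each tree votes its leaf majority."""
    leaves = rf.apply(X)  # (n, n_trees)
    votes = np.zeros(X.shape[0])
    pos_col = int(np.where(rf.classes_ == 1)[0][0])
    for t_idx, tree in enumerate(rf.estimators_):
        value = tree.tree_.value[:, 0, :]  # (n_nodes, n_classes)
        leaf_vote = (np.argmax(value, axis=1) == pos_col).astype(float)
        votes += leaf_vote[leaves[:, t_idx]]
    return votes / len(rf.estimators_)


def backward_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_valid: np.ndarray,
    y_valid: np.ndarray,
    names: tuple[str, ...] = FEATURE_NAMES,
    eps: float = 0.002,
    n_trees: int = 120,
    mtry: int = 3,
    seed: int = 0,
    n_repeats: int = 2,
) -> tuple[list[str], list[dict]]:
    """Drop the least accuracy-important predictor while validation AUC holds.

    Importance is the mean decrease in validation accuracy under feature
    permutation.  Selection stops when removing another predictor would cost
    more than ``eps`` AUC relative to the best model seen, or when a single
    predictor remains.  Returns the surviving names and the selection trace.
    """
    from sklearn.inspection import permutation_importance
    from sklearn.metrics import roc_auc_score

    if len(np.unique(y_train)) < 2 or len(np.unique(y_valid)) < 2:
        raise ValueError("both classes required in train and validation sets")

    current = list(names)
    trace = []
    best_auc = -np.inf
    best_set = list(current)
    while True:
        cols = [names.index(n) for n in current]
        rf = train_forest(
            X_train[:, cols], y_train, n_trees=n_trees, mtry=min(mtry, len(cols)), seed=seed
        )
        auc = roc_auc_score(y_valid, vote_fraction(rf, X_valid[:, cols]))
        trace.append(dict(n_predictors=len(current), auc=float(auc), kept=list(current)))
        if auc >= best_auc - 1e-12:
            best_auc, best_set = auc, list(current)
        if np.isinf(eps) and len(current) > 1:
            pass  # greedy collapse to a single predictor
        elif auc < best_auc - eps:
            return best_set, trace
        if len(current) == 1:
            return (current if np.isinf(eps) else best_set), trace
        imp = permutation_importance(
            rf,
            X_valid[:, cols],
            y_valid,
            n_repeats=n_repeats,
            random_state=seed,
            scoring="accuracy",
        )
        drop = current[int(np.argmin(imp.importances_mean))]
        current.remove(drop)


def calibrate_threshold(
    scores: np.ndarray, labels: np.ndarray, target_specificity: float = 0.99
) -> tuple[float, float]:
    """Smallest score threshold with specificity ≥ target on the given set.

    Returns (tau, achieved_specificity); an unreachable target yields tau=1
    with the achieved value reported.
    """
    neg = np.sort(np.asarray(scores)[np.asarray(labels) == 0])
    if len(neg) == 0:
        raise ValueError("no negatives to calibrate on")
    n = len(neg)
    for tau in np.unique(np.asarray(scores)):
        spec = np.searchsorted(neg, tau, side="left") / n
        if spec >= target_specificity:
            return float(tau), float(spec)
    # unreachable (e.g. everything ties at the top): report tau = 1
    return 1.0, float(np.searchsorted(neg, 1.0, side="left") / n)


def score_bins_ci(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency score bins with Wilson 95% CIs on the spliceogenic
    proportion, plus an R² trend statistic between bin score and proportion."""
    import warnings as _w

    from statsmodels.stats.proportion import proportion_confint

    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n = len(scores)
    while n_bins > 1 and n < n_bins * 20:
        n_bins -= 1
        _w.warn(f"too few variants; reducing to {n_bins} bins")
    order = np.argsort(scores, kind="mergesort")
    edges = [order[int(round(i * n / n_bins)) : int(round((i + 1) * n / n_bins))] for i in range(n_bins)]
    rows = []
    for i, idx in enumerate(edges):
        k = int(labels[idx].sum())
        m = len(idx)
        lo, hi = proportion_confint(k, m, alpha=0.05, method="wilson")
        rows.append(
            dict(
                bin=i,
                n=m,
                score_lo=float(scores[idx].min()),
                score_hi=float(scores[idx].max()),
                score_mean=float(scores[idx].mean()),
                k_spliceogenic=k,
                proportion=k / m,
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    df = pd.DataFrame(rows)
    x, yv = df["score_mean"], df["proportion"]
    if np.var(x) > 0 and np.var(yv) > 0:
        r = np.corrcoef(x, yv)[0, 1]
        df.attrs["r_squared"] = float(r * r)
    else:
        df.attrs["r_squared"] = float("nan")
    return df


def interpret(
    fv: FeatureVector,
    region: str,
    thresholds: InterpretThresholds,
    positive: bool,
) -> str:
    """Motif-level interpretation of a positive call; negatives are NTR."""
    if not positive:
        return "NTR"
    flags = []
    if region in CONSENSUS_REGIONS and fv.spice_probability >= thresholds.spice:
        flags.append("consensus_alteration")
    if fv.mask.get("ppt") and fv.motif_scores.delta_ppt <= -thresholds.ppt_drop:
        flags.append("ppt_alteration")
    if fv.mask.get("bp") and fv.motif_scores.delta_bp <= -thresholds.bp_drop:
        flags.append("bp_alteration")
    if fv.mask.get("esr") and fv.motif_scores.delta_esr <= -thresholds.esr_drop:
        flags.append("esr_alteration")
    if fv.call.pseudo_exon_pair:
        flags.append("pseudo_exon_creation")
    elif fv.call.mechanism in ("B_de_novo", "C_cryptic", "D_de_novo_plus_cryptic"):
        # a natural-site shift (mechanism A) is a consequence of the consensus
        # damage already flagged above, not an independent motif hit
        flags.append("new_splice_site")
    elif fv.call.mechanism == "A_natural_shift" and not flags:
        flags.append("new_splice_site")
    if len(flags) == 1:
        return flags[0]
    if len(flags) >= 2:
        return "complex"
    # positive decision with no flag: the forest saw something the per-motif
    # thresholds did not; report the strongest sub-threshold site if any
    return "new_splice_site" if fv.call.best is not None else "complex"


# ---------------------------------------------------------------------------
# The assembled model
# ---------------------------------------------------------------------------


@dataclass
class SpipModel:
    """Everything needed to score a variant, trained as one unit."""

    scoring: ScoringModels
    metascore: SiteMetascore
    spice: SpiceModel
    forest: RandomForestClassifier
    selected: list[str]
    tau: float
    achieved_specificity: float
    ci_table: pd.DataFrame
    negative_ci: pd.DataFrame | None = None
    thresholds: InterpretThresholds = field(default_factory=InterpretThresholds)
    seed: int = 0
    scan_window: int = 100
    selection_trace: list = field(default_factory=list)

    def featurize(self, ctx: VariantContext, genome: Genome) -> FeatureVector:
        ms = score_variant_motifs(ctx, genome, self.scoring)
        call = scan_for_new_sites(
            ctx, genome, self.metascore, self.scoring, window=self.scan_window
        )
        if ctx.region in CONSENSUS_REGIONS:
            spice_p = spice_like_probability(self.spice, ms, ctx.region)
        else:
            spice_p = 0.0
        return extract_features(ctx, ms, call, spice_p)

    def score_features(self, fvs: list[FeatureVector]) -> np.ndarray:
        cols = [FEATURE_NAMES.index(n) for n in self.selected]
        X = np.stack([fv.values for fv in fvs])[:, cols]
        return vote_fraction(self.forest, X)

    def result_row(self, ctx: VariantContext, fv: FeatureVector, score: float) -> dict:
        positive = score >= self.tau
        label = interpret(fv, ctx.region, self.thresholds, positive)
        if positive:
            tbl = self.ci_table
            hit = tbl[(tbl.score_lo <= score) & (score <= tbl.score_hi)]
            if hit.empty:
                hit = tbl.iloc[[int(np.argmin(np.abs(tbl.score_mean - score)))]]
            ci_low, ci_high = float(hit.iloc[-1].ci_low), float(hit.iloc[-1].ci_high)
        elif self.negative_ci is not None and len(self.negative_ci):
            tbl = self.negative_ci
            hit = tbl[tbl.region == ctx.region]
            if hit.empty:
                hit = tbl.iloc[[0]]
            ci_low, ci_high = float(hit.iloc[0].ci_low), float(hit.iloc[0].ci_high)
        else:
            ci_low = ci_high = float("nan")
        ms = fv.motif_scores
        return dict(
            variant_id=ctx.variant.id or "",
            transcript=ctx.transcript.id,
            hgvs_c=ctx.c_notation,
            region=ctx.region,
            spip_score=round(float(score), 6),
            decision="positive" if positive else "NTR",
            interpretation=label,
            ci_low=round(ci_low, 4) if np.isfinite(ci_low) else "",
            ci_high=round(ci_high, 4) if np.isfinite(ci_high) else "",
            delta_ssf=round(fv.values[0], 4),
            delta_mes=round(fv.values[1], 4),
            spice_probability=round(fv.spice_probability, 4),
            denovo_p_mut=round(fv.values[4], 4),
            delta_esr=round(ms.delta_esr, 4),
            delta_bp=round(ms.delta_bp, 4),
            delta_ppt=round(ms.delta_ppt, 4),
            mechanism=fv.call.mechanism,
            error="",
        )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = dict(
            format_version=1,
            selected=self.selected,
            tau=self.tau,
            achieved_specificity=self.achieved_specificity,
            seed=self.seed,
            scan_window=self.scan_window,
            thresholds=vars(self.thresholds),
            feature_names=list(FEATURE_NAMES),
            region_code={k: v for k, v in REGION_CODE.items()},
            spice_beta=self.spice.beta.tolist(),
            metascore=dict(
                donor=dict(
                    beta=self.metascore.donor.beta.tolist(),
                    threshold=self.metascore.donor.threshold,
                ),
                acceptor=dict(
                    beta=self.metascore.acceptor.beta.tolist(),
                    threshold=self.metascore.acceptor.threshold,
                ),
            ),
            selection_trace=self.selection_trace,
        )
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        self.ci_table.to_csv(path / "ci_table.tsv", sep="\t", index=False)
        if self.negative_ci is not None:
            self.negative_ci.to_csv(path / "negative_ci.tsv", sep="\t", index=False)
        joblib.dump(
            dict(scoring=self.scoring, metascore=self.metascore, spice=self.spice,
                 forest=self.forest),
            path / "model.joblib",
        )

    @classmethod
    def load(cls, path) -> "SpipModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        blobs = joblib.load(path / "model.joblib")
        neg_path = path / "negative_ci.tsv"
        return cls(
            scoring=blobs["scoring"],
            metascore=blobs["metascore"],
            spice=blobs["spice"],
            forest=blobs["forest"],
            selected=meta["selected"],
            tau=meta["tau"],
            achieved_specificity=meta["achieved_specificity"],
            ci_table=pd.read_csv(path / "ci_table.tsv", sep="\t"),
            negative_ci=pd.read_csv(neg_path, sep="\t") if neg_path.exists() else None,
            thresholds=InterpretThresholds(**meta["thresholds"]),
            seed=meta["seed"],
            scan_window=meta["scan_window"],
            selection_trace=meta.get("selection_trace", []),
        )


def negative_region_ci(
    scores: np.ndarray, labels: np.ndarray, regions: list[str], tau: float
) -> pd.DataFrame:
    """False-negative-rate Wilson CIs among predicted negatives, per region."""
    from statsmodels.stats.proportion import proportion_confint

    df = pd.DataFrame(dict(score=scores, label=labels, region=regions))
    neg = df[df.score < tau]
    rows = []
    for region, grp in neg.groupby("region"):
        k, m = int(grp.label.sum()), len(grp)
        lo, hi = proportion_confint(k, m, alpha=0.05, method="wilson")
        rows.append(
            dict(region=region, n=m, k_false_negative=k, fn_rate=k / max(1, m),
                 ci_low=float(lo), ci_high=float(hi))
        )
    return pd.DataFrame(rows)
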