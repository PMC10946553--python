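"""End-to-end orchestration: featurize a labeled collection, fit the full
model stack (motif models → site metascore → consensus model → forest), and
batch-score variant tables deterministically across worker counts."""

from __future__ import annotations

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .motif_scores import ScoringModels, score_variant_motifs
from .reference_io import (
    Genome,
    GenomicVariant,
    TranscriptIndex,
    classify_region,
    normalize,
    parse_hgvs,
)
from .site_metascore import (
    CONSENSUS_REGIONS,
    SiteMetascore,
    SpiceModel,
    scan_for_new_sites,
    spice_features,
    train_spice_model,
)
from .spip_model import (
    FEATURE_NAMES,
    InterpretThresholds,
    SpipModel,
    backward_select,
    calibrate_threshold,
    extract_features,
    negative_region_ci,
    score_bins_ci,
    train_forest,
    vote_fraction,
)
from .evaluation import evaluate_scores, positional_split

# fallback consensus-alteration model when a collection lacks labeled
# consensus variants of both classes: strongly negative score deltas imply
# alteration
FALLBACK_SPICE_BETA = np.array([-4.0, -0.25, -10.0])

CHUNK = 250  # rows per worker task; fixed so outputs are order-stable


def _analyze_chunk(rows, genome, transcripts, scoring, metascore, scan_window):
    out = []
    for row in rows:
        t = transcripts[row["transcript"]]
        var = GenomicVariant(
            chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
            id=row.get("variant_id"),
        )
        ctx = classify_region(t, var)
        ms = score_variant_motifs(ctx, genome, scoring)
        call = scan_for_new_sites(ctx, genome, metascore, scoring, window=scan_window)
        out.append((ctx, ms, call))
    return out


def analyze_collection(
    df: pd.DataFrame,
    genome: Genome,
    transcripts: TranscriptIndex,
    scoring: ScoringModels,
    metascore: SiteMetascore,
    scan_window: int = 100,
    workers: int = 1,
):
    rows = df.to_dict("records")
    chunks = [rows[i : i + CHUNK] for i in range(0, len(rows), CHUNK)]
    if workers == 1:
        parts = [
            _analyze_chunk(c, genome, transcripts, scoring, metascore, scan_window)
            for c in chunks
        ]
    else:
        parts = Parallel(n_jobs=workers)(
            delayed(_analyze_chunk)(
                c, genome, transcripts, scoring, metascore, scan_window
            )
            for c in chunks
        )
    return [item for part in parts for item in part]


def fit_spice_from_collection(analyzed, labels) -> SpiceModel:
    feats, ys = [], []
    for (ctx, ms, _), y in zip(analyzed, labels):
        if ctx.region in CONSENSUS_REGIONS:
            feats.append(spice_features(ms))
            ys.append(y)
    ys = np.asarray(ys)
    if len(ys) >= 10 and len(np.unique(ys)) == 2:
        return train_spice_model(np.asarray(feats), ys)
    return SpiceModel(beta=FALLBACK_SPICE_BETA.copy(), n_train=0)


def features_from_analysis(analyzed, spice: SpiceModel) -> tuple[np.ndarray, list]:
    fvs = []
    for ctx, ms, call in analyzed:
        if ctx.region in CONSENSUS_REGIONS:
            spice_p = spice.probability(*spice_features(ms))
        else:
            spice_p = 0.0
        fvs.append(extract_features(ctx, ms, call, spice_p))
    X = np.stack([fv.values for fv in fvs])
    return X, fvs


def fit_spip_model(
    genome: Genome,
    transcripts: TranscriptIndex,
    esr_table: dict[str, float],
    collection: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    mtry: int = 3,
    selection_trees: int = 120,
    selection_eps: float = 0.002,
    target_specificity: float = 0.99,
    scan_window: int = 100,
    workers: int = 1,
    thresholds: InterpretThresholds | None = None,
) -> tuple[SpipModel, dict]:
    """Train the full stack on a labeled collection.

    The collection frame needs columns transcript, chrom, pos, ref, alt,
    label, region.  Training/validation is a 50/50 split keyed on genomic
    position.  Returns the model and a report with validation metrics.
    """
    scoring = ScoringModels.from_reference(genome, transcripts, esr_table)
    metascore = SiteMetascore.fit(transcripts, genome, scoring, seed=seed)

    analyzed = analyze_collection(
        collection, genome, transcripts, scoring, metascore, scan_window, workers
    )
    y = collection["label"].to_numpy(int)
    spice = fit_spice_from_collection(analyzed, y)
    X, fvs = features_from_analysis(analyzed, spice)

    train_mask = positional_split(collection["chrom"], collection["pos"], seed=seed)
    selected, trace = backward_select(
        X[train_mask],
        y[train_mask],
        X[~train_mask],
        y[~train_mask],
        eps=selection_eps,
        n_trees=selection_trees,
        mtry=mtry,
        seed=seed,
    )
    cols = [FEATURE_NAMES.index(n) for n in selected]
    forest = train_forest(
        X[train_mask][:, cols], y[train_mask], n_trees=n_trees, mtry=min(mtry, len(cols)),
        seed=seed,
    )
    scores_valid = vote_fraction(forest, X[~train_mask][:, cols])
    y_valid = y[~train_mask]
    tau, achieved = calibrate_threshold(scores_valid, y_valid, target_specificity)
    ci_table = score_bins_ci(scores_valid, y_valid)
    regions_valid = collection.loc[~train_mask, "region"].tolist()
    neg_ci = negative_region_ci(scores_valid, y_valid, regions_valid, tau)

    model = SpipModel(
        scoring=scoring,
        metascore=metascore,
        spice=spice,
        forest=forest,
        selected=selected,
        tau=tau,
        achieved_specificity=achieved,
        ci_table=ci_table,
        negative_ci=neg_ci,
        thresholds=thresholds or InterpretThresholds(),
        seed=seed,
        scan_window=scan_window,
        selection_trace=trace,
    )
    report = dict(
        valid=evaluate_scores(y_valid, scores_valid, regions=regions_valid),
        scores_valid=scores_valid,
        y_valid=y_valid,
        train_mask=train_mask,
        X=X,
        fvs=fvs,
        analyzed=analyzed,
        selected=selected,
        tau=tau,
        achieved_specificity=achieved,
        ci_r_squared=ci_table.attrs.get("r_squared"),
    )
    return model, report


# ---------------------------------------------------------------------------
# Batch scoring (row-isolated failures, worker-count independent output)
# ---------------------------------------------------------------------------

OUTPUT_COLUMNS = (
    "variant_id",
    "transcript",
    "hgvs_c",
    "region",
    "spip_score",
    "decision",
    "interpretation",
    "ci_low",
    "ci_high",
    "delta_ssf",
    "delta_mes",
    "spice_probability",
    "denovo_p_mut",
    "delta_esr",
    "delta_bp",
    "delta_ppt",
    "mechanism",
    "error",
)


def _error_row(row, exc) -> dict:
    d = {c: "" for c in OUTPUT_COLUMNS}
    d["variant_id"] = row.get("variant_id", "")
    d["transcript"] = row.get("transcript", "")
    d["hgvs_c"] = row.get("hgvs_c", "")
    d["error"] = f"{type(exc).__name__}: {exc}"
    return d


def _score_chunk(rows, model: SpipModel, genome, transcripts):
    out = []
    for row in rows:
        try:
            if row.get("hgvs_c") and row.get("transcript"):
                t, var, c_notation = parse_hgvs(
                    f"{row['transcript']}:{row['hgvs_c']}"
                    if not str(row["hgvs_c"]).startswith(row["transcript"])
                    else str(row["hgvs_c"]),
                    transcripts,
                    genome,
                )
                var = GenomicVariant(
                    var.chrom, var.pos, var.ref, var.alt, id=row.get("variant_id")
                )
            else:
                t = transcripts[row["transcript"]]
                var = normalize(
                    GenomicVariant(
                        row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                        id=row.get("variant_id"),
                    ),
                    genome,
                )
            ctx = classify_region(t, var)
            fv = model.featurize(ctx, genome)
            score = float(model.score_features([fv])[0])
            out.append(model.result_row(ctx, fv, score))
        except Exception as exc:  # noqa: BLE001 - row-scoped isolation
            out.append(_error_row(row, exc))
    return out


def score_table(
    df: pd.DataFrame,
    model: SpipModel,
    genome: Genome,
    transcripts: TranscriptIndex,
    workers: int = 1,
) -> pd.DataFrame:
    """Score a variant table; one output row per input row, order preserved.

    Output is byte-identical for any worker count: rows are processed in
    fixed chunks and reassembled in input order.
    """
    rows = df.to_dict("records")
    chunks = [rows[i : i + CHUNK] for i in range(0, len(rows), CHUNK)]
    if workers == 1:
        parts = [_score_chunk(c, model, genome, transcripts) for c in chunks]
    else:
        parts = Parallel(n_jobs=workers)(
            delayed(_score_chunk)(c, model, genome, transcripts) for c in chunks
        )
    flat = [r for part in parts for r in part]
    return pd.DataFrame(flat, columns=list(OUTPUT_COLUMNS))
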