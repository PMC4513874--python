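"""Functional k-nearest-neighbour target prediction.

Direct vs indirect target classification uses the cosine-normalized
windowed inner product of first-derivative curves as the similarity, an
unweighted k-vote posterior, stratified cross-validated AUC (Mann-Whitney
rank form, Hanley-McNeil SEs), a shuffle-based FDR curve obtained by
rerunning the identical pipeline on null training sets, and a per-miRNA
specificity scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .fda import CurveSet, cosine_similarity, rms_scale
from .targets import GeneAnnotation, build_training_sets

__all__ = [
    "FknnModel",
    "train_fknn",
    "classify",
    "auc_mann_whitney",
    "hanley_mcneil_se",
    "cross_validate",
    "CVResult",
    "estimate_fdr",
    "FdrCurve",
    "rank_predictions",
    "specificity_scan",
]

POSTERIOR_HI = 0.75
POSTERIOR_LO = 0.25


@dataclass
class FknnModel:
    training: CurveSet          # RMS-scaled curves
    labels: np.ndarray          # 1 = direct, 0 = indirect
    k: int
    window: tuple[float, float] | None
    deriv_order: int = 1


def train_fknn(curves: CurveSet, labels, k: int = 11, window=None,
               deriv_order: int = 1) -> FknnModel:
    """Store RMS-scaled training curves and labels for k-NN voting."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(curves):
        raise ValueError("labels length mismatch")
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids vote ties)")
    if k > len(curves):
        raise ValueError(f"k={k} exceeds training size {len(curves)}")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    win = None if window is None else (float(window[0]), float(window[1]))
    return FknnModel(curves, labels, k, win, deriv_order)


def classify(model: FknnModel, curves: CurveSet) -> pd.DataFrame:
    """Posterior = direct fraction among the k most similar training
    curves; calls: target (>=0.75), nontarget (<=0.25), else ambiguous."""
    if curves.basis != model.training.basis:
        raise ValueError("query curves must share the training basis")
    S = cosine_similarity(curves, model.training,
                          deriv_order=model.deriv_order, window=model.window)
    k = model.k
    # stable neighbour order: similarity desc, training index asc
    order = np.lexsort((np.arange(S.shape[1])[None, :].repeat(len(S), 0),
                        -S), axis=1)[:, :k]
    posterior = model.labels[order].mean(axis=1)
    call = np.where(posterior >= POSTERIOR_HI, "target",
                    np.where(posterior <= POSTERIOR_LO, "nontarget",
                             "ambiguous"))
    return pd.DataFrame({"posterior": posterior, "call": call},
                        index=pd.Index(curves.gene_ids, name="gene"))


# ---------------------------------------------------------------------------
# AUC machinery
# ---------------------------------------------------------------------------

def auc_mann_whitney(pos_scores, neg_scores) -> float:
    """AUC via the rank (Mann-Whitney U) formulation, ties counted 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class CVResult:
    auc: float                   # pooled held-out AUC
    se_folds: float              # SD of fold AUCs / sqrt(n_folds)
    se_hanley: float
    fold_aucs: np.ndarray
    posteriors: pd.Series        # pooled held-out posteriors
    labels: pd.Series


def cross_validate(curves: CurveSet, labels, k: int = 11, window=None,
                   n_folds: int = 10, rng_seed: int = 0,
                   deriv_order: int = 1) -> CVResult:
    """Stratified k-fold CV; AUC of pooled held-out posteriors."""
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(f"need >= {n_folds} examples per class "
                         f"(have {n_pos}/{n_neg})")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=rng_seed)
    post = np.empty(len(labels))
    fold_aucs = []
    idx = np.arange(len(labels))
    for train_idx, test_idx in skf.split(idx, labels):
        fold_k = min(k, len(train_idx) if len(train_idx) % 2 else
                     len(train_idx) - 1)
        model = train_fknn(curves.subset(
            [curves.gene_ids[i] for i in train_idx]), labels[train_idx],
            k=fold_k, window=window, deriv_order=deriv_order)
        pred = classify(model, curves.subset(
            [curves.gene_ids[i] for i in test_idx]))
        post[test_idx] = pred["posterior"].to_numpy()
        fold_aucs.append(auc_mann_whitney(
            post[test_idx][labels[test_idx] == 1],
            post[test_idx][labels[test_idx] == 0]))
    auc = auc_mann_whitney(post[labels == 1], post[labels == 0])
    fold_aucs = np.asarray(fold_aucs)
    return CVResult(
        auc=auc,
        se_folds=float(fold_aucs.std(ddof=1) / np.sqrt(n_folds)),
        se_hanley=hanley_mcneil_se(auc, n_pos, n_neg),
        fold_aucs=fold_aucs,
        posteriors=pd.Series(post, index=curves.gene_ids),
        labels=pd.Series(labels, index=curves.gene_ids),
    )


# ---------------------------------------------------------------------------
# Shuffle FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrCurve:
    fc_cutoffs: np.ndarray          # linear scale
    real_counts: np.ndarray
    null_mean_counts: np.ndarray
    fdr: np.ndarray                 # NaN where real count is 0
    n_reps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fc_cutoff": self.fc_cutoffs, "n_predicted": self.real_counts,
            "null_mean": self.null_mean_counts, "fdr": self.fdr})


def _count_targets(model: FknnModel, curves: CurveSet, fc_ref: pd.Series,
                   cutoffs: np.ndarray) -> np.ndarray:
    pred = classify(model, curves)
    hit = pred["posterior"] >= POSTERIOR_HI
    fc_up = fc_ref.reindex(pred.index).to_numpy()
    return np.array([(hit & (fc_up >= np.log2(c))).sum() for c in cutoffs])


def estimate_fdr(curves_scaled: CurveSet, fc: pd.DataFrame,
                 predictions, annotations: GeneAnnotation, *,
                 threshold: float = 1.5, k: int = 11,
                 window=(2.0, 20.0), fc_cutoffs=(1.0, 1.2, 1.5, 2.0),
                 n_reps: int = 50, reference_time: float = 4.0,
                 rng_seed: int = 0) -> FdrCurve:
    """Shuffle-based FDR: rerun the identical train/classify pipeline on
    null training sets randomly sampled under the same non-specific
    filtering cutoffs, and take the ratio of predicted-target counts.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    cutoffs = np.asarray(fc_cutoffs, dtype=float)
    fc_ref = fc[_time_col(fc, reference_time)]

    sets = build_training_sets(predictions, annotations, fc,
                               threshold=threshold, rng_seed=rng_seed)
    direct, indirect = sorted(sets.direct), sorted(sets.indirect)
    n = len(direct)

    def fit_count(d_ids, i_ids):
        ids = list(d_ids) + list(i_ids)
        labels = np.r_[np.ones(len(d_ids), int), np.zeros(len(i_ids), int)]
        model = train_fknn(curves_scaled.subset(ids), labels, k=k,
                           window=window)
        return _count_targets(model, curves_scaled, fc_ref, cutoffs)

    real = fit_count(direct, indirect)

    from .targets import nonspecific_filter
    pool = sorted(nonspecific_filter(fc, threshold)
                  & set(curves_scaled.gene_ids))
    if len(pool) < 2 * n:
        raise ValueError("responder pool too small for null training sets")
    rng = np.random.default_rng(rng_seed + 1)
    null_counts = np.zeros((n_reps, len(cutoffs)))
    for r in range(n_reps):
        pick = rng.choice(pool, size=2 * n, replace=False)
        null_counts[r] = fit_count(pick[:n], pick[n:])
    null_mean = null_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(real > 0, np.minimum(null_mean / real, 1.0), np.nan)
    return FdrCurve(cutoffs, real, null_mean, fdr, n_reps)


def _time_col(fc: pd.DataFrame, time: float) -> str:
    for c in fc.columns:
        t = float(c[1:]) if isinstance(c, str) and c.startswith("t") \
            else float(c)
        if np.isclose(t, time):
            return c
    raise ValueError(f"reference time {time} h absent from fold-change grid")


def rank_predictions(predictions: pd.DataFrame, fc: pd.DataFrame,
                     fc_cutoff: float = 1.5, reference_time: float = 4.0
                     ) -> pd.DataFrame:
    """Targets (posterior >= 0.75 and linear FC at the reference time >=
    cutoff) ranked by FC descending; ties by posterior then gene id."""
    fc_ref = fc[_time_col(fc, reference_time)]
    df = predictions.copy()
    df["log2fc_ref"] = fc_ref.reindex(df.index)
    keep = ((df["posterior"] >= POSTERIOR_HI)
            & (df["log2fc_ref"] >= np.log2(fc_cutoff)))
    out = (df[keep].rename_axis("gene").reset_index()
           .sort_values(["log2fc_ref", "posterior", "gene"],
                        ascending=[False, False, True], kind="stable")
           .set_index("gene"))
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Per-miRNA specificity scan
# ---------------------------------------------------------------------------

def specificity_scan(per_mirna_predictions: dict, curves_scaled: CurveSet,
                     fc: pd.DataFrame, annotations: GeneAnnotation, *,
                     focal_carriers=None, focal_mirna=None,
                     min_set_size: int = 150,
                     threshold: float = 1.5, k: int = 11,
                     window=(2.0, 10.0), n_folds: int = 10,
                     rng_seed: int = 0) -> pd.DataFrame:
    """Delta-AUC of each miRNA's model on its own vs other miRNAs' sets.

    For each miRNA with a prediction list of at least ``min_set_size``:
    build direct/indirect sets under the shared non-specific filter
    (excluding focal-miRNA seed carriers from non-focal sets when
    ``focal_carriers`` is given), subsample every direct set to the common
    matched size, train the early-window model, and report
    AUC_self (cross-validated) minus the mean AUC obtained on the other
    miRNAs' sets, with Hanley-McNeil-based p-values for the difference.
    """
    from .targets import nonspecific_filter

    focal_carriers = set() if focal_carriers is None else set(focal_carriers)
    responders = nonspecific_filter(fc, threshold) & set(
        curves_scaled.gene_ids)
    eligible = {m: set(map(str, lst)) for m, lst in
                per_mirna_predictions.items() if len(lst) >= min_set_size}
    if len(eligible) < 2:
        raise ValueError("need >= 2 miRNA prediction lists of size "
                         f">= {min_set_size}")

    rng = np.random.default_rng(rng_seed)
    # co-target exclusion: comparator (non-focal) sets drop genes carrying
    # the focal miRNA's seed, so shared targets cannot inflate their AUC
    directs = {}
    for m, preds in eligible.items():
        d = preds & responders
        if focal_carriers and m != focal_mirna:
            d -= focal_carriers
        directs[m] = d
    sizes = {m: len(d) for m, d in directs.items()}
    n0 = min(sizes.values())
    if n0 < n_folds:
        raise ValueError(f"matched direct-set size {n0} too small: {sizes}")

    sets = {}
    for m in sorted(eligible):
        d = sorted(directs[m])
        d = list(rng.choice(d, size=n0, replace=False)) if len(d) > n0 else d
        pool = sorted(responders - eligible[m] - set(d) - focal_carriers)
        i = list(rng.choice(pool, size=n0, replace=False))
        sets[m] = (d, i)

    rows = []
    for m, (d, i) in sets.items():
        ids = d + i
        labels = np.r_[np.ones(len(d), int), np.zeros(len(i), int)]
        cv = cross_validate(curves_scaled.subset(ids), labels, k=k,
                            window=window, n_folds=min(n_folds, n0),
                            rng_seed=rng_seed)
        model = train_fknn(curves_scaled.subset(ids), labels, k=k,
                           window=window)
        cross_aucs = []
        for m2, (d2, i2) in sets.items():
            if m2 == m:
                continue
            eval_ids = [g for g in d2 + i2 if g not in set(ids)]
            eval_lab = np.array([1 if g in set(d2) else 0 for g in eval_ids])
            if eval_lab.sum() == 0 or eval_lab.sum() == len(eval_lab):
                continue
            pred = classify(model, curves_scaled.subset(eval_ids))
            cross_aucs.append(auc_mann_whitney(
                pred["posterior"][eval_lab == 1],
                pred["posterior"][eval_lab == 0]))
        auc_other = float(np.mean(cross_aucs)) if cross_aucs else np.nan
        delta = cv.auc - auc_other
        se_self = hanley_mcneil_se(cv.auc, n0, n0)
        se_other = hanley_mcneil_se(auc_other, n0, n0) \
            if np.isfinite(auc_other) else np.nan
        z = delta / np.sqrt(se_self ** 2 + se_other ** 2) \
            if np.isfinite(auc_other) else np.nan
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"mirna": m, "auc_self": cv.auc, "auc_other": auc_other,
                     "delta_auc": delta, "p_value": p, "n_matched": n0})
    return pd.DataFrame(rows).set_index("mirna")
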