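"""Per-timepoint statistics characterizing the multiphasic response.

Covers seed enrichment across time, direct/indirect discrimination AUC,
rank-based (weighted Kolmogorov-Smirnov) gene-set enrichment with a
gene-label permutation null, the TF-motif/miRNA-seed significance ratio,
up/down asymmetry tests, the 4 h <-> 32 h coherence analysis, the split
of TF-target responses by whether the TF is itself a miRNA target, and
cumulative-distribution / seed-removal analyses of UTR vs CDS seed
effects with shuffled-seed controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .predict import auc_mann_whitney
from .targets import GeneAnnotation, SeedSpec

__all__ = [
    "seed_enrichment_by_time",
    "discrimination_auc_by_time",
    "gsea_enrichment_score",
    "set_enrichment_by_time",
    "tf_mir_ratio",
    "updown_asymmetry",
    "coherence_analysis",
    "CoherenceResult",
    "tf_target_split_response",
    "seed_region_effect",
    "SeedRegionEffect",
]


def _times(fc: pd.DataFrame) -> np.ndarray:
    return np.array([float(c[1:]) if isinstance(c, str) and c.startswith("t")
                     else float(c) for c in fc.columns])


def _col(fc: pd.DataFrame, time: float) -> str:
    t = _times(fc)
    hits = np.flatnonzero(np.isclose(t, time))
    if not len(hits):
        raise ValueError(f"time {time} h not in grid")
    return fc.columns[hits[0]]


# ---------------------------------------------------------------------------
# Seed enrichment and discrimination across time
# ---------------------------------------------------------------------------

def seed_enrichment_by_time(fc: pd.DataFrame, annotations: GeneAnnotation,
                            fc_threshold: float = 1.5) -> pd.DataFrame:
    """Per timepoint: seed-carrier fraction among responders vs the
    all-gene background, with one-sided binomial p-values.

    Responders at time t are genes with |log2FC(t)| >= log2(threshold).
    """
    carriers = annotations.carriers()
    genes = fc.index.intersection(carriers.index)
    if len(genes) < len(fc):
        raise ValueError("annotations must cover the fold-change genes")
    carriers = carriers.reindex(fc.index)
    bg_frac = float(carriers.mean())
    cut = np.log2(fc_threshold)
    rows = []
    for col, t in zip(fc.columns, _times(fc)):
        fg = fc.index[fc[col].abs() >= cut]
        n_fg = len(fg)
        if n_fg == 0:
            rows.append({"time": t, "fraction": np.nan, "p_value": np.nan,
                         "n_fg": 0, "n_bg": len(fc)})
            continue
        k = int(carriers.loc[fg].sum())
        p = stats.binomtest(k, n_fg, bg_frac, alternative="greater").pvalue
        rows.append({"time": t, "fraction": k / n_fg, "p_value": float(p),
                     "n_fg": n_fg, "n_bg": len(fc)})
    return pd.DataFrame(rows)


def discrimination_auc_by_time(fc: pd.DataFrame, direct_set,
                               indirect_set) -> pd.DataFrame:
    """AUC of FC(t) separating direct from indirect genes, per time."""
    direct, indirect = set(direct_set), set(indirect_set)
    if not direct or not indirect:
        raise ValueError("both sets must be non-empty")
    if direct & indirect:
        raise ValueError("sets must be disjoint")
    missing = (direct | indirect) - set(fc.index)
    if missing:
        raise ValueError(f"set members missing from fc: {sorted(missing)[:5]}")
    d_idx, i_idx = sorted(direct), sorted(indirect)
    rows = [{"time": t,
             "auc": auc_mann_whitney(fc.loc[d_idx, col], fc.loc[i_idx, col]),
             "n_fg": len(d_idx), "n_bg": len(i_idx)}
            for col, t in zip(fc.columns, _times(fc))]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-based set enrichment (weighted KS running sum)
# ---------------------------------------------------------------------------

def gsea_enrichment_score(ranked_values: np.ndarray, member: np.ndarray,
                          weight: float = 1.0, signed: bool = False
                          ) -> float:
    """Weighted KS running-sum enrichment score.

    ``ranked_values`` must be sorted descending; ``member`` is the
    membership mask in that order.  Hits advance by |value|^weight
    (normalized), misses retreat by 1/(N - n_hits).  Returns the maximum
    positive deviation, or the extreme signed deviation if ``signed``.
    """
    member = np.asarray(member, bool)
    n, nh = len(member), int(member.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper subset of the ranked genes")
    w = np.abs(np.asarray(ranked_values, float)) ** weight
    hit = np.where(member, w, 0.0)
    denom = hit.sum()
    if denom == 0:
        hit = member.astype(float)
        denom = nh
    run = np.cumsum(hit / denom - (~member) / (n - nh))
    if signed:
        return float(run[np.argmax(np.abs(run))])
    return float(run.max())


def set_enrichment_by_time(fc: pd.DataFrame, gene_sets: dict,
                           n_perm: int = 999, weight: float = 1.0,
                           rng_seed: int = 0, min_size: int = 5
                           ) -> pd.DataFrame:
    """Permutation GSEA of each set at each timepoint.

    Genes are ranked by FC(t) descending; p-values are one-sided for
    positive enrichment from a gene-label permutation null (random sets
    of the same size), p = (1 + #{ES_perm >= ES_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: p-values are coarse")
    universe = list(map(str, fc.index))
    n = len(universe)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for col, t in zip(fc.columns, _times(fc)):
        vals = fc[col].to_numpy(float)
        order = np.argsort(-vals, kind="stable")
        ranked = vals[order]
        gene_pos = {g: i for i, g in
                    enumerate(np.asarray(universe)[order])}
        w = np.abs(ranked) ** weight
        miss_step_base = np.ones(n)
        for name, members in gene_sets.items():
            m_idx = [gene_pos[g] for g in members if g in gene_pos]
            nh = len(m_idx)
            if nh < min_size or nh == n:
                continue
            mask = np.zeros(n, bool)
            mask[m_idx] = True
            es = gsea_enrichment_score(ranked, mask, weight)
            # vectorized permutation null: random same-size sets
            perm_idx = np.argsort(
                rng.random((n_perm, n)), axis=1)[:, :nh]
            hitw = np.zeros((n_perm, n))
            np.put_along_axis(hitw, perm_idx, w[perm_idx], axis=1)
            hits = np.zeros((n_perm, n))
            np.put_along_axis(hits, perm_idx, 1.0, axis=1)
            denom = hitw.sum(axis=1)
            denom[denom == 0] = nh
            run = np.cumsum(hitw / denom[:, None]
                            - (miss_step_base - hits) / (n - nh), axis=1)
            es_perm = run.max(axis=1)
            p = (1 + np.sum(es_perm >= es)) / (n_perm + 1)
            rows.append({"set": name, "time": t, "es": es,
                         "p_value": float(p), "n_set": nh})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = np.nan
        for t, grp in out.groupby("time"):
            out.loc[grp.index, "p_bh"] = stats.false_discovery_control(
                grp["p_value"])
    return out


def tf_mir_ratio(enrichments: pd.DataFrame, tf_set_ids, mir_set_ids,
                 alpha: float = 1e-4) -> pd.DataFrame:
    """Per time: (# significant TF-motif sets) / (# significant miRNA-seed
    sets) at level alpha; undefined (NaN, flagged) when the miRNA count is
    zero."""
    tf_ids, mir_ids = set(tf_set_ids), set(mir_set_ids)
    rows = []
    for t, grp in enrichments.groupby("time"):
        sig = grp[grp["p_value"] < alpha]
        n_tf = int(sig["set"].isin(tf_ids).sum())
        n_mir = int(sig["set"].isin(mir_ids).sum())
        ratio = n_tf / n_mir if n_mir else np.nan
        rows.append({"time": t, "n_tf": n_tf, "n_mir": n_mir,
                     "ratio": ratio, "defined": bool(n_mir)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Up/down asymmetry
# ---------------------------------------------------------------------------

def updown_asymmetry(fc: pd.DataFrame, threshold: float = 1.5,
                     delta: float = 0.10) -> pd.DataFrame:
    """Per time: up/down responder counts and an exact binomial test of
    whether the up-proportion deviates from 0.5 by more than ``delta``.

    H0 places the success probability at the interval boundary nearest
    the observed proportion (0.5 + delta if p_hat > 0.5 else 0.5 - delta)
    and takes the corresponding outward tail.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    cut = np.log2(threshold)
    rows = []
    for col, t in zip(fc.columns, _times(fc)):
        v = fc[col]
        n_up = int((v >= cut).sum())
        n_down = int((v <= -cut).sum())
        n = n_up + n_down
        if n == 0:
            rows.append({"time": t, "n_up": 0, "n_down": 0,
                         "up_fraction": np.nan, "p_value": np.nan})
            continue
        p_hat = n_up / n
        if p_hat > 0.5:
            p = stats.binom.sf(n_up - 1, n, 0.5 + delta)
        else:
            p = stats.binom.cdf(n_up, n, 0.5 - delta)
        rows.append({"time": t, "n_up": n_up, "n_down": n_down,
                     "up_fraction": p_hat, "p_value": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 4 h <-> 32 h coherence
# ---------------------------------------------------------------------------

@dataclass
class CoherenceResult:
    t1: float
    t2: float
    n_up1: int
    n_down1: int
    n_up2: int
    n_down2: int
    overlap_fraction: float     # up-at-t2 genes preceded by up-at-t1
    fisher_odds: float
    fisher_p: float
    coherent_fraction: float    # among up-at-t1 genes responding at t2
    table: np.ndarray           # 2x2 up1 x up2 within responder universe
    sign_table: pd.DataFrame    # gene x {sign_t1, sign_t2}, heatmap input
    note: str = ""


def coherence_analysis(fc: pd.DataFrame, t1: float = 4.0,
                       thr1: float = 1.5, t2: float = 32.0,
                       thr2: float = 1.3) -> CoherenceResult:
    """Overlap and coherence of responses at two timepoints.

    Universe = genes responding at t1 (|FC| >= thr1) or t2 (|FC| >= thr2).
    Fisher exact test: up-at-t1 vs up-at-t2 cross-classification within
    the universe.  Coherent fraction: among genes up at t1 AND responding
    at t2, the fraction also up at t2.
    """
    c1, c2 = _col(fc, t1), _col(fc, t2)
    v1, v2 = fc[c1], fc[c2]
    cut1, cut2 = np.log2(thr1), np.log2(thr2)
    s1 = np.sign(v1) * (v1.abs() >= cut1)
    s2 = np.sign(v2) * (v2.abs() >= cut2)
    universe = fc.index[(s1 != 0) | (s2 != 0)]
    u1 = (s1.loc[universe] > 0)
    u2 = (s2.loc[universe] > 0)
    a = int((u1 & u2).sum())
    b = int((u1 & ~u2).sum())
    c = int((~u1 & u2).sum())
    d = int((~u1 & ~u2).sum())
    table = np.array([[a, b], [c, d]])
    note = ""
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        note = "degenerate margins: Fisher p = 1"
        odds, p = np.nan, 1.0
    else:
        odds, p = stats.fisher_exact(table, alternative="greater")
    up2_total = a + c
    overlap = a / up2_total if up2_total else np.nan
    both = (s1.loc[universe] > 0) & (s2.loc[universe] != 0)
    coherent = float((s2.loc[universe][both] > 0).mean()) if both.any() \
        else np.nan
    sign_table = pd.DataFrame(
        {f"sign_t{t1:g}": s1.loc[universe].astype(int),
         f"sign_t{t2:g}": s2.loc[universe].astype(int)}
    ).sort_values(f"sign_t{t1:g}", ascending=False, kind="stable")
    return CoherenceResult(
        t1=t1, t2=t2,
        n_up1=int((s1 > 0).sum()), n_down1=int((s1 < 0).sum()),
        n_up2=int((s2 > 0).sum()), n_down2=int((s2 < 0).sum()),
        overlap_fraction=overlap, fisher_odds=float(odds)
        if np.isfinite(odds) else np.nan, fisher_p=float(p),
        coherent_fraction=coherent, table=table, sign_table=sign_table,
        note=note)


# ---------------------------------------------------------------------------
# TF-target split response
# ---------------------------------------------------------------------------

def tf_target_split_response(fc: pd.DataFrame, targets_of_mir_tfs,
                             targets_of_other_tfs,
                             responder_threshold: float = 1.5,
                             query_time: float = 32.0):
    """Mean FC +/- SE per time for targets of miRNA-targeted TFs vs
    targets of other TFs, restricted to genes responding (|FC| >=
    threshold) at any time; plus the between-set difference at the query
    time.  Genes in both sets are excluded."""
    set_a = set(targets_of_mir_tfs)
    set_b = set(targets_of_other_tfs)
    shared = set_a & set_b
    set_a, set_b = set_a - shared, set_b - shared
    cut = np.log2(responder_threshold)
    responders = set(fc.index[fc.abs().max(axis=1) >= cut])
    rows = []
    for name, s in (("mir_tf_targets", set_a), ("other_tf_targets", set_b)):
        sel = sorted((s & responders) & set(fc.index))
        if not sel:
            raise ValueError(f"{name} empty after responder filtering")
        sub = fc.loc[sel]
        for col, t in zip(fc.columns, _times(fc)):
            v = sub[col]
            rows.append({"set": name, "time": t, "mean_fc": float(v.mean()),
                         "se": float(v.std(ddof=1) / np.sqrt(len(v))),
                         "n": len(v)})
    df = pd.DataFrame(rows)
    qa = df[(df["set"] == "mir_tf_targets")
            & np.isclose(df["time"], query_time)]["mean_fc"].iloc[0]
    qb = df[(df["set"] == "other_tf_targets")
            & np.isclose(df["time"], query_time)]["mean_fc"].iloc[0]
    return df, float(qa - qb)


# ---------------------------------------------------------------------------
# CDS/UTR seed-effect analyses with shuffled-seed controls
# ---------------------------------------------------------------------------

@dataclass
class SeedRegionEffect:
    ks_results: pd.DataFrame       # group vs no-seed KS statistic + p
    removal: pd.DataFrame          # per region: delta and shuffled control


def _has_site(seqs: dict, genes, site: str) -> pd.Series:
    return pd.Series({g: site in seqs[g] for g in genes})


def seed_region_effect(fc_at_reference: pd.Series,
                       annotations: GeneAnnotation, mirna: SeedSpec,
                       n_shuffles: int = 50, threshold: float = 1.5,
                       rng_seed: int = 0) -> SeedRegionEffect:
    """UTR vs CDS seed effects at a reference timepoint.

    (a) Two-sample KS tests of FC for UTR-seed / CDS-seed / both-seed
    genes against no-seed genes.  (b) For upward responders (FC >=
    threshold), the decrease in mean FC when 7-mer seed carriers in
    {3'UTR, CDS, gene body} are removed, against shuffled-miRNA-seed
    controls (mean +/- sd over ``n_shuffles`` uniform shuffles).
    """
    ann = annotations.table
    genes = fc_at_reference.index.intersection(ann.index)
    fcv = fc_at_reference.loc[genes]
    utr = ann.loc[genes, "seed7_utr"].fillna(0) > 0
    cds = ann.loc[genes, "seed7_cds"].fillna(0) > 0
    groups = {"utr_only": utr & ~cds, "cds_only": cds & ~utr,
              "both": utr & cds}
    none = ~utr & ~cds
    ks_rows = []
    for name, mask in groups.items():
        if mask.sum() == 0 or none.sum() == 0:
            ks_rows.append({"group": name, "ks": np.nan, "p_value": np.nan,
                            "n": int(mask.sum())})
            continue
        res = stats.ks_2samp(fcv[mask], fcv[none])
        ks_rows.append({"group": name, "ks": float(res.statistic),
                        "p_value": float(res.pvalue), "n": int(mask.sum())})

    # removal analysis on the upward responder set
    resp = fcv.index[fcv >= np.log2(threshold)]
    have_seqs = (annotations.utr_sequences is not None
                 and annotations.cds_sequences is not None)
    removal_rows = []
    if len(resp) and have_seqs:
        useqs = annotations.utr_sequences
        cseqs = annotations.cds_sequences
        rng = np.random.default_rng(rng_seed)
        base_mean = float(fcv.loc[resp].mean())

        def deltas(seed7: str) -> dict[str, float]:
            in_utr = _has_site(useqs, resp, seed7)
            in_cds = _has_site(cseqs, resp, seed7)
            out = {}
            for region, mask in (("utr3", in_utr), ("cds", in_cds),
                                 ("gene_body", in_utr | in_cds)):
                keep = resp[~mask.loc[resp].to_numpy()]
                out[region] = (base_mean - float(fcv.loc[keep].mean())
                               if len(keep) else np.nan)
            return out

        real = deltas(mirna.seed7)
        ctrl = {r: [] for r in real}
        letters = list(mirna.mirna_sequence)
        for _ in range(n_shuffles):
            rng.shuffle(letters)
            shuffled = SeedSpec("".join(letters))
            for r, v in deltas(shuffled.seed7).items():
                ctrl[r].append(v)
        for r in real:
            cv = np.asarray(ctrl[r], float)
            removal_rows.append({
                "region": r, "delta": real[r],
                "control_mean": float(np.nanmean(cv)),
                "control_sd": float(np.nanstd(cv, ddof=1)),
                "n_shuffles": n_shuffles})
    return SeedRegionEffect(pd.DataFrame(ks_rows),
                            pd.DataFrame(removal_rows))
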