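"""Post-normalization of fold changes and qPCR quantification.

Residual intensity-dependent (M-A) bias left by upstream array
normalization is removed by centring each timepoint's M-A cloud on a
loess fit through a large housekeeping-gene set: corrected
M = M - Mhat(A), applied only where the housekeeping fit is precise.
qPCR expression is quantified by delta-delta-Ct against the geometric mean
of three housekeeping genes (arithmetic mean on the Ct scale), with a
one-sample t-test of the early 2-4 h peak against the later background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_ma",
    "LoessFit",
    "loess_fit",
    "loess_correct",
    "ddct_normalize",
    "peak_ttest",
    "QPCR_HOUSEKEEPING",
]

QPCR_HOUSEKEEPING = ("GAPDH", "ACTB", "YWHAQ")


def compute_ma(treated: pd.Series, control: pd.Series, log_scale: bool = True
               ) -> pd.DataFrame:
    """Per-gene M (log2 ratio) and A (mean log2 intensity).

    Inputs are log2 intensities by default; with ``log_scale=False`` they
    are linear and must be strictly positive.
    """
    if not treated.index.equals(control.index):
        control = control.reindex(treated.index)
        if control.isna().any():
            raise ValueError("treated/control gene sets differ")
    t, c = treated.astype(float), control.astype(float)
    if not log_scale:
        bad = t.index[(t <= 0) | (c <= 0)]
        if len(bad):
            raise ValueError(
                f"non-positive linear intensity for gene(s) {list(bad[:5])}")
        t, c = np.log2(t), np.log2(c)
    if not (np.isfinite(t).all() and np.isfinite(c).all()):
        bad = t.index[~(np.isfinite(t) & np.isfinite(c))]
        raise ValueError(f"non-finite intensity for gene(s) {list(bad[:5])}")
    return pd.DataFrame({"A": (t + c) / 2, "M": t - c})


@dataclass
class LoessFit:
    """Local linear (degree-1, tricube) fit with pointwise SEs.

    Stores the training points so the smooth and its standard error can be
    evaluated at arbitrary abscissae inside the training range.
    """

    x: np.ndarray
    y: np.ndarray
    span: float
    sigma: float

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    def predict(self, x_new) -> tuple[np.ndarray, np.ndarray]:
        """Return (fitted value, SE of fit) at each point of x_new."""
        xq = np.atleast_1d(np.asarray(x_new, dtype=float))
        n = len(self.x)
        q = max(int(np.ceil(self.span * n)), 3)
        fit = np.empty(len(xq))
        se = np.empty(len(xq))
        for i, x0 in enumerate(xq):
            d = np.abs(self.x - x0)
            idx = np.argpartition(d, q - 1)[:q]
            dmax = d[idx].max()
            if dmax == 0:
                dmax = 1.0
            w = (1 - np.minimum(d[idx] / dmax, 1.0) ** 3) ** 3
            w = np.maximum(w, 1e-12)
            dx = self.x[idx] - x0
            # weighted linear regression; fitted value at x0 = intercept
            X = np.column_stack([np.ones(q), dx])
            XtW = X.T * w
            beta_cov = np.linalg.pinv(XtW @ X)
            l_vec = (beta_cov @ XtW)[0]          # equivalent kernel at x0
            fit[i] = l_vec @ self.y[idx]
            se[i] = self.sigma * np.sqrt(l_vec @ l_vec)
        return fit, se


def loess_fit(x, y, span: float = 0.5) -> LoessFit:
    """Fit a degree-1 tricube loess; residual scale from the self-fit."""
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    fit = LoessFit(x[order], y[order], span, sigma=0.0)
    fitted, _ = fit.predict(fit.x)
    resid = fit.y - fitted
    # ~2 effective parameters per local fit
    fit.sigma = float(np.sqrt(np.sum(resid ** 2) / max(len(x) - 2, 1)))
    return fit


def loess_correct(ma: pd.DataFrame, housekeeping_ids,
                  span: float = 0.5, se_threshold: float = 0.02,
                  skip_if_se_above: bool = True
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Centre M on the housekeeping loess curve: corrected M = M - Mhat(A).

    Genes whose local housekeeping fit is imprecise (SE above
    ``se_threshold``; direction flippable via ``skip_if_se_above``) and
    genes whose A lies outside the housekeeping range are returned
    unadjusted.  Returns (corrected M, per-gene info frame with columns
    mhat, se, adjusted).
    """
    hk = [g for g in housekeeping_ids if g in ma.index]
    if len(hk) < 30:
        raise ValueError(f"need >=30 housekeeping genes with M-A values, "
                         f"got {len(hk)}")
    hk_ma = ma.loc[hk]
    fit = loess_fit(hk_ma["A"].to_numpy(), hk_ma["M"].to_numpy(), span)
    lo, hi = fit.x_range

    A = ma["A"].to_numpy(dtype=float)
    in_range = (A >= lo) & (A <= hi)
    mhat = np.zeros(len(ma))
    se = np.full(len(ma), np.nan)
    if in_range.any():
        mhat[in_range], se[in_range] = fit.predict(A[in_range])

    if skip_if_se_above:
        precise = np.nan_to_num(se, nan=np.inf) <= se_threshold
    else:
        precise = np.nan_to_num(se, nan=np.inf) >= se_threshold
    adjusted = in_range & precise
    n_out = int((~in_range).sum())
    if n_out:
        warnings.warn(f"{n_out} genes outside housekeeping A range left "
                      "unadjusted")
    corrected = ma["M"] - np.where(adjusted, mhat, 0.0)
    info = pd.DataFrame({"mhat": mhat, "se": se, "adjusted": adjusted},
                        index=ma.index)
    return corrected, info


def ddct_normalize(ct: pd.DataFrame,
                   housekeeping=QPCR_HOUSEKEEPING) -> pd.DataFrame:
    """Delta-delta-Ct log2 fold changes per target gene and timepoint.

    log2FC(t) = -[(Ct_tgt,trt - mean Ct_hk,trt) - (Ct_tgt,ctl - mean
    Ct_hk,ctl)]; the arithmetic mean of housekeeping Cts equals the
    geometric mean of their expression levels.  Timepoints with any
    missing Ct are dropped with a warning.
    """
    req = {"gene", "condition", "time", "ct"}
    if not req <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {req}")
    housekeeping = list(housekeeping)
    targets = sorted(set(ct["gene"]) - set(housekeeping))
    if not targets:
        raise ValueError("no target genes in Ct table")
    wide = ct.pivot_table(index="time", columns=["gene", "condition"],
                          values="ct", aggfunc="mean")

    needed = [(g, c) for g in housekeeping + targets
              for c in ("treated", "control")]
    missing_cols = [col for col in needed if col not in wide.columns]
    if missing_cols:
        raise ValueError(f"Ct table missing series {missing_cols[:4]}")
    complete = wide.loc[:, needed].notna().all(axis=1)
    if not complete.all():
        dropped = list(wide.index[~complete])
        warnings.warn(f"dropping timepoints with missing Ct: {dropped}")
    wide = wide.loc[complete]

    hk_trt = wide[[(g, "treated") for g in housekeeping]].mean(axis=1)
    hk_ctl = wide[[(g, "control") for g in housekeeping]].mean(axis=1)
    out = {}
    for g in targets:
        d_trt = wide[(g, "treated")] - hk_trt
        d_ctl = wide[(g, "control")] - hk_ctl
        out[g] = -(d_trt - d_ctl)
    return pd.DataFrame(out)


def peak_ttest(fc_series: pd.Series, peak_window=(2.0, 4.0),
               background_window=(5.0, 40.0)) -> tuple[float, float]:
    """One-sample t-test of peak-window FC against the background mean.

    ``fc_series`` is indexed by time (hours).  Windows are inclusive.
    """
    t = fc_series.index.to_numpy(dtype=float)
    peak = fc_series[(t >= peak_window[0]) & (t <= peak_window[1])]
    bg = fc_series[(t >= background_window[0]) & (t <= background_window[1])]
    if len(peak) < 2 or len(bg) < 2:
        raise ValueError("need >=2 points in each window")
    if np.allclose(peak.std(ddof=1), 0):
        raise ValueError("zero variance in peak window")
    res = stats.ttest_1samp(peak.to_numpy(), popmean=float(bg.mean()))
    return float(res.statistic), float(res.pvalue)
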