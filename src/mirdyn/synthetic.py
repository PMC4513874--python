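"""Synthetic antimiR time-course data with known ground truth.

Emulates the statistical structure of a 17-timepoint (2-112 h) antimiR
inhibition experiment: direct miRNA targets show an upward de-repression
impulse near 4 h (linear FC ~1.58) followed by a coherent upward secondary
bump near 32 h (~1.28); indirect targets show a sign-mixed 32 h response
only; non-targets show noise with optional low-amplitude late drift; and
housekeeping genes carry no planted signal and no seed sites.  Sequence
generation plants miRNA seed sites in a configurable fraction of direct
genes (default 58%) versus background (35%), and draws 3'UTR lengths with
a configurable Spearman correlation to the 4 h response (default 0.27).
Array-intensity generation adds a smooth intensity-dependent (M-A) bias
for exercising the loess post-normalization.

All randomness flows from a single generator seeded by ``rng_seed``;
identical configs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .targets import (MIR9_SEQUENCE, GeneAnnotation, SeedSpec,
                      annotate_sequences)

__all__ = [
    "MICROARRAY_TIME_GRID",
    "QPCR_TIME_GRID",
    "SynthConfig",
    "SynthDataset",
    "IntensityTable",
    "generate_timecourse",
    "generate_sequences",
    "generate_array_intensities",
    "generate_qpcr",
    "bias_curve",
]

#: sampling schedule of the microarray time course (hours)
MICROARRAY_TIME_GRID = (2., 4., 6., 8., 10., 12., 14., 16., 18., 20., 22.,
                        26., 32., 40., 56., 80., 112.)
#: denser early schedule used for qPCR validation (hours)
QPCR_TIME_GRID = (1., 2., 3., 4., 5., 6., 8., 10., 12., 14., 16., 18., 20.,
                  22., 26., 32., 40.)

_HOUSEKEEPING_QPCR = ("GAPDH", "ACTB", "YWHAQ")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Fold changes are represented internally as log2; ``*_fc`` parameters
    are quoted on the linear scale and converted via log2.
    """

    n_direct: int = 150
    n_indirect: int = 1000
    n_nontarget: int = 2500
    n_housekeeping: int = 300
    time_grid: tuple[float, ...] = MICROARRAY_TIME_GRID
    direct_peak_time: float = 4.0
    direct_peak_fc: float = 1.58        # linear
    secondary_peak_time: float = 32.0
    secondary_peak_fc: float = 1.28     # linear
    peak_width_early: float = 2.0       # h, Gaussian sd of the 4 h bump
    peak_width_late: float = 6.0        # h, Gaussian sd of the 32 h bump
    noise_sd: float = 0.15              # log2 units, i.i.d. per gene x time
    amplitude_jitter_sd: float = 0.0    # log2 units, per-gene amplitude
    indirect_fc_median: float = 1.4     # linear, median |FC| of indirect bump
    indirect_fc_sigma: float = 0.55     # lognormal sigma of that amplitude
    late_drift_sd: float = 0.08         # log2 units, non-target drift
    seed_frac_fg: float = 0.58
    seed_frac_bg: float = 0.35
    utr_length_fc_rho: float = 0.27     # Spearman, UTR length vs 4 h FC
    bias_amplitude: float = 0.3         # log2 units, max |M-A bias|
    qpcr_ct_sd: float = 0.0             # Ct noise for the qPCR generator
    mirna_sequence: str = MIR9_SEQUENCE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_direct", "n_indirect", "n_nontarget",
                     "n_housekeeping"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t = np.asarray(self.time_grid, dtype=float)
        if len(t) < 4 or not np.all(np.diff(t) > 0) or not np.all(t > 0):
            raise ValueError("time_grid must be >=4 strictly increasing "
                             "positive times")
        for name in ("direct_peak_time", "direct_peak_fc",
                     "secondary_peak_time", "secondary_peak_fc",
                     "peak_width_early", "peak_width_late", "noise_sd",
                     "amplitude_jitter_sd", "indirect_fc_median",
                     "indirect_fc_sigma", "late_drift_sd", "seed_frac_fg",
                     "seed_frac_bg", "utr_length_fc_rho", "bias_amplitude",
                     "qpcr_ct_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("seed_frac_fg", "seed_frac_bg"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def seed_spec(self) -> SeedSpec:
        return SeedSpec(self.mirna_sequence)


@dataclass
class SynthDataset:
    fc: pd.DataFrame                      # genes x timepoints, log2
    true_labels: pd.Series                # gene -> direct|indirect|nontarget
    annotations: GeneAnnotation
    predictions: list[str]                # external-predictor emulation
    housekeeping_ids: list[str]
    config: SynthConfig

    def __post_init__(self) -> None:
        labelled = set(self.true_labels.index)
        if labelled != set(self.fc.index):
            raise ValueError("label partition must cover all genes")


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    # Gaussian truncated at 4 sigma: planted peak amplitudes are then
    # exactly recoverable (no cross-talk between the 4 h and 32 h bumps)
    z = (t - center) / width
    return np.where(np.abs(z) <= 4.0, np.exp(-0.5 * z ** 2), 0.0)


def generate_timecourse(config: SynthConfig) -> SynthDataset:
    """Generate the full synthetic dataset (fold changes, labels,
    sequences/annotations, external prediction list)."""
    rng = np.random.default_rng(config.rng_seed)
    t = np.asarray(config.time_grid, dtype=float)
    nT = len(t)

    ids_direct = [f"D{i:04d}" for i in range(config.n_direct)]
    ids_indirect = [f"I{i:04d}" for i in range(config.n_indirect)]
    ids_nontarget = [f"N{i:04d}" for i in range(config.n_nontarget)]
    ids_hk = [f"H{i:04d}" for i in range(config.n_housekeeping)]
    genes = ids_direct + ids_indirect + ids_nontarget + ids_hk

    a1 = np.log2(config.direct_peak_fc)
    a2 = np.log2(config.secondary_peak_fc)
    bump1 = _bump(t, config.direct_peak_time, config.peak_width_early)
    bump2 = _bump(t, config.secondary_peak_time, config.peak_width_late)

    signal = np.zeros((len(genes), nT))
    jit = config.amplitude_jitter_sd
    # direct: coherent up bumps at both peaks; a shared lognormal
    # per-gene scale (off by default) models gene-to-gene responsiveness
    if config.n_direct:
        scale = (np.exp(rng.normal(0.0, jit, config.n_direct))
                 if jit else np.ones(config.n_direct))
        signal[:config.n_direct] = scale[:, None] * (
            a1 * bump1 + a2 * bump2)[None, :]
    # indirect: signed (mixed up/down) secondary bump only, with a
    # lognormal amplitude spread so a realistic fraction of downstream
    # responses crosses the FC>=1.5 responder filter
    off = config.n_direct
    if config.n_indirect:
        signs = rng.choice([-1.0, 1.0], size=config.n_indirect)
        mags = np.exp(rng.normal(np.log(np.log2(config.indirect_fc_median)),
                                 config.indirect_fc_sigma,
                                 config.n_indirect))
        signal[off:off + config.n_indirect] = (
            (signs * mags)[:, None] * bump2)
    # non-targets: low-amplitude late drift (ramping in after ~40 h)
    off += config.n_indirect
    if config.n_nontarget:
        drift = rng.normal(0.0, config.late_drift_sd, config.n_nontarget)
        ramp = np.clip((t - 40.0) / (t[-1] - 40.0 + 1e-9), 0.0, 1.0)
        signal[off:off + config.n_nontarget] = drift[:, None] * ramp[None, :]
    # housekeeping rows stay zero

    noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    fc = pd.DataFrame(signal + noise,
                      index=pd.Index(genes, name="gene_id"),
                      columns=[f"t{g:g}" for g in t])

    labels = pd.Series(
        ["direct"] * config.n_direct + ["indirect"] * config.n_indirect
        + ["nontarget"] * (config.n_nontarget + config.n_housekeeping),
        index=fc.index, name="label")

    fc4 = pd.Series(signal[:, _nearest(t, config.direct_peak_time)]
                    + noise[:, _nearest(t, config.direct_peak_time)],
                    index=fc.index)
    annotations = generate_sequences(config, labels, fc_at_peak=fc4,
                                     housekeeping_ids=ids_hk, rng=rng)
    return SynthDataset(fc, labels, annotations, list(ids_direct), ids_hk,
                        config)


def _nearest(t: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(t - value)))


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequences(rng, lengths) -> list[str]:
    return ["".join(np.char.decode(
        _BASES[rng.integers(0, 4, size=int(n))])) for n in lengths]


def _scrub(seq: str, pattern: str, rng) -> str:
    """Destroy every occurrence of `pattern` by mutating its middle base."""
    s = list(seq)
    while True:
        joined = "".join(s)
        pos = joined.find(pattern)
        if pos == -1:
            return joined
        mid = pos + len(pattern) // 2
        choices = [b for b in "ACGT" if b != s[mid]]
        s[mid] = choices[int(rng.integers(0, 3))]


def generate_sequences(config: SynthConfig, labels: pd.Series,
                       fc_at_peak: pd.Series | None = None,
                       housekeeping_ids=(), rng=None) -> GeneAnnotation:
    """Random UTR/CDS sequences with planted seed sites.

    A 7- or 8-mer seed site is planted in ``seed_frac_fg`` of direct
    (responding) genes and ``seed_frac_bg`` of other genes; housekeeping
    genes never carry sites.  Chance occurrences in designated non-carriers
    are scrubbed so realized fractions match the planted Bernoulli draws.
    UTR lengths follow a lognormal law coupled to the 4 h fold change by a
    Gaussian copula calibrated to the requested Spearman correlation.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    seed = config.seed_spec
    genes = list(labels.index)
    n = len(genes)
    hk = set(housekeeping_ids)

    # --- UTR lengths with rank correlation to 4 h FC
    eps = rng.standard_normal(n)
    if fc_at_peak is not None and config.utr_length_fc_rho != 0:
        rho_p = 2 * np.sin(np.pi * config.utr_length_fc_rho / 6)
        ranks = fc_at_peak.reindex(genes).rank().to_numpy()
        z_fc = _norm_scores(ranks)
        z = rho_p * z_fc + np.sqrt(1 - rho_p ** 2) * eps
    else:
        z = eps
    utr_len = np.maximum(50, np.round(np.exp(np.log(800) + 0.6 * z))
                         ).astype(int)
    cds_len = np.maximum(150, np.round(
        np.exp(np.log(1200) + 0.4 * rng.standard_normal(n)))).astype(int)

    utr_seqs = dict(zip(genes, _random_sequences(rng, utr_len)))
    cds_seqs = dict(zip(genes, _random_sequences(rng, cds_len)))

    is_direct = (labels == "direct").reindex(genes).to_numpy()
    u = rng.random(n)
    carrier = np.where(is_direct, u < config.seed_frac_fg,
                       u < config.seed_frac_bg)
    carrier &= ~np.isin(genes, list(hk))

    plant_region = rng.random(n) < 0.5      # True -> UTR, else CDS
    plant_eight = rng.random(n) < 0.5       # True -> 8-mer site

    for i, g in enumerate(genes):
        for region, store in (("utr", utr_seqs), ("cds", cds_seqs)):
            s = _scrub(store[g], seed.seed7, rng)
            if carrier[i] and ((region == "utr") == bool(plant_region[i])):
                site = seed.seed8 if plant_eight[i] else seed.seed7
                pos = int(rng.integers(0, len(s) - len(site) + 1))
                s = s[:pos] + site + s[pos + len(site):]
            store[g] = s
    return annotate_sequences(utr_seqs, cds_seqs, seed)


def _norm_scores(ranks: np.ndarray) -> np.ndarray:
    from scipy.stats import norm
    return norm.ppf(ranks / (len(ranks) + 1))


# ---------------------------------------------------------------------------
# Array intensities with planted M-A bias
# ---------------------------------------------------------------------------

_A_RANGE = (4.0, 14.0)


def bias_curve(A, amplitude: float) -> np.ndarray:
    """Smooth intensity-dependent bias with max |value| = amplitude.

    One sine period over the generated intensity range, mimicking residual
    non-linear normalization bias on an M-A plot.
    """
    lo, hi = _A_RANGE
    return amplitude * np.sin(2 * np.pi * (np.asarray(A, float) - lo)
                              / (hi - lo))


@dataclass
class IntensityTable:
    """Paired treated/control log2 intensities (genes x timepoints)."""

    control: pd.DataFrame
    treated: pd.DataFrame
    housekeeping_ids: list[str]
    bias_amplitude: float

    def ma(self, time_col: str) -> pd.DataFrame:
        from .normalize import compute_ma
        return compute_ma(self.treated[time_col], self.control[time_col])


def generate_array_intensities(config: SynthConfig, dataset: SynthDataset
                               ) -> IntensityTable:
    """Per-gene log2 intensities: treated = control + log2FC + bias(A0).

    The bias is evaluated at the pre-bias mean intensity
    A0 = control + log2FC/2, so with bias_amplitude=0 the recomputed M
    equals the planted log2 FC exactly.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    fc = dataset.fc
    base = rng.uniform(*_A_RANGE, size=len(fc))
    control = pd.DataFrame(
        np.repeat(base[:, None], fc.shape[1], axis=1),
        index=fc.index, columns=fc.columns)
    a0 = control + fc / 2
    treated = control + fc + bias_curve(a0, config.bias_amplitude)
    return IntensityTable(control, treated, list(dataset.housekeeping_ids),
                          config.bias_amplitude)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_qpcr(config: SynthConfig, planted_log2fc=None,
                  target_name: str = "TARGET") -> pd.DataFrame:
    """Ct table for one target and three housekeeping genes.

    Ct decreases by 1 per doubling of planted abundance; housekeeping
    genes are flat across conditions.  ``planted_log2fc`` is the target's
    log2 FC on the qPCR grid (default: the direct-gene bump profile).
    Long format: gene, condition (treated|control), time, ct.
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    t = np.asarray(QPCR_TIME_GRID)
    if planted_log2fc is None:
        planted_log2fc = (np.log2(config.direct_peak_fc)
                          * _bump(t, config.direct_peak_time,
                                  config.peak_width_early)
                          + np.log2(config.secondary_peak_fc)
                          * _bump(t, config.secondary_peak_time,
                                  config.peak_width_late))
    planted_log2fc = np.asarray(planted_log2fc, dtype=float)
    if planted_log2fc.shape != t.shape:
        raise ValueError("planted_log2fc must match the qPCR grid")

    base_ct = {target_name: 24.0, "GAPDH": 18.0, "ACTB": 17.0, "YWHAQ": 22.0}
    rows = []
    for gene, base in base_ct.items():
        for cond in ("control", "treated"):
            shift = (-planted_log2fc if (cond == "treated"
                                         and gene == target_name) else 0.0)
            ct = base + shift + rng.normal(0, config.qpcr_ct_sd, len(t))
            rows.extend({"gene": gene, "condition": cond,
                         "time": float(ti), "ct": float(ci)}
                        for ti, ci in zip(t, ct))
    return pd.DataFrame(rows)
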