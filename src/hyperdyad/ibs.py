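"""Cohort-level inter-brain synchrony (IBS) statistics.

Pipeline: per dyad, wavelet coherence between every male channel and
every female channel; time-averaged squared coherence per segment
(pooled rest baseline, block 1, block 2, pooled task) converted to
Fisher z; a task-vs-rest paired-t scan over the full frequency grid and
all channel pairs with Benjamini-Hochberg correction to select the
task-related frequency band; a group x block mixed-ANCOVA scan over all
channel pairs of the band-averaged z; a dyad-recombination permutation
test of the surviving pair; and a time-lag scan that shifts the male
series relative to the female series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .config import AnalysisConfig
from .stats import _check_collinearity, _ols_effect_f, fdr_bh, simple_effects
from .wtc import CoherenceMap, MorletGrid, SmoothingKernel, cwt_morlet

__all__ = [
    "IBSResult",
    "BandSelection",
    "InteractionScan",
    "PermutationResult",
    "fisher_z",
    "segment_average",
    "compute_cohort_ibs",
    "select_band",
    "band_average",
    "interaction_scan",
    "dyad_permutation_test",
    "timelag_scan",
]

SEGMENTS = ("rest", "block1", "block2", "task")


def fisher_z(coherence, *, on_magnitude: bool = True):
    """Fisher z of (time-averaged) squared coherence.  Default
    z = arctanh(sqrt(R2)); values at 1 are capped at 1 - 1e-7."""
    r2 = np.asarray(coherence, dtype=float)
    if np.any(r2 < -1e-12) or np.any(r2 > 1 + 1e-12):
        raise ValueError("coherence must lie in [0, 1]")
    r2 = np.clip(r2, 0.0, 1.0 - 1e-7)
    arg = np.sqrt(r2) if on_magnitude else r2
    return np.arctanh(arg)


def _segment_masks(timeline, fs, n_t):
    masks = {
        "rest": timeline.sample_mask(fs, n_t, "rest"),
        "block1": timeline.sample_mask(fs, n_t, "block", 1),
        "block2": timeline.sample_mask(fs, n_t, "block", 2),
    }
    masks["task"] = masks["block1"] | masks["block2"]
    return masks


def segment_average(cmap: CoherenceMap, timeline, segment: str) -> np.ndarray:
    """Per-frequency mean squared coherence over the samples of a
    segment ('rest' pools the three rest periods, 'task' both blocks),
    excluding points outside the cone of influence.  Frequencies whose
    segment lies entirely outside the COI are NaN."""
    n_t = cmap.coherence.shape[1]
    seg_mask = _segment_masks(timeline, cmap.fs, n_t)[segment]
    valid = cmap.valid_mask() & seg_mask[None, :]
    counts = valid.sum(axis=1)
    sums = np.where(valid, cmap.coherence, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# cohort IBS

@dataclass
class IBSResult:
    """Fisher-z coherence per dyad x (male ch, female ch) x segment x
    frequency, plus the dyad metadata needed by every downstream test."""

    z: np.ndarray                 # (n_dyads, n_ch, n_ch, n_seg, n_freq)
    freqs_hz: np.ndarray
    dyad_ids: list
    groups: list
    covariates: pd.DataFrame      # indexed like dyad_ids
    segments: tuple = SEGMENTS
    fs: float = 1.0

    @property
    def n_dyads(self) -> int:
        return self.z.shape[0]

    def seg_index(self, name: str) -> int:
        return self.segments.index(name)


def _dyad_segment_r2(hbo_m, hbo_f, timeline, fs, grid, kernel, masks,
                     channels_m=None, channels_f=None):
    """All-pairs per-segment mean R2 for one dyad.

    Returns (n_ch_m, n_ch_f, n_seg, n_freq).  CWTs and smoothed auto
    spectra are computed once per channel; only the cross term is
    smoothed per pair.
    """
    n_ch_m = hbo_m.shape[0]
    n_ch_f = hbo_f.shape[0]
    channels_m = range(n_ch_m) if channels_m is None else channels_m
    channels_f = range(n_ch_f) if channels_f is None else channels_f
    n_t = hbo_m.shape[1]
    inv_s = 1.0 / grid.scales_s[:, None]

    def _prep(series):
        w, coi = cwt_morlet(series, grid)
        auto = kernel.smooth(np.abs(w) ** 2 * inv_s)
        return w, auto, coi

    wm, am, coi = {}, {}, None
    for c in channels_m:
        wm[c], am[c], coi = _prep(hbo_m[c])
    wf, af = {}, {}
    for c in channels_f:
        wf[c], af[c], coi = _prep(hbo_f[c])

    valid_scale = grid.scales_s[:, None] <= (coi[None, :])
    seg_names = list(masks)
    seg_valid = [valid_scale & masks[s][None, :] for s in seg_names]
    counts = np.stack([v.sum(axis=1) for v in seg_valid])       # (n_seg, n_scales)
    out = np.full((n_ch_m, n_ch_f, len(seg_names), len(grid.freqs_hz)), np.nan)
    for i in channels_m:
        for j in channels_f:
            sxy = kernel.smooth(wm[i] * np.conj(wf[j]) * inv_s)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.abs(sxy) ** 2 / (am[i] * af[j])
            r2 = np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)
            for k, v in enumerate(seg_valid):
                sums = np.where(v, r2, 0.0).sum(axis=1)
                out[i, j, k] = np.where(counts[k] > 0,
                                        sums / np.maximum(counts[k], 1), np.nan)
    return out


def compute_cohort_ibs(sessions, hbo_pairs, config: AnalysisConfig,
                       freq_range=None) -> IBSResult:
    """Fisher-z segment coherence for every dyad and channel pair over
    the configured search range."""
    freq_range = freq_range or config.band_search_hz
    fs = config.downsample_hz
    grid = MorletGrid(fs, freq_range, config.scales_per_octave, config.omega0)
    z_all, ids, groups, covs = [], [], [], []
    kernel = None
    for sess, (hm, hf) in zip(sessions, hbo_pairs):
        n_t = hm.hbo.shape[1]
        if kernel is None or kernel.n_t != n_t:
            kernel = SmoothingKernel(grid, n_t)
        masks = _segment_masks(sess.timeline, fs, n_t)
        r2 = _dyad_segment_r2(hm.hbo, hf.hbo, sess.timeline, fs, grid, kernel, masks)
        bad_m, bad_f = hm.bad_channel_mask, hf.bad_channel_mask
        r2[bad_m, :, :, :] = np.nan
        r2[:, bad_f, :, :] = np.nan
        with np.errstate(invalid="ignore"):
            z_all.append(np.where(np.isfinite(r2), fisher_z(np.nan_to_num(r2)), np.nan))
        ids.append(sess.dyad_id)
        groups.append(sess.group)
        covs.append(sess.covariates)
    return IBSResult(np.stack(z_all), grid.freqs_hz, ids, groups,
                     pd.DataFrame(covs, index=ids), SEGMENTS, fs)


# ---------------------------------------------------------------------------
# band selection

@dataclass
class BandSelection:
    freqs_hz: np.ndarray
    t: np.ndarray           # (n_ch_m, n_ch_f, n_freq) task-vs-rest paired t
    p: np.ndarray
    fdr_mask: np.ndarray
    band_hz: Optional[tuple]     # (low, high) rounded to 2 decimals, or None
    band_freq_indices: np.ndarray  # indices into freqs_hz inside the band
    n_pairs: int

    @property
    def is_empty(self) -> bool:
        return self.band_hz is None


def select_band(ibs: IBSResult, q: float | None = None,
                config: AnalysisConfig | None = None) -> BandSelection:
    """Task-vs-rest scan: for every channel pair and frequency, a paired
    t over dyads of z(task) - z(rest); BH-FDR across all tests; the
    selected band is the contiguous run of frequencies containing at
    least one significant pair (the run with the most significant tests
    when several exist), reported as (low, high) rounded to 2 decimals."""
    if ibs.n_dyads < 2:
        raise ValueError("band selection needs at least 2 dyads")
    q = q if q is not None else (config.band_fdr_q if config else 0.005)
    it, ir = ibs.seg_index("task"), ibs.seg_index("rest")
    diff = ibs.z[:, :, :, it, :] - ibs.z[:, :, :, ir, :]  # (n_d, m, f, n_fr)
    finite = np.all(np.isfinite(diff), axis=0)
    n = ibs.n_dyads
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * spstats.t.sf(np.abs(t), n - 1)
    t[~finite] = np.nan
    p[~finite] = np.nan
    mask, _ = fdr_bh(p, q)
    freq_any = mask.any(axis=(0, 1))      # per frequency: >=1 significant pair
    band, idx = _best_run(ibs.freqs_hz, freq_any, mask.sum(axis=(0, 1)))
    n_pairs = ibs.z.shape[1] * ibs.z.shape[2]
    return BandSelection(ibs.freqs_hz, t, p, mask, band, idx, n_pairs)


def _best_run(freqs, freq_any, weights):
    """Contiguous runs of True in freq_any; pick the run with the most
    significant tests.  Returns ((low, high) rounded, indices) or
    (None, empty)."""
    if not freq_any.any():
        return None, np.array([], dtype=int)
    runs = []
    start = None
    for i, flag in enumerate(freq_any):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(freq_any) - 1))
    best = max(runs, key=lambda r: weights[r[0]: r[1] + 1].sum())
    idx = np.arange(best[0], best[1] + 1)
    lohi = (float(round(freqs[idx].min(), 2)), float(round(freqs[idx].max(), 2)))
    return lohi, idx


def band_average(ibs: IBSResult, band: BandSelection | tuple) -> np.ndarray:
    """Mean z over the selected band's frequencies:
    (n_dyads, n_ch_m, n_ch_f, n_seg)."""
    if isinstance(band, BandSelection):
        if band.is_empty:
            raise ValueError("empty frequency band: nothing to average "
                             "(run select_band on a cohort with task-related IBS)")
        idx = band.band_freq_indices
    else:
        lo, hi = band
        idx = np.nonzero((ibs.freqs_hz >= lo - 1e-9) & (ibs.freqs_hz <= hi + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"no scan frequencies inside band {band}")
    return ibs.z[..., idx].mean(axis=-1)


# ---------------------------------------------------------------------------
# group x block interaction scan

def _ancova_interaction(y1, y2, grp_sign, covs):
    """Fast mixed-ANCOVA effects from per-unit block values.
    Returns dict effect -> (F, p)."""
    diff = y2 - y1
    mean = (y1 + y2) / 2.0
    x = np.column_stack([np.ones(len(diff)), grp_sign, covs])
    _check_collinearity(x)
    out = {}
    f, _, _, p, eta = _ols_effect_f(mean, x, 1)
    out["group"] = (f, p, eta)
    f, _, _, p, eta = _ols_effect_f(diff, x, 0)
    out["block"] = (f, p, eta)
    f, _, _, p, eta = _ols_effect_f(diff, x, 1)
    out["interaction"] = (f, p, eta)
    return out


@dataclass
class InteractionScan:
    F: np.ndarray                 # (n_ch_m, n_ch_f) interaction F
    p: np.ndarray
    fdr_mask: np.ndarray
    survivors: list               # [(ch_m, ch_f)] 1-based, FDR-corrected
    precorrection_hits: list      # [(ch_m, ch_f)] p < alpha before FDR
    simple_effects: dict = field(default_factory=dict)  # pair -> DataFrame
    band_hz: Optional[tuple] = None


def _cohort_design(ibs: IBSResult, covariates):
    grp = np.array([1.0 if g == "couple" else -1.0 for g in ibs.groups])
    if covariates:
        covs = ibs.covariates[list(covariates)].to_numpy(float)
        covs = covs - covs.mean(axis=0, keepdims=True)
    else:
        covs = np.empty((ibs.n_dyads, 0))
    return grp, covs


def interaction_scan(ibs: IBSResult, band: BandSelection | tuple,
                     covariates=("age_m", "age_f"),
                     config: AnalysisConfig | None = None) -> InteractionScan:
    """Group x block mixed ANCOVA of band-averaged z at every channel
    pair, BH-FDR corrected across pairs; also reports the pre-correction
    hit list (p < alpha) used for classification features, and simple
    effects for the FDR survivors."""
    cfg = config or AnalysisConfig()
    bz = band_average(ibs, band)                    # (n_d, m, f, n_seg)
    i1, i2 = ibs.seg_index("block1"), ibs.seg_index("block2")
    grp, covs = _cohort_design(ibs, covariates)
    n_m, n_f = bz.shape[1], bz.shape[2]
    F = np.full((n_m, n_f), np.nan)
    p = np.full((n_m, n_f), np.nan)
    for i in range(n_m):
        for j in range(n_f):
            y1, y2 = bz[:, i, j, i1], bz[:, i, j, i2]
            if not (np.all(np.isfinite(y1)) and np.all(np.isfinite(y2))):
                continue
            eff = _ancova_interaction(y1, y2, grp, covs)
            F[i, j], p[i, j] = eff["interaction"][0], eff["interaction"][1]
    mask, _ = fdr_bh(p, cfg.interaction_fdr_q)
    survivors = [(int(i) + 1, int(j) + 1) for i, j in zip(*np.nonzero(mask))]
    hits = [(int(i) + 1, int(j) + 1)
            for i, j in zip(*np.nonzero(np.nan_to_num(p, nan=1.0)
                                        < cfg.precorrection_alpha))]
    simple = {}
    for (ci, cj) in survivors:
        rows = []
        for d in range(ibs.n_dyads):
            for blk, seg in ((1, i1), (2, i2)):
                rows.append((ibs.dyad_ids[d], ibs.groups[d], blk,
                             bz[d, ci - 1, cj - 1, seg]))
        tbl = pd.DataFrame(rows, columns=["unit", "group", "block", "z"])
        simple[(ci, cj)] = simple_effects(tbl, "z", "group", "block")
    band_hz = band.band_hz if isinstance(band, BandSelection) else tuple(band)
    return InteractionScan(F, p, mask, survivors, hits, simple, band_hz)


# ---------------------------------------------------------------------------
# band-restricted fast path (permutation and lag machinery)

class _BandEngine:
    """Caches per-member CWT/auto-spectra at one channel each and
    produces band-averaged z per block for arbitrary member pairings and
    sample shifts of the male series."""

    def __init__(self, sessions, hbo_pairs, target_pair, band_hz,
                 config: AnalysisConfig):
        self.fs = config.downsample_hz
        lo, hi = band_hz
        margin = 2 ** (4 * 1.0 / config.scales_per_octave)
        self.grid = MorletGrid(self.fs, (lo / margin, min(hi * margin, self.fs / 2)),
                               config.scales_per_octave, config.omega0)
        self.band_idx = np.nonzero((self.grid.freqs_hz >= lo - 1e-9)
                                   & (self.grid.freqs_hz <= hi + 1e-9))[0]
        if self.band_idx.size == 0:
            raise ValueError(f"no scan frequencies inside band {band_hz}")
        self.ch_m, self.ch_f = target_pair
        self.sessions = sessions
        # recordings differ by a few samples (random cue durations); member
        # recombination needs a common time axis, so truncate to the minimum
        # length (this only ever clips the tail of the final rest period)
        self.n_t = min(hm.hbo.shape[1] for (hm, _) in hbo_pairs)
        self.kernel = SmoothingKernel(self.grid, self.n_t)
        self.inv_s = 1.0 / self.grid.scales_s[:, None]
        self.wm, self.am, self.wf, self.af = [], [], [], []
        coi = None
        for (hm, hf) in hbo_pairs:
            w, coi = cwt_morlet(hm.hbo[self.ch_m - 1][: self.n_t], self.grid)
            self.wm.append(w)
            self.am.append(self.kernel.smooth(np.abs(w) ** 2 * self.inv_s))
            w, _ = cwt_morlet(hf.hbo[self.ch_f - 1][: self.n_t], self.grid)
            self.wf.append(w)
            self.af.append(self.kernel.smooth(np.abs(w) ** 2 * self.inv_s))
        self.valid_scale = self.grid.scales_s[:, None] <= coi[None, :]
        self.fisher_on_magnitude = config.fisher_on_magnitude

    def block_masks(self, sess_idx, lo_cut=0, hi_cut=None):
        tl = self.sessions[sess_idx].timeline
        masks = []
        for b in (1, 2):
            m = tl.sample_mask(self.fs, self.n_t, "block", b)
            m = m.copy()
            m[:lo_cut] = False
            if hi_cut is not None:
                m[hi_cut:] = False
            masks.append(m)
        return masks

    def pair_block_z(self, i_male, j_female, sess_for_timeline=None,
                     shift_samples=0):
        """Band-mean z for blocks 1 and 2, pairing male member of dyad
        ``i_male`` with female member of dyad ``j_female``.  A nonzero
        ``shift_samples`` advances the male series by that many samples
        (positive = male activity earlier, i.e. male leads)."""
        sess_idx = sess_for_timeline if sess_for_timeline is not None else j_female
        k = int(shift_samples)
        if k == 0:
            wm, am = self.wm[i_male], self.am[i_male]
            wf, af = self.wf[j_female], self.af[j_female]
            lo_cut, hi_cut = 0, None
        else:
            # shift the male transform along time; truncate the overlap
            wm = np.roll(self.wm[i_male], -k, axis=1)
            am = np.roll(self.am[i_male], -k, axis=1)
            wf, af = self.wf[j_female], self.af[j_female]
            lo_cut = max(0, -k)
            hi_cut = self.n_t - max(0, k)
        sxy = self.kernel.smooth(wm * np.conj(wf) * self.inv_s)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.abs(sxy) ** 2 / (am * af)
        r2 = np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)
        out = []
        for mask in self.block_masks(sess_idx, lo_cut, hi_cut):
            v = self.valid_scale & mask[None, :]
            counts = v.sum(axis=1)
            sums = np.where(v, r2, 0.0).sum(axis=1)
            meanr2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            zb = fisher_z(np.nan_to_num(meanr2[self.band_idx]),
                          on_magnitude=self.fisher_on_magnitude)
            out.append(float(np.mean(zb)))
        return out[0], out[1]


@dataclass
class PermutationResult:
    observed_F: float
    null_F: np.ndarray
    p: float
    n_iter: int
    target_pair: tuple


def dyad_permutation_test(sessions, hbo_pairs, target_pair, band_hz,
                          config: AnalysisConfig, seed: int,
                          n_iter: int | None = None, *,
                          mode: str = "within_group",
                          covariates=()) -> PermutationResult:
    """Dyad-recombination null for the group x block interaction at one
    channel pair.

    Each iteration re-pairs male and female members at random (within
    group by default; ``mode='couples_only'`` recombines only the couple
    stratum) and recomputes the band IBS and interaction F.  The p-value
    uses the add-one convention (1 + #{null >= observed}) / (n_iter + 1).
    Re-pairing preserves group sizes and the one-male-one-female
    composition by construction.
    """
    import warnings
    n_iter = n_iter if n_iter is not None else config.perm_iterations
    if n_iter < 100:
        warnings.warn("permutation with fewer than 100 iterations is unstable")
    eng = _BandEngine(sessions, hbo_pairs, target_pair, band_hz, config)
    groups = np.array([s.group for s in sessions])
    idx_by_group = {g: np.nonzero(groups == g)[0] for g in ("couple", "control")}
    grp_sign = np.where(groups == "couple", 1.0, -1.0)
    if covariates:
        age_m = np.array([s.covariates.get(covariates[0], np.nan) for s in sessions])
        age_f = np.array([s.covariates.get(covariates[1], np.nan) for s in sessions])
    # cache: z per (male dyad, female dyad) combination, same group only
    cache: dict[tuple, tuple] = {}

    def combo_z(i, j):
        if (i, j) not in cache:
            cache[(i, j)] = eng.pair_block_z(i, j)
        return cache[(i, j)]

    def interaction_f(female_of):
        y1 = np.empty(len(sessions))
        y2 = np.empty(len(sessions))
        for d in range(len(sessions)):
            y1[d], y2[d] = combo_z(d, female_of[d])
        if covariates:
            covs = np.column_stack([age_m, age_f[female_of]])
            covs = covs - covs.mean(axis=0, keepdims=True)
        else:
            covs = np.empty((len(sessions), 0))
        return _ancova_interaction(y1, y2, grp_sign, covs)["interaction"][0]

    identity = np.arange(len(sessions))
    observed = interaction_f(identity)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null = np.empty(n_iter)
    for it in range(n_iter):
        female_of = identity.copy()
        for g, members in idx_by_group.items():
            if mode == "couples_only" and g != "couple":
                continue
            female_of[members] = rng.permutation(members)
        null[it] = interaction_f(female_of)
    p = (1 + int(np.sum(null >= observed))) / (n_iter + 1)
    return PermutationResult(float(observed), null, float(p), n_iter,
                             tuple(target_pair))


def timelag_scan(sessions, hbo_pairs, target_pair, band_hz,
                 config: AnalysisConfig, lags_s=None,
                 covariates=()) -> pd.DataFrame:
    """Interaction F as a function of a time shift applied to the male
    series.  Positive lag = male series advanced (male activity leads);
    negative lag = male series delayed.  The non-overlapping ends are
    truncated for both members.  Returns a DataFrame (lag_s, F, p)."""
    lags_s = tuple(lags_s) if lags_s is not None else config.lags_s
    n_t = min(hm.hbo.shape[1] for (hm, _) in hbo_pairs)
    max_shift = max(abs(l) for l in lags_s) * config.downsample_hz
    if max_shift > n_t / 10:
        raise ValueError("lag exceeds a tenth of the recording length")
    eng = _BandEngine(sessions, hbo_pairs, target_pair, band_hz, config)
    groups = np.array([s.group for s in sessions])
    grp_sign = np.where(groups == "couple", 1.0, -1.0)
    if covariates:
        covs = np.column_stack(
            [[s.covariates.get(c, np.nan) for s in sessions] for c in covariates])
        covs = covs - covs.mean(axis=0, keepdims=True)
    else:
        covs = np.empty((len(sessions), 0))
    rows = []
    for lag in lags_s:
        k = int(round(lag * config.downsample_hz))
        y1 = np.empty(len(sessions))
        y2 = np.empty(len(sessions))
        for d in range(len(sessions)):
            y1[d], y2[d] = eng.pair_block_z(d, d, shift_samples=k)
        eff = _ancova_interaction(y1, y2, grp_sign, covs)["interaction"]
        rows.append((float(lag), eff[0], eff[1],
                     float(y1.mean()), float(y2.mean())))
    return pd.DataFrame(rows, columns=["lag_s", "F", "p",
                                       "mean_z_block1", "mean_z_block2"])
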