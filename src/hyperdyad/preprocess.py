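"""Preprocessing chain: raw dual-wavelength intensity to analysis-ready
1 Hz HbO with channel and subject quality control.

Order of operations: channel CV screening on raw intensity, optical
density conversion, discrete-wavelet motion correction, PCA removal of
the global (systemic) component, anti-aliased downsampling to the
analysis rate, and finally the modified Beer-Lambert inversion to HbO /
HbR concentrations.  The PCA filter runs on optical density, before the
Beer-Lambert step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .config import AnalysisConfig
from .session import DyadSession, ValidationError
from .simulate import EXTINCTION

__all__ = [
    "QCReport",
    "HbOSeries",
    "channel_cv",
    "apply_channel_qc",
    "intensity_to_od",
    "wavelet_motion_correct",
    "pca_global_filter",
    "downsample",
    "beer_lambert",
    "preprocess_recording",
    "preprocess_session",
    "preprocess_cohort",
]


@dataclass
class QCReport:
    """Per-channel coefficient of variation and the resulting channel /
    participant exclusion decisions for the two members of a dyad."""

    cv_pct: dict            # participant_id -> (n_ch,) max-over-wavelength CV %
    bad_channels: dict      # participant_id -> boolean mask (n_ch,)
    bad_fraction: dict      # participant_id -> float
    excluded: dict          # participant_id -> bool

    def dyad_excluded(self) -> bool:
        return any(self.excluded.values())


@dataclass
class HbOSeries:
    """Preprocessed hemoglobin series at the analysis rate."""

    hbo: np.ndarray            # (n_ch, n_t) uM
    hbr: np.ndarray
    fs_hz: float
    bad_channel_mask: np.ndarray  # True where the channel failed QC

    def validate(self) -> None:
        good = ~self.bad_channel_mask
        if not np.all(np.isfinite(self.hbo[good])):
            raise ValidationError("non-finite HbO values on good channels")


# ---------------------------------------------------------------------------
# channel QC

def channel_cv(intensity: np.ndarray) -> np.ndarray:
    """Coefficient of variation (percent) per channel and wavelength:
    100 * sd / mean over time.  Zero-mean channels get +inf (always bad)."""
    mean = intensity.mean(axis=-1)
    sd = intensity.std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    cv[~np.isfinite(cv)] = np.inf
    return cv


def apply_channel_qc(session: DyadSession, cv_threshold_pct: float = 7.5,
                     subject_frac: float = 0.30) -> QCReport:
    """Flag channels with CV strictly above the threshold at either
    wavelength; a participant is excluded iff the bad-channel fraction
    strictly exceeds ``subject_frac``.  A dyad is dropped downstream if
    either member is excluded."""
    if not (0 < cv_threshold_pct < 100):
        raise ValidationError("cv_threshold_pct must lie in (0, 100)")
    if not (0 < subject_frac < 1):
        raise ValidationError("subject_frac must lie in (0, 1)")
    cvs, bads, fracs, excl = {}, {}, {}, {}
    for rec in (session.member_m, session.member_f):
        if rec.intensity is not None:
            cv = channel_cv(rec.intensity)      # (n_ch, 2)
            ch_cv = cv.max(axis=1)
        else:  # direct-HbO recordings carry no optical CV; all channels pass
            ch_cv = np.zeros(rec.n_channels)
        bad = ch_cv > cv_threshold_pct
        frac = float(bad.mean()) if len(bad) else 0.0
        cvs[rec.participant_id] = ch_cv
        bads[rec.participant_id] = bad
        fracs[rec.participant_id] = frac
        excl[rec.participant_id] = frac > subject_frac
    return QCReport(cvs, bads, fracs, excl)


# ---------------------------------------------------------------------------
# optical density

def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical density relative to the channel's mean intensity:
    od(t) = -ln(I(t) / mean_t I).  Requires strictly positive input."""
    if np.any(intensity <= 0):
        ch, *_ = np.nonzero((intensity <= 0).any(axis=-1))
        raise ValidationError(f"non-positive intensity on channel index {ch[:5]}")
    mean = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / mean)


# ---------------------------------------------------------------------------
# motion correction

def wavelet_motion_correct(od: np.ndarray, alpha_iqr: float = 1.5, *,
                           wavelet: str = "db5", levels: int = 4) -> np.ndarray:
    """Discrete-wavelet motion-artifact removal.

    The series is decomposed to ``levels`` detail levels; within each
    level, coefficients lying outside median +/- alpha_iqr * IQR are set
    to zero, and the series is reconstructed at its original length.
    Applied along the last axis.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim == 1:
        return _wmc_1d(od, alpha_iqr, wavelet, levels)
    out = np.empty_like(od)
    for idx in np.ndindex(od.shape[:-1]):
        out[idx] = _wmc_1d(od[idx], alpha_iqr, wavelet, levels)
    return out


def _wmc_1d(x, alpha_iqr, wavelet, levels):
    n = len(x)
    w = pywt.Wavelet(wavelet)
    levels = min(levels, pywt.dwt_max_level(n, w.dec_len))
    if levels < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    guard = w.dec_len       # boundary coefficients reflect the signal
    cleaned = [coeffs[0]]   # extension, not motion; never zero them
    for d in coeffs[1:]:
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        fence = alpha_iqr * (q3 - q1)
        keep = np.abs(d - med) <= fence
        keep[:guard] = True
        keep[-guard:] = True
        cleaned.append(np.where(keep, d, 0.0))
    rec = pywt.waverec(cleaned, wavelet, mode="symmetric")
    return rec[:n]


# ---------------------------------------------------------------------------
# PCA global filtering

def pca_global_filter(od: np.ndarray, covariance_removed: float = 0.80):
    """Remove the global (spatially coherent) component from a
    channels x time matrix.

    The time-demeaned matrix is decomposed by SVD; the smallest leading
    set of components whose cumulative explained variance reaches
    ``covariance_removed`` is subtracted.  Returns the filtered matrix
    and the number of components removed.
    """
    if not (0 < covariance_removed < 1):
        raise ValidationError("covariance_removed must lie in (0, 1)")
    od = np.asarray(od, dtype=float)
    if od.shape[0] < 2:
        raise ValidationError("PCA filtering needs at least 2 channels")
    mean = od.mean(axis=1, keepdims=True)
    x = od - mean
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return od.copy(), 0
    cum = np.cumsum(var) / total
    k = int(np.searchsorted(cum, covariance_removed - 1e-12) + 1)
    k = min(k, len(s))
    removed = (u[:, :k] * s[:k]) @ vt[:k]
    return od - removed, k


# ---------------------------------------------------------------------------
# downsampling

def downsample(series: np.ndarray, from_hz: float, to_hz: float) -> np.ndarray:
    """Anti-aliased downsampling along the last axis: zero-phase
    Butterworth low-pass at 0.45 * to_hz, then interpolation onto the
    uniform target grid of length round(n * to_hz / from_hz)."""
    if to_hz >= from_hz:
        raise ValidationError("to_hz must be below from_hz")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    sos = sps.butter(8, 0.45 * to_hz, btype="lowpass", fs=from_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, series, axis=-1)
    n_out = int(round(n * to_hz / from_hz))
    t_out = np.arange(n_out) / to_hz
    t_in = np.arange(n) / from_hz
    if series.ndim == 1:
        return np.interp(t_out, t_in, filtered)
    out = np.empty(series.shape[:-1] + (n_out,))
    for idx in np.ndindex(series.shape[:-1]):
        out[idx] = np.interp(t_out, t_in, filtered[idx])
    return out


# ---------------------------------------------------------------------------
# Beer-Lambert inversion

def beer_lambert(od_760: np.ndarray, od_830: np.ndarray, distance_cm: float = 3.0,
                 dpf: tuple[float, float] = (6.0, 6.0),
                 extinction: dict | None = None):
    """Invert the modified Beer-Lambert relation per channel and sample:
    solve the 2x2 system OD_l = (e_HbO,l * HbO + e_HbR,l * HbR) * 1e-6
    * d * DPF_l for (HbO, HbR) in micromolar."""
    ext = extinction or EXTINCTION
    wls = sorted(ext)
    a = np.array([[ext[wls[0]][0], ext[wls[0]][1]],
                  [ext[wls[1]][0], ext[wls[1]][1]]]) * 1e-6
    a = a * (distance_cm * np.asarray(dpf)[:, None])
    if abs(np.linalg.det(a)) < 1e-18:
        raise ValidationError("extinction/DPF matrix is singular")
    inv = np.linalg.inv(a)
    od = np.stack([od_760, od_830], axis=-2)  # (..., 2, n_t)
    hb = np.einsum("ij,...jt->...it", inv, od)
    return hb[..., 0, :], hb[..., 1, :]


# ---------------------------------------------------------------------------
# full chain

def preprocess_recording(rec, config: AnalysisConfig) -> HbOSeries:
    """Run the full chain on one participant's recording.  Recordings
    that already carry HbO (fast simulation path) are passed through,
    resampled if needed."""
    bad = np.zeros(rec.n_channels, dtype=bool)
    if rec.intensity is None:
        # direct-HbO recordings skip the optical steps but still get motion
        # correction, global-component removal and (if needed) resampling
        hbo = wavelet_motion_correct(rec.hbo, config.wavelet_iqr_fence,
                                     wavelet=config.wavelet,
                                     levels=config.wavelet_levels)
        hbr = rec.hbr if rec.hbr is not None else np.zeros_like(rec.hbo)
        if hbo.shape[0] >= 2:
            hbo, _ = pca_global_filter(hbo, config.pca_covariance_removed)
        if rec.fs_hz > config.downsample_hz:
            hbo = downsample(hbo, rec.fs_hz, config.downsample_hz)
            hbr = downsample(hbr, rec.fs_hz, config.downsample_hz)
        return HbOSeries(hbo, hbr, config.downsample_hz, bad)
    od = intensity_to_od(rec.intensity)  # (n_ch, 2, n_t)
    od = wavelet_motion_correct(od, config.wavelet_iqr_fence,
                                wavelet=config.wavelet, levels=config.wavelet_levels)
    for w in range(2):
        od[:, w, :], _ = pca_global_filter(od[:, w, :], config.pca_covariance_removed)
    od = downsample(od, rec.fs_hz, config.downsample_hz)
    hbo, hbr = beer_lambert(od[:, 0, :], od[:, 1, :],
                            rec.source_detector_distance_cm, config.dpf)
    return HbOSeries(hbo, hbr, config.downsample_hz, bad)


def preprocess_session(session: DyadSession, config: AnalysisConfig):
    """QC + full chain for both members.  Returns (HbOSeries male,
    HbOSeries female, QCReport); the QC bad-channel masks are attached to
    the outputs.  Callers drop the dyad when ``report.dyad_excluded()``."""
    report = apply_channel_qc(session, config.cv_threshold_pct,
                              config.bad_channel_subject_frac)
    out = []
    for rec in (session.member_m, session.member_f):
        series = preprocess_recording(rec, config)
        series.bad_channel_mask = report.bad_channels[rec.participant_id].copy()
        out.append(series)
    return out[0], out[1], report


def preprocess_cohort(sessions, config: AnalysisConfig):
    """Preprocess every session; dyads with an excluded member are
    dropped.  Returns (kept_sessions, hbo_pairs, reports)."""
    kept, pairs, reports = [], [], []
    for s in sessions:
        hm, hf, rep = preprocess_session(s, config)
        reports.append(rep)
        if rep.dyad_excluded():
            continue
        kept.append(s)
        pairs.append((hm, hf))
    return kept, pairs, reports
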