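"""Analysis configuration: one dataclass holding every tunable parameter,
with the study's published defaults, plus a YAML loader.

The config file is a YAML mapping with optional sections (``preprocess``,
``ibs``, ``gca``, ``classify``, ``general``); keys may also be given flat
at top level.  Unknown keys and out-of-range values raise ``ConfigError``
naming the offending key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


def _default_lags() -> tuple[int, ...]:
    # signed lags in seconds, 2..10 step 2 both directions; 0 is the main
    # (unshifted) analysis and is not part of the lag scan
    return tuple(range(-10, 0, 2)) + tuple(range(2, 12, 2))


def _default_ks() -> tuple[int, ...]:
    return tuple(range(1, 32, 2))


@dataclass
class AnalysisConfig:
    # --- channel / subject quality control ---
    cv_threshold_pct: float = 7.5          # channel bad if CV > 7.5 %
    bad_channel_subject_frac: float = 0.30  # subject fails if > 30 % bad

    # --- preprocessing ---
    pca_covariance_removed: float = 0.80
    downsample_hz: float = 1.0
    wavelet: str = "db5"                   # motion-correction wavelet family
    wavelet_levels: int = 4
    wavelet_iqr_fence: float = 1.5
    dpf: tuple[float, float] = (6.0, 6.0)  # differential pathlength, per wavelength

    # --- inter-brain synchrony ---
    band_search_hz: tuple[float, float] = (0.01, 0.5)
    band_fdr_q: float = 0.005
    interaction_fdr_q: float = 0.05
    precorrection_alpha: float = 0.005     # "significant before FDR" hit rule
    perm_iterations: int = 1000
    lags_s: tuple[int, ...] = field(default_factory=_default_lags)
    omega0: float = 6.0                    # Morlet centre frequency
    scales_per_octave: int = 12
    fisher_on_magnitude: bool = True       # z = arctanh(sqrt(R2)); False: arctanh(R2)

    # --- directional coupling ---
    gc_max_order: int = 8

    # --- classification ---
    knn_ks: tuple[int, ...] = field(default_factory=_default_ks)
    knn_null_iterations: int = 10000

    # --- general ---
    rng_seed: int = 0

    def validate(self) -> None:
        def _range(name, lo, hi, open_lo=False, open_hi=False):
            v = getattr(self, name)
            ok = (v > lo if open_lo else v >= lo) and (v < hi if open_hi else v <= hi)
            if not ok:
                raise ConfigError(f"{name}={v!r} out of range")

        _range("cv_threshold_pct", 0, 100, open_lo=True)
        _range("bad_channel_subject_frac", 0, 1, open_lo=True, open_hi=True)
        _range("pca_covariance_removed", 0, 1, open_lo=True, open_hi=True)
        _range("downsample_hz", 0, 100, open_lo=True)
        _range("band_fdr_q", 0, 1, open_lo=True, open_hi=True)
        _range("interaction_fdr_q", 0, 1, open_lo=True, open_hi=True)
        _range("precorrection_alpha", 0, 1, open_lo=True, open_hi=True)
        if self.perm_iterations < 1:
            raise ConfigError(f"perm_iterations={self.perm_iterations} must be >= 1")
        if self.knn_null_iterations < 1:
            raise ConfigError("knn_null_iterations must be >= 1")
        if self.gc_max_order < 1:
            raise ConfigError("gc_max_order must be >= 1")
        if self.wavelet_levels < 1:
            raise ConfigError("wavelet_levels must be >= 1")
        if self.wavelet_iqr_fence <= 0:
            raise ConfigError("wavelet_iqr_fence must be positive")
        lo, hi = self.band_search_hz
        if not (0 < lo < hi):
            raise ConfigError(f"band_search_hz={self.band_search_hz} invalid")
        if hi > self.downsample_hz / 2 + 1e-12:
            raise ConfigError("band_search_hz upper edge exceeds the analysis Nyquist")
        if any(l == 0 for l in self.lags_s):
            raise ConfigError("lags_s must exclude 0 (0 is the main analysis)")
        if any(k < 1 or k % 2 == 0 for k in self.knn_ks):
            raise ConfigError("knn_ks must be odd and >= 1")


_SECTIONS = ("general", "preprocess", "ibs", "gca", "classify", "behavior")
_TUPLE_KEYS = {"band_search_hz", "lags_s", "knn_ks", "dpf"}
_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig`; unspecified keys keep the published
    defaults.  ``path=None`` or an empty file yields the default config."""
    flat: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        for key, val in raw.items():
            if key in _SECTIONS and isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
    unknown = set(flat) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in _TUPLE_KEYS & set(flat):
        flat[key] = tuple(flat[key])
    cfg = AnalysisConfig(**flat)
    cfg.validate()
    return cfg
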