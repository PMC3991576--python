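"""The twelve short-term HRV measures.

Time domain: SDNN, RMSSD, pNN50, CVrr.  Frequency domain: VLF, LF, HF, VHF
and TP band powers of the RR tachogram plus the LF/HF ratio, computed from an
FFT periodogram of the evenly resampled tachogram.  Nonlinear: approximate
entropy (ApEn) and sample entropy (SampEn).

Frequency bands follow the short-term HRV convention: VLF 0–0.04 Hz,
LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, VHF 0.4–1.0 Hz, TP 0–0.4 Hz.  Band powers
are reported on a compressed log scale, ``ln(1 + power in ms^2)``, by
default; set ``SpectralConfig.log_scale=False`` for raw ms^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, interpolate, signal

from .rr_io import RRSeries

__all__ = [
    "SpectralConfig",
    "EntropyConfig",
    "HRVFeatures",
    "TimeDomain",
    "BandPowers",
    "FeatureError",
    "FEATURE_NAMES",
    "time_domain",
    "power_spectrum",
    "band_powers",
    "apen",
    "sampen",
    "featurize",
]

#: canonical ordering of the 12 measures in tables and CSV output
FEATURE_NAMES = (
    "sdnn", "rmssd", "pnn50", "cvrr",
    "vlf", "lf", "hf", "vhf", "tp", "lf_hf",
    "apen", "sampen",
)

BANDS = {
    "vlf": (0.0, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
    "vhf": (0.40, 1.00),
    "tp": (0.0, 0.40),
}


class FeatureError(ValueError):
    """A feature stage failed; the message names the stage."""


@dataclass(frozen=True)
class SpectralConfig:
    """Settings for the tachogram power spectrum.

    resample_hz : evenly spaced resampling rate of the tachogram (Hz).
        Must be at least 2 Hz so the Nyquist frequency covers the 1.0 Hz
        upper edge of the VHF band.
    detrend : 'linear' or 'none', applied to the resampled signal.
    window : FFT taper name accepted by :func:`scipy.signal.get_window`.
    segment_s : Welch segment length in seconds; ``None`` uses a single
        full-length periodogram.
    log_scale : report band powers as ``ln(1 + ms^2)`` when True.
    """

    resample_hz: float = 4.0
    detrend: str = "linear"
    window: str = "hann"
    segment_s: float | None = None
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.resample_hz < 2.0:
            raise ValueError("resample_hz must be >= 2 Hz (Nyquist must reach 1.0 Hz)")
        if self.detrend not in ("linear", "none"):
            raise ValueError("detrend must be 'linear' or 'none'")


@dataclass(frozen=True)
class EntropyConfig:
    """Settings for ApEn/SampEn: embedding dimension ``m``, delay ``tau``
    (in beats) and the tolerance ``r = r_coeff * SD`` of the series."""

    m: int = 2
    tau: int = 1
    r_coeff: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")
        if self.r_coeff <= 0:
            raise ValueError("r_coeff must be positive")


class TimeDomain(NamedTuple):
    sdnn: float
    rmssd: float
    pnn50: float
    cvrr: float


class BandPowers(NamedTuple):
    vlf: float
    lf: float
    hf: float
    vhf: float
    tp: float
    lf_hf: float


@dataclass(frozen=True)
class HRVFeatures:
    """The 12 HRV measures of one short (nominally 5-min) segment."""

    sdnn: float
    rmssd: float
    pnn50: float
    cvrr: float
    vlf: float
    lf: float
    hf: float
    vhf: float
    tp: float
    lf_hf: float
    apen: float
    sampen: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def time_domain(rr: RRSeries) -> TimeDomain:
    """SDNN, RMSSD, pNN50 and CVrr of an interval series.

    SDNN is the sample standard deviation (n-1 denominator) in ms, RMSSD the
    root mean square of successive differences in ms, pNN50 the percentage of
    successive differences strictly greater than 50 ms, and CVrr the
    coefficient of variation ``100 * SDNN / mean`` (dimensionless, percent
    scale).
    """
    x = rr.intervals
    if x.size < 2:
        raise ValueError("time-domain measures need at least 2 intervals")
    sdnn = float(np.std(x, ddof=1))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(d) > 50.0) / d.size)
    cvrr = float(100.0 * sdnn / np.mean(x))
    return TimeDomain(sdnn, rmssd, pnn50, cvrr)


def power_spectrum(rr: RRSeries, cfg: SpectralConfig = SpectralConfig()):
    """Periodogram of the RR tachogram.

    The tachogram (interval value against cumulative beat time) is resampled
    at ``cfg.resample_hz`` by cubic interpolation, detrended and tapered, and
    the one-sided FFT periodogram is rescaled so that its trapezoidal
    integral over [0, Nyquist] equals the variance of the detrended resampled
    signal (Parseval contract).

    Returns ``(f, psd)`` with ``psd`` in ms^2/Hz.
    """
    if rr.duration_s < 60.0:
        raise ValueError(
            f"spectral analysis needs at least 60 s of data, got {rr.duration_s:.1f} s"
        )
    t = rr.end_times_s()
    if t.size < 4:
        raise ValueError("spectral analysis needs at least 4 beats")
    fs = cfg.resample_hz
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = interpolate.CubicSpline(t, rr.intervals)(grid)
    if cfg.detrend == "linear":
        x = signal.detrend(x, type="linear")
    else:
        x = x - np.mean(x)
    if cfg.segment_s is None:
        f, psd = signal.periodogram(x, fs=fs, window=cfg.window, detrend=False)
    else:
        f, psd = signal.welch(
            x, fs=fs, window=cfg.window, nperseg=int(cfg.segment_s * fs), detrend=False
        )
    var = float(np.var(x))
    raw_integral = float(np.trapezoid(psd, f))
    psd = psd * (var / raw_integral) if raw_integral > 0 else np.zeros_like(psd)
    return f, psd


def _band_integral(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal band power with interpolated band edges, so that adjacent
    bands tile the axis exactly (TP = VLF + LF + HF on the raw scale)."""
    cum = np.concatenate(([0.0], integrate.cumulative_trapezoid(psd, f)))
    c_lo, c_hi = np.interp([lo, hi], f, cum)
    return float(c_hi - c_lo)


def band_powers(spectrum, cfg: SpectralConfig = SpectralConfig()) -> BandPowers:
    """Integrate the PSD over the five HRV bands and form the LF/HF ratio.

    With ``cfg.log_scale`` the five powers are reported as ``ln(1 + ms^2)``
    and the ratio is taken between the log-scaled LF and HF.  An HF power of
    zero makes the ratio undefined (NaN).
    """
    f, psd = spectrum
    if f[-1] < 1.0 - 1e-9:
        raise ValueError("spectrum must cover 0-1.0 Hz to resolve the VHF band")
    raw = {name: _band_integral(f, psd, lo, hi) for name, (lo, hi) in BANDS.items()}
    if cfg.log_scale:
        out = {name: math.log1p(v) for name, v in raw.items()}
    else:
        out = raw
    lf_hf = out["lf"] / out["hf"] if out["hf"] > 0 else math.nan
    return BandPowers(out["vlf"], out["lf"], out["hf"], out["vhf"], out["tp"], lf_hf)


def _templates(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _chebyshev_pairwise(T: np.ndarray) -> np.ndarray:
    return np.max(np.abs(T[:, None, :] - T[None, :, :]), axis=2)


def apen(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Approximate entropy (Pincus).

    ``C_i^m(r)`` is the fraction of length-``m`` templates (self-match
    included) within Chebyshev distance ``r = r_coeff * SD`` of template
    ``i``; ``Phi^m`` is the mean of ``ln C_i^m`` and
    ``ApEn = Phi^m - Phi^(m+1)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < cfg.m + 2:
        raise ValueError(f"ApEn needs at least m+2={cfg.m + 2} samples, got {x.size}")
    r = cfg.r_coeff * float(np.std(x))
    if r <= 0:
        raise ValueError("zero-variance input: tolerance r is degenerate")

    def phi(m: int) -> float:
        T = _templates(x, m, cfg.tau)
        c = np.mean(_chebyshev_pairwise(T) <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(cfg.m) - phi(cfg.m + 1)


def sampen(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Sample entropy (Richman-Moorman).

    ``B`` counts length-``m`` template pairs (self-matches excluded) within
    tolerance ``r``, ``A`` the length-``m+1`` pairs over the same template
    index range; ``SampEn = -ln(A / B)``.  Returns NaN when no length-``m+1``
    pair matches (the statistic is undefined/infinite).
    """
    x = np.asarray(x, dtype=float)
    if x.size < cfg.m + 2:
        raise ValueError(f"SampEn needs at least m+2={cfg.m + 2} samples, got {x.size}")
    r = cfg.r_coeff * float(np.std(x))
    if r <= 0:
        raise ValueError("zero-variance input: tolerance r is degenerate")
    n_templ = x.size - cfg.m * cfg.tau
    Tm = _templates(x, cfg.m, cfg.tau)[:n_templ]
    Tm1 = _templates(x, cfg.m + 1, cfg.tau)

    def paircount(T: np.ndarray) -> int:
        d = _chebyshev_pairwise(T)
        iu = np.triu_indices(T.shape[0], k=1)
        return int(np.count_nonzero(d[iu] <= r))

    B = paircount(Tm)
    A = paircount(Tm1)
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B)


def featurize(
    rr: RRSeries,
    spectral_cfg: SpectralConfig = SpectralConfig(),
    entropy_cfg: EntropyConfig = EntropyConfig(),
) -> HRVFeatures:
    """Compute all 12 measures for one segment.

    Deterministic given the input series and configs.  Failures in a stage
    are re-raised as :class:`FeatureError` naming that stage.
    """
    try:
        td = time_domain(rr)
    except ValueError as e:
        raise FeatureError(f"time_domain: {e}") from e
    try:
        bp = band_powers(power_spectrum(rr, spectral_cfg), spectral_cfg)
    except ValueError as e:
        raise FeatureError(f"spectrum: {e}") from e
    try:
        ae = apen(rr.intervals, entropy_cfg)
        se = sampen(rr.intervals, entropy_cfg)
    except ValueError as e:
        raise FeatureError(f"entropy: {e}") from e
    return HRVFeatures(
        sdnn=td.sdnn, rmssd=td.rmssd, pnn50=td.pnn50, cvrr=td.cvrr,
        vlf=bp.vlf, lf=bp.lf, hf=bp.hf, vhf=bp.vhf, tp=bp.tp, lf_hf=bp.lf_hf,
        apen=ae, sampen=se,
    )
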