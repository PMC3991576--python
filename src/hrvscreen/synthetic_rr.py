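"""Seeded synthetic 5-min RR-interval generator for two subject classes.

Each series is a direct modulation of the RR value (not an integral-pulse
model): a mean level plus slow very-low-frequency drift, an LF oscillation, a
second oscillation at a configurable frequency, and white beat-to-beat noise.
The deterministic/stochastic mix is controlled by ``regularity`` and the
whole modulation is rescaled analytically so the expected series SD equals
``sd_target``.

The bundled presets emulate the group statistics of the published reference
cohort rather than textbook physiology.  In particular the CHF-like preset
puts most of its (large) variance into a regular oscillation at 0.45 Hz —
inside the VHF band, mimicking beat-to-beat alternans.  That reproduces the
reference cohort's signature of a very large SDNN with RMSSD > SDNN, small
power in the VLF-HF bands (hence a low SUM_FD), and low entropy, which is
what makes the two classes separable in the (SUM_TD, SUM_FD) plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rr_io import RRSeries, write_rr_file

__all__ = [
    "ClassParams",
    "healthy_params",
    "chf_params",
    "overlapping_params",
    "simulate_rr",
    "simulate_cohort",
]

# VLF drift frequencies (integer cycle counts over 300 s), amplitudes ~ 1/f
_VLF_FREQS = (1.0 / 150.0, 1.0 / 100.0, 1.0 / 60.0)


@dataclass(frozen=True)
class ClassParams:
    """Generator parameters for one subject class.

    mean_rr, sd_target : ms — target mean and SD of the series.
    lf_amp @ lf_freq, hf_amp @ hf_freq : ms, Hz — two sinusoidal modulations
        (nominal amplitudes before rescaling to sd_target).
    one_over_f_amp : ms — total nominal amplitude of the slow VLF drift.
    noise_sd : ms — nominal white-noise SD.
    regularity : in [0, 1]; 0.5 is a neutral mix, larger values weight the
        deterministic modulation over the noise.
    """

    mean_rr: float = 950.0
    sd_target: float = 80.0
    lf_amp: float = 45.0
    lf_freq: float = 0.095
    hf_amp: float = 15.0
    hf_freq: float = 0.275
    one_over_f_amp: float = 80.0
    noise_sd: float = 12.0
    regularity: float = 0.5
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if min(self.lf_amp, self.hf_amp, self.one_over_f_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must lie in [0, 1]")


def healthy_params() -> ClassParams:
    """Healthy preset: mean RR ~950 ms, SDNN ~81 ms spread across the
    VLF/LF/HF bands, noisy enough for entropies above 1."""
    return ClassParams()


def chf_params() -> ClassParams:
    """CHF-like preset mirroring the reference group statistics: SDNN ~298 ms
    dominated by a regular alternans-like 0.45 Hz oscillation (VHF band), so
    VLF-HF band powers and entropy stay low."""
    return ClassParams(
        mean_rr=1050.0,
        sd_target=298.0,
        lf_amp=6.0,
        lf_freq=0.095,
        hf_amp=100.0,
        hf_freq=0.45,
        one_over_f_amp=10.0,
        noise_sd=2.0,
        regularity=0.95,
    )


def overlapping_params() -> ClassParams:
    """A milder CHF-like class whose features overlap the healthy class."""
    return ClassParams(
        mean_rr=1000.0,
        sd_target=120.0,
        lf_amp=30.0,
        lf_freq=0.095,
        hf_amp=40.0,
        hf_freq=0.45,
        one_over_f_amp=60.0,
        noise_sd=10.0,
        regularity=0.7,
    )


def _components(p: ClassParams):
    """(amplitude, frequency) pairs of the deterministic modulation."""
    w = np.array([1.0 / f for f in _VLF_FREQS])
    w = w / math.sqrt(float(np.sum(w**2)))
    comps = [(p.one_over_f_amp * wi, fi) for wi, fi in zip(w, _VLF_FREQS)]
    comps.append((p.lf_amp, p.lf_freq))
    comps.append((p.hf_amp, p.hf_freq))
    return comps


def simulate_rr(params: ClassParams, seed) -> RRSeries:
    """Generate one RR series; deterministic given params and seed."""
    rng = np.random.default_rng(seed)
    comps = _components(params)
    det_gain = math.sqrt(2.0 * params.regularity)
    noise_gain = math.sqrt(2.0 * (1.0 - params.regularity))
    var0 = det_gain**2 * sum(a**2 for a, _ in comps) / 2.0 + (noise_gain * params.noise_sd) ** 2
    scale = params.sd_target / math.sqrt(var0) if var0 > 0 else 0.0
    det_envelope = scale * det_gain * sum(a for a, _ in comps)
    if params.mean_rr - det_envelope <= 0:
        raise ValueError(
            "parameters imply nonpositive RR intervals "
            f"(mean {params.mean_rr} ms, deterministic envelope {det_envelope:.0f} ms)"
        )
    phases = rng.uniform(0.0, 2.0 * math.pi, size=len(comps))
    noise_sd = scale * noise_gain * params.noise_sd
    # Modulators are evaluated on the nominal beat-time grid k*mean_rr (open
    # loop).  Feeding each generated interval back into the clock would
    # phase-lock oscillations near half the beat rate and shrink their
    # realized variance well below sd_target.
    n_max = int(math.ceil(params.duration_s * 1000.0 / params.mean_rr * 2)) + 8
    t_nom = np.arange(n_max) * (params.mean_rr / 1000.0)
    det = sum(
        a * np.sin(2.0 * math.pi * f * t_nom + ph)
        for (a, f), ph in zip(comps, phases)
    )
    rr = params.mean_rr + scale * det_gain * det + noise_sd * rng.standard_normal(n_max)
    rr = np.maximum(rr, 1.0)  # clip pathological noise excursions positive
    n_beats = int(np.searchsorted(np.cumsum(rr) / 1000.0, params.duration_s)) + 1
    return RRSeries(intervals=rr[:n_beats], source_id=f"sim-{seed}")


def simulate_cohort(
    n_chf: int = 17,
    n_healthy: int = 30,
    chf: ClassParams | None = None,
    healthy: ClassParams | None = None,
    seed: int = 0,
    out_dir=None,
    duration_s: float | None = None,
):
    """Generate a labelled two-class cohort of RR series.

    Defaults mirror the reference cohort size (17 CHF, 30 healthy) with the
    separable presets.  Returns ``(records, labels)``; with ``out_dir`` the
    series are also written as RR text files plus a ``manifest.csv``
    (columns record_id, path, label; CHF=1).
    """
    if n_chf < 1 or n_healthy < 1:
        raise ValueError("need at least one record per class")
    chf = chf if chf is not None else chf_params()
    healthy = healthy if healthy is not None else healthy_params()
    if duration_s is not None:
        chf = replace(chf, duration_s=duration_s)
        healthy = replace(healthy, duration_s=duration_s)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_chf + n_healthy)
    records, labels, ids = [], [], []
    for i in range(n_chf + n_healthy):
        is_chf = i < n_chf
        params = chf if is_chf else healthy
        rid = f"chf_{i:03d}" if is_chf else f"healthy_{i - n_chf:03d}"
        rr = simulate_rr(params, children[i])
        rr = RRSeries(rr.intervals, rr.beat_labels, rr.t0_offset, source_id=rid)
        records.append(rr)
        labels.append(1 if is_chf else 0)
        ids.append(rid)
    labels = np.asarray(labels, dtype=int)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for rr, rid in zip(records, ids):
            path = out_dir / f"{rid}.rr.txt"
            write_rr_file(rr, path)
            paths.append(str(path))
        manifest = pd.DataFrame({"record_id": ids, "path": paths, "label": labels})
        with open(out_dir / "manifest.csv", "w") as fh:
            fh.write("# hrvscreen:manifest:v1\n")
            manifest.to_csv(fh, index=False)
    return records, labels
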