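"""Synthetic dynamometer experiments for pipeline testing and calibration.

Emulates the reference study design: a full factorial of uncut chip thickness
(UCT) {0.5, 0.6, 0.7, 0.8} mm × cutting angle {0°, 45°, 90°} with five
replicates, a 10 mm stroke at 100 mm/min ploughing speed sampled at 1 kHz,
plus indentation (force-versus-volume) records.  Forces come from the
calibrated laws — Fz = C·V(h)^α and Fp = f_p(θ)·Fz — with multiplicative
log-normal measurement noise (forces are positive and instrument error scales
with signal) and optional isolated spikes mimicking charge-amplifier glitches.
Every trace embeds its generating ground truth for closed-loop testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnisotropyModel,
    NormalForceModel,
    ToolGeometry,
    empirical_normal_force,
    indentation_volume,
    ploughing_coefficient,
)
from .io import write_manifest_csv, write_trace_csv
from .preprocessing import ForceTrace

__all__ = [
    "ExperimentDesign",
    "NoiseSpec",
    "generate_indentation",
    "generate_plough_trial",
    "generate_experiment",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial ploughing-experiment design.

    Defaults reproduce the reference study: UCT levels in mm, cutting angles
    in degrees, five replicates per cell, 10 mm stroke at 100 mm/min, 1 kHz
    sampling.  ``lead_s`` is the zero-force dwell either side of the stroke
    and ``ramp_s`` the linear engagement ramp.
    """

    uct_levels: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8)
    angles: tuple[float, ...] = (0.0, 45.0, 90.0)
    replicates: int = 5
    stroke_mm: float = 10.0
    speed_mm_min: float = 100.0
    sampling_hz: float = 1000.0
    lead_s: float = 0.5
    ramp_s: float = 0.05

    def __post_init__(self) -> None:
        if not self.uct_levels or not self.angles:
            raise ValueError("uct_levels and angles must be nonempty")
        if any(h <= 0 for h in self.uct_levels):
            raise ValueError("all UCT levels must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("stroke_mm", "speed_mm_min", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def engaged_duration_s(self) -> float:
        """Time the tool spends cutting: stroke / feed speed."""
        return self.stroke_mm / (self.speed_mm_min / 60.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description for the generator.

    ``sd`` is the standard deviation of the multiplicative log-normal noise
    (as a proportion of signal); ``spike_rate`` is the expected number of
    spikes per 1000 samples of engaged signal; spikes multiply the sample by
    ``spike_magnitude``.  A seed is mandatory whenever any randomness is on.
    """

    sd: float = 0.01
    spike_rate: float = 0.0
    spike_magnitude: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0 or self.spike_rate < 0:
            raise ValueError("noise rates must be nonnegative")
        if (self.sd > 0 or self.spike_rate > 0) and self.seed is None:
            raise ValueError("a seed is mandatory for any nonzero randomness")


def generate_indentation(
    nmodel: NormalForceModel,
    v_range: tuple[float, float] = (0.05, 0.6),
    n: int = 1000,
    noise: NoiseSpec = NoiseSpec(seed=0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Indentation records (V, Fz) drawn from the power law with noise.

    Volumes are uniform on ``v_range`` (mm³); forces are
    ``C·V^α · exp(ε)`` with ε ~ Normal(0, sd).  Deterministic given the seed.
    Returns a DataFrame with columns ``v_mm3, fz_n``.
    """
    lo, hi = v_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid volume range {v_range}")
    if n < 2:
        raise ValueError("need n >= 2 records")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    V = rng.uniform(lo, hi, size=n)
    eps = rng.normal(0.0, noise.sd, size=n) if noise.sd > 0 else np.zeros(n)
    Fz = nmodel.C * V**nmodel.alpha * np.exp(eps)
    return pd.DataFrame({"v_mm3": V, "fz_n": Fz})


def generate_plough_trial(
    h: float,
    theta: float,
    nmodel: NormalForceModel,
    amodel: AnisotropyModel,
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseSpec = NoiseSpec(seed=0),
    tool: ToolGeometry = ToolGeometry(),
    rng: np.random.Generator | None = None,
    trial_id: str = "",
    replicate: int = 0,
) -> ForceTrace:
    """One ploughing trial: lead-in, linear ramp, engaged plateau, lead-out.

    The engaged plateau holds Fz = C·V(h)^α and Fp = f_p(θ)·Fz for
    stroke/speed seconds; per-sample multiplicative log-normal noise and
    optional spikes apply wherever the tool touches the bone.  The generating
    truth (forces, plateau indices) is embedded in ``ground_truth``.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    V = indentation_volume(h, tool)
    Fz0 = empirical_normal_force(V, nmodel)
    fp_coeff = ploughing_coefficient(theta, amodel)
    Fp0 = fp_coeff * Fz0

    fs = design.sampling_hz
    n_lead = int(round(design.lead_s * fs))
    n_ramp = int(round(design.ramp_s * fs))
    n_eng = int(round(design.engaged_duration_s * fs))
    n = 2 * n_lead + 2 * n_ramp + n_eng
    envelope = np.zeros(n)
    up = slice(n_lead, n_lead + n_ramp)
    plateau = slice(n_lead + n_ramp, n_lead + n_ramp + n_eng)
    down = slice(n_lead + n_ramp + n_eng, n_lead + n_ramp + n_eng + n_ramp)
    envelope[up] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    envelope[plateau] = 1.0
    envelope[down] = np.linspace(1.0, 0.0, n_ramp, endpoint=False)

    if noise.sd > 0:
        gz = np.exp(rng.normal(0.0, noise.sd, size=n))
        gp = np.exp(rng.normal(0.0, noise.sd, size=n))
    else:
        gz = gp = np.ones(n)
    fz = envelope * Fz0 * gz
    fp = envelope * Fp0 * gp

    if noise.spike_rate > 0:
        # spikes drawn after the noise stream so the base signal is unchanged
        engaged_idx = np.flatnonzero(envelope > 0)
        n_spikes = rng.poisson(noise.spike_rate * engaged_idx.size / 1000.0)
        if n_spikes > 0:
            where = rng.choice(engaged_idx, size=min(n_spikes, engaged_idx.size),
                               replace=False)
            fz[where] *= noise.spike_magnitude
            fp[where] *= noise.spike_magnitude

    time = np.arange(n) / fs
    return ForceTrace(
        time=time,
        fz=fz,
        fp=fp,
        metadata={
            "h_mm": h,
            "theta_deg": theta,
            "speed_mm_min": design.speed_mm_min,
            "replicate": replicate,
            "trial_id": trial_id or f"h{h:g}_t{theta:g}_r{replicate}",
        },
        ground_truth={
            "true_fz_n": Fz0,
            "true_fp_n": Fp0,
            "true_fp_coeff": fp_coeff,
            "v_mm3": V,
            "engaged_start": n_lead + n_ramp,
            "engaged_stop": n_lead + n_ramp + n_eng,
        },
    )


def generate_experiment(
    design: ExperimentDesign,
    nmodel: NormalForceModel,
    amodel: AnisotropyModel,
    noise: NoiseSpec = NoiseSpec(seed=0),
    tool: ToolGeometry = ToolGeometry(),
    outdir: str | Path | None = None,
) -> tuple[list[ForceTrace], pd.DataFrame]:
    """Full factorial experiment: one trace per (UCT, angle, replicate) cell.

    Per-trial random streams are spawned from the single experiment seed, so
    the whole experiment is reproducible from (design, models, noise, seed).
    When ``outdir`` is given, trace CSVs and the manifest CSV are written
    there using the standard dialects.
    """
    base = np.random.SeedSequence(noise.seed if noise.seed is not None else 0)
    cells = [
        (h, th, r)
        for h in design.uct_levels
        for th in design.angles
        for r in range(1, design.replicates + 1)
    ]
    children = base.spawn(len(cells))
    traces: list[ForceTrace] = []
    rows = []
    for (h, th, r), child in zip(cells, children):
        trial_id = f"h{h:g}_t{th:g}_r{r}"
        trace = generate_plough_trial(
            h, th, nmodel, amodel, design=design, noise=noise, tool=tool,
            rng=np.random.default_rng(child), trial_id=trial_id, replicate=r,
        )
        traces.append(trace)
        rows.append(
            {
                "trial_id": trial_id,
                "h_mm": h,
                "theta_deg": th,
                "speed_mm_min": design.speed_mm_min,
                "replicate": r,
                "seed": noise.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for trace in traces:
            write_trace_csv(
                outdir / f"{trace.metadata['trial_id']}.csv",
                trace.time, trace.fz, trace.fp,
            )
        write_manifest_csv(outdir / "manifest.csv", manifest)
    return traces, manifest
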