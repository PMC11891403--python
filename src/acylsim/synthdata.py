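"""Synthetic LCMS-like measurement data with the study's structure.

Targeted LCMS time series are emulated as per-analyte count series with:

* an internal-normaliser channel per draw (the nonacylated-ACP-peptide
  channel for acyl-ACP measurements, a constitutive reference protein for
  protein measurements),
* two biological replicates by default,
* three pre-feeding baseline samples,
* multiplicative lognormal noise with a configurable coefficient of
  variation.

Counts are arbitrary-scale; every downstream analysis is ratio-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = [
    "NoiseModel",
    "simulate_lcms_counts",
    "simulate_protein_response",
    "default_sample_times",
    "MEASUREMENT_COLUMNS",
]

#: tidy schema of a measurement table
MEASUREMENT_COLUMNS = ["analyte", "time_s", "replicate", "counts",
                       "normalizer_counts"]

#: arbitrary LCMS count scale per µM
COUNT_SCALE = 1e4

#: concentration of the species backing the normaliser channel (arbitrary)
NORMALIZER_LEVEL = 1.0


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise with coefficient of variation ``cv``."""

    cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def draws(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Unit-mean multiplicative noise factors."""
        if self.cv == 0:
            return np.ones(n)
        sigma2 = np.log1p(self.cv**2)
        return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def default_sample_times(t_step: float, n_baseline: int = 3,
                         post_minutes=(1, 2, 5, 10, 20, 40, 60)) -> np.ndarray:
    """Sampling scheme of a feeding experiment: three pre-feeding samples
    then a handful of post-feeding time points (seconds, absolute)."""
    pre = t_step - 60.0 * np.arange(n_baseline, 0, -1)
    post = t_step + 60.0 * np.asarray(post_minutes, dtype=float)
    return np.concatenate([pre, post])


def simulate_lcms_counts(
    truth: Trajectory,
    analytes: list[str],
    sample_times: np.ndarray,
    n_replicates: int = 2,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Draw an LCMS-style count table from a model trajectory.

    Each (analyte, time, replicate) cell is ``COUNT_SCALE`` times the true
    concentration times an independent unit-mean lognormal factor; the
    normaliser channel is drawn independently with the same cv.
    """
    if not analytes:
        raise ValueError("analyte list is empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.min() < truth.times[0] or sample_times.max() > truth.times[-1]:
        raise ValueError("sample_times outside the trajectory span")

    rng = np.random.default_rng(noise.seed)
    rows = []
    for analyte in analytes:
        series = np.interp(sample_times, truth.times, truth.series(analyte))
        for rep in range(1, n_replicates + 1):
            factors = noise.draws(rng, len(sample_times))
            norm_factors = noise.draws(rng, len(sample_times))
            for t, conc, f, g in zip(sample_times, series, factors, norm_factors):
                rows.append({
                    "analyte": analyte,
                    "time_s": float(t),
                    "replicate": rep,
                    "counts": COUNT_SCALE * conc * f,
                    "normalizer_counts": COUNT_SCALE * NORMALIZER_LEVEL * g,
                })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def simulate_protein_response(
    times: np.ndarray,
    baseline: float,
    fold: float,
    tau: float = 2400.0,
) -> np.ndarray:
    """Phenomenological induction curve for a regulated enzyme level.

    ``baseline * (1 + (fold-1) * (1-exp(-t/tau)))`` for t >= 0 and the
    baseline before the stimulus.  The default time constant puts 95% of
    the approach to the new plateau at about two hours, matching the
    adaptation timescale of the unsaturated-branch enzymes after a
    feeding switch.  Transcriptional mechanism is deliberately not
    modelled.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if fold <= 0:
        raise ValueError("fold must be positive")
    times = np.asarray(times, dtype=float)
    response = np.where(
        times < 0,
        baseline,
        baseline * (1.0 + (fold - 1.0) * -np.expm1(-np.maximum(times, 0) / tau)),
    )
    return response
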