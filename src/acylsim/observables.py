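"""Observables and statistics used to summarise feeding experiments.

These mirror the quantities reported for the LCMS measurements: values
normalised to the average of three pre-treatment baseline measurements,
fold changes of acyl-ACP pools in a post-feeding window, the C16:0
fraction of the PlsB acyl-ACP substrate pool, the acyl-chain composition
of the phosphatidic-acid pool at the sn-1 and sn-2 positions, reference-
protein (TufA-style) normalisation, and a two-tailed unequal-variance
(Welch) t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import Trajectory
from .model import LIPID_CHAINS, StateVector, pa_id

__all__ = [
    "NormalizedSeries",
    "CompositionSeries",
    "normalize_to_baseline",
    "fold_change_at",
    "plsb_substrate_fraction",
    "pa_composition",
    "welch_t_test",
    "normalize_to_reference",
]

#: default post-step readout window (s): the immediate (~1 min) response
IMMEDIATE_WINDOW = (60.0, 300.0)


@dataclass
class NormalizedSeries:
    """A time series divided by its pre-treatment baseline mean."""

    analyte: str
    times: np.ndarray
    values: np.ndarray
    baseline_mean: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CompositionSeries:
    """Per-chain fractional composition over time at one sn position."""

    position: str  # "sn1" or "sn2"
    times: np.ndarray
    fractions: dict[str, np.ndarray]  # chain label -> fraction series


def normalize_to_baseline(
    analyte: str,
    times: np.ndarray,
    values: np.ndarray,
    n_baseline: int = 3,
) -> NormalizedSeries:
    """Divide a series by the mean of its first ``n_baseline`` points.

    The first ``n_baseline`` samples are taken to be the pre-treatment
    measurements; the study design uses three.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) < n_baseline:
        raise ValueError(
            f"need at least {n_baseline} pre-treatment points, got {len(values)}")
    baseline = float(values[:n_baseline].mean())
    if baseline <= 0:
        raise ValueError(f"baseline mean must be positive, got {baseline}")
    return NormalizedSeries(analyte, times, values / baseline, baseline)


def fold_change_at(
    traj: Trajectory,
    species: str,
    window: tuple[float, float] = IMMEDIATE_WINDOW,
) -> float:
    """Mean concentration in a post-step window over the pre-step level.

    ``window`` is given relative to the feeding step.  The pre-step level
    is the concentration immediately before the step (the pre-feeding
    steady state).
    """
    if traj.protocol is None:
        raise ValueError("trajectory has no feeding protocol")
    t_step = traj.protocol.t_step
    if window[0] < 0 or window[1] <= window[0]:
        raise ValueError("window must lie after the feeding step")
    pre_mask = traj.times <= t_step
    if not pre_mask.any():
        raise ValueError("no pre-step samples in trajectory")
    pre = float(traj.series(species)[pre_mask][-1])
    if pre <= 0:
        raise ValueError(f"pre-step concentration of {species} is zero; "
                         "fold change undefined")
    post = traj.window_mean(species, t_step + window[0], t_step + window[1])
    return post / pre


def plsb_substrate_fraction(state: StateVector, include_coa: bool = False) -> float:
    """Fraction of C16:0 within the PlsB substrate pool.

    By default only the acyl-ACP substrates enter the pool, i.e.
    [C16:0-ACP] / ([C16:0-ACP] + [C18:1-ACP]); with ``include_coa`` the
    corresponding acyl-CoA concentrations are added to each term.
    """
    c160 = state["C16:0-ACP"]
    c181 = state["C18:1-ACP"]
    if include_coa:
        c160 += state["C16:0-CoA"]
        c181 += state["C18:1-CoA"]
    total = c160 + c181
    if total <= 0:
        raise ValueError("PlsB substrate pool is empty")
    return c160 / total


def pa_composition(traj: Trajectory) -> tuple[CompositionSeries, CompositionSeries]:
    """Acyl-chain composition of the PA pool at sn-1 and sn-2 over time.

    For each time point the fraction of total PA bearing each chain at a
    position, marginalised over the other position.  Errors if the PA
    pool is empty at any reported time.
    """
    n_t = len(traj.times)
    sn1 = {ch: np.zeros(n_t) for ch in LIPID_CHAINS}
    sn2 = {ch: np.zeros(n_t) for ch in LIPID_CHAINS}
    total = np.zeros(n_t)
    for a in LIPID_CHAINS:
        for b in LIPID_CHAINS:
            series = traj.series(pa_id(a, b))
            sn1[a] += series
            sn2[b] += series
            total += series
    if np.any(total <= 0):
        t_bad = traj.times[np.argmax(total <= 0)]
        raise ValueError(f"PA pool empty at t={t_bad} s; composition undefined")
    return (
        CompositionSeries("sn1", traj.times,
                          {ch: sn1[ch] / total for ch in LIPID_CHAINS}),
        CompositionSeries("sn2", traj.times,
                          {ch: sn2[ch] / total for ch in LIPID_CHAINS}),
    )


def welch_t_test(a, b) -> dict[str, float]:
    """Two-tailed two-sample t-test with unequal variances.

    Returns the Welch statistic, the Welch-Satterthwaite degrees of
    freedom and the two-tailed p-value.  This is the "2-tailed, unequal
    distribution" flavour of the spreadsheet T.TEST function.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("both samples have zero variance; t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def normalize_to_reference(protein_counts, reference_counts) -> np.ndarray:
    """Element-wise ratio of protein counts to a reference channel
    (abundance of a constitutive reference protein such as TufA)."""
    protein = np.asarray(protein_counts, dtype=float)
    reference = np.asarray(reference_counts, dtype=float)
    if protein.shape != reference.shape:
        raise ValueError("protein and reference series must align")
    if np.any(reference <= 0):
        raise ValueError("reference counts must be strictly positive")
    return protein / reference
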