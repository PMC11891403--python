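"""Elementary rate laws: irreversible Michaelis-Menten kinetics, one- and
two-substrate forms, with an optional noncompetitive Hill-type inhibition
factor used for the long-chain acyl-ACP feedback on the lumped ACC-FabD
initiation reaction.
"""

from __future__ import annotations

import math

__all__ = ["mm_rate", "mm_rate_two_substrate", "hill_inhibition"]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


def mm_rate(vmax: float, s: float, km: float) -> float:
    """Irreversible single-substrate Michaelis-Menten rate vmax*s/(km+s).

    Parameters are in µM and seconds: vmax in µM/s, s and km in µM.
    Monotone nondecreasing in s and bounded above by vmax.
    """
    _check_positive(vmax=vmax, km=km)
    if s < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {s}")
    return vmax * s / (km + s)


def hill_inhibition(inhibitor: float, ki: float, n: float) -> float:
    """Noncompetitive inhibition factor 1/(1+(I/ki)^n); ki=inf disables it."""
    if inhibitor < 0:
        raise ValueError(f"inhibitor concentration must be >= 0, got {inhibitor}")
    if not ki > 0:
        raise ValueError(f"ki must be strictly positive (or inf), got {ki}")
    if math.isinf(ki) or inhibitor == 0.0:
        return 1.0
    return 1.0 / (1.0 + (inhibitor / ki) ** n)


def mm_rate_two_substrate(
    vmax: float,
    s1: float,
    km1: float,
    s2: float,
    km2: float,
    inhibitor: float = 0.0,
    ki: float = math.inf,
    n: float = 1.0,
) -> float:
    """Two-substrate Michaelis-Menten rate with noncompetitive inhibition.

    Returns ``vmax * s1/(km1+s1) * s2/(km2+s2) * 1/(1+(inhibitor/ki)^n)``.
    Used for the lumped ACC-FabD initiation (inhibited by the free
    long-chain acyl-ACP pool), for FabH condensation and for the elongation
    steps (ki=inf, i.e. uninhibited).
    """
    _check_positive(vmax=vmax, km1=km1, km2=km2)
    if s1 < 0 or s2 < 0:
        raise ValueError("substrate concentrations must be >= 0")
    return (
        vmax
        * (s1 / (km1 + s1))
        * (s2 / (km2 + s2))
        * hill_inhibition(inhibitor, ki, n)
    )
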