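"""Conversions among the three currencies of nitrogen isotope composition.

EA-IRMS instruments report δ¹⁵N (per-mil deviation of the ¹⁵N/¹⁴N ratio from
atmospheric N₂), whereas tracer mass balances are written in atom percent
(the percentage of N atoms that are ¹⁵N).  The three representations are
exactly interconvertible:

    δ¹⁵N = (R_sample / R_standard − 1) × 1000
    at%  = 100 · R / (1 + R)
    R    = R_standard · (δ/1000 + 1)

with R the dimensionless ¹⁵N/¹⁴N ratio.  All functions accept scalars or
numpy arrays and default the standard to atmospheric N₂.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: ¹⁵N/¹⁴N ratio of atmospheric N₂ (the δ¹⁵N reference standard).
R_AIR = 0.0036765


def _asarray(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def delta_from_ratio(r_sample, r_standard: float = R_AIR):
    """δ¹⁵N (‰) of a sample ratio against a standard ratio.

    Raises ``ValueError`` for non-positive ratios.
    """
    arr, scalar = _asarray(r_sample)
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    if np.any(arr <= 0):
        raise ValueError("sample ratio must be positive")
    return _ret((arr / r_standard - 1.0) * 1000.0, scalar)


def ratio_from_delta(delta, r_standard: float = R_AIR):
    """¹⁵N/¹⁴N ratio implied by a δ¹⁵N value (‰)."""
    arr, scalar = _asarray(delta)
    if r_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {r_standard}")
    if np.any(arr <= -1000.0):
        raise ValueError("delta values at or below -1000 permil imply a non-positive ratio")
    return _ret(r_standard * (arr / 1000.0 + 1.0), scalar)


def atom_percent_from_ratio(r):
    """Atom percent ¹⁵N from a ¹⁵N/¹⁴N ratio: 100·R/(1+R)."""
    arr, scalar = _asarray(r)
    if np.any(arr <= 0):
        raise ValueError("ratio must be positive")
    return _ret(100.0 * arr / (1.0 + arr), scalar)


def ratio_from_atom_percent(ap):
    """¹⁵N/¹⁴N ratio from atom percent ¹⁵N: R = ap/(100−ap)."""
    arr, scalar = _asarray(ap)
    if np.any((arr <= 0) | (arr >= 100)):
        raise ValueError("atom percent must lie strictly between 0 and 100")
    return _ret(arr / (100.0 - arr), scalar)


def atom_percent_from_delta(delta, r_standard: float = R_AIR):
    """Atom percent ¹⁵N implied by δ¹⁵N (‰) against ``r_standard``.

    Strictly increasing in δ; δ = 0 maps to the standard's own atom
    percent (≈0.3663 % for air N₂).
    """
    return atom_percent_from_ratio(ratio_from_delta(delta, r_standard))


def delta_from_atom_percent(ap, r_standard: float = R_AIR):
    """δ¹⁵N (‰) implied by atom percent ¹⁵N; inverse of
    :func:`atom_percent_from_delta`."""
    return delta_from_ratio(ratio_from_atom_percent(ap), r_standard)


@dataclass(frozen=True)
class IsotopeValue:
    """One nitrogen isotope composition in all three currencies.

    Attributes
    ----------
    delta_permil : float
        δ¹⁵N vs atmospheric N₂, ‰.
    atom_percent : float
        Percent of N atoms that are ¹⁵N, in (0, 100).
    ratio : float
        ¹⁵N/¹⁴N, dimensionless, > 0.
    """

    delta_permil: float
    atom_percent: float
    ratio: float

    @classmethod
    def from_delta(cls, delta: float, r_standard: float = R_AIR) -> "IsotopeValue":
        r = ratio_from_delta(delta, r_standard)
        return cls(delta_permil=float(delta), atom_percent=atom_percent_from_ratio(r), ratio=r)

    @classmethod
    def from_atom_percent(cls, ap: float, r_standard: float = R_AIR) -> "IsotopeValue":
        r = ratio_from_atom_percent(ap)
        return cls(delta_permil=delta_from_ratio(r, r_standard), atom_percent=float(ap), ratio=r)

    @classmethod
    def from_ratio(cls, r: float, r_standard: float = R_AIR) -> "IsotopeValue":
        return cls(
            delta_permil=delta_from_ratio(r, r_standard),
            atom_percent=atom_percent_from_ratio(r),
            ratio=float(r),
        )
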