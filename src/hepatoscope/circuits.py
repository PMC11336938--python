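"""Lumped-circuit models for on-skin bioimpedance measurements.

Two ingredients make up a measured liver impedance: the electrode-skin
contact interface, modelled as a Randles equivalent circuit (a series
skin/gel resistance ``R_d`` in front of a charge-transfer resistance
``R_e`` in parallel with the double-layer capacitance ``C_dl``), and the
frequency-dependent tissue path, modelled with a Cole-type dispersion.

Raising the double-layer capacitance lowers the contact impedance at any
given frequency, which is the mechanism that motivates nano-structured
electrode coatings; fat-infiltrated tissue conducts poorly at low
frequency because lipid bilayers block current, so a fatty liver shows an
elevated low-frequency plateau ``R0`` relative to a hydrated healthy one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElectrodeSkinModel",
    "TissueDispersion",
    "FrequencyGrid",
    "frequency_grid",
    "electrode_skin_impedance",
    "tissue_path_impedance",
]


@dataclass(frozen=True)
class ElectrodeSkinModel:
    """Randles-circuit parameters of one electrode-skin interface.

    Parameters
    ----------
    R_d : float
        Series (skin/gel) resistance, ohm.
    C_dl : float
        Double-layer capacitance, farad.
    R_e : float
        Charge-transfer resistance, ohm.
    """

    R_d: float
    C_dl: float
    R_e: float

    def __post_init__(self) -> None:
        for name in ("R_d", "C_dl", "R_e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")


@dataclass(frozen=True)
class TissueDispersion:
    """Cole-type dispersion parameters of one tissue current path.

    ``R0`` and ``Rinf`` are the zero- and infinite-frequency resistive
    plateaus (ohm), ``fc`` the characteristic frequency (Hz) and
    ``alpha`` the fractional dispersion exponent in (0, 1] (``alpha = 1``
    recovers a single-time-constant Debye relaxation).
    """

    R0: float
    Rinf: float
    fc: float
    alpha: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.R0) and np.isfinite(self.Rinf)) or not self.R0 > self.Rinf > 0:
            raise ValueError(f"need R0 > Rinf > 0, got R0={self.R0!r}, Rinf={self.Rinf!r}")
        if not np.isfinite(self.fc) or self.fc <= 0:
            raise ValueError(f"fc must be positive, got {self.fc!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha!r}")


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing measurement frequencies, Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("frequencies must be positive and finite")
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return int(self.frequencies.size)


def frequency_grid(f_min: float = 1e3, f_max: float = 1e5, n: int = 30) -> FrequencyGrid:
    """Log-spaced sweep of ``n`` frequencies from ``f_min`` to ``f_max``.

    The default mirrors a 30-point sweep across 1-100 kHz.  Endpoints are
    exact; consecutive points share a constant ratio.
    """
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    if f_max < f_min:
        raise ValueError(f"f_max ({f_max}) must be >= f_min ({f_min})")
    if n < 1 or (f_max > f_min and n < 2):
        raise ValueError(f"need n >= 2 to span ({f_min}, {f_max}), got n={n}")
    if f_max == f_min:
        f = np.full(n, float(f_min))
        if n > 1:
            raise ValueError("degenerate span supports only a single point")
    else:
        f = np.geomspace(f_min, f_max, n)
        f[0], f[-1] = f_min, f_max  # exact endpoints
    return FrequencyGrid(f)


def electrode_skin_impedance(
    model: ElectrodeSkinModel,
    f: float | np.ndarray,
    *,
    literal: bool = False,
) -> complex | np.ndarray:
    """Complex electrode-skin contact impedance at frequency ``f`` (Hz).

    Default is the Randles reading ``Z = R_d + 1/(jωC_dl + 1/R_e)`` with
    ``ω = 2πf``: the double-layer capacitance in parallel with the
    charge-transfer resistance, in series with the skin/gel resistance.
    Its real part lies in ``[R_d, R_d + R_e]`` and its reactance is
    capacitive (imaginary part <= 0); increasing ``C_dl`` strictly lowers
    ``|Z|`` at fixed ``f``.

    ``literal=True`` evaluates the dimensionally inconsistent series
    reading ``R_d + 1/(jωC_dl) + 1/R_e`` instead, retained only for
    comparison against the parallel form.
    """
    f = np.asarray(f, dtype=float) if np.ndim(f) else float(f)
    if np.any(np.asarray(f) <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f
    if literal:
        return model.R_d + 1.0 / (1j * w * model.C_dl) + 1.0 / model.R_e
    return model.R_d + 1.0 / (1j * w * model.C_dl + 1.0 / model.R_e)


def tissue_path_impedance(d: TissueDispersion, f: float | np.ndarray) -> complex | np.ndarray:
    """Cole-type complex tissue impedance ``Rinf + (R0-Rinf)/(1+(jf/fc)^alpha)``.

    ``|Z|`` decays monotonically from ``R0`` at DC to ``Rinf`` at high
    frequency; the fractional exponent broadens the dispersion, as is
    typical of biological tissue.
    """
    f = np.asarray(f, dtype=float) if np.ndim(f) else float(f)
    if np.any(np.asarray(f) <= 0):
        raise ValueError("frequency must be positive")
    s = (1j * f / d.fc) ** d.alpha
    return d.Rinf + (d.R0 - d.Rinf) / (1.0 + s)
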