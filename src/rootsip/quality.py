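"""Linear error models and raw-data quality filters.

Impedance magnitude errors follow the linear model ``a*|Z| + b`` (relative
slope a, absolute floor b in Ohm); phase errors follow ``c*|phi| + d`` with a
relative slope c and an absolute floor d in radians.  Errors are magnitudes,
so the relative phase term uses |phi|.

Filtering mirrors standard practice for irregular surface schemes where
reciprocal checks are unavailable: per frequency, strongly positive
(non-physical, inductive-looking) phases are removed first, then phases more
than k sample standard deviations from the per-frequency mean.  The 3-sigma
pass is single-pass, not iterated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scheme import MeasurementScheme

__all__ = [
    "ErrorModel",
    "ImpedanceDataset",
    "magnitude_error",
    "phase_error",
    "phase_error_from_data",
    "filter_positive_phase",
    "filter_phase_3sigma",
]

MRAD = 1e-3  # radians per mrad


@dataclass(frozen=True)
class ErrorModel:
    """Linear error model parameters.

    a : relative magnitude error (dimensionless, e.g. 0.02 for 2%)
    b : absolute magnitude error (Ohm for impedances, Ohm*m for resistivities)
    c : relative phase error (dimensionless)
    d_abs : absolute phase error (radians)
    """

    a: float = 0.02
    b: float = 0.01
    c: float = 0.02
    d_abs: float = 1.0 * MRAD

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d_abs) < 0:
            raise ValueError("error-model parameters must be non-negative")


def magnitude_error(em: ErrorModel, z_mag) -> np.ndarray | float:
    """Magnitude error ``a*|Z| + b`` (same units as ``b``)."""
    z_mag = np.asarray(z_mag, dtype=float)
    if np.any(z_mag < 0):
        raise ValueError("impedance magnitude must be non-negative")
    out = em.a * z_mag + em.b
    return float(out) if out.ndim == 0 else out


def phase_error(em: ErrorModel, phi) -> np.ndarray | float:
    """Phase error ``c*|phi| + d`` in radians."""
    phi = np.asarray(phi, dtype=float)
    out = em.c * np.abs(phi) + em.d_abs
    return float(out) if out.ndim == 0 else out


def phase_error_from_data(phases, mask=None) -> float:
    """Absolute phase error as half the sample std of one frequency's phases."""
    phases = np.asarray(phases, dtype=float)
    if mask is not None:
        phases = phases[np.asarray(mask, dtype=bool)]
    if phases.size < 2:
        raise ValueError("need at least 2 valid phase values to estimate d")
    return 0.5 * float(np.std(phases, ddof=1))


@dataclass
class ImpedanceDataset:
    """Complex transfer impedances per (configuration, frequency) with a
    validity mask; masked-out entries are excluded from all statistics."""

    scheme: MeasurementScheme
    frequencies: np.ndarray
    z: np.ndarray  # complex, shape (n_configs, n_freqs)
    mask: np.ndarray | None = None  # True = valid

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z = np.asarray(self.z, dtype=complex)
        expected = (len(self.scheme), self.frequencies.size)
        if self.z.shape != expected:
            raise ValueError(f"impedance array must have shape {expected}")
        if self.mask is None:
            self.mask = np.ones(expected, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != expected:
                raise ValueError(f"mask must have shape {expected}")

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.z)

    def n_valid(self) -> int:
        return int(self.mask.sum())


def filter_positive_phase(
    ds: ImpedanceDataset, threshold: float = 5.0 * MRAD
) -> ImpedanceDataset:
    """Mask entries whose impedance phase exceeds +threshold (radians).

    Negative phases (the physical capacitive sign) are always retained.
    Returns a new dataset; the input is untouched.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = ds.mask & ~(ds.phase > threshold)
    return ImpedanceDataset(ds.scheme, ds.frequencies, ds.z, mask)


def filter_phase_3sigma(ds: ImpedanceDataset, k: float = 3.0) -> ImpedanceDataset:
    """Per frequency, mask phases deviating more than k sample standard
    deviations from the mean of the currently valid phases (single pass)."""
    mask = ds.mask.copy()
    phase = ds.phase
    for j in range(ds.frequencies.size):
        valid = mask[:, j]
        if valid.sum() < 3:
            warnings.warn(
                f"fewer than 3 valid entries at {ds.frequencies[j]:g} Hz; "
                "skipping outlier filter",
                stacklevel=2,
            )
            continue
        p = phase[valid, j]
        mu = p.mean()
        sd = p.std(ddof=1)
        if sd == 0:
            continue
        bad = np.abs(phase[:, j] - mu) > k * sd
        mask[:, j] &= ~(bad & valid)
    return ImpedanceDataset(ds.scheme, ds.frequencies, ds.z, mask)
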