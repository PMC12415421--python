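"""Frequency-sampled complex resistivity/conductivity containers.

A spectral impedance tomogram assigns to every cell of a 2D inversion grid a
complex resistivity spectrum ``rho(omega) = |rho| * exp(i*phi)`` sampled on a
shared frequency grid.  The complex conductivity is its reciprocal,

    sigma(omega) = 1 / rho(omega) = sigma' + i*sigma'',

where the real part describes conduction and the imaginary part polarization.
Phases are stored in radians throughout; a capacitive (normal induced
polarization) response has negative resistivity phase and hence positive
imaginary conductivity.  File I/O uses mrad (see :mod:`rootsip.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "ComplexSpectrum",
    "CellGrid",
    "TomogramStack",
    "to_conductivity",
    "value_at",
]

MRAD_PER_RAD = 1000.0


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive measurement frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("frequency grid needs at least 2 frequencies")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ``2*pi*f`` in rad/s."""
        return 2.0 * np.pi * self.frequencies

    def index_of(self, f: float, rtol: float = 1e-9) -> int:
        """Index of ``f`` on the grid, or raise naming the nearest frequencies."""
        freqs = self.frequencies
        hit = np.flatnonzero(np.isclose(freqs, f, rtol=rtol, atol=0.0))
        if hit.size:
            return int(hit[0])
        below = freqs[freqs < f]
        above = freqs[freqs > f]
        lo = f"{below[-1]:g} Hz" if below.size else "none"
        hi = f"{above[0]:g} Hz" if above.size else "none"
        raise KeyError(
            f"{f:g} Hz is not on the frequency grid "
            f"(nearest below: {lo}, nearest above: {hi})"
        )

    @classmethod
    def log_spaced(cls, f_min: float, f_max: float, n: int) -> "FrequencyGrid":
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n))


def default_survey_grid() -> FrequencyGrid:
    """23 log-evenly spaced frequencies from 0.1 Hz to 10 kHz."""
    return FrequencyGrid.log_spaced(0.1, 1.0e4, 23)


@dataclass(frozen=True)
class ComplexSpectrum:
    """One cell's complex resistivity spectrum (magnitude in Ohm*m, phase in rad)."""

    grid: FrequencyGrid
    magnitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        ph = np.asarray(self.phase, dtype=float)
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "phase", ph)
        n = len(self.grid)
        if mag.shape != (n,) or ph.shape != (n,):
            raise ValueError("magnitude/phase length must match the frequency grid")
        if np.any(mag <= 0):
            raise ValueError("resistivity magnitude must be positive")
        if np.any(np.abs(ph) >= np.pi / 2):
            raise ValueError("|phase| must be below pi/2 rad")

    @property
    def rho(self) -> np.ndarray:
        """Complex resistivity per frequency."""
        return self.magnitude * np.exp(1j * self.phase)

    @property
    def sigma(self) -> np.ndarray:
        """Complex conductivity per frequency (reciprocal resistivity)."""
        return 1.0 / self.rho

    @property
    def sigma_real(self) -> np.ndarray:
        return self.sigma.real

    @property
    def sigma_imag(self) -> np.ndarray:
        return self.sigma.imag

    @classmethod
    def from_complex(cls, grid: FrequencyGrid, rho: np.ndarray) -> "ComplexSpectrum":
        rho = np.asarray(rho, dtype=complex)
        return cls(grid, np.abs(rho), np.angle(rho))


def to_conductivity(s: ComplexSpectrum, f: float) -> tuple[float, float]:
    """Real and imaginary conductivity (S/m) at an on-grid frequency.

    ``sigma = 1/(|rho| e^{i phi})``; a negative resistivity phase gives a
    positive imaginary conductivity.
    """
    i = s.grid.index_of(f)
    sig = 1.0 / (s.magnitude[i] * np.exp(1j * s.phase[i]))
    return float(sig.real), float(sig.imag)


def value_at(s: ComplexSpectrum, f: float, mode: str = "loglog") -> complex:
    """Complex resistivity at ``f``.

    mode "exact" requires grid membership; mode "loglog" (default) interpolates
    log-magnitude and phase linearly in log-frequency, suiting the log-even
    sampling of field surveys.  Extrapolation outside the grid span is refused.
    """
    freqs = s.grid.frequencies
    try:
        i = s.grid.index_of(f)
    except KeyError:
        if mode == "exact":
            raise
        i = None
    if i is not None:
        return complex(s.magnitude[i] * np.exp(1j * s.phase[i]))
    if mode != "loglog":
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if not (freqs[0] <= f <= freqs[-1]):
        raise ValueError(
            f"{f:g} Hz is outside the grid span "
            f"[{freqs[0]:g}, {freqs[-1]:g}] Hz; refusing to extrapolate"
        )
    lf = np.log(f)
    lfs = np.log(freqs)
    lmag = float(np.interp(lf, lfs, np.log(s.magnitude)))
    ph = float(np.interp(lf, lfs, s.phase))
    return complex(np.exp(lmag) * np.exp(1j * ph))


@dataclass(frozen=True)
class CellGrid:
    """2D profile grid: cell ids, x along profile (m), z depth (m, positive down),
    and cell volumes (m^3; cell area times 1 m unit out-of-plane thickness)."""

    cell_ids: np.ndarray
    x: np.ndarray
    z: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.cell_ids)
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        v = np.asarray(self.volume, dtype=float)
        for name, arr in (("x", x), ("z", z), ("volume", v)):
            if arr.shape != ids.shape:
                raise ValueError(f"{name} must match cell_ids in shape")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("cell ids must be unique")
        if np.any(v <= 0):
            raise ValueError("cell volumes must be positive")
        object.__setattr__(self, "cell_ids", ids)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "volume", v)

    def __len__(self) -> int:
        return self.cell_ids.size

    def index_of(self, cell_id) -> int:
        hit = np.flatnonzero(self.cell_ids == cell_id)
        if not hit.size:
            raise KeyError(f"unknown cell id {cell_id!r}")
        return int(hit[0])

    @classmethod
    def regular(
        cls, nx: int, nz: int, dx: float, dz: float, x0: float = 0.0
    ) -> "CellGrid":
        """Regular grid of nx columns and nz rows; cell centers at half-steps."""
        xs = x0 + (np.arange(nx) + 0.5) * dx
        zs = (np.arange(nz) + 0.5) * dz
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        n = nx * nz
        return cls(np.arange(n), X.ravel(), Z.ravel(), np.full(n, dx * dz * 1.0))


@dataclass
class TomogramStack:
    """A cell grid with one complex resistivity spectrum per cell, all sharing
    one frequency grid — the pipeline's central container."""

    grid: CellGrid
    spectra: list[ComplexSpectrum] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.grid):
            raise ValueError("need exactly one spectrum per cell")
        fg = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid is not fg and not np.array_equal(
                s.grid.frequencies, fg.frequencies
            ):
                raise ValueError("all spectra must share one frequency grid")

    @property
    def frequency_grid(self) -> FrequencyGrid:
        return self.spectra[0].grid

    def spectrum(self, cell_id) -> ComplexSpectrum:
        return self.spectra[self.grid.index_of(cell_id)]
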