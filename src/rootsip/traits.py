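"""Root-zone trait extraction: ERI, volume-weighted aggregates, Schwarz
length scales, and trait correlations.

The electrical root index (ERI) is the log-log slope of the imaginary
conductivity between a low and a high frequency,

    ERI = log(sigma''_HF / sigma''_LF) / log(f_HF / f_LF),

a measure of spectral dispersion used as a root-presence proxy: fine roots
polarize mainly at high frequencies while soil water/temperature variations
move the whole spectrum multiplicatively, to which the ERI is blind.  For
small phases it is approximated by the same slope on phase magnitudes.

Relaxation times translate to polarizing-structure size via the Schwarz
relation tau = r^2/(2D), i.e. diameter d = 2*sqrt(2*D*tau) for an ion
diffusion coefficient D (default 1e-9 m^2/s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import CellGrid, TomogramStack, value_at

__all__ = [
    "PlantRecord",
    "RootZone",
    "TraitResult",
    "select_zone",
    "soil_reference_zone",
    "zone_weighted_mean",
    "eri",
    "eri_phase_approx",
    "eri_map",
    "schwarz_diameter",
    "rbd",
    "pearson",
]

SPECIES = ("sugar_beet", "maize")
DEFAULT_DIFFUSION = 1e-9  # m^2/s, typical ion diffusion coefficient


@dataclass(frozen=True)
class PlantRecord:
    plant_id: str
    species: str
    stem_x: float  # m along profile
    fresh_root_mass: float  # kg
    offset_flag: bool = False  # plant off the image plane

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if self.fresh_root_mass < 0:
            raise ValueError("fresh root mass cannot be negative")


@dataclass(frozen=True)
class RootZone:
    """Cells of the excavated validation window around one plant stem."""

    plant_id: str
    x_min: float
    x_max: float
    z_min: float
    z_max: float
    cell_ids: np.ndarray
    v_rz: float  # m^3

    def __post_init__(self) -> None:
        if np.asarray(self.cell_ids).size == 0:
            raise ValueError("root zone has no member cells")


@dataclass(frozen=True)
class TraitResult:
    plant_id: str
    mean_rho_mag: float
    mean_m_tot: float
    mean_tau_s: float
    mean_eri: float
    rbd: float
    cell_diameter_m: float


def select_zone(
    grid: CellGrid,
    plant: PlantRecord,
    width: float = 0.20,
    depth: float = 0.25,
) -> RootZone:
    """Root zone: cells whose centers fall in the closed window
    [stem_x - width/2, stem_x + width/2] x [0, depth]."""
    x_min, x_max = plant.stem_x - width / 2.0, plant.stem_x + width / 2.0
    return _window_zone(grid, plant.plant_id, x_min, x_max, 0.0, depth)


def soil_reference_zone(
    grid: CellGrid,
    x_min: float,
    x_max: float,
    z_range: tuple[float, float] = (0.50, 1.00),
) -> RootZone:
    """Root-free reference: all cells in the x extent at 50-100 cm depth."""
    return _window_zone(grid, "soil_reference", x_min, x_max, *z_range)


def _window_zone(grid, zone_id, x_min, x_max, z_min, z_max) -> RootZone:
    inside = (
        (grid.x >= x_min) & (grid.x <= x_max) & (grid.z >= z_min) & (grid.z <= z_max)
    )
    if not inside.any():
        raise ValueError(
            f"no cell centers inside window x=[{x_min:g},{x_max:g}] m, "
            f"z=[{z_min:g},{z_max:g}] m"
        )
    return RootZone(
        zone_id,
        x_min,
        x_max,
        z_min,
        z_max,
        grid.cell_ids[inside],
        float(grid.volume[inside].sum()),
    )


def zone_weighted_mean(values: dict, zone: RootZone, grid: CellGrid) -> float:
    """Cell-volume-weighted mean of ``values`` (cell_id -> value) over a zone.

    Cells with missing or non-finite values are excluded and the zone volume
    renormalized over the survivors (with a warning).
    """
    vs, ws = [], []
    n_dropped = 0
    for cid in zone.cell_ids:
        v = values.get(cid, float("nan"))
        if v is None or not np.isfinite(v):
            n_dropped += 1
            continue
        vs.append(v)
        ws.append(grid.volume[grid.index_of(cid)])
    if not vs:
        raise ValueError(f"zone {zone.plant_id}: no valid cell values")
    if n_dropped:
        warnings.warn(
            f"zone {zone.plant_id}: {n_dropped} invalid cell(s) excluded; "
            "volume renormalized",
            stacklevel=2,
        )
    ws = np.asarray(ws)
    return float(np.dot(ws, vs) / ws.sum())


def eri(
    sigma_im_lf: float, sigma_im_hf: float, f_lf: float, f_hf: float
) -> float:
    """Electrical root index from imaginary conductivities (base-invariant).

    Returns NaN (flagged invalid) when either imaginary conductivity is
    non-positive — near-zero phases make the log slope meaningless.
    """
    if f_hf <= f_lf:
        raise ValueError("f_hf must exceed f_lf")
    if sigma_im_lf <= 0 or sigma_im_hf <= 0:
        return float("nan")
    return math.log(sigma_im_hf / sigma_im_lf) / math.log(f_hf / f_lf)


def eri_phase_approx(
    phi_lf: float, phi_hf: float, f_lf: float, f_hf: float
) -> float:
    """ERI from phase magnitudes — valid for small phases and a flat
    conductivity magnitude between the two frequencies."""
    if f_hf <= f_lf:
        raise ValueError("f_hf must exceed f_lf")
    if phi_lf == 0 or phi_hf == 0 or (phi_lf > 0) != (phi_hf > 0):
        return float("nan")
    return math.log(abs(phi_hf) / abs(phi_lf)) / math.log(f_hf / f_lf)


def eri_map(
    stack: TomogramStack,
    f_lf: float = 3.125,
    f_hf: float = 1000.0,
    mode: str = "loglog",
    use_phase_approx: bool = False,
) -> dict:
    """Per-cell ERI field (cell_id -> ERI, NaN where flagged invalid).

    Frequencies absent from the grid are resolved by log-log interpolation.
    """
    out = {}
    for cid, spec in zip(stack.grid.cell_ids, stack.spectra):
        r_lf = value_at(spec, f_lf, mode=mode)
        r_hf = value_at(spec, f_hf, mode=mode)
        if use_phase_approx:
            out[cid] = eri_phase_approx(
                float(np.angle(r_lf)), float(np.angle(r_hf)), f_lf, f_hf
            )
        else:
            s_lf = (1.0 / r_lf).imag
            s_hf = (1.0 / r_hf).imag
            out[cid] = eri(s_lf, s_hf, f_lf, f_hf)
    return out


def schwarz_diameter(tau: float, diffusion: float = DEFAULT_DIFFUSION) -> float:
    """Diameter (m) of the polarizing structure implied by a relaxation time.

    Inverts the Schwarz relation tau = r^2/(2D): d = 2*sqrt(2*D*tau).
    """
    if tau < 0:
        raise ValueError("relaxation time cannot be negative")
    if diffusion <= 0:
        raise ValueError("diffusion coefficient must be positive")
    return 2.0 * math.sqrt(2.0 * diffusion * tau)


def schwarz_diameter_um(tau: float, diffusion: float = DEFAULT_DIFFUSION) -> int:
    """Diameter in whole micrometres (truncated), the reporting convention."""
    return int(schwarz_diameter(tau, diffusion) * 1e6)


def rbd(plant: PlantRecord, zone: RootZone) -> float:
    """Root biomass density: fresh root mass over root-zone volume (kg/m^3)."""
    if zone.v_rz <= 0:
        raise ValueError("root-zone volume must be positive")
    return plant.fresh_root_mass / zone.v_rz


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equally sized samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)
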