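"""Synthetic spectral-impedance field scenes with known ground truth.

Generates tomogram-like complex resistivity fields for a 2D profile: a
polarizable soil background plus plant-root anomalies inside the excavation
windows around each stem.  All spectra are Debye superpositions, so every
downstream stage (decomposition, ERI, traits) can be validated against exact
per-cell truth.  The presets emulate the qualitative field signatures of a
maize / sugar-beet trial:

* soil: phase decreasing with frequency to about -10 mrad at 1 kHz;
* maize: added high-frequency (>= 100 Hz) dispersion, minimum phase about
  -15 mrad, no low-frequency peak;
* sugar beet (mid/late season): an additional low-frequency Debye peak
  (tau ~ 17-80 ms, peak -10 to -15 mrad) on top of a strong high-frequency
  polarization reaching about -25 mrad.

Noise is applied in (magnitude, phase) space, independent across cells and
frequencies, with standard deviations from the linear error models; it has
no spatial correlation (real inversion output does).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .debye import debye_forward
from .quality import ErrorModel, ImpedanceDataset
from .scheme import MeasurementScheme
from .spectra import CellGrid, ComplexSpectrum, FrequencyGrid, TomogramStack
from .traits import PlantRecord, select_zone

__all__ = [
    "PlantAnomaly",
    "RbdCoupling",
    "SceneConfig",
    "SyntheticScene",
    "build_scene",
    "halfspace_impedances",
    "attach_validation",
    "maize_scene_config",
    "mixed_scene_config",
]

HF_TAU_CUTOFF = 2e-3  # s; terms faster than this count as "high-frequency"


def soil_terms() -> list[tuple[float, float]]:
    """Soil Debye terms: broad dispersion levelling off near -10 mrad at 1 kHz
    (about -5 mrad at 1 Hz), flat-ish between 100 Hz and 1 kHz."""
    taus = np.logspace(-4.6, -1.0, 9)
    return [(0.0075, float(t)) for t in taus]


def maize_terms(scale: float = 1.0) -> list[tuple[float, float]]:
    """Added maize-root dispersion: high-frequency terms only, deepening the
    phase to about -15 mrad at 1 kHz at full strength."""
    return [(0.0055 * scale, 1.0e-4), (0.0035 * scale, 3.2e-4), (0.0018 * scale, 1.0e-3)]


def beet_terms(timestep: str = "t2", scale: float = 1.0) -> list[tuple[float, float]]:
    """Added sugar-beet dispersion: strong high-frequency polarization (phase
    to about -25 mrad at 1 kHz) plus a low-frequency storage-cell peak that
    grows and slows over the season (peaking near 4 Hz at t2, 2 Hz at t3)."""
    hf = [(0.017 * scale, 1.0e-4), (0.010 * scale, 3.2e-4), (0.005 * scale, 1.0e-3)]
    lf = {
        "t1": [(0.005 * scale, 0.017)],
        "t2": [(0.009 * scale, 0.055)],
        "t3": [(0.014 * scale, 0.110)],
    }
    try:
        return lf[timestep] + hf
    except KeyError:
        raise ValueError(f"unknown timestep {timestep!r}; use t1, t2 or t3") from None


@dataclass(frozen=True)
class PlantAnomaly:
    """One plant's added polarization inside its excavation window."""

    plant_id: str
    species: str
    stem_x: float
    terms: tuple  # ((m, tau), ...)
    width: float = 0.20
    depth: float = 0.25
    rho0_factor: float = 1.2  # plants sit in drier, more resistive soil


@dataclass(frozen=True)
class RbdCoupling:
    """Linear link from zone-mean high-frequency chargeability to fresh root
    mass, with multiplicative lognormal scatter."""

    gain: float = 1200.0  # kg/m^3 per unit chargeability
    intercept: float = 0.0  # kg
    sigma: float = 0.25  # lognormal sigma

    def __post_init__(self) -> None:
        if self.gain < 0 or self.sigma < 0:
            raise ValueError("coupling gain and sigma must be non-negative")


@dataclass(frozen=True)
class SceneConfig:
    nx: int = 130
    nz: int = 24
    dx: float = 0.05
    dz: float = 0.05
    x0: float = 0.0
    f_min: float = 0.1
    f_max: float = 1.0e4
    n_freq: int = 23
    soil_rho0: float = 60.0
    soil: tuple = tuple(soil_terms())
    plants: tuple = ()
    coupling: RbdCoupling = RbdCoupling()
    error_model: ErrorModel | None = ErrorModel()  # None = noise-free
    seed: int = 0

    def frequency_grid(self) -> FrequencyGrid:
        return FrequencyGrid.log_spaced(self.f_min, self.f_max, self.n_freq)

    def cell_grid(self) -> CellGrid:
        return CellGrid.regular(self.nx, self.nz, self.dx, self.dz, self.x0)


@dataclass
class SyntheticScene:
    config: SceneConfig
    stack: TomogramStack
    truth_rho0: dict  # cell_id -> rho0
    truth_terms: dict  # cell_id -> ((m, tau), ...), soil + anomaly
    truth_root_terms: dict  # cell_id -> ((m, tau), ...), anomaly only
    plants: list = field(default_factory=list)  # PlantRecord, after validation
    true_rbd: dict = field(default_factory=dict)  # plant_id -> kg/m^3

    def true_m_tot(self, cell_id) -> float:
        return sum(m for m, _ in self.truth_terms[cell_id])

    def true_root_hf_chargeability(
        self, cell_id, tau_cutoff: float = HF_TAU_CUTOFF
    ) -> float:
        """Root-added (soil-free) high-frequency chargeability of a cell."""
        return sum(m for m, t in self.truth_root_terms[cell_id] if t <= tau_cutoff)


def build_scene(config: SceneConfig) -> SyntheticScene:
    """Compose per-cell Debye parameters (soil + anomalies), run the forward
    model and add error-model noise.  Deterministic under the config seed."""
    grid = config.cell_grid()
    fgrid = config.frequency_grid()
    freqs = fgrid.frequencies

    # per-cell parameter assembly; cells inside several windows stack anomalies
    terms_per_cell = {cid: list(config.soil) for cid in grid.cell_ids}
    root_terms_per_cell: dict = {cid: [] for cid in grid.cell_ids}
    rho0_per_cell = {cid: config.soil_rho0 for cid in grid.cell_ids}
    for pl in config.plants:
        x_lo, x_hi = pl.stem_x - pl.width / 2, pl.stem_x + pl.width / 2
        inside = (
            (grid.x >= x_lo) & (grid.x <= x_hi) & (grid.z >= 0) & (grid.z <= pl.depth)
        )
        for cid in grid.cell_ids[inside]:
            terms_per_cell[cid].extend(pl.terms)
            root_terms_per_cell[cid].extend(pl.terms)
            rho0_per_cell[cid] = config.soil_rho0 * pl.rho0_factor
    for cid, terms in terms_per_cell.items():
        if sum(m for m, _ in terms) >= 1.0:
            raise ValueError(f"cell {cid}: total chargeability must stay below 1")

    # forward model on unique parameter signatures (cheap: few distinct zones)
    cache: dict = {}
    spectra_rho = np.empty((len(grid), freqs.size), dtype=complex)
    for i, cid in enumerate(grid.cell_ids):
        key = (rho0_per_cell[cid], tuple(terms_per_cell[cid]))
        if key not in cache:
            ms = [m for m, _ in key[1]]
            ts = [t for _, t in key[1]]
            cache[key] = debye_forward(key[0], ms, ts, freqs)
        spectra_rho[i] = cache[key]

    mag = np.abs(spectra_rho)
    ph = np.angle(spectra_rho)
    if config.error_model is not None:
        em = config.error_model
        rng = np.random.default_rng([config.seed, 0])
        mag = mag + rng.normal(0.0, em.a * mag + em.b)
        ph = ph + rng.normal(0.0, em.c * np.abs(ph) + em.d_abs)
        mag = np.maximum(mag, 1e-6)

    spectra = [ComplexSpectrum(fgrid, mag[i], ph[i]) for i in range(len(grid))]
    stack = TomogramStack(grid, spectra)
    truth_terms = {cid: tuple(t) for cid, t in terms_per_cell.items()}
    truth_root = {cid: tuple(t) for cid, t in root_terms_per_cell.items()}
    scene = SyntheticScene(config, stack, rho0_per_cell, truth_terms, truth_root)
    attach_validation(scene, config.coupling)
    return scene


def attach_validation(scene: SyntheticScene, coupling: RbdCoupling) -> list:
    """Derive plant validation records from generator truth.

    fresh_root_mass = gain * (zone-mean true HF chargeability) * V_rz *
    lognormal(0, sigma) + intercept.  Rank order of the noise-free masses
    equals the rank order of the true zone chargeability.
    """
    grid = scene.stack.grid
    rng = np.random.default_rng([scene.config.seed, 1])
    records: list[PlantRecord] = []
    scene.true_rbd = {}
    for pl in scene.config.plants:
        probe = PlantRecord(pl.plant_id, pl.species, pl.stem_x, 0.0)
        zone = select_zone(grid, probe, width=pl.width, depth=pl.depth)
        w = np.array([grid.volume[grid.index_of(c)] for c in zone.cell_ids])
        mhf = np.array([scene.true_root_hf_chargeability(c) for c in zone.cell_ids])
        mhf_mean = float(np.dot(w, mhf) / w.sum())
        noise = float(np.exp(rng.normal(0.0, coupling.sigma))) if coupling.sigma else 1.0
        mass = coupling.gain * mhf_mean * zone.v_rz * noise + coupling.intercept
        records.append(PlantRecord(pl.plant_id, pl.species, pl.stem_x, mass))
        scene.true_rbd[pl.plant_id] = mass / zone.v_rz
    scene.plants = records
    return records


def halfspace_impedances(
    spectrum: ComplexSpectrum, scheme: MeasurementScheme
) -> ImpedanceDataset:
    """Transfer impedances of a homogeneous half-space: Z = rho(omega)/K."""
    ks = np.array([c.k for c in scheme.configs])
    z = spectrum.rho[None, :] / ks[:, None]
    return ImpedanceDataset(scheme, spectrum.grid.frequencies, z)


def maize_scene_config(
    seed: int = 0,
    n_plants: int = 8,
    noise: bool = True,
    sigma_rbd: float = 0.25,
) -> SceneConfig:
    """Default maize phenotyping scene: 8 plants at 0.75 m row spacing with
    per-plant root-system strength drawn once from the seed."""
    rng = np.random.default_rng([seed, 2])
    plants = []
    for i in range(n_plants):
        # field maize root mass varies severalfold between neighbouring plants
        scale = float(rng.uniform(0.15, 1.0))
        plants.append(
            PlantAnomaly(
                plant_id=f"maize_{i + 1}",
                species="maize",
                stem_x=0.60 + 0.75 * i,
                terms=tuple(maize_terms(scale)),
            )
        )
    return SceneConfig(
        plants=tuple(plants),
        coupling=RbdCoupling(sigma=sigma_rbd),
        error_model=ErrorModel() if noise else None,
        seed=seed,
    )


def mixed_scene_config(
    timestep: str = "t2", seed: int = 0, noise: bool = True
) -> SceneConfig:
    """Season-snapshot scene: 4 maize plants (left) and 4 sugar beets (right)
    on a 9.75 m profile, emulating one survey timestep."""
    rng = np.random.default_rng([seed, 3])
    plants = []
    for i in range(4):
        plants.append(
            PlantAnomaly(
                f"maize_{i + 1}",
                "maize",
                1.00 + 0.75 * i,
                tuple(maize_terms(float(rng.uniform(0.5, 1.0)))),
            )
        )
    for i in range(4):
        plants.append(
            PlantAnomaly(
                f"beet_{i + 1}",
                "sugar_beet",
                6.00 + 0.40 * i,
                tuple(beet_terms(timestep, float(rng.uniform(0.6, 1.0)))),
            )
        )
    cfg = SceneConfig(
        nx=195,
        plants=tuple(plants),
        error_model=ErrorModel() if noise else None,
        seed=seed,
    )
    return cfg


def scene_noise_free(config: SceneConfig) -> SceneConfig:
    return replace(config, error_model=None)
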