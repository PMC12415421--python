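"""Readers and writers for the pipeline's tabular text formats.

All tables are plain delimited text (CSV) with a mandatory header; units are
encoded in column names.  Phases are stored in mrad on disk (the field's
display unit) and converted to radians on read.  Output tables carry the
run-configuration hash as a leading ``#`` comment line.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quality import ErrorModel
from .scheme import ElectrodeArray, MeasurementScheme
from .spectra import CellGrid, ComplexSpectrum, FrequencyGrid, TomogramStack
from .traits import PlantRecord

__all__ = [
    "RunConfig",
    "read_spectra",
    "write_spectra",
    "read_plants",
    "write_plants",
    "write_scheme",
    "read_scheme_table",
    "write_table",
]

SPECTRA_COLUMNS = [
    "cell_id",
    "x_m",
    "z_m",
    "volume_m3",
    "frequency_hz",
    "rho_mag_ohmm",
    "phase_mrad",
]
PLANT_COLUMNS = ["plant_id", "species", "x_m", "fresh_root_mass_kg", "offset_flag"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the standard field settings."""

    f_lf: float = 3.125  # Hz, ERI low-frequency bound
    f_hf: float = 1000.0  # Hz, ERI high-frequency bound
    f_max_restricted: float = 55.0  # Hz, low-frequency decomposition cap
    f_max_inverted: float = 1000.0  # Hz, upper analysis bound
    error: ErrorModel = field(default_factory=ErrorModel)
    d_mode: str = "fixed"  # or "half_std"
    positive_phase_mrad: float = 5.0
    sigma_k: float = 3.0
    max_abs_k: float = 5.0
    tau_points_per_decade: int = 20
    zone_width: float = 0.20
    zone_depth: float = 0.25
    soil_z_range: tuple = (0.50, 1.00)
    diffusion: float = 1e-9  # m^2/s
    seed: int = 0
    fit_scope: str = "zones"  # "zones" (root + soil zones) or "all" cells

    def __post_init__(self) -> None:
        if self.f_lf >= self.f_hf:
            raise ValueError("f_lf must be below f_hf")
        if self.zone_width <= 0 or self.zone_depth <= 0:
            raise ValueError("zone dimensions must be positive")
        if self.d_mode not in ("fixed", "half_std"):
            raise ValueError("d_mode must be 'fixed' or 'half_std'")

    def hash(self) -> str:
        payload = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        em = raw.pop("error", None)
        cfg = cls(**raw)
        if em is not None:
            cfg.error = ErrorModel(**em)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True))


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_spectra(stack: TomogramStack, path, config_hash: str | None = None) -> None:
    grid = stack.grid
    freqs = stack.frequency_grid.frequencies
    rows = []
    for i, cid in enumerate(grid.cell_ids):
        s = stack.spectra[i]
        for j, f in enumerate(freqs):
            rows.append(
                (cid, grid.x[i], grid.z[i], grid.volume[i], f, s.magnitude[j],
                 s.phase[j] * 1e3)
            )
    df = pd.DataFrame(rows, columns=SPECTRA_COLUMNS)
    write_table(df, path, config_hash)


def read_spectra(path) -> TomogramStack:
    """Read a spectra table into a tomogram stack.

    Frequencies may appear in any order (they are sorted); validation errors
    name the offending rows.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra table is missing columns: {missing}")
    bad = df.index[df["rho_mag_ohmm"] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive resistivity magnitude in rows {bad.tolist()[:5]}"
        )
    dup = df.duplicated(subset=["cell_id", "frequency_hz"])
    if dup.any():
        raise ValueError(
            f"duplicate (cell, frequency) pairs in rows {df.index[dup].tolist()[:5]}"
        )
    df = df.sort_values(["cell_id", "frequency_hz"], kind="stable")
    first = df.groupby("cell_id", sort=True).first()
    cell_ids = first.index.to_numpy()
    grid = CellGrid(
        cell_ids,
        first["x_m"].to_numpy(),
        first["z_m"].to_numpy(),
        first["volume_m3"].to_numpy(),
    )
    fgrid = None
    spectra = []
    for cid in cell_ids:
        sub = df[df["cell_id"] == cid]
        freqs = sub["frequency_hz"].to_numpy()
        if fgrid is None:
            fgrid = FrequencyGrid(freqs)
        elif not np.array_equal(freqs, fgrid.frequencies):
            raise ValueError(f"cell {cid!r} has a different frequency grid")
        spectra.append(
            ComplexSpectrum(
                fgrid,
                sub["rho_mag_ohmm"].to_numpy(),
                sub["phase_mrad"].to_numpy() * 1e-3,
            )
        )
    return TomogramStack(grid, spectra)


def write_plants(plants: list, path, config_hash: str | None = None) -> None:
    df = pd.DataFrame(
        [(p.plant_id, p.species, p.stem_x, p.fresh_root_mass, int(p.offset_flag))
         for p in plants],
        columns=PLANT_COLUMNS,
    )
    write_table(df, path, config_hash)


def read_plants(path) -> list:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PLANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plant table is missing columns: {missing}")
    return [
        PlantRecord(
            str(r.plant_id), r.species, float(r.x_m), float(r.fresh_root_mass_kg),
            bool(r.offset_flag),
        )
        for r in df.itertuples()
    ]


def write_scheme(scheme: MeasurementScheme, path) -> None:
    lines = [
        f"# electrode array: n={scheme.array.n}, "
        f"{len(scheme.injections)} injections, {len(scheme)} configurations",
        "A,B,M,N,K_m",
    ]
    for c in scheme.configs:
        lines.append(f"{c.a},{c.b},{c.m},{c.n},{c.k:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_electrodes(path) -> ElectrodeArray:
    """Electrode file: columns x_m, z_m (header mandatory)."""
    df = pd.read_csv(path, comment="#")
    return ElectrodeArray(df[["x_m", "z_m"]].to_numpy())


def read_injections(path) -> list:
    """Injection file: columns A, B, ordered as acquired."""
    df = pd.read_csv(path, comment="#")
    return [(int(a), int(b)) for a, b in zip(df["A"], df["B"])]
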