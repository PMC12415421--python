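"""End-to-end trait-extraction pipeline over a tomogram spectra table.

Stage order mirrors field processing: per-cell Debye decomposition (full band
and low-frequency-restricted for sugar beet), per-cell ERI, root-zone
volume-weighted aggregation, root biomass density, Schwarz length scales and
trait correlations.  All outputs are deterministic given the configuration;
every table carries the configuration hash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .debye import fit_debye
from .io import RunConfig, write_table
from .spectra import TomogramStack
from .traits import (
    PlantRecord,
    eri_map,
    pearson,
    rbd,
    schwarz_diameter,
    select_zone,
    soil_reference_zone,
    zone_weighted_mean,
)

log = logging.getLogger("rootsip")

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    config: RunConfig
    config_hash: str
    fits: pd.DataFrame
    eri: pd.DataFrame
    traits: pd.DataFrame
    correlations: pd.DataFrame
    soil_reference: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = self.config_hash
        write_table(self.fits, outdir / "debye_fits.csv", h)
        write_table(self.eri, outdir / "eri_map.csv", h)
        write_table(self.traits, outdir / "traits.csv", h)
        write_table(self.correlations, outdir / "correlations.csv", h)
        self.config.to_yaml(outdir / "config.yaml")


def _fit_cells(stack: TomogramStack, cell_ids, config: RunConfig, f_max: float):
    out = {}
    for cid in cell_ids:
        s = stack.spectrum(cid)
        out[cid] = fit_debye(
            s,
            error_model=config.error,
            points_per_decade=config.tau_points_per_decade,
            f_max=f_max,
        )
    return out


def run_pipeline(
    config: RunConfig, stack: TomogramStack, plants: list[PlantRecord]
) -> PipelineReport:
    """Run decomposition, ERI and trait extraction; returns all result tables."""
    h = config.hash()
    grid = stack.grid
    log.info("pipeline start: %d cells, %d plants, config %s", len(grid), len(plants), h)

    zones = {p.plant_id: select_zone(grid, p, config.zone_width, config.zone_depth)
             for p in plants}
    maize_x = [p.stem_x for p in plants if p.species == "maize"]
    soil_zone = None
    if maize_x:
        soil_zone = soil_reference_zone(
            grid, min(maize_x) - config.zone_width / 2,
            max(maize_x) + config.zone_width / 2, config.soil_z_range,
        )

    # Debye decompositions: full band everywhere needed; low-frequency
    # restricted fits for sugar-beet zones (slow storage-cell process)
    if config.fit_scope == "all":
        fit_ids = list(grid.cell_ids)
    else:
        fit_ids = sorted(
            {cid for z in zones.values() for cid in z.cell_ids}
            | (set(soil_zone.cell_ids) if soil_zone else set())
        )
    full_fits = _fit_cells(stack, fit_ids, config, config.f_max_inverted)
    beet_ids = sorted(
        {cid for p in plants if p.species == "sugar_beet"
         for cid in zones[p.plant_id].cell_ids}
    )
    lf_fits = _fit_cells(stack, beet_ids, config, config.f_max_restricted)
    log.info("decomposed %d cells (full), %d cells (restricted <= %g Hz)",
             len(full_fits), len(lf_fits), config.f_max_restricted)

    fit_rows = []
    for cid, f in full_fits.items():
        fit_rows.append((cid, f.rho0, f.m_tot, f.tau_mean, f.rms, f.f_max_used))
    for cid, f in lf_fits.items():
        fit_rows.append((cid, f.rho0, f.m_tot, f.tau_mean, f.rms, f.f_max_used))
    fits_df = pd.DataFrame(
        fit_rows,
        columns=["cell_id", "rho0_ohmm", "m_tot", "tau_mean_s", "rms", "f_max_hz"],
    )

    # per-cell ERI field
    eri_field = eri_map(stack, config.f_lf, config.f_hf)
    n_invalid = sum(1 for v in eri_field.values() if not np.isfinite(v))
    if n_invalid:
        log.info("ERI: %d cell(s) flagged invalid", n_invalid)
    eri_df = pd.DataFrame(
        [(cid, grid.x[i], grid.z[i], eri_field[cid])
         for i, cid in enumerate(grid.cell_ids)],
        columns=["cell_id", "x_m", "z_m", "eri"],
    )

    # per-plant traits
    trait_rows = []
    for p in plants:
        zone = zones[p.plant_id]
        mag_lf = {
            cid: float(np.abs(stack.spectrum(cid).rho[0])) for cid in zone.cell_ids
        }
        mean_mag = zone_weighted_mean(mag_lf, zone, grid)
        m_map = {cid: full_fits[cid].m_tot for cid in zone.cell_ids}
        mean_m = zone_weighted_mean(m_map, zone, grid)
        if p.species == "sugar_beet":
            tau_src = lf_fits
        else:
            tau_src = full_fits
        tau_map = {cid: tau_src[cid].tau_mean for cid in zone.cell_ids}
        mean_tau = zone_weighted_mean(tau_map, zone, grid)
        mean_eri = zone_weighted_mean(eri_field, zone, grid)
        diam = schwarz_diameter(mean_tau, config.diffusion) if mean_tau > 0 else np.nan
        trait_rows.append(
            (p.plant_id, p.species, mean_mag, mean_m, mean_tau, mean_eri,
             rbd(p, zone), diam)
        )
    traits_df = pd.DataFrame(
        trait_rows,
        columns=["plant_id", "species", "mean_rho_mag_ohmm", "mean_m_tot",
                 "mean_tau_s", "mean_eri", "rbd_kg_m3", "cell_diameter_m"],
    )

    # trait correlations per species
    corr_rows = []
    for species, xcol in (
        ("sugar_beet", "mean_rho_mag_ohmm"),
        ("sugar_beet", "mean_m_tot"),
        ("maize", "mean_eri"),
    ):
        sub = traits_df[traits_df.species == species]
        if len(sub) >= 3 and sub[xcol].notna().all():
            try:
                r, pval = pearson(sub[xcol], sub["rbd_kg_m3"])
            except ValueError:
                continue
            corr_rows.append((species, xcol, "rbd_kg_m3", r, pval, len(sub)))
    corr_df = pd.DataFrame(
        corr_rows, columns=["species", "x", "y", "pearson_r", "p_value", "n"]
    )

    soil_ref = {}
    if soil_zone is not None:
        soil_ref = {
            "mean_eri": zone_weighted_mean(eri_field, soil_zone, grid),
            "n_cells": len(soil_zone.cell_ids),
        }

    log.info("pipeline done: %d plants, %d correlations", len(plants), len(corr_df))
    return PipelineReport(config, h, fits_df, eri_df, traits_df, corr_df, soil_ref)
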