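#!/usr/bin/env python
"""Generate the synthetic field scenes for the three survey timesteps plus
the maize phenotyping scene, and write their spectra/plant/truth tables.

Each mixed scene emulates one seasonal snapshot of a maize / sugar-beet
profile; the maize scene is the 8-plant layout used for the ERI-phenotyping
analysis.  Outputs go to results/scenes/<name>/.
"""

from pathlib import Path

import pandas as pd

from rootsip.io import write_plants, write_spectra, write_table
from rootsip.synthetic import build_scene, maize_scene_config, mixed_scene_config

OUT = Path(__file__).resolve().parent.parent / "results" / "scenes"
SEED = 0


def dump(scene, name: str) -> None:
    d = OUT / name
    d.mkdir(parents=True, exist_ok=True)
    write_spectra(scene.stack, d / "spectra.csv")
    write_plants(scene.plants, d / "plants.csv")
    truth = pd.DataFrame(
        [
            (cid, scene.truth_rho0[cid], scene.true_m_tot(cid),
             scene.true_root_hf_chargeability(cid))
            for cid in scene.stack.grid.cell_ids
        ],
        columns=["cell_id", "rho0_ohmm", "m_tot_true", "m_hf_root_true"],
    )
    write_table(truth, d / "truth_cells.csv")
    write_table(
        pd.DataFrame(sorted(scene.true_rbd.items()),
                     columns=["plant_id", "true_rbd_kg_m3"]),
        d / "truth_rbd.csv",
    )
    n_cells = len(scene.stack.grid)
    print(f"  {name}: {n_cells} cells, {len(scene.plants)} plants -> {d}")


def main() -> None:
    print(f"simulating scenes (seed {SEED})")
    for timestep in ("t1", "t2", "t3"):
        dump(build_scene(mixed_scene_config(timestep, seed=SEED)), timestep)
    dump(build_scene(maize_scene_config(seed=SEED)), "maize")


if __name__ == "__main__":
    main()
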