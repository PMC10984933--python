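#!/usr/bin/env python
"""Generate the synthetic study inputs with ground truth.

Writes calibrated 2-D particle masks at three designed aggregate
fractions (10 %, 20 %, 30 % of cells+aggregates; two fields each) and
one two-channel 3-D biofilm stack (colonies geometry, designed EPS/cell
ratio 0.8, snr 5) under results/fixtures/, with truth tables and a
manifest recording every parameter and seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ecmquant.synthetic import (  # noqa: E402
    Scene3DParams,
    generate_biofilm_stack,
    generate_particle_scene,
    scene_params_for_fraction,
    write_fixtures,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main():
    scenes2d = []
    for g, frac in enumerate((0.10, 0.20, 0.30)):
        for j in range(2):
            p = scene_params_for_fraction(frac, seed=SEED + 100 * g + j)
            scenes2d.append(generate_particle_scene(p))
    stack = generate_biofilm_stack(
        Scene3DParams(target_ratio=0.8, overlap_fraction=0.2, seed=SEED)
    )
    manifest = write_fixtures(OUT, scenes2d=scenes2d, scenes3d=[stack])
    print(f"wrote {len(manifest['scenes2d'])} 2-D scenes and "
          f"{len(manifest['scenes3d'])} 3-D stack(s) to {OUT}")
    truth = stack[2]
    print(f"3-D truth: cell {truth.cell_volume:.1f} µm³, "
          f"EPS {truth.eps_volume:.1f} µm³, overlap {truth.overlap_volume:.1f} µm³, "
          f"mean thickness {truth.mean_thickness:.2f} µm")


if __name__ == "__main__":
    main()
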