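#!/usr/bin/env python
"""Generate the synthetic field campaign.

Writes one CSV suite (spectra, PAR, fluorescence, pigments, biomass,
morphometrics, truth) per patch density class under
results/simulated/<class>/.  The moderate-density suite carries the
plant-level sampling; all four classes carry the optical profiles.

Default noise reflects the campaign (5% spectral/fluorescence, 25%
between-leaf trait variation); pass --noiseless for exact round-trip
inputs.
"""

import argparse
from pathlib import Path

from canopylight.synthetic import Scenario, write_scenario_csvs

DENSITIES = ("open_water", "low", "moderate", "high")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    ap.add_argument("--noiseless", action="store_true")
    args = ap.parse_args()

    for density in DENSITIES:
        sc = Scenario(density_class=density, seed=args.seed)
        if args.noiseless:
            sc = sc.noiseless()
        paths = write_scenario_csvs(sc, args.out / density)
        print(f"{density}: {len(paths)} files under {args.out / density}")


if __name__ == "__main__":
    main()
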