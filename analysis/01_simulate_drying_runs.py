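#!/usr/bin/env python
"""Generate the synthetic weighing series for all five drying temperatures.

The raw weighing curves behind the reference study were not deposited, so
the analysis starts from synthetic series that follow the study's fitted
logarithmic drying curves, its weighing cadence (every 20 min in the
first hour, every 30 min for two hours, hourly until three constant
weighings) and its final moisture contents, with Gaussian measurement
noise of sd 0.01 on the moisture ratio.

Writes one weighing-series CSV per temperature under results/runs/.
"""

import sys
from pathlib import Path

from foamdry.drying import write_weighing_series
from foamdry.synthetic import SyntheticConfig, generate_run

OUT = Path(__file__).resolve().parent.parent / "results" / "runs"


def main(seed: int = 42) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(noise_sd=0.01, seed=seed)
    print(f"seed {seed}, MR noise sd {config.noise_sd}, "
          f"dry mass {config.dry_mass} g, tare {config.tare_mass} g")
    for T in sorted(config.params_by_temp):
        series, _ = generate_run(config, T)
        path = OUT / f"run_{int(T)}C.csv"
        write_weighing_series(series, path)
        print(f"  {T:g} °C: {len(series.times)} weighings over "
              f"{series.times[-1]:g} min -> {path.name}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
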