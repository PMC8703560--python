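"""Monte-Carlo check of the synthetic-weather presets.

Simulates many days per preset and prints the empirical daily-light-
integral mean and standard deviation next to the preset's calibration
targets.  Used to choose the frozen cloud parameters in
greenlight.synthetic_weather; re-run after any preset change.

Usage: python scripts/calibrate_weather.py [--days 1000] [--seed 0]
"""

import argparse

import numpy as np

from greenlight.phytomodel import integral_over_day
from greenlight.synthetic_weather import PRESETS, generate_days


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--days", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    for name, preset in PRESETS.items():
        trace = generate_days(preset, args.days, seed=args.seed)
        dli = np.array(
            [integral_over_day(trace.day(d), trace.step_seconds) for d in range(trace.n_days)]
        )
        print(
            f"{name:15s} DLI mean {dli.mean():6.3f} (target {preset.target_dli_mean:5.2f})  "
            f"sd {dli.std(ddof=1):6.3f} (target {preset.target_dli_sd:5.2f})  "
            f"min {dli.min():6.3f} max {dli.max():6.3f}"
        )


if __name__ == "__main__":
    main()
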