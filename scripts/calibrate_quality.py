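#!/usr/bin/env python
"""Quality-gate calibration report.

Renders a seeded suite of clean scenes and their five degraded variants,
prints the distribution of each quality measurement per condition and the
flags fired under the current config, so the frozen default thresholds can
be audited or re-derived after a generator change.

Usage:  python scripts/calibrate_quality.py [--seed 30] [--n 8]
"""

from __future__ import annotations

import argparse
import collections

import numpy as np

from fundusdr.config import RunConfig
from fundusdr.grading import assess_quality
from fundusdr.pipeline import preprocess_scene
from fundusdr.synthetic import DEGRADE_MODES, LesionLoad, SceneSpec, degrade, render_scene


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=30)
    ap.add_argument("--n", type=int, default=8)
    ap.add_argument("--severity", type=float, default=0.5)
    args = ap.parse_args()
    cfg = RunConfig()

    measurements = collections.defaultdict(list)
    flags = collections.defaultdict(collections.Counter)
    for seed in range(args.seed, args.seed + args.n):
        image, _ = render_scene(
            SceneSpec(
                seed=seed,
                lesion_loads={"hemorrhage": LesionLoad((2, 5), (50.0, 400.0), 0.85)},
            )
        )
        variants = [("clean", image)]
        variants += [(m, degrade(image, m, args.severity, seed=seed)) for m in DEGRADE_MODES]
        for name, im in variants:
            prep = preprocess_scene(im, cfg)
            q = assess_quality(im, prep.roi, prep.disc, cfg)
            measurements[name].append(
                [q.fuzzy_score, q.dark_fraction, q.saturated_fraction, q.eyelash_score, q.decenter_px]
            )
            flags[name]["|".join(sorted(q.flags)) or "(qualified)"] += 1

    cols = ["fuzzy", "dark_frac", "sat_frac", "eyelash", "decenter_px"]
    print(f"{'condition':<12}" + "".join(f"{c:>22}" for c in cols))
    for name, rows in measurements.items():
        arr = np.asarray(rows)
        cells = [f"{arr[:, j].min():.3g}..{arr[:, j].max():.3g}" for j in range(arr.shape[1])]
        print(f"{name:<12}" + "".join(f"{c:>22}" for c in cells))
    print("\nflags fired:")
    for name, counter in flags.items():
        print(f"  {name:<12} {dict(counter)}")
    print(
        "\nthresholds: fuzzy>="
        f"{cfg.fuzzy_min_score}, dark<={cfg.dark_max_fraction}, "
        f"sat<={cfg.saturated_max_fraction}, eyelash<={cfg.eyelash_max_score}, "
        f"decenter<={cfg.decenter_max_px}px"
    )


if __name__ == "__main__":
    main()
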