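#!/usr/bin/env python
"""Attractor cascade of the periodically forced aggressive tumor.

Host-directed dose D(t) = D(1 - cos(omega t)) applied to the
tumor-dominant benchmark: near the characteristic frequency the
system settles on a period-1 limit cycle (tumor and host oscillate,
neither extinct); as omega grows, the oscillation amplitude falls
monotonically and the cycle shrinks into the small high-frequency
attractor.

Writes results/periodic_scan.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lvtumor as lv

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    entry = lv.fixtures()["regime4_forced"]
    omegas = sorted({1.0 / 14.0, 0.2, 0.7, 2.0, 6.0, 20.0, 60.0})
    tab = lv.amplitude_vs_frequency(
        (0.5, 0.5),
        omegas,
        params=entry["kinetics"],
        D=entry["D"],
        beta_y=entry["beta_y"],
        min_transient_time=1200.0,
    )
    tab.to_csv(RESULTS / "periodic_scan.csv", index=False)
    print(tab.to_string(index=False))
    assert np.all(np.diff(tab["amplitude_y"]) < 0)
    print("\nHost-oscillation amplitude decreases monotonically with omega;")
    print("the low-frequency limit cycle (controlled coexistence) gives way")
    print("to a point-like attractor at high forcing frequency.")


if __name__ == "__main__":
    main()
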