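#!/usr/bin/env python
"""Error control and power of the combined correction.

Two simulation studies: (a) family-wise error of the min(RFT, FDR)
threshold over 200 null cohorts (n=100, 1,000-vertex patch, smooth
0.3 mm noise); (b) recovery of the planted sex effect (0.5 mm peak) at
the study sample size n=287 over 10 seeds.  Writes
results/error_control.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casm.validation import (                        # noqa: E402
    effect_recovery_experiment,
    null_fwer_experiment,
)

OUT = ROOT / "results"


def main():
    OUT.mkdir(exist_ok=True)
    fwer = null_fwer_experiment(n_replicates=200, n_subjects=100,
                                n_vertices=1000, seed=1)
    rec = effect_recovery_experiment(n_seeds=10, n_subjects=287,
                                     n_vertices=1000, seed=1)
    out = {"null_fwer": fwer, "effect_recovery": rec}
    (OUT / "error_control.json").write_text(json.dumps(out, indent=1))
    print(f"empirical FWER {fwer['fwer']:.3f} over {fwer['n_replicates']} "
          f"null cohorts (binomial bound {fwer['bound']:.3f})")
    print(f"sex-effect recovery at n=287: median beta/truth correlation "
          f"{rec['median_correlation']:.3f}, median coverage of the "
          f"strongly-affected region {rec['median_overlap']:.2f}")


if __name__ == "__main__":
    main()
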