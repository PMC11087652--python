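#!/usr/bin/env python
"""Statistical validation summary of the whole pipeline.

Re-runs the validation studies (oracle equivalence, permutation
calibration, planted-effect recovery, influence directionality, graph
closed forms, behavioral layer, determinism) and writes
results/validation.json.  This is the same battery the test suite
asserts on; here it is reported as numbers for the record.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS

from converse_align import validation as val

SEED = 7


def main():
    out = {
        "oracle": val.ols_oracle_equivalence(seed=SEED),
        "permutation_calibration": val.permutation_calibration(
            seed=SEED, n_perm=1000),
        "permutation_exhaustive": val.permutation_exhaustive_agreement(
            seed=SEED),
        "effect_recovery": val.effect_recovery(seed=SEED, n_seeds=50),
        "influence": val.influence_directionality(seed=SEED),
        "graph_metrics": val.graph_metric_checks(seed=SEED),
        "behavior": val.behavioral_checks(seed=SEED),
        "determinism": val.pipeline_determinism(seed=SEED),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "validation.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    print(json.dumps(out, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
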