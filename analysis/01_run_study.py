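#!/usr/bin/env python
"""Run the full benchmark study: simulate, weight, estimate associations.

Writes weights.csv, associations.csv, oracle_associations.csv, ess.json,
manifest.json and config.yaml to results/study/. Takes roughly five minutes
at the default population size of 500 000.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from volunteerbias.config import RunConfig
from volunteerbias.pipeline import run_pipeline


def main() -> None:
    cfg = RunConfig(seed=1, out_dir="results/study")
    result = run_pipeline(cfg)
    print(json.dumps(result.manifest, indent=2, default=str))
    for name, path in result.artifacts.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
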