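#!/usr/bin/env python
"""Cost comparison of tiered genetic-testing strategies.

Panel-first (gene panel for everyone, exome only after a negative panel)
versus WES-only, at equal diagnostic yield, over the patients who
completed testing. Prices are per trio; counts come from the triage
tallies. Writes results/cost.
"""

import argparse
import json
from pathlib import Path

from crsexome.config import RunConfig
from crsexome.workflow import cost_block


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    tallies = json.loads(
        (args.results_dir / "triage" / "tallies.json").read_text())
    cfg = RunConfig()
    block = cost_block(tallies, cfg)

    out = args.results_dir / "cost"
    out.mkdir(parents=True, exist_ok=True)
    (out / "cost.json").write_text(
        json.dumps(block, indent=1, sort_keys=True) + "\n")

    print(f"evaluated patients: {block['n_evaluated']}")
    print("strategy      panel_pos   wes_pos   both_neg      total  per-trio")
    for name in ("panel_first", "wes_only"):
        b = block[name]
        print(f"{name:<12} {b['panel_pos']:>10.0f} {b['wes_pos']:>9.0f} "
              f"{b['both_neg']:>10.0f} {b['total']:>10.0f} "
              f"{b['per_trio']:>9.0f}")
    s = block["savings"]
    print(f"panel-first saves ${s['absolute_per_trio']:.0f} per trio "
          f"({s['percent_saved']}%) versus WES-only")


if __name__ == "__main__":
    main()
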