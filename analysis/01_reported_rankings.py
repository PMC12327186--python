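#!/usr/bin/env python
"""Rebuild the geometric-mean consensus from the published per-method orderings.

For each condition (motility, morphology) the four algorithms' printed
stability listings are converted to competition-rank vectors and aggregated.
Finding: all seven motility consensus values and six of seven morphology
values match the published figures exactly; the morphology U6 value is the
single known discrepancy (3.66 recomputed vs 3.63 published).

Writes results/reported_consensus.csv and results/reported_consensus.json.
"""

import json
from pathlib import Path

import pandas as pd

from refmirna import run_reported_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    report = run_reported_fixture()
    rows = []
    for condition, block in report.items():
        print(f"[{condition}] most stable: {block['best']}")
        for rank, cand in enumerate(block["order"], start=1):
            row = block["values"][cand]
            note = "known discrepancy" if row["known_discrepancy"] else ""
            print(
                f"  {rank}. {cand:12s} computed {row['display']:.2f} "
                f"reported {row['reported']:.2f} {note}"
            )
            rows.append({"condition": condition, "rank": rank, "candidate": cand, **row})
    pd.DataFrame(rows).to_csv(OUT / "reported_consensus.csv", index=False)
    (OUT / "reported_consensus.json").write_text(json.dumps(report, indent=2))
    n_match = sum(r["match"] for r in rows)
    print(f"\n{n_match}/{len(rows)} consensus values reproduced exactly.")


if __name__ == "__main__":
    main()
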