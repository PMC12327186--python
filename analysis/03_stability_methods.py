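#!/usr/bin/env python
"""Run all four stability algorithms plus the consensus on the simulated cohort.

Reads results/sim/ (produced by 02_simulate_cohort.py; regenerated here if
missing), writes per-method score CSVs, the geNorm trace, the NormFinder
decomposition and consensus.csv under results/stability/, and prints how
well the consensus order tracks the ground-truth disorder order.
"""

import json
from pathlib import Path

from scipy import stats

from refmirna import RunConfig, run_stability

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "stability"


def main() -> None:
    if not (SIM / "ct.csv").exists():
        from refmirna import SimSpec, simulate_ct, write_ct_table

        SIM.mkdir(parents=True, exist_ok=True)
        table, truth = simulate_ct(SimSpec(seed=20240917))
        write_ct_table(table, SIM / "ct.csv", SIM / "metadata.csv")
        (SIM / "truth.json").write_text(json.dumps(truth, indent=2))
    cfg = RunConfig(
        ct_path=str(SIM / "ct.csv"),
        metadata_path=str(SIM / "metadata.csv"),
        out_dir=str(OUT),
        seed=20240917,
    )
    result = run_stability(cfg)
    cons = result["consensus"]
    print("consensus ranking (most stable first):")
    print(cons.to_string(index=False))

    truth = json.loads((SIM / "truth.json").read_text())
    disorder = dict(zip(truth["candidates"], truth["disorder"]))
    rho = stats.spearmanr(
        [disorder[c] for c in cons["candidate"]], cons["rank"]
    ).statistic
    print(f"\nSpearman(consensus rank, true disorder) = {rho:.3f}")


if __name__ == "__main__":
    main()
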