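"""Orchestration: run all stability methods plus the consensus on one table
and write the standard CSV/JSON result bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .consensus import DEFAULT_TIE_TOLERANCE, consensus_from_scores
from .ct_io import CtTable, load_ct_table
from .errors import ContractError
from .normfinder import normfinder_decompose, normfinder_stability
from .pairwise import delta_ct_stability, genorm_rank, genorm_v, pairwise_sd
from .bestkeeper import bestkeeper_index, bestkeeper_stats
from .reported import KNOWN_DISCREPANCIES, REPORTED_CONSENSUS, reported_consensus
from .simulate import METHODS

log = logging.getLogger("refmirna")


def _pkg_version() -> str:
    try:
        return version("refmirna")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Resolved configuration for one stability run."""

    ct_path: str = ""
    metadata_path: str = ""
    out_dir: str = "results"
    condition: str = ""
    methods: tuple[str, ...] = METHODS
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE
    test_variant: str = "student"
    dialect: str = "wide"
    seed: int = 0
    verbosity: int = 0

    _KNOWN = {
        "ct_path", "metadata_path", "out_dir", "condition", "methods",
        "tie_tolerance", "test_variant", "dialect", "seed", "verbosity",
    }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - cls._KNOWN
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        if isinstance(cfg.methods, (list, tuple)):
            cfg.methods = tuple(cfg.methods)
        for m in cfg.methods:
            if m not in METHODS:
                raise ContractError(f"unknown method {m!r}; choose from {METHODS}")
        return cfg


def _score_frame(score: pd.Series, method: str, condition: str) -> pd.DataFrame:
    ordered = score.sort_values(kind="mergesort")
    return pd.DataFrame(
        {
            "candidate": ordered.index,
            "stability": ordered.to_numpy(),
            "rank": ordered.rank(method="min").astype(int).to_numpy(),
            "method": method,
            "condition": condition,
        }
    )


def run_stability(config: RunConfig, table: CtTable | None = None) -> dict:
    """Run the configured methods + consensus; write the result bundle.

    Returns a dict with the per-method score frames, the consensus frame
    and the paths written.  ``table`` may be passed directly (e.g. a
    synthetic table); otherwise it is loaded from the configured paths.
    """
    if table is None:
        table = load_ct_table(
            config.ct_path, config.metadata_path, dialect=config.dialect
        )
    condition = config.condition or table.condition
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    scores: dict[str, pd.Series] = {}
    genorm_ranks = None

    for method in config.methods:
        if method == "delta_ct":
            scores["delta_ct"] = delta_ct_stability(pairwise_sd(table))
        elif method == "genorm":
            trace = genorm_rank(table)
            genorm_ranks = trace.ranks()
            v_values = {
                f"V{n}/{n+1}": genorm_v(trace, table, n)
                for n in range(2, table.n_candidates)
            }
            trace_json = {
                "exclusion_order": trace.exclusion_order,
                "m_at_exclusion": trace.m_at_exclusion,
                "final_pair": list(trace.final_pair),
                "pairwise_variation": v_values,
            }
            path = out / "genorm_trace.json"
            path.write_text(json.dumps(trace_json, indent=2))
            written.append(str(path))
            scores["genorm"] = trace.stability()
        elif method == "normfinder":
            decomp = normfinder_decompose(table)
            scores["normfinder"] = normfinder_stability(decomp)
            path = out / "normfinder_decomposition.csv"
            decomp.to_frame().to_csv(path, index=False, float_format="%.6f")
            written.append(str(path))
        elif method == "bestkeeper":
            report = bestkeeper_stats(table)
            path = out / "bestkeeper.csv"
            report.to_csv(path, index=False, float_format="%.6f")
            written.append(str(path))
            idx_path = out / "bestkeeper_index.csv"
            bestkeeper_index(table).rename_axis("sample").reset_index().to_csv(
                idx_path, index=False, float_format="%.6f"
            )
            written.append(str(idx_path))
            scores["bestkeeper"] = pd.Series(
                report["mad"].to_numpy(), index=report["candidate"], name="stability"
            )

    frames: dict[str, pd.DataFrame] = {}
    for method, score in scores.items():
        frame = _score_frame(score, method, condition)
        if method == "genorm" and genorm_ranks is not None:
            # ranking comes from the exclusion order (final pair tied at 1),
            # not from re-sorting the recorded M values
            frame["rank"] = [int(genorm_ranks[c]) for c in frame["candidate"]]
            frame = frame.sort_values("rank", kind="mergesort").reset_index(drop=True)
        path = out / f"{method}.csv"
        frame.to_csv(path, index=False, float_format="%.6f")
        written.append(str(path))
        frames[method] = frame

    # geNorm contributes exclusion-order ranks; the other methods are
    # ranked from their stability values.
    rank_inputs = {m: s for m, s in scores.items() if m != "genorm"}
    cons = consensus_from_scores(
        rank_inputs,
        genorm_ranks=genorm_ranks,
        tie_tolerance=config.tie_tolerance,
    )
    cons_frame = cons.to_frame()
    cons_path = out / "consensus.csv"
    cons_frame.to_csv(cons_path, index=False, float_format="%.6f")
    written.append(str(cons_path))

    summary = {
        "version": _pkg_version(),
        "seed": config.seed,
        "condition": condition,
        "config": {**asdict(config), "methods": list(config.methods)},
        "consensus": {
            c: {"geomean": cons.geomean[c], "display": cons.display[c]}
            for c in cons.order
        },
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    written.append(str(summary_path))

    config_path = out / "run_config.json"
    config_path.write_text(json.dumps({**asdict(config), "methods": list(config.methods)}, indent=2))
    written.append(str(config_path))

    log.info("refmirna %s, seed %d, condition %r: wrote %d files to %s",
             summary["version"], config.seed, condition, len(written), out)
    return {"scores": frames, "consensus": cons_frame, "ranking": cons, "written": written}


def run_reported_fixture() -> dict:
    """Recompute the consensus from the packaged published orderings.

    Returns, per condition, the recomputed display values alongside the
    published ones and a match flag (U6/morphology is expected not to
    match and carries a note).
    """
    out: dict[str, dict] = {}
    for condition in ("motility", "morphology"):
        cons = reported_consensus(condition)
        reported = REPORTED_CONSENSUS[condition]
        discrepant = set(KNOWN_DISCREPANCIES[condition])
        rows = {}
        for cand in cons.candidates:
            rows[cand] = {
                "display": cons.display[cand],
                "reported": reported[cand],
                "match": abs(cons.display[cand] - reported[cand]) < 0.005,
                "known_discrepancy": cand in discrepant,
            }
        out[condition] = {
            "values": rows,
            "order": cons.order,
            "best": cons.order[0],
        }
    return out
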