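"""BestKeeper-style descriptive stability statistics.

Per candidate: n, min/max Ct, arithmetic and geometric mean Ct, the
"SD (+/- Cp)" implemented as the mean absolute deviation (MAD) from the
arithmetic mean, and CV as a percentage of the mean.  The BestKeeper index
is the per-sample geometric mean of candidate Cts; each candidate's
profile is correlated with the index (Pearson r, two-tailed p).

Candidates are ranked ascending by MAD; a consistency flag marks MAD <= 1
cycle.  r and CV are reported but do not determine the ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import CtTable
from .errors import ContractError, ValidationError


def bestkeeper_index(table: CtTable, subset: list[str] | None = None) -> pd.Series:
    """Per-sample geometric mean of Ct over ``subset`` (default: all candidates)."""
    if subset is not None and len(subset) == 0:
        raise ContractError("index subset must be non-empty")
    rows = (
        range(table.n_candidates)
        if subset is None
        else [table.candidates.index(c) for c in subset]
    )
    ct = table.ct[list(rows)]
    if np.any(ct <= 0):
        raise ValidationError("geometric mean undefined for non-positive Ct")
    index = np.exp(np.log(ct).mean(axis=0))
    return pd.Series(index, index=table.samples, name="index")


def bestkeeper_correlations(table: CtTable, index: pd.Series) -> pd.DataFrame:
    """Pearson r (and two-tailed p) between each candidate's Ct profile and the index.

    Zero-variance candidates (or a zero-variance index) get r = NaN with
    an ``r_defined = False`` flag instead of an error.
    """
    if table.n_samples < 3:
        raise ContractError("correlation needs >= 3 samples")
    idx = index.loc[table.samples].to_numpy()
    rows = []
    idx_degenerate = np.std(idx) == 0
    for i, cand in enumerate(table.candidates):
        y = table.ct[i]
        if idx_degenerate or np.std(y) == 0:
            rows.append({"candidate": cand, "r": np.nan, "p": np.nan, "r_defined": False})
            continue
        r, p = stats.pearsonr(y, idx)
        rows.append({"candidate": cand, "r": float(r), "p": float(p), "r_defined": True})
    return pd.DataFrame(rows)


def bestkeeper_stats(table: CtTable) -> pd.DataFrame:
    """Full per-candidate BestKeeper report plus ascending MAD rank.

    Columns: n, min, max, mean, geo_mean, mad, cv, consistent (MAD <= 1),
    r, p against the all-candidate index, and rank (1 = most stable).
    """
    if np.any(table.ct <= 0):
        raise ValidationError("BestKeeper requires positive Ct values")
    ct = table.ct
    n = table.n_samples
    mean = ct.mean(axis=1)
    mad = np.abs(ct - mean[:, None]).mean(axis=1)
    report = pd.DataFrame(
        {
            "candidate": table.candidates,
            "n": n,
            "min": ct.min(axis=1),
            "max": ct.max(axis=1),
            "mean": mean,
            "geo_mean": np.exp(np.log(ct).mean(axis=1)),
            "mad": mad,
            "cv": 100.0 * mad / mean,
            "consistent": mad <= 1.0,
        }
    )
    if n >= 3:
        corr = bestkeeper_correlations(table, bestkeeper_index(table))
        report = report.merge(corr, on="candidate")
    else:
        report["r"] = np.nan
        report["p"] = np.nan
        report["r_defined"] = False
    report["rank"] = report["mad"].rank(method="min").astype(int)
    return report


def bestkeeper_stability(table: CtTable) -> pd.Series:
    """MAD per candidate as the single stability value (ascending = more stable)."""
    report = bestkeeper_stats(table)
    return pd.Series(report["mad"].to_numpy(), index=report["candidate"], name="stability")
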