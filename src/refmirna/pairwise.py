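"""Pairwise Ct-difference stability: comparative delta-Ct and geNorm.

Both algorithms are built on the same kernel: for every unordered candidate
pair (i, j), the sample standard deviation (n-1 denominator) of the
per-sample Ct difference ``Ct_i(s) - Ct_j(s)``.  With amplification
efficiency fixed at E = 2, the SD of the log2 expression ratio used by
geNorm reduces exactly to this Ct-difference SD, so the full-panel geNorm
M value coincides with the comparative delta-Ct stability — a property the
test suite asserts on random tables.

The comparative delta-Ct stability of candidate i is the mean of its pair
SDs over all other candidates.  geNorm additionally ranks by stepwise
exclusion: the candidate with the highest M on the current subset is
removed (its M at that step is its reported stability) until two remain;
the final pair shares the final M and the top rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_io import CtTable
from .errors import ContractError

#: Tolerance within which two M values are considered tied during
#: stepwise exclusion; ties are broken lexicographically by candidate id.
M_TIE_EPS = 1e-12


def pairwise_sd(table: CtTable) -> pd.DataFrame:
    """Symmetric matrix of pair SDs: entry (i, j) = SD_s(Ct_i(s) - Ct_j(s)).

    Samples are pooled across groups within the condition.  The matrix is
    invariant under adding any per-sample constant to all candidates
    (shared loading cancels in the difference) and under per-candidate
    constants (an offset does not change an SD).
    """
    if table.n_samples < 2:
        raise ContractError("pairwise SD undefined for < 2 samples")
    ct = table.ct
    k = table.n_candidates
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sd = np.std(ct[i] - ct[j], ddof=1)
            out[i, j] = out[j, i] = sd
    return pd.DataFrame(out, index=table.candidates, columns=table.candidates)


def delta_ct_stability(matrix: pd.DataFrame) -> pd.Series:
    """Comparative delta-Ct stability: mean pair SD per candidate (ascending = more stable)."""
    k = matrix.shape[0]
    if k < 2:
        raise ContractError("need >= 2 candidates")
    values = (matrix.sum(axis=1)) / (k - 1)
    return values.rename("stability")


def genorm_m(table: CtTable, subset: list[str] | None = None) -> pd.Series:
    """geNorm M value for each candidate within ``subset`` (default: full panel).

    M_i = mean over j != i in the subset of SD_s(Ct_i - Ct_j), at fixed
    efficiency E = 2.
    """
    sub = table if subset is None else table.subset(subset)
    if sub.n_candidates < 2:
        raise ContractError("geNorm M needs a subset of >= 2 candidates")
    return delta_ct_stability(pairwise_sd(sub)).rename("m_value")


@dataclass
class GeNormTrace:
    """Record of the stepwise geNorm exclusion.

    ``exclusion_order`` lists candidates worst-first; ``m_at_exclusion``
    maps each candidate to the M computed on the subset present when it was
    excluded (the final two candidates share the final-step M).
    ``step_subsets`` stores the candidate subset at each exclusion step.
    """

    exclusion_order: list[str]
    m_at_exclusion: dict[str, float]
    final_pair: tuple[str, str]
    step_subsets: list[list[str]] = field(default_factory=list)

    def stability(self) -> pd.Series:
        return pd.Series(self.m_at_exclusion, name="stability")

    def ranks(self) -> pd.Series:
        """Competition ranks from the exclusion order: final pair tied at 1,
        then 3, 4, ... in reverse exclusion order."""
        ranks = {self.final_pair[0]: 1, self.final_pair[1]: 1}
        rank = 3
        for cand in reversed(self.exclusion_order):
            ranks[cand] = rank
            rank += 1
        return pd.Series(ranks, name="rank")


def genorm_rank(table: CtTable) -> GeNormTrace:
    """Stepwise geNorm ranking by iterative exclusion of the least stable candidate."""
    if table.n_candidates < 3:
        raise ContractError("stepwise geNorm needs >= 3 candidates")
    current = list(table.candidates)
    exclusion_order: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    step_subsets: list[list[str]] = []
    while len(current) > 2:
        step_subsets.append(list(current))
        m = genorm_m(table, current)
        worst_value = m.max()
        # ties within eps broken lexicographically for determinism
        tied = sorted(c for c in current if m[c] >= worst_value - M_TIE_EPS)
        worst = tied[0]
        m_at_exclusion[worst] = float(m[worst])
        exclusion_order.append(worst)
        current.remove(worst)
    step_subsets.append(list(current))
    final_m = genorm_m(table, current)
    a, b = sorted(current)
    m_at_exclusion[a] = float(final_m[a])
    m_at_exclusion[b] = float(final_m[b])
    return GeNormTrace(exclusion_order, m_at_exclusion, (a, b), step_subsets)


def _normalization_factor(table: CtTable, subset: list[str]) -> np.ndarray:
    """Per-sample geometric mean of relative quantities Q = 2**(minCt - Ct)."""
    rows = [table.candidates.index(c) for c in subset]
    q = 2.0 ** (table.ct[rows].min(axis=1, keepdims=True) - table.ct[rows])
    return np.exp(np.log(q).mean(axis=0))


def genorm_v(trace: GeNormTrace, table: CtTable, n: int) -> float:
    """geNorm pairwise variation V_{n/n+1}.

    SD over samples of log2(NF_n / NF_{n+1}), where NF_k is the per-sample
    geometric mean of relative quantities of the top-k ranked candidates.
    """
    k = table.n_candidates
    if not (2 <= n < k):
        raise ContractError(f"n must satisfy 2 <= n < {k}")
    order = list(trace.final_pair) + list(reversed(trace.exclusion_order))
    nf_n = _normalization_factor(table, order[:n])
    nf_n1 = _normalization_factor(table, order[: n + 1])
    return float(np.std(np.log2(nf_n / nf_n1), ddof=1))
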