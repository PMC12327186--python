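"""Synthetic Ct-table generator with known ground truth.

The generator emulates the study design every stability stage targets:
seven candidate assays measured by qPCR in two cohorts of five bulls,
in technical triplicates.  Each collapsed Ct value is

    Ct_igj = B_i + L_gj + delta_i * [g = 2] + eps_igj

with candidate baseline B_i (cycles), a per-sample loading effect
L_gj ~ N(0, tau^2) shared by all candidates within a sample (pipetting /
input-amount variation), an optional group shift delta_i applied to the
second group (a truly condition-dependent candidate), and candidate noise
eps_igj ~ N(0, sigma_i^2).  Technical replicates add independent
N(0, replicate_sd^2) read noise and are collapsed by arithmetic mean.

Ground truth: the disorder score sqrt(sigma_i^2 + delta_i^2 / 4) ranks
candidates from most to least stable.  It is a documented surrogate for
"how much non-loading variation this candidate carries", not a claim about
any particular method's estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bestkeeper import bestkeeper_stability
from .consensus import ConsensusRanking, consensus_from_scores
from .ct_io import CtTable
from .errors import ContractError
from .normfinder import normfinder
from .pairwise import delta_ct_stability, genorm_rank, pairwise_sd

#: Methods the recovery experiment can run.
METHODS = ("delta_ct", "genorm", "normfinder", "bestkeeper")


@dataclass
class SimSpec:
    """Full parameterization of the synthetic Ct generator.

    Defaults mirror the emulated study scale: 7 candidates, two groups of
    5 samples, triplicates, baselines in the mid-Ct range, loading SD
    tau = 0.8 cycles and per-candidate noise between 0.1 and 1.5 cycles.
    """

    k: int = 7
    n_per_group: tuple[int, int] = (5, 5)
    group_labels: tuple[str, str] = ("High", "Low/Moderate")
    baselines: tuple[float, ...] | None = None   # drawn once in [18, 30] if None
    tau: float = 0.8                             # loading-effect SD, cycles
    sigma: tuple[float, ...] | None = None       # per-candidate noise SD, cycles
    delta: tuple[float, ...] | None = None       # group-2 shift, cycles (default 0)
    n_replicates: int = 3
    replicate_sd: float = 0.15                   # technical read noise, cycles
    seed: int = 0
    condition: str = "synthetic"

    def resolve(self) -> "SimSpec":
        """Fill baselines/sigma/delta deterministically from the seed."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5E1F]))
        baselines = self.baselines
        if baselines is None:
            baselines = tuple(rng.uniform(18.0, 30.0, self.k))
        sigma = self.sigma if self.sigma is not None else tuple(rng.uniform(0.1, 1.5, self.k))
        delta = self.delta if self.delta is not None else tuple(0.0 for _ in range(self.k))
        spec = replace(self, baselines=baselines, sigma=sigma, delta=delta)
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.k < 2:
            raise ContractError("need k >= 2 candidates")
        if any(n < 1 for n in self.n_per_group):
            raise ContractError("each group needs >= 1 sample")
        for name, arr in (("baselines", self.baselines), ("sigma", self.sigma), ("delta", self.delta)):
            if arr is not None and len(arr) != self.k:
                raise ContractError(f"{name} must have length k = {self.k}")
        if self.baselines is not None and any(not (0 < b < 45) for b in self.baselines):
            raise ContractError("baselines must lie in (0, 45) cycles")
        if self.sigma is not None and any(s < 0 for s in self.sigma):
            raise ContractError("sigma must be >= 0")
        if self.tau < 0 or self.replicate_sd < 0:
            raise ContractError("tau and replicate_sd must be >= 0")
        if self.n_replicates < 1:
            raise ContractError("need >= 1 technical replicate")

    def disorder(self) -> np.ndarray:
        """Ground-truth disorder score sqrt(sigma^2 + delta^2/4), ascending = stable."""
        spec = self if self.sigma is not None and self.delta is not None else self.resolve()
        return np.sqrt(np.asarray(spec.sigma) ** 2 + np.asarray(spec.delta) ** 2 / 4.0)

    @property
    def candidates(self) -> list[str]:
        return [f"cand{i+1:02d}" for i in range(self.k)]


def simulate_ct(spec: SimSpec, *, rng: np.random.Generator | None = None) -> tuple[CtTable, dict]:
    """Draw one Ct table from ``spec``; returns ``(table, truth)``.

    ``truth`` holds the resolved baselines, sigma, delta and the disorder
    scores.  The same seed always yields the identical table: one seeded
    generator drives all draws in a fixed order.
    """
    spec = spec.resolve()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC7]))
    n1, n2 = spec.n_per_group
    n = n1 + n2
    group_idx = np.array([0] * n1 + [1] * n2)
    samples = [f"s{j+1:02d}" for j in range(n)]
    group_of = {s: spec.group_labels[g] for s, g in zip(samples, group_idx)}

    baselines = np.asarray(spec.baselines)
    sigma = np.asarray(spec.sigma)
    delta = np.asarray(spec.delta)
    loading = rng.normal(0.0, spec.tau, size=n)
    eps = rng.normal(0.0, 1.0, size=(spec.k, n)) * sigma[:, None]
    true_ct = baselines[:, None] + loading[None, :] + delta[:, None] * (group_idx == 1)[None, :] + eps
    reads = true_ct[:, :, None] + rng.normal(0.0, spec.replicate_sd, size=(spec.k, n, spec.n_replicates))
    ct = reads.mean(axis=2)

    table = CtTable(spec.candidates, samples, ct, group_of, spec.condition)
    truth = {
        "baselines": baselines.tolist(),
        "sigma": sigma.tolist(),
        "delta": delta.tolist(),
        "disorder": spec.disorder().tolist(),
        "candidates": spec.candidates,
        "seed": spec.seed,
    }
    return table, truth


def run_methods(table: CtTable, methods: tuple[str, ...] = METHODS) -> tuple[dict[str, pd.Series], pd.Series | None]:
    """Run the selected stability methods on one table.

    Returns ``(scores, genorm_ranks)`` ready for
    :func:`refmirna.consensus.consensus_from_scores`.
    """
    scores: dict[str, pd.Series] = {}
    genorm_ranks: pd.Series | None = None
    for m in methods:
        if m == "delta_ct":
            scores["delta_ct"] = delta_ct_stability(pairwise_sd(table))
        elif m == "genorm":
            trace = genorm_rank(table)
            genorm_ranks = trace.ranks()
        elif m == "normfinder":
            scores["normfinder"] = normfinder(table)
        elif m == "bestkeeper":
            scores["bestkeeper"] = bestkeeper_stability(table)
        else:
            raise ContractError(f"unknown method {m!r}")
    return scores, genorm_ranks


def consensus_for_table(table: CtTable, methods: tuple[str, ...] = METHODS) -> ConsensusRanking:
    scores, genorm_ranks = run_methods(table, methods)
    return consensus_from_scores(scores, genorm_ranks=genorm_ranks)


def recovery_experiment(
    spec: SimSpec,
    *,
    methods: tuple[str, ...] = METHODS,
    n_rep: int = 100,
    seed: int = 0,
) -> dict:
    """Monte-Carlo rank-recovery experiment.

    Requires a unique ground-truth most-stable candidate (strictly smallest
    disorder).  For each replicate a fresh table is drawn and every method
    (plus the consensus) records where it ranked the true winner.  The
    report gives per-method top-1 recovery fractions and full rank
    distributions.
    """
    spec = spec.resolve()
    disorder = spec.disorder()
    order = np.argsort(disorder)
    if disorder[order[0]] >= disorder[order[1]]:
        raise ContractError("ground truth ambiguous: no strictly smallest disorder score")
    winner = spec.candidates[order[0]]

    names = [m for m in methods] + ["consensus"]
    rank_hits: dict[str, list[int]] = {name: [] for name in names}
    root = np.random.SeedSequence([seed, spec.seed, 0x8EC0])
    for child in root.spawn(n_rep):
        rng = np.random.default_rng(child)
        table, _ = simulate_ct(spec, rng=rng)
        scores, genorm_ranks = run_methods(table, methods)
        for m, s in scores.items():
            ordered = s.sort_values(kind="mergesort").index.tolist()
            rank_hits[m].append(ordered.index(winner) + 1)
        if genorm_ranks is not None:
            # competition rank; the tied final pair both count as rank 1
            rank_hits["genorm"].append(int(genorm_ranks[winner]))
        cons = consensus_from_scores(scores, genorm_ranks=genorm_ranks)
        rank_hits["consensus"].append(cons.order.index(winner) + 1)

    report = {
        "winner": winner,
        "n_rep": n_rep,
        "top1": {name: float(np.mean([r == 1 for r in ranks])) for name, ranks in rank_hits.items()},
        "rank_distribution": {
            name: {int(r): int(c) for r, c in zip(*np.unique(ranks, return_counts=True))}
            for name, ranks in rank_hits.items()
        },
    }
    return report
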