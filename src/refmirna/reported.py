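"""Published per-method stability orderings for the bovine sperm panel.

The source study for this panel reports, per condition (sperm motility
and sperm morphology cohorts), the ordered stability listing of each of
the four algorithms.  Listings separate candidates by ">" (strictly
better) or join them by a comma when the printed stability values are
identical (a tie).  The tier lists below encode exactly that structure:
each inner list is one tie set; candidates printed with equal values but
separated by ">" remain separate tiers.

These orderings are *inputs* to the consensus stage: together with the
competition-rank convention they reproduce the published geometric-mean
consensus values.  The one known exception is U6 under the morphology
condition, whose published consensus (3.63) cannot be obtained from any
integer rank combination consistent with the printed orderings; the
closest reconstruction is 180**(1/4) = 3.66.  It is reported with a
discrepancy flag rather than forced to agree.
"""

from __future__ import annotations

from .consensus import ConsensusRanking, geometric_mean_rank, ranks_from_tiers

LET7C = "Let-7c-5p"
MIR100 = "miR-100-5p"
MIR204 = "miR-204-5p"
MIR25 = "miR-25-3p"
MIR26A = "miR-26a-5p"
MIR92A = "miR-92a-3p"
U6 = "U6"

CANDIDATES = [LET7C, MIR100, MIR204, MIR25, MIR26A, MIR92A, U6]

#: method -> ordered tier lists (best first), motility condition
MOTILITY_TIERS: dict[str, list[list[str]]] = {
    # 1.07 > 1.15 > 1.16 > 1.16 > 1.17 > 1.27 > 1.30 (equal 1.16 values are
    # still separated by ">", so they do not tie)
    "delta_ct": [[LET7C], [MIR25], [MIR100], [MIR204], [U6], [MIR92A], [MIR26A]],
    # 0.83, 0.83 > 0.97 > 1.05 > 1.09 > 1.13 > 1.18 (final pair tied)
    "genorm": [[LET7C, U6], [MIR25], [MIR204], [MIR92A], [MIR100], [MIR26A]],
    # 0.63 > 0.79 > 0.81 > 0.83 > 0.83 > 0.90 > 1.20
    "normfinder": [[LET7C], [MIR100], [MIR25], [MIR204], [U6], [MIR92A], [MIR26A]],
    # 0.22 > 0.56 > 0.94, 0.94 > 0.94 > 0.96 > 1.06 (the comma-joined 0.94
    # pair ties; the following 0.94 sits after a ">" and does not)
    "bestkeeper": [[U6], [LET7C], [MIR25, MIR26A], [MIR92A], [MIR100], [MIR204]],
}

#: method -> ordered tier lists (best first), morphology condition
MORPHOLOGY_TIERS: dict[str, list[list[str]]] = {
    # 1.20 > 1.22 > 1.28 > 1.34 > 1.57 > 1.57 > 2.07
    "delta_ct": [[MIR92A], [LET7C], [MIR100], [MIR25], [MIR204], [U6], [MIR26A]],
    # 0.52, 0.52 > 0.80 > 0.94 > 1.10 > 1.12 > 1.47
    "genorm": [[MIR92A, LET7C], [MIR100], [MIR25], [U6], [MIR204], [MIR26A]],
    # 0.57 > 0.63 > 0.70 > 0.81 > 1.18 > 1.24 > 1.87
    "normfinder": [[MIR92A], [LET7C], [MIR100], [MIR25], [MIR204], [U6], [MIR26A]],
    # 0.67 > 0.79 > 1.06 > 1.15 > 1.38 > 1.81 > 1.82
    "bestkeeper": [[U6], [MIR92A], [LET7C], [MIR25], [MIR100], [MIR204], [MIR26A]],
}

#: Published geometric-mean consensus display values per condition.
REPORTED_CONSENSUS: dict[str, dict[str, float]] = {
    "motility": {
        LET7C: 1.18, U6: 2.23, MIR25: 2.71, MIR100: 3.83,
        MIR204: 4.60, MIR92A: 5.47, MIR26A: 5.66,
    },
    "morphology": {
        MIR92A: 1.18, LET7C: 1.86, MIR100: 3.40, U6: 3.63,
        MIR25: 4.00, MIR204: 5.47, MIR26A: 7.00,
    },
}

#: Candidates whose published consensus is known not to be reproducible
#: from the printed per-method orderings.
KNOWN_DISCREPANCIES: dict[str, list[str]] = {"motility": [], "morphology": [U6]}

#: Morphology-cohort group means (% defects) from the published defect
#: table: component means, reported major/minor, and the printed totals.
MORPHOLOGY_GROUP_MEANS: dict[str, dict[str, float]] = {
    "Approved": {
        "acrosome": 3.20, "head": 3.20, "vacuoles": 2.80, "pcd": 1.80,
        "midpiece": 1.20, "major": 12.20, "detached_head": 2.40,
        "bent_tail": 8.00, "minor": 10.40, "total": 22.60,
    },
    "Non-approved": {
        "acrosome": 3.40, "head": 6.00, "vacuoles": 5.80, "pcd": 7.60,
        "midpiece": 0.40, "major": 24.00, "detached_head": 2.40,
        "bent_tail": 23.80, "minor": 26.20, "total": 50.20,
    },
}


def tier_consensus(tiers_by_method: dict[str, list[list[str]]]) -> ConsensusRanking:
    """Consensus ranking from per-method tier lists (rank reconstruction)."""
    vectors = [
        ranks_from_tiers(tiers, method=name) for name, tiers in tiers_by_method.items()
    ]
    return geometric_mean_rank(vectors)


def reported_consensus(condition: str) -> ConsensusRanking:
    """Consensus recomputed from the published orderings for one condition."""
    tiers = {"motility": MOTILITY_TIERS, "morphology": MORPHOLOGY_TIERS}[condition]
    return tier_consensus(tiers)
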