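"""Ct-table data model, validation, replicate handling and file I/O.

The central container is :class:`CtTable`: a complete candidates x samples
matrix of qPCR cycle-threshold (Ct) values together with a sample -> group
map and a free-text condition label.  All four stability algorithms in this
package consume a ``CtTable`` and assume the matrix is complete — missing
values are a hard error, never imputed.

Valid Ct values lie in ``(0, 45]`` cycles: the assays run 40 amplification
cycles, and a small headroom is allowed for instrument extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from importlib import resources

from .errors import ContractError, InputOutputError, ValidationError

CT_MIN = 0.0
CT_MAX = 45.0

#: Default replicate-spread QC threshold (cycles).  Triplicates whose
#: max-min spread exceeds this are flagged for review, never dropped:
#: silently changing n would corrupt every downstream SD.
DEFAULT_SPREAD_THRESHOLD = 0.5


def _check_ct_value(value: float, where: str) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"non-finite Ct value at {where}")
    if not (CT_MIN < value <= CT_MAX):
        raise ValidationError(
            f"Ct value {value} at {where} outside ({CT_MIN}, {CT_MAX}] cycles"
        )


@dataclass
class CtTable:
    """Complete candidates x samples Ct matrix with group labels.

    Parameters
    ----------
    candidates
        Ordered candidate (assay) identifiers; unique.
    samples
        Ordered sample identifiers; unique.
    ct
        2-D array, shape ``(len(candidates), len(samples))``, cycles.
    group_of
        Map from sample id to group label (e.g. ``"High"`` /
        ``"Low/Moderate"``).
    condition
        Free-text condition label (e.g. ``"motility"``).
    """

    candidates: list[str]
    samples: list[str]
    ct: np.ndarray
    group_of: dict[str, str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.candidates = list(self.candidates)
        self.samples = list(self.samples)
        self.ct = np.asarray(self.ct, dtype=float)
        if len(set(self.candidates)) != len(self.candidates):
            raise ValidationError("duplicate candidate identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if len(self.candidates) < 2 or len(self.samples) < 2:
            raise ValidationError("need >= 2 candidates and >= 2 samples")
        if self.ct.shape != (len(self.candidates), len(self.samples)):
            raise ValidationError(
                f"ct matrix shape {self.ct.shape} does not match "
                f"{len(self.candidates)} candidates x {len(self.samples)} samples"
            )
        for i, cand in enumerate(self.candidates):
            for j, sample in enumerate(self.samples):
                _check_ct_value(self.ct[i, j], f"({cand}, {sample})")
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")

    # -- convenience ------------------------------------------------------

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        return np.array(
            [j for j, s in enumerate(self.samples) if self.group_of[s] == group],
            dtype=int,
        )

    def require_groups(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        groups = self.groups
        if len(groups) < min_groups:
            raise ContractError(
                f"operation requires >= {min_groups} groups, found {len(groups)}"
            )
        for g in groups:
            n = len(self.group_columns(g))
            if n < min_per_group:
                raise ContractError(
                    f"group {g!r} has {n} samples, need >= {min_per_group}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: candidates as rows, samples as columns."""
        return pd.DataFrame(self.ct, index=self.candidates, columns=self.samples)

    def subset(self, candidates: Sequence[str]) -> "CtTable":
        keep = [c for c in self.candidates if c in set(candidates)]
        if len(keep) < 2:
            raise ContractError("subset must keep >= 2 candidates")
        rows = [self.candidates.index(c) for c in keep]
        return CtTable(keep, self.samples, self.ct[rows, :], dict(self.group_of), self.condition)

    def shifted(self, per_sample: np.ndarray | None = None,
                per_candidate: np.ndarray | None = None) -> "CtTable":
        """Copy with additive per-sample and/or per-candidate offsets (for invariance checks)."""
        ct = self.ct.copy()
        if per_sample is not None:
            ct = ct + np.asarray(per_sample, dtype=float)[None, :]
        if per_candidate is not None:
            ct = ct + np.asarray(per_candidate, dtype=float)[:, None]
        return CtTable(list(self.candidates), list(self.samples), ct,
                       dict(self.group_of), self.condition)


@dataclass
class ReplicateSet:
    """Technical replicates for one (candidate, sample) well group."""

    sample: str
    candidate: str
    replicate_cts: list[float]

    def __post_init__(self) -> None:
        if not self.replicate_cts:
            raise ValidationError(
                f"empty replicate set for ({self.candidate}, {self.sample})"
            )
        for v in self.replicate_cts:
            _check_ct_value(v, f"replicate of ({self.candidate}, {self.sample})")

    @property
    def spread(self) -> float:
        return max(self.replicate_cts) - min(self.replicate_cts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_cts))


@dataclass
class PanelEntry:
    assay_name: str
    assay_id: str
    mature_sequence: str


@dataclass
class CandidatePanel:
    """Assay panel: one TaqMan-style entry per candidate."""

    entries: list[PanelEntry]

    @property
    def names(self) -> list[str]:
        return [e.assay_name for e in self.entries]


#: Alphabets for panel validation.  Mature miRNA sequences are RNA; the U6
#: snRNA control is given as a DNA control sequence.
MIRNA_ALPHABET = set("ACGU")
DNA_ALPHABET = set("ACGT")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputOutputError(f"could not parse {path}: {exc}") from exc


def load_metadata(metadata_path: str | Path, sep: str | None = None) -> pd.DataFrame:
    meta = _read_table(metadata_path, sep)
    required = {"sample", "group"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns 'sample' and 'group'; found {list(meta.columns)}"
        )
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"duplicate samples in metadata: {dups}")
    return meta


def load_ct_table(
    path: str | Path,
    metadata_path: str | Path,
    *,
    dialect: str = "wide",
    sep: str | None = None,
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
) -> CtTable:
    """Read a Ct matrix plus sample metadata from disk.

    Two dialects are supported.  ``wide``: first column ``candidate``,
    remaining columns are sample ids, cells are Ct values.  ``long``:
    columns ``sample, candidate, replicate, ct``; replicates are collapsed
    by arithmetic mean (see :func:`collapse_replicates`).
    """
    meta = load_metadata(metadata_path, sep)
    group_of = dict(zip(meta["sample"], meta["group"]))
    condition = ""
    if "condition" in meta.columns and len(meta):
        condition = str(meta["condition"].iloc[0])

    raw = _read_table(path, sep)
    if dialect == "wide":
        if raw.columns[0] != "candidate":
            raise ValidationError(
                f"wide dialect requires first column 'candidate', found {raw.columns[0]!r}"
            )
        candidates = raw["candidate"].tolist()
        samples = [c for c in raw.columns[1:]]
        values = np.empty((len(candidates), len(samples)))
        for i, cand in enumerate(candidates):
            for j, sample in enumerate(samples):
                cell = raw.iloc[i][sample]
                try:
                    values[i, j] = float(cell)
                except (TypeError, ValueError):
                    raise InputOutputError(
                        f"non-numeric Ct value {cell!r} at row {cand!r}, column {sample!r}"
                    ) from None
        missing = [s for s in samples if s not in group_of]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return CtTable(candidates, samples, values, group_of, condition)
    if dialect == "long":
        required = {"sample", "candidate", "ct"}
        if not required.issubset(raw.columns):
            raise ValidationError(
                f"long dialect requires columns {sorted(required)}; found {list(raw.columns)}"
            )
        sets: dict[tuple[str, str], list[float]] = {}
        order_c: dict[str, None] = {}
        order_s: dict[str, None] = {}
        for row in raw.itertuples(index=False):
            try:
                value = float(row.ct)
            except (TypeError, ValueError):
                raise InputOutputError(
                    f"non-numeric Ct value {row.ct!r} for "
                    f"({row.candidate!r}, {row.sample!r})"
                ) from None
            sets.setdefault((str(row.candidate), str(row.sample)), []).append(value)
            order_c.setdefault(str(row.candidate))
            order_s.setdefault(str(row.sample))
        replicate_sets = [
            ReplicateSet(sample=s, candidate=c, replicate_cts=v)
            for (c, s), v in sets.items()
        ]
        table, _flags = collapse_replicates(
            replicate_sets, spread_threshold=spread_threshold,
            group_of=group_of, condition=condition,
            candidate_order=list(order_c), sample_order=list(order_s),
        )
        return table
    raise ContractError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")


def write_ct_table(table: CtTable, path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write the wide-dialect CSV (and optionally the metadata CSV)."""
    frame = table.to_frame()
    frame.insert(0, "candidate", frame.index)
    frame.to_csv(path, index=False, float_format="%.6f")
    if metadata_path is not None:
        pd.DataFrame(
            {
                "sample": table.samples,
                "group": [table.group_of[s] for s in table.samples],
                "condition": table.condition,
            }
        ).to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------

def collapse_replicates(
    raw: Iterable[ReplicateSet],
    *,
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
    group_of: Mapping[str, str] | None = None,
    condition: str = "",
    candidate_order: Sequence[str] | None = None,
    sample_order: Sequence[str] | None = None,
) -> tuple[CtTable, list[dict]]:
    """Collapse technical replicates to one Ct per (candidate, sample).

    Each pair's Ct is the arithmetic mean of its replicates.  Pairs whose
    max-min spread exceeds ``spread_threshold`` cycles are returned in the
    QC-flag list (candidate, sample, spread, replicates) — flagged, never
    dropped.

    Returns ``(table, flags)``.
    """
    raw = list(raw)
    if not raw:
        raise ValidationError("no replicate sets supplied")
    by_pair: dict[tuple[str, str], ReplicateSet] = {}
    for rset in raw:
        key = (rset.candidate, rset.sample)
        if key in by_pair:
            merged = by_pair[key].replicate_cts + rset.replicate_cts
            by_pair[key] = ReplicateSet(rset.sample, rset.candidate, merged)
        else:
            by_pair[key] = rset
    candidates = list(candidate_order) if candidate_order else sorted({c for c, _ in by_pair})
    samples = list(sample_order) if sample_order else sorted({s for _, s in by_pair})
    values = np.full((len(candidates), len(samples)), np.nan)
    flags: list[dict] = []
    for (cand, sample), rset in by_pair.items():
        i, j = candidates.index(cand), samples.index(sample)
        values[i, j] = rset.mean
        if rset.spread > spread_threshold:
            flags.append(
                {
                    "candidate": cand,
                    "sample": sample,
                    "spread": rset.spread,
                    "replicates": list(rset.replicate_cts),
                }
            )
    if np.isnan(values).any():
        holes = [
            (candidates[i], samples[j])
            for i, j in zip(*np.nonzero(np.isnan(values)))
        ]
        raise ValidationError(f"incomplete matrix after collapse; missing pairs: {holes}")
    if group_of is None:
        group_of = {s: "all" for s in samples}
    table = CtTable(candidates, samples, values, dict(group_of), condition)
    return table, flags


# ---------------------------------------------------------------------------
# Group summaries and comparisons
# ---------------------------------------------------------------------------

def summarize_group_ct(table: CtTable) -> pd.DataFrame:
    """Per candidate per group: n, mean Ct, SD (n-1) and SEM, in cycles."""
    table.require_groups()
    rows = []
    for g in table.groups:
        cols = table.group_columns(g)
        block = table.ct[:, cols]
        n = len(cols)
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        for i, cand in enumerate(table.candidates):
            rows.append(
                {
                    "candidate": cand,
                    "group": g,
                    "n": n,
                    "mean_ct": mean[i],
                    "sd_ct": sd[i],
                    "sem_ct": sd[i] / math.sqrt(n),
                }
            )
    return pd.DataFrame(rows)


def compare_group_ct(table: CtTable, *, test: str = "student", alpha: float = 0.05) -> pd.DataFrame:
    """Two-tailed unpaired t-test per candidate between the two groups.

    ``test`` is ``"student"`` (equal-variance, the default) or ``"welch"``.
    """
    from scipy import stats

    groups = table.groups
    if len(groups) != 2:
        raise ContractError(f"exactly 2 groups required, found {len(groups)}")
    table.require_groups()
    if test not in {"student", "welch"}:
        raise ContractError(f"unknown test variant {test!r}")
    cols_a = table.group_columns(groups[0])
    cols_b = table.group_columns(groups[1])
    rows = []
    for i, cand in enumerate(table.candidates):
        a, b = table.ct[i, cols_a], table.ct[i, cols_b]
        res = stats.ttest_ind(a, b, equal_var=(test == "student"))
        rows.append(
            {
                "candidate": cand,
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Candidate panel
# ---------------------------------------------------------------------------

def load_panel(path: str | Path | None = None) -> CandidatePanel:
    """Load an assay panel TSV (``assay_name, assay_id, mature_sequence``).

    With no path, the packaged seven-candidate bovine-sperm panel (six
    mature miRNA sequences plus the U6 snRNA control) is returned.
    """
    if path is None:
        ref = resources.files("refmirna").joinpath("data/candidate_panel.tsv")
        with resources.as_file(ref) as p:
            frame = _read_table(p, "\t")
    else:
        frame = _read_table(path, "\t")
    required = {"assay_name", "assay_id", "mature_sequence"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"panel file must have columns {sorted(required)}")
    entries = [
        PanelEntry(str(r.assay_name), str(r.assay_id), str(r.mature_sequence))
        for r in frame.itertuples(index=False)
    ]
    return CandidatePanel(entries)


def validate_panel(panel: CandidatePanel) -> pd.DataFrame:
    """Alphabet / non-emptiness report for a candidate panel.

    miRNA entries must use {A,C,G,U}; entries whose name marks them as a
    control snRNA (``U6``) use the DNA alphabet {A,C,G,T}.  Returns one row
    per entry with ``valid`` and ``problems`` columns; never raises.
    """
    rows = []
    for e in panel.entries:
        problems: list[str] = []
        seq = e.mature_sequence.strip().upper()
        is_control = "U6" in e.assay_name.upper()
        alphabet = DNA_ALPHABET if is_control else MIRNA_ALPHABET
        if not seq:
            problems.append("empty sequence")
        else:
            bad = sorted(set(seq) - alphabet)
            if bad:
                kind = "DNA" if is_control else "RNA"
                problems.append(f"characters {bad} outside {kind} alphabet")
        rows.append(
            {
                "assay_name": e.assay_name,
                "length": len(seq),
                "valid": not problems,
                "problems": "; ".join(problems),
            }
        )
    return pd.DataFrame(rows)
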