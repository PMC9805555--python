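"""Evaluation machinery: AUROC, leave-one-out prediction, region recovery
and promoter-state/expression correlation.

AUROC is used throughout as the tie-aware probability that a random positive
bin outranks a random negative one (ties contribute 0.5) — equivalently the
normalized Mann-Whitney U statistic.  The tie convention matters here:
counting-based score tracks with few samples take only N+1 distinct values,
so ties are the norm, not the exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeIndex, SampleGroup
from .summarize import (
    SummaryMatrix,
    base_count_summary,
    sample_training_positions,
    summarize_group,
)

__all__ = [
    "LooReport",
    "auroc",
    "leave_one_out",
    "region_recovery_auroc",
    "expression_correlation",
    "read_region_bins",
]


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware area under the ROC curve.

    Equals the normalized Mann-Whitney U: ranks are averaged over ties, so
    tied positive/negative pairs contribute 0.5.  Requires both classes
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal-length")
    pos = labels != 0
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class LooReport:
    """Leave-one-out evaluation results for one group.

    ``table`` holds one row per (held-out member, state): the AUROC of the
    remaining members' summary probability for that state against the
    held-out sample's binary state indicator.  Pairs where the held-out
    sample never (or always) carries the state are recorded with
    ``skipped=True`` and a NaN AUROC.
    """

    group_id: str
    method: str
    table: pd.DataFrame  # columns: held_out_sample, state, auroc, method, skipped

    def mean_auroc(self) -> float:
        vals = self.table.loc[~self.table["skipped"], "auroc"]
        return float(vals.mean())

    def mean_auroc_by_state(self) -> pd.Series:
        ok = self.table[~self.table["skipped"]]
        return ok.groupby("state")["auroc"].mean()


def leave_one_out(
    group: SampleGroup,
    method: str = "csrep",
    fraction: float = 0.1,
    seed: int = 0,
    l2_strength: float = 1.0,
) -> LooReport:
    """Leave-one-out cross-validation of a group summary.

    For each member n, summarize the group without n and score, per state,
    how well the summary probability column ranks the bins the held-out
    sample assigned to that state.
    """
    if method not in ("csrep", "base_count"):
        raise ValueError(f"unknown method {method!r}")
    if method == "csrep" and group.N < 3:
        raise ValueError("leave-one-out with csrep needs N >= 3 (>= 2 remaining)")
    if method == "base_count" and group.N < 2:
        raise ValueError("leave-one-out needs N >= 2")
    rows = []
    for member in group.members:
        rest = group.without(member.sample_id)
        if method == "csrep":
            summary = summarize_group(rest, fraction=fraction, seed=seed,
                                      l2_strength=l2_strength)
        else:
            summary = base_count_summary(rest)
        for s in range(1, group.scheme.S + 1):
            y = (member.states == s).astype(np.int8)
            if y.min() == y.max():
                rows.append((member.sample_id, s, np.nan, method, True))
                continue
            rows.append((member.sample_id, s, auroc(summary.probs[:, s - 1], y), method, False))
    table = pd.DataFrame(rows, columns=["held_out_sample", "state", "auroc", "method", "skipped"])
    return LooReport(group_id=group.group_id, method=method, table=table)


def region_recovery_auroc(
    score_track: np.ndarray,
    positive_bins: Iterable[int],
    background_bins: Iterable[int],
) -> float:
    """AUROC of a per-bin score for recovering a positive region set against
    a background set that contains it (e.g. chrX TSS bins vs all TSS bins)."""
    score_track = np.asarray(score_track, dtype=float)
    positive = set(int(b) for b in positive_bins)
    background = set(int(b) for b in background_bins)
    if not positive or not background:
        raise ValueError("positive and background sets must be non-empty")
    if not positive <= background:
        raise ValueError("positive bins must be a subset of the background")
    if positive == background:
        raise ValueError("positive set equals background: AUROC undefined")
    bins = np.fromiter(sorted(background), dtype=np.int64)
    labels = np.isin(bins, np.fromiter(sorted(positive), dtype=np.int64)).astype(np.int8)
    return auroc(score_track[bins], labels)


def expression_correlation(
    summary: SummaryMatrix,
    tss_bins: Sequence[int],
    expression: Sequence[float],
    state: int,
) -> float:
    """Spearman correlation between a state's summary probability at each
    gene's TSS bin and the genes' expression values (average-rank ties)."""
    tss_bins = np.asarray(tss_bins, dtype=np.int64)
    expr = np.asarray(expression, dtype=float)
    if tss_bins.shape != expr.shape:
        raise ValueError("tss_bins and expression must be equal-length")
    if tss_bins.size < 3:
        raise ValueError("need at least 3 genes")
    if tss_bins.min() < 0 or tss_bins.max() >= summary.index.n_bins:
        raise ValueError("TSS bin index out of range")
    if not 1 <= state <= summary.scheme.S:
        raise ValueError(f"state {state} outside 1..{summary.scheme.S}")
    probs = summary.probs[tss_bins, state - 1]
    if np.ptp(probs) == 0 or np.ptp(expr) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(probs, expr).statistic
    return float(rho)


def read_region_bins(bed: str | Path, index: GenomeIndex) -> set[int]:
    """Bin indices overlapping any BED interval by >= 1 bp (set semantics:
    nested or duplicate intervals contribute once)."""
    out: set[int] = set()
    for ln, line in enumerate(Path(bed).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{bed}:{ln}: expected >=3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        try:
            out.update(index.interval_bins(chrom, start, end))
        except KeyError:
            raise ValueError(f"{bed}:{ln}: chromosome {chrom!r} not in genome index") from None
    return out
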