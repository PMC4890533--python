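"""DeCyder-style 2D-DIGE spot tables: signed folds, trends, candidate cuts.

Difference gel electrophoresis compares two co-separated samples spot by
spot.  The image software reports one *signed average fold change* per
spot: a ratio magnitude ≥ 1 whose sign says which condition is higher —
here a negative fold means the second-listed condition is higher.  The
printed "overall trend" column is relative to the second condition, hence

    fold < 0  →  trend "Up"   (higher in the second condition)
    fold > 0  →  trend "Down" (lower in the second condition)

This module converts folds to trends, applies the magnitude cutoffs used
for candidate listing (>1.75) and spot selection (>2.0), and expands a
signed fold into a pair of relative levels for the integration stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError


@dataclass
class SpotRecord:
    """One DIGE spot in one two-condition comparison."""

    spot_id: str
    comparison: tuple[str, str]      # (first condition, second condition)
    fold: float                      # signed, |fold| >= 1
    gene: str | None = None          # post-identification gene symbol
    trend: str | None = None         # "Up"/"Down" relative to second condition

    def with_trend(self) -> "SpotRecord":
        return replace(self, trend=trend_from_fold(self.fold))


def trend_from_fold(signed_fold: float) -> str:
    """Trend of the second-listed condition implied by a signed fold."""
    if abs(signed_fold) < 1:
        raise InputError(
            f"DIGE folds are ratio magnitudes >= 1; got {signed_fold}"
        )
    return "Up" if signed_fold < 0 else "Down"


def select_candidate_spots(
    spots: Sequence[SpotRecord], fold_cutoff: float
) -> list[SpotRecord]:
    """Spots whose fold magnitude strictly exceeds the cutoff, in order."""
    if fold_cutoff <= 1:
        raise InputError(f"fold cutoff must exceed 1, got {fold_cutoff}")
    return [s for s in spots if abs(s.fold) > fold_cutoff]


def fold_to_relative_levels(
    record: SpotRecord, baseline: str = "first"
) -> tuple[float, float]:
    """Expand a signed fold into (level_first, level_second).

    The baseline condition is set to 1; the other condition is |fold| if
    it is the higher one, else 1/|fold|.  The two levels form a single
    scale block anchored at the named baseline — they are comparable with
    each other but not across blocks with different baselines.
    """
    if baseline not in ("first", "second"):
        raise InputError(f"baseline must be 'first' or 'second', got {baseline!r}")
    mag = abs(record.fold)
    if mag < 1:
        raise InputError(f"DIGE folds are ratio magnitudes >= 1; got {record.fold}")
    second_higher = record.fold < 0
    if mag == 1:
        return (1.0, 1.0)
    if baseline == "first":
        return (1.0, mag) if second_higher else (1.0, 1.0 / mag)
    return (1.0 / mag, 1.0) if second_higher else (mag, 1.0)


def signed_fold_from_levels(level_first: float, level_second: float) -> float:
    """Inverse of :func:`fold_to_relative_levels` (1.0 for equal levels)."""
    if level_first <= 0 or level_second <= 0:
        raise InputError("levels must be positive")
    if level_second > level_first:
        return -level_second / level_first
    if level_first > level_second:
        return level_first / level_second
    return 1.0


def profiles_from_spots(records: Sequence[SpotRecord], tau: float | None = None):
    """Per-gene four-group profiles from axis spot folds.

    Uses each gene's WT-axis (WTV vs WTC) and KO-axis (KOV vs KOC) folds,
    anchored at the villus of each genotype, so the two axis blocks are
    internally consistent but carry independent scales: the returned
    profiles are comparable on the axis comparisons only.  Genes without
    an identified symbol or without any axis fold are skipped.  When a
    gene maps to several spots in one comparison the largest-magnitude
    fold is used (the best-measured spot in DeCyder terms).
    """
    from .design import DEFAULT_TAU
    from .differential import GradientProfile

    if tau is None:
        tau = DEFAULT_TAU
    axis_folds: dict[str, dict[str, float]] = {}
    for r in records:
        if not r.gene:
            continue
        if r.comparison == ("WTV", "WTC"):
            axis = "wt_axis"
        elif r.comparison == ("KOV", "KOC"):
            axis = "ko_axis"
        else:
            continue
        prev = axis_folds.setdefault(r.gene, {}).get(axis)
        if prev is None or abs(r.fold) > abs(prev):
            axis_folds[r.gene][axis] = r.fold
    profiles = {}
    for gene, folds in axis_folds.items():
        levels = {"WTV": 1.0, "WTC": 1.0, "KOV": 1.0, "KOC": 1.0}
        comparable = set()
        if "wt_axis" in folds:
            _, levels["WTC"] = fold_to_relative_levels(
                SpotRecord(spot_id="", comparison=("WTV", "WTC"), fold=folds["wt_axis"])
            )
            comparable.add("wt_axis")
        if "ko_axis" in folds:
            _, levels["KOC"] = fold_to_relative_levels(
                SpotRecord(spot_id="", comparison=("KOV", "KOC"), fold=folds["ko_axis"])
            )
            comparable.add("ko_axis")
        profiles[gene] = GradientProfile(
            feature=gene, levels=levels, comparable=frozenset(comparable), tau=tau
        )
    return profiles


# ---------------------------------------------------------------------------
# Tables

def annotate_trends(df: pd.DataFrame, fold_column: str = "avg_fold_change") -> pd.DataFrame:
    """Add/overwrite a ``trend`` column computed from the signed folds."""
    out = df.copy()
    out["trend"] = [trend_from_fold(f) for f in out[fold_column]]
    return out


def trend_counts(df: pd.DataFrame, fold_column: str = "avg_fold_change") -> dict[str, int]:
    """Count spots lower ("Down") and higher ("Up") in the second condition."""
    trends = [trend_from_fold(f) for f in df[fold_column]]
    return {"Down": trends.count("Down"), "Up": trends.count("Up")}


def read_spot_table(path) -> pd.DataFrame:
    """Read a spot TSV (columns: spot id, comparison, fold, optional gene)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"spot_id": str})
    required = {"spot_id", "comparison_first", "comparison_second", "avg_fold_change"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"spot table missing columns: {sorted(missing)}")
    return df


def records_from_frame(df: pd.DataFrame) -> list[SpotRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(
            SpotRecord(
                spot_id=str(row["spot_id"]),
                comparison=(row["comparison_first"], row["comparison_second"]),
                fold=float(row["avg_fold_change"]),
                gene=row.get("gene") if isinstance(row.get("gene"), str) else None,
            ).with_trend()
        )
    return recs


def write_spot_table(records: Iterable[SpotRecord], path) -> None:
    rows = [
        {
            "spot_id": r.spot_id,
            "comparison_first": r.comparison[0],
            "comparison_second": r.comparison[1],
            "avg_fold_change": r.fold,
            "gene": r.gene or "",
            "trend": r.trend or trend_from_fold(r.fold),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
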