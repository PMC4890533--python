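"""Four-group differential expression, gradient calls, and the PCA overview.

The design crosses genotype (WT, PepT1 KO) with compartment (villus,
crypt).  Features (miRNAs) are compared pairwise in four fixed
comparisons — WT axis, KO axis, villi, crypts (see
:mod:`cryptvillus.design`) — with a two-tailed Student's t-test; a feature
is *selected* in a comparison when p < 0.05 and its linear signal exceeds
500 in at least one of the two groups.

Per-genotype gradient direction is then called at a fold threshold τ
(default 1.45): crypt/villus ≥ τ → "up", villus/crypt ≥ τ → "down",
otherwise "same"; and the WT→KO change of that call is categorized as
preserved / lost / gained / reversed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import COMPARISONS, COMPARISON_ORDER, DEFAULT_TAU, GROUPS
from .errors import InputError

DEFAULT_ALPHA = 0.05
DEFAULT_SIGNAL_THRESHOLD = 500.0

DIRECTIONS = ("down", "same", "up")


@dataclass
class ComparisonResult:
    """Two-group test result for one feature in one comparison."""

    feature: str
    comparison: str
    mean_first: float
    mean_second: float
    fold: float                 # ratio >= 1
    direction: str              # "up"/"down": second group vs first
    p_value: float
    mean_signal: float          # max of the two group means (linear scale)
    selected: bool
    insufficient_replication: bool = False


def _ttest_pvalue(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    """Two-sided two-sample t-test p-value, safe for degenerate inputs.

    Zero pooled variance with equal means (a constant feature) is an
    exact null and maps to p = 1 rather than NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    if np.isnan(p):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(p)


def pairwise_de(
    values_a,
    values_b,
    *,
    feature: str = "",
    comparison: str = "",
    alpha: float = DEFAULT_ALPHA,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    equal_var: bool = True,
) -> ComparisonResult:
    """Compare two replicate vectors on the linear signal scale.

    ``values_a`` is the first-listed group, ``values_b`` the second; NaN
    entries are undetected replicates.  A feature with fewer than two
    detected replicates in either group is flagged
    ``insufficient_replication`` and never selected (its p-value is NaN).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return ComparisonResult(
            feature=feature, comparison=comparison,
            mean_first=float(a.mean()) if a.size else np.nan,
            mean_second=float(b.mean()) if b.size else np.nan,
            fold=np.nan, direction="same", p_value=np.nan,
            mean_signal=np.nan, selected=False,
            insufficient_replication=True,
        )
    ma, mb = float(a.mean()), float(b.mean())
    if ma <= 0 or mb <= 0:
        raise InputError("group mean signal must be positive on the linear scale")
    p = _ttest_pvalue(a, b, equal_var)
    if mb > ma:
        fold, direction = mb / ma, "up"
    elif mb < ma:
        fold, direction = ma / mb, "down"
    else:
        fold, direction = 1.0, "same"
    mean_signal = max(ma, mb)
    selected = bool(p < alpha and mean_signal > signal_threshold)
    return ComparisonResult(
        feature=feature, comparison=comparison, mean_first=ma, mean_second=mb,
        fold=fold, direction=direction, p_value=p, mean_signal=mean_signal,
        selected=selected,
    )


def run_comparisons(
    signal: pd.DataFrame,
    groups: pd.Series,
    *,
    alpha: float = DEFAULT_ALPHA,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    equal_var: bool = True,
    adjust: str | None = None,
) -> pd.DataFrame:
    """All four pairwise comparisons for every feature.

    ``signal`` is features × samples on the linear signal scale (NaN =
    undetected); ``groups`` maps sample → group.  Returns a tidy frame
    with one row per (feature, comparison).  ``adjust="bh"`` additionally
    reports Benjamini-Hochberg adjusted p-values per comparison (the
    default selection still uses raw p, matching the panel convention).
    """
    frames = []
    for label in COMPARISON_ORDER:
        first, second = COMPARISONS[label]
        cols_a = groups.index[groups == first]
        cols_b = groups.index[groups == second]
        if len(cols_a) == 0 or len(cols_b) == 0:
            raise InputError(f"comparison {label}: missing group {first} or {second}")
        va = signal[cols_a].to_numpy(dtype=float)
        vb = signal[cols_b].to_numpy(dtype=float)
        na = np.isfinite(va).sum(axis=1)
        nb = np.isfinite(vb).sum(axis=1)
        enough = (na >= 2) & (nb >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ma = np.nanmean(np.where(np.isfinite(va), va, np.nan), axis=1)
            mb = np.nanmean(np.where(np.isfinite(vb), vb, np.nan), axis=1)
            p = stats.ttest_ind(va, vb, axis=1, equal_var=equal_var,
                                nan_policy="omit").pvalue
        p = np.asarray(p, dtype=float)
        # constant features: equal means are an exact null, not undefined
        degenerate = np.isnan(p) & enough
        p[degenerate & np.isclose(ma, mb)] = 1.0
        p[degenerate & ~np.isclose(ma, mb)] = 0.0
        p[~enough] = np.nan
        hi = np.maximum(ma, mb)
        lo = np.minimum(ma, mb)
        with np.errstate(invalid="ignore", divide="ignore"):
            fold = np.where(enough, hi / lo, np.nan)
        direction = np.where(mb > ma, "up", np.where(mb < ma, "down", "same"))
        mean_signal = np.where(enough, hi, np.nan)
        selected = enough & (p < alpha) & (mean_signal > signal_threshold)
        frames.append(pd.DataFrame({
            "feature": signal.index.astype(str),
            "comparison": label,
            "mean_first": ma, "mean_second": mb,
            "fold": fold, "direction": direction,
            "p_value": p, "mean_signal": mean_signal,
            "selected": selected,
            "insufficient_replication": ~enough,
        }))
    df = pd.concat(frames, ignore_index=True)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = np.nan
        for label in COMPARISON_ORDER:
            m = (df["comparison"] == label) & df["p_value"].notna()
            if m.any():
                df.loc[m, "p_adjusted"] = multipletests(
                    df.loc[m, "p_value"], method="fdr_bh"
                )[1]
    return df


# ---------------------------------------------------------------------------
# Gradient calls

def classify_axis_direction(first_level: float, second_level: float,
                            tau: float = DEFAULT_TAU) -> str:
    """Direction of the second level relative to the first at threshold τ.

    "up" iff second/first ≥ τ, "down" iff first/second ≥ τ, else "same".
    For an axis comparison the first level is the villus, the second the
    crypt, so "up" reads "higher in crypts".
    """
    if tau <= 1:
        raise InputError(f"tau must exceed 1, got {tau}")
    if not (first_level > 0 and second_level > 0):
        raise InputError("expression levels must be positive")
    if second_level / first_level >= tau:
        return "up"
    if first_level / second_level >= tau:
        return "down"
    return "same"


@dataclass
class GradientProfile:
    """Four-group relative levels with per-comparison comparability.

    ``levels`` maps group → relative level.  Levels may sit on more than
    one scale block (e.g. DIGE folds normalized within genotype); a
    comparison's direction is defined only when both its groups share a
    block, recorded in ``comparable``.
    """

    feature: str
    levels: dict[str, float]
    comparable: frozenset[str] = frozenset(COMPARISON_ORDER)
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        for g, v in self.levels.items():
            if not (v > 0):
                raise InputError(f"{self.feature}: non-positive level for {g}")

    def direction(self, comparison: str) -> str | None:
        """Direction call for one comparison, or None if incomparable."""
        if comparison not in self.comparable:
            return None
        first, second = COMPARISONS[comparison]
        return classify_axis_direction(self.levels[first], self.levels[second], self.tau)

    def directions(self) -> dict[str, str | None]:
        return {c: self.direction(c) for c in COMPARISON_ORDER}


@dataclass
class GradientChange:
    feature: str
    wt_call: str
    ko_call: str
    category: str


def gradient_change_category(wt_call: str, ko_call: str, *, feature: str = "") -> GradientChange:
    """Categorize how the axis gradient changes between genotypes.

    reversed: WT and KO calls strictly opposite; preserved: equal and not
    flat; lost: a WT gradient flattens in KO; gained: a KO gradient absent
    in WT; preserved-null: flat in both.
    """
    for name, call in (("wt_call", wt_call), ("ko_call", ko_call)):
        if call not in DIRECTIONS:
            raise InputError(f"{name} must be one of {DIRECTIONS}, got {call!r}")
    if {wt_call, ko_call} == {"up", "down"}:
        cat = "reversed"
    elif wt_call == ko_call:
        cat = "preserved-null" if wt_call == "same" else "preserved"
    elif ko_call == "same":
        cat = "lost"
    else:
        cat = "gained"
    return GradientChange(feature=feature, wt_call=wt_call, ko_call=ko_call, category=cat)


def gradient_profiles(
    signal: pd.DataFrame,
    groups: pd.Series,
    *,
    tau: float = DEFAULT_TAU,
    baseline: str = "WTV",
) -> dict[str, GradientProfile]:
    """Per-feature four-group relative levels from a single-scale matrix.

    Group levels are arithmetic means of detected replicates, rescaled so
    the baseline group is 1.  qPCR panel data live on one scale, so every
    comparison is comparable.
    """
    profiles: dict[str, GradientProfile] = {}
    means = {}
    for g in GROUPS:
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise InputError(f"no samples for group {g}")
        means[g] = signal[cols].mean(axis=1, skipna=True)
    for feat in signal.index:
        levels = {g: float(means[g][feat]) for g in GROUPS}
        if any(not np.isfinite(v) or v <= 0 for v in levels.values()):
            continue  # undetected in an entire group: no profile
        base = levels[baseline]
        profiles[str(feat)] = GradientProfile(
            feature=str(feat),
            levels={g: v / base for g, v in levels.items()},
            tau=tau,
        )
    return profiles


def gradient_change_table(profiles: dict[str, GradientProfile]) -> pd.DataFrame:
    """WT-vs-KO axis change category for every profile."""
    rows = []
    for feat, prof in profiles.items():
        wt = prof.direction("wt_axis")
        ko = prof.direction("ko_axis")
        if wt is None or ko is None:
            continue
        ch = gradient_change_category(wt, ko, feature=feat)
        rows.append({"feature": feat, "wt_call": wt, "ko_call": ko,
                     "category": ch.category})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA overview

def pca_overview(values: pd.DataFrame, k: int = 50):
    """Sample map from the k most variable features (2 principal components).

    ``values`` is features × samples (e.g. normalized cycles-scale
    expression).  Features are ranked by variance across samples (ties
    broken lexicographically by feature id for determinism), the matrix is
    mean-centered per feature, and the samples' coordinates on the first
    two principal components are returned together with the retained
    feature list.  Component signs are arbitrary.
    """
    import warnings

    from sklearn.decomposition import PCA

    if values.shape[1] < 3:
        raise InputError("PCA overview needs at least 3 samples")
    variances = values.var(axis=1, skipna=False)
    usable = variances[np.isfinite(variances)]
    if len(usable) < k:
        warnings.warn(
            f"only {len(usable)} features with finite variance; using all",
            stacklevel=2,
        )
        k = len(usable)
    if k < 1:
        raise InputError("no features with finite variance")
    order = pd.DataFrame({"var": usable, "id": usable.index.astype(str)})
    order = order.sort_values(["var", "id"], ascending=[False, True])
    top = order.index[:k]
    x = values.loc[top].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    n_comp = min(2, values.shape[1] - 1, k)
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(x.T)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=values.columns, columns=cols), list(top)
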