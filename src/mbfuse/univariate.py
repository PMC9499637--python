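"""Univariate group comparisons, correlations and clinical stratification.

Two distinct multiplicity regimes are used downstream and are kept apart on
purpose: Kruskal-Wallis + Benjamini-Hochberg FDR for table-wide ecology
scans, and Mann-Whitney + Bonferroni for confirming the (few) features
selected by the multivariate VIP rule.  Clinical cut-off schemes (blood pH
severity strata, anti-GAD positivity, ...) stratify samples for contrast
definitions.

Standard tests are delegated to scipy/statsmodels; this module fixes the
edge-case contracts (degenerate ties, exact-vs-asymptotic switching,
pairwise-complete deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (g−1 df).

    If every observation is identical the tie correction degenerates; the
    contract here is H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("kruskal_wallis needs total n >= 3")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


#: exact Mann-Whitney enumeration is used up to this combined sample size
MANN_WHITNEY_EXACT_MAX_N = 12


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` (default) uses the exact null distribution when
    n_x + n_y <= 12 and the pooled data is tie-free, otherwise the normal
    approximation with tie correction and continuity correction.  ``"exact"``
    and ``"asymptotic"`` force the respective method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires nonempty samples")
    if mode == "auto":
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (x.size + y.size <= MANN_WHITNEY_EXACT_MAX_N
                             and tie_free) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p_list, method: str = "bh_fdr") -> np.ndarray:
    """Multiple-testing adjustment.

    ``"bonferroni"`` is min(1, m·p); ``"bh_fdr"`` is the Benjamini-Hochberg
    step-up with monotonicity enforcement.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}
    if method not in key:
        raise ValueError(f"method must be one of {sorted(key)}, got {method!r}")
    return multipletests(p, method=key[method])[1]


def pearson(x, y, pairwise_complete: bool = True) -> tuple[float, float]:
    """Pearson correlation with a t-transform p-value (n−2 df).

    Missing entries (NaN) are dropped pairwise when ``pairwise_complete``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if pairwise_complete:
        mask = np.isfinite(x) & np.isfinite(y)
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("pearson needs >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and p over the columns of ``df``."""
    cols = list(df.columns)
    m = len(cols)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r[i, j], p[i, j] = pearson(df[cols[i]], df[cols[j]])
            r[j, i], p[j, i] = r[i, j], p[i, j]
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


# ---------------------------------------------------------------------------
# clinical stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Half-open interval [lower, upper) mapped to a stratum label."""

    label: str
    lower: float
    upper: float


@dataclass(frozen=True)
class IntervalScheme:
    """Ordered list of disjoint half-open intervals."""

    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.lower)
        for iv in ivs:
            if not iv.lower < iv.upper:
                raise ValueError(f"empty interval {iv}")
        for a, b in zip(ivs, ivs[1:]):
            if a.upper > b.lower:
                raise ValueError(f"overlapping intervals {a} and {b}")

    def assign(self, value: float) -> str | None:
        for iv in self.intervals:
            if iv.lower <= value < iv.upper:
                return iv.label
        return None


@dataclass(frozen=True)
class ThresholdScheme:
    """Single cut-off with a direction; ``strict`` means 'above' is > cutoff."""

    cutoff: float
    strict: bool = True
    above_label: str = "high"
    below_label: str = "low"

    def assign(self, value: float) -> str:
        above = value > self.cutoff if self.strict else value >= self.cutoff
        return self.above_label if above else self.below_label


#: blood pH severity strata used for diabetic-ketoacidosis grading
PH_STRATA = IntervalScheme((
    Interval("severe", -np.inf, 7.10),
    Interval("moderate", 7.10, 7.32),
    Interval("normal", 7.32, np.inf),
))

#: binary blood pH split at 7.32 (less vs more severe onset)
PH_BINARY = IntervalScheme((
    Interval("pH<7.32", -np.inf, 7.32),
    Interval("pH>=7.32", 7.32, np.inf),
))

#: anti-GAD positivity cut-off (> 1 U/mL)
ANTI_GAD_SCHEME = ThresholdScheme(1.0, strict=True)


def stratify_samples(clinical: pd.DataFrame, variable: str,
                     scheme: IntervalScheme | ThresholdScheme) -> pd.Series:
    """Label each non-missing sample by the cut-off scheme.

    Samples with missing values (or, for interval schemes, values outside
    the scheme's range) are excluded with a log entry.
    """
    if variable not in clinical.columns:
        raise KeyError(f"clinical variable {variable!r} not found")
    values = clinical[variable]
    labels: dict[str, str] = {}
    dropped = []
    for sid, v in values.items():
        if pd.isna(v):
            dropped.append(sid)
            continue
        lab = scheme.assign(float(v))
        if lab is None:
            dropped.append(sid)
            continue
        labels[sid] = lab
    if dropped:
        log.info("stratify_samples(%s): excluded %d samples (missing/out of range)",
                 variable, len(dropped))
    return pd.Series(labels, name=f"{variable}_stratum")


# ---------------------------------------------------------------------------
# differential features
# ---------------------------------------------------------------------------

def differential_features(table, labels, test: str = "kruskal",
                          adjust: str = "bh_fdr", alpha: float = 0.05,
                          alpha_adjusted: float = 0.1) -> pd.DataFrame:
    """Per-feature group comparison with multiplicity control.

    Runs Kruskal-Wallis (any number of groups) or Mann-Whitney (two groups)
    on every feature, adjusts p-values, and flags features meeting *both*
    the raw threshold ``alpha`` and the adjusted threshold
    ``alpha_adjusted``.  Returns a TestResultTable-style DataFrame with
    per-group medians and the direction (group with the largest median).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != table.n_samples:
        raise ValueError("labels length does not match table")
    group_names = list(pd.unique(labels))
    X = table.values
    stats_, ps = [], []
    for j in range(X.shape[1]):
        col = X[:, j]
        if test == "kruskal":
            s, p = kruskal_wallis(col, labels)
        elif test == "mannwhitney":
            if len(group_names) != 2:
                raise ValueError("mannwhitney test requires exactly 2 groups")
            s, p = mann_whitney(col[labels == group_names[0]],
                                col[labels == group_names[1]])
        else:
            raise ValueError(f"unknown test {test!r}")
        stats_.append(s)
        ps.append(p)
    p_adj = adjust_pvalues(ps, method=adjust)
    medians = {f"median_{g}": np.median(X[labels == g], axis=0) for g in group_names}
    med_mat = np.column_stack([medians[f"median_{g}"] for g in group_names])
    direction = [str(group_names[int(np.argmax(row))]) for row in med_mat]
    out = pd.DataFrame({
        "feature": table.feature_ids,
        "statistic": stats_,
        "p": ps,
        "p_adj": p_adj,
        **medians,
        "direction": direction,
    })
    out["flag"] = (out["p"] <= alpha) & (out["p_adj"] <= alpha_adjusted)
    return out
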