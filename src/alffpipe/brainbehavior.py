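"""Brain-behavior correlation with FDR control, plus the WMH lesion rule.

Regional mean ALFF in clusters showing group differences is correlated
(Pearson) with the neurocognitive scores on which the patient group is
deficient relative to controls; the full cluster x score family of tests
is corrected with Benjamini-Hochberg FDR.  White-matter lesion burden is
classified pathological when the count exceeds one lesion per decade of
age.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

log = logging.getLogger(__name__)


def classify_wmh_pathological(n_lesions: int, age: float) -> bool:
    """Pathological lesion burden: strictly more than one lesion per decade."""
    if n_lesions < 0:
        raise InvalidInputError("lesion count must be non-negative")
    if age <= 0:
        raise InvalidInputError("age must be positive")
    return n_lesions > age / 10.0


def select_deficit_scores(
    cohort: pd.DataFrame,
    group_a: str = "SCD",
    group_b: str = "CTL",
    alpha: float = 0.05,
    score_columns: list[str] | None = None,
) -> list[str]:
    """Scores on which ``group_a`` is significantly lower than ``group_b``.

    One unadjusted two-sample t-test per score; a score qualifies only if
    the ``group_a`` mean is lower AND p < alpha.  Scores with fewer than
    two observations in either group are skipped with a warning.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError("alpha must lie in (0, 1)")
    for g in (group_a, group_b):
        if not (cohort["group"] == g).any():
            raise InvalidInputError(f"group {g!r} absent from cohort")
    if score_columns is None:
        reserved = {"subject_id", "group", "age", "wmh_count"}
        score_columns = [c for c in cohort.columns if c not in reserved]
    selected = []
    for score in score_columns:
        a = cohort.loc[cohort["group"] == group_a, score].dropna().to_numpy(float)
        b = cohort.loc[cohort["group"] == group_b, score].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            log.warning("score %r skipped: fewer than 2 observations per group", score)
            continue
        if a.mean() >= b.mean():
            continue
        t, p = stats.ttest_ind(a, b)
        if p < alpha:
            selected.append(score)
    return selected


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p (t transform, df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise InvalidInputError("Pearson correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, reject flags).

    Adjusted p_(i) = min_{j >= i} m p_(j) / j, clipped at 1; input order is
    preserved.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise InvalidInputError("q must lie in (0, 1)")
    reject, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


def correlate_clusters_scores(
    cohort: pd.DataFrame,
    regional_alff: np.ndarray,
    scores: list[str],
    q: float = 0.05,
    cluster_ids: list[int] | None = None,
) -> pd.DataFrame:
    """All (cluster, score) Pearson tests with BH-FDR over the full family.

    ``regional_alff`` rows align with cohort rows; missing scores are
    dropped pairwise per test with n reported per row.  Sorted by adjusted
    p.
    """
    regional_alff = np.asarray(regional_alff, dtype=float)
    if regional_alff.shape[0] != len(cohort):
        raise InvalidInputError("regional_alff rows must align with the cohort table")
    n_clusters = regional_alff.shape[1]
    if cluster_ids is None:
        cluster_ids = list(range(1, n_clusters + 1))
    if n_clusters == 0 or len(scores) == 0:
        log.warning("empty cluster or score set; returning empty correlation table")
        return pd.DataFrame(
            columns=["cluster_id", "score", "r", "p", "p_fdr", "significant", "n"]
        )
    rows = []
    for j, cid in enumerate(cluster_ids):
        for score in scores:
            y = cohort[score].to_numpy(float)
            x = regional_alff[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if int(ok.sum()) < 3:
                log.warning("pair (cluster %s, %s) skipped: n < 3", cid, score)
                continue
            r, p = pearson_r(x[ok], y[ok])
            rows.append(
                {"cluster_id": cid, "score": score, "r": r, "p": p, "n": int(ok.sum())}
            )
    if not rows:
        return pd.DataFrame(
            columns=["cluster_id", "score", "r", "p", "p_fdr", "significant", "n"]
        )
    table = pd.DataFrame(rows)
    p_adj, reject = bh_fdr(table["p"].to_numpy(), q=q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    table = table.sort_values("p_fdr", kind="stable").reset_index(drop=True)
    return table[["cluster_id", "score", "r", "p", "p_fdr", "significant", "n"]]
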