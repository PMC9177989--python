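"""Evaluation of predicted spatial fractions against region annotations.

* ``roc_auc`` — can a cell type's predicted fraction discriminate spots of
  its expected tissue region?  AUC equals the Mann-Whitney statistic
  (concordant pairs + half credit for ties, over all positive/negative
  pairs).
* ``auc_significance`` — one-sided Wilcoxon rank-sum p-value that fractions
  in the target region exceed the rest; the caller Bonferroni-corrects
  across (cell type x slide) comparisons and declares significance at
  corrected p < 0.05.
* ``domain_fraction_ranking`` — the tissue-domain mapping procedure: scale
  each type's fraction to [0, 1] across all spots, average per region, rank
  types within a region by in-region/out-region mean ratio, drop types with
  in-region scaled mean < 0.2, and attach BH-adjusted rank-sum p-values.

Spots labelled ``"unknown"`` are excluded from both positives and negatives.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import FractionMap
from .markers import bh_adjust

__all__ = [
    "roc_auc",
    "auc_significance",
    "bonferroni",
    "region_auc_report",
    "domain_fraction_ranking",
]

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "unknown"


def _validate_binary(scores, positives):
    scores = np.asarray(scores, dtype=np.float64)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape or scores.ndim != 1:
        raise ValueError("scores and positives must be 1-D arrays of equal length")
    if positives.all() or not positives.any():
        raise ValueError("need at least one positive and one negative spot")
    return scores, positives


def roc_auc(scores, positives) -> float:
    """AUC = (concordant + 0.5 * tied pairs) / (n_pos * n_neg)."""
    scores, positives = _validate_binary(scores, positives)
    return float(roc_auc_score(positives, scores))


def auc_significance(scores, positives, exact_limit: int = 25) -> float:
    """One-sided rank-sum p-value for positives' scores exceeding negatives'.

    Exact enumeration of the null when both groups have <= ``exact_limit``
    samples and no ties; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    scores, positives = _validate_binary(scores, positives)
    pos, neg = scores[positives], scores[~positives]
    has_ties = np.unique(scores).size < scores.size
    method = "exact" if (len(pos) <= exact_limit and len(neg) <= exact_limit and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="greater", method=method)
    return float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if m <= 0:
        raise ValueError("number of tests must be positive")
    return min(1.0, float(p) * m)


def region_auc_report(
    fm: FractionMap,
    type_to_region: dict[str, str],
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """AUC + significance for each (cell type, expected region) pair.

    ``type_to_region`` maps a cell type to the region where it should
    localize.  Bonferroni correction uses ``n_tests`` (defaults to the
    number of pairs evaluated).
    """
    if fm.region_label is None:
        raise ValueError("FractionMap has no region labels")
    labels = np.asarray(fm.region_label, dtype=object)
    known = labels != UNKNOWN_LABEL
    m = n_tests if n_tests is not None else len(type_to_region)
    rows = []
    for cell_type, region in type_to_region.items():
        j = fm.cell_types.index(cell_type)
        scores = fm.fractions[known, j]
        positives = labels[known] == region
        auc = roc_auc(scores, positives)
        p = auc_significance(scores, positives)
        p_corr = bonferroni(p, m)
        rows.append((cell_type, region, auc, p, p_corr, p_corr < alpha))
    return pd.DataFrame(
        rows,
        columns=["cell_type", "region", "AUC", "raw_p", "corrected_p", "significant"],
    )


def domain_fraction_ranking(
    fm: FractionMap,
    min_scaled_mean: float = 0.2,
    top_n: int = 7,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Rank cell types within each tissue region by relative enrichment.

    Per type, min-max scale its fraction across all spots; per region,
    compute the mean scaled fraction; rank by (mean in region) / (mean
    elsewhere), infinite ratios (zero elsewhere) sorting above all finite
    ones with ties broken by adjusted p; exclude types whose in-region mean
    scaled fraction is below ``min_scaled_mean``; attach BH-adjusted
    one-sided rank-sum p-values (region vs rest).  Returns the top
    ``top_n`` table per region.
    """
    if fm.region_label is None:
        raise ValueError("FractionMap has no region labels")
    labels = np.asarray(fm.region_label, dtype=object)
    regions = [r for r in pd.unique(labels) if r != UNKNOWN_LABEL]
    if len(regions) < 2:
        raise ValueError("domain ranking needs at least two regions")

    frac = fm.fractions
    lo, hi = frac.min(axis=0), frac.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (frac - lo) / span

    out: dict[str, pd.DataFrame] = {}
    for region in sorted(regions):
        mask = labels == region
        if not mask.any():
            logger.warning("region %r has no spots; skipped", region)
            continue
        other = (~mask) & (labels != UNKNOWN_LABEL)
        rows = []
        raw_ps = []
        for j, cell_type in enumerate(fm.cell_types):
            mean_in = scaled[mask, j].mean()
            mean_out = scaled[other, j].mean() if other.any() else 0.0
            ratio = np.inf if mean_out == 0 else mean_in / mean_out
            p = stats.mannwhitneyu(
                scaled[mask, j], scaled[other, j], alternative="greater",
                method="asymptotic",
            ).pvalue if other.any() else np.nan
            rows.append([cell_type, mean_in, mean_out, ratio])
            raw_ps.append(p)
        padj = bh_adjust(np.nan_to_num(np.asarray(raw_ps), nan=1.0))
        df = pd.DataFrame(rows, columns=["cell_type", "mean_in", "mean_out", "ratio"])
        df["raw_p"] = raw_ps
        df["adjusted_p"] = padj
        df["significant"] = df["adjusted_p"] < alpha
        df = df[df["mean_in"] >= min_scaled_mean]
        # infinite ratios first, then descending ratio, ties by adjusted p
        df = df.sort_values(
            by=["ratio", "adjusted_p"], ascending=[False, True], kind="stable"
        ).head(top_n)
        out[region] = df.reset_index(drop=True)
    return out
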