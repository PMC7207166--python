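"""Compound-level integration: z-scores, correlations, hit gating, KS enrichment.

The screen's per-assay inhibition percentages are standardized to z-scores
across the compound panel, correlated pairwise (Pearson) with explicit,
recorded exclusion lists (no automated outlier rejection), gated into
positive / negative hits against a reference compound's predicted score,
and annotated compound classes are tested for enrichment in high predicted
scores with a two-sample Kolmogorov-Smirnov test against the entire
compound population (class members included, as the population is defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

__all__ = [
    "zscore",
    "correlate",
    "select_hits",
    "ks_enrichment",
    "EnrichmentResult",
    "plot_ecdf_pair",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one class-vs-population KS enrichment test."""

    class_label: str
    n_class: int
    n_population: int
    statistic: float  # KS D in [0, 1]
    pvalue: float
    direction: str  # "two-sided" or "greater" (class shifted to higher scores)

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError("KS statistic must be in [0, 1]")
        if not 0.0 < self.pvalue <= 1.0 + 1e-12:
            raise ValueError("p-value must be in (0, 1]")


def zscore(values) -> np.ndarray:
    """Standardize to zero mean and unit sample standard deviation.

    NaNs are excluded from the moments and propagated in the output.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("need >= 2 finite values to standardize")
    mean = arr[finite].mean()
    sd = arr[finite].std(ddof=1)
    if sd <= 0:
        raise ValueError("zero variance; z-scores undefined")
    out = np.full(arr.shape, np.nan)
    out[finite] = (arr[finite] - mean) / sd
    return out


def correlate(x, y, exclude: set | None = None, ids=None):
    """Pearson correlation on pairwise-complete records minus explicit exclusions.

    ``ids`` aligns with ``x``/``y``; records whose id is in ``exclude`` are
    dropped, mirroring the screen's named exclusion of outlier compound
    classes (e.g. vinca alkaloids, which block the microscopy readouts).

    Returns ``(R, p, n_used, excluded_ids)`` with a two-sided t-based p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must align")
    exclude = set(exclude or ())
    if ids is None:
        ids = np.arange(x.size)
    ids = np.asarray(ids)
    keep = np.isfinite(x) & np.isfinite(y) & ~np.isin(ids, list(exclude))
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError(f"only {n_used} paired finite values after exclusion; need >= 3")
    res = stats.pearsonr(x[keep], y[keep])
    excluded_ids = sorted(str(i) for i in ids[np.isin(ids, list(exclude))])
    return float(res.statistic), float(res.pvalue), n_used, excluded_ids


def select_hits(table: pd.DataFrame, reference_id: str) -> pd.DataFrame:
    """Gate compounds into potential ICD inducers and negative hits.

    Positive hits entered clinical assays, have an IC50 below 1 uM
    (equivalently -log10 of the molar IC50 above 6) and a predicted score
    strictly above the reference compound's (the standard inducer,
    mitoxantrone in the original screen).  Negative hits are clinical
    compounds with IC50 above 1 uM and a predicted score below 1.  Everything
    else — the reference itself included — is unclassified.

    Requires columns ``compound_id``, ``ic50_uM``, ``icd_score``,
    ``clinical_flag``; returns a copy with a ``hit_class`` column in
    {"positive", "negative", "unclassified"}.
    """
    for col in ("compound_id", "ic50_uM", "icd_score", "clinical_flag"):
        if col not in table.columns:
            raise KeyError(f"required column {col!r} missing")
    ref = table.loc[table["compound_id"] == reference_id, "icd_score"]
    if ref.empty or not np.isfinite(ref.iloc[0]):
        raise ValueError(f"reference compound {reference_id!r} absent or has no score")
    ref_score = float(ref.iloc[0])
    out = table.copy()
    ic50_uM = out["ic50_uM"].to_numpy(dtype=float)
    score = out["icd_score"].to_numpy(dtype=float)
    clinical = out["clinical_flag"].to_numpy(dtype=bool)
    with np.errstate(divide="ignore"):
        neg_log_ic50 = -np.log10(ic50_uM * 1e-6)  # molar scale
    positive = (neg_log_ic50 > 6.0) & (score > ref_score) & clinical
    negative = (ic50_uM > 1.0) & (score < 1.0) & clinical
    out["hit_class"] = np.where(
        positive, "positive", np.where(negative, "negative", "unclassified")
    )
    return out


def ks_enrichment(
    table: pd.DataFrame,
    class_label: str,
    score_col: str = "icd_score",
    annotation_col: str = "annotations",
    alternative: str = "two-sided",
    disjoint_background: bool = False,
) -> tuple[EnrichmentResult, tuple[ECDF, ECDF]]:
    """KS test of an annotated class's scores against the entire population.

    The population is the full table (class members included) unless
    ``disjoint_background`` is set.  ``alternative="greater"`` tests whether
    the class is shifted toward *higher* scores (one-sided); the default is
    two-sided.  Returns the enrichment result and the (class, population)
    empirical distribution functions for plotting.
    """
    if annotation_col not in table.columns or score_col not in table.columns:
        raise KeyError(f"columns {annotation_col!r} and {score_col!r} required")
    in_class = table[annotation_col].astype(str).str.contains(
        class_label, regex=False
    ) & (table[annotation_col].astype(str) != "")
    class_scores = table.loc[in_class, score_col].dropna().to_numpy(dtype=float)
    if class_scores.size < 2:
        raise ValueError(
            f"class {class_label!r} has {class_scores.size} scored members; need >= 2"
        )
    if disjoint_background:
        pop = table.loc[~in_class, score_col].dropna().to_numpy(dtype=float)
    else:
        pop = table[score_col].dropna().to_numpy(dtype=float)
    if pop.size < 10:
        raise ValueError("population too small (< 10 compounds)")
    if alternative == "greater":
        # class shifted to higher scores <=> its CDF lies below the population's
        res = stats.ks_2samp(class_scores, pop, alternative="less")
        direction = "greater"
    elif alternative == "two-sided":
        res = stats.ks_2samp(class_scores, pop, alternative="two-sided")
        direction = "two-sided"
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    result = EnrichmentResult(
        class_label=class_label,
        n_class=int(class_scores.size),
        n_population=int(pop.size),
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        direction=direction,
    )
    return result, (ECDF(class_scores), ECDF(pop))


def plot_ecdf_pair(result: EnrichmentResult, ecdfs, path: str) -> None:
    """Export the class-vs-population ECDF pair as a vector plot."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    class_ecdf, pop_ecdf = ecdfs
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.step(pop_ecdf.x, pop_ecdf.y, color="black", where="post",
            label=f"all compounds (n={result.n_population})")
    ax.step(class_ecdf.x, class_ecdf.y, color="red", where="post",
            label=f"{result.class_label} (n={result.n_class})")
    ax.set_xlabel("ICD prediction score")
    ax.set_ylabel("cumulative fraction")
    ax.set_title(f"KS D={result.statistic:.3f}, p={result.pvalue:.2e}")
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
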