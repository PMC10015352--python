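"""Method-comparison and screening statistics for bilirubin validation.

The validation machinery mirrors how smartphone bilirubin estimates are
compared with total serum bilirubin (TSB) in clinical studies: Pearson
correlation, Bland-Altman agreement (bias and limits of agreement
bias +/- z sd of the paired differences), empirical ROC analysis against a
severe-hyperbilirubinemia definition (TSB > 250 umol/L) with the Youden
cutoff, Kruskal-Wallis with Dunn's post hoc test across measurement
methods, and recruitment accounting.  Unit conversion uses
1 mg/dL = 17.1 umol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forward_model import BilicamError

UMOL_PER_MGDL = 17.1

#: severe neonatal hyperbilirubinemia definition, umol/L
SEVERE_TSB_UMOL_L = 250.0


def umol_to_mgdl(x: float | np.ndarray) -> float | np.ndarray:
    """Convert bilirubin umol/L -> mg/dL (divide by 17.1; round only for display)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise BilicamError("bilirubin concentrations must be >= 0")
    out = x / UMOL_PER_MGDL
    return float(out) if out.ndim == 0 else out


def mgdl_to_umol(x: float | np.ndarray) -> float | np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise BilicamError("bilirubin concentrations must be >= 0")
    out = x * UMOL_PER_MGDL
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementStats:
    pearson_r: float
    p_value: float
    bias: float            # mean(x - y)
    loa_lower: float       # bias - z sd
    loa_upper: float       # bias + z sd
    n: int


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise BilicamError("pearson needs paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise BilicamError("pearson undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(x, y, z: float = 1.96) -> tuple[AgreementStats, pd.DataFrame]:
    """Bland-Altman agreement of paired measurements x (device) vs y (reference).

    Differences d = x - y; bias = mean(d); limits of agreement
    bias +/- z sd(d) with the sample (n-1) standard deviation.  Returns the
    statistics and the plot data (pair means vs differences).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise BilicamError("bland_altman needs paired samples with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    r, p = pearson(x, y) if x.size >= 3 and np.std(x) > 0 and np.std(y) > 0 \
        else (float("nan"), float("nan"))
    st = AgreementStats(pearson_r=r, p_value=p, bias=bias,
                        loa_lower=bias - z * sd, loa_upper=bias + z * sd,
                        n=int(x.size))
    plot = pd.DataFrame({"mean": (x + y) / 2.0, "difference": d})
    return st, plot


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningStats:
    roc: pd.DataFrame          # cutoff, sensitivity, specificity (cutoffs sorted)
    auc: float
    youden_cutoff: float
    sensitivity: float         # at the Youden cutoff
    specificity: float
    disease_threshold: float   # TSB definition used for labels, umol/L


def sens_spec_at(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of the predicate score > cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise BilicamError("both classes must be present")
    pred = scores > cutoff
    sens = float(np.sum(pred & labels) / np.sum(labels))
    spec = float(np.sum(~pred & ~labels) / np.sum(~labels))
    return sens, spec


def roc(scores, labels, disease_threshold: float = SEVERE_TSB_UMOL_L
        ) -> ScreeningStats:
    """Empirical ROC over all distinct cutoffs with the predicate score > cutoff.

    AUC by trapezoid over the step curve, which equals the pair-counting
    identity [#(pos > neg) + 1/2 #(pos = neg)] / (n_pos n_neg).  The Youden
    cutoff maximizes sensitivity + specificity - 1, taking the smallest
    cutoff on ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise BilicamError("both classes must be present")
    cutoffs = np.concatenate([[scores.min() - 1.0], np.unique(scores)])
    rows = [(c, *sens_spec_at(scores, labels, c)) for c in cutoffs]
    table = pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity"])
    fpr = 1.0 - table["specificity"].to_numpy()
    tpr = table["sensitivity"].to_numpy()
    order = np.argsort(fpr, kind="stable")
    auc = float(-np.trapezoid(tpr, fpr))  # cutoff ascending = fpr descending
    j = tpr + table["specificity"].to_numpy() - 1.0
    best = np.flatnonzero(j == j.max())
    youden = float(table["cutoff"].iloc[best.min()])
    sens, spec = sens_spec_at(scores, labels, youden)
    return ScreeningStats(roc=table, auc=auc, youden_cutoff=youden,
                          sensitivity=sens, specificity=spec,
                          disease_threshold=disease_threshold)


def auc_pair_counting(scores, labels) -> float:
    """O(n^2) pair-counting AUC: oracle for the trapezoid computation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def kruskal_dunn(groups: list, adjust: str = "bonferroni"
                 ) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn pairwise post hoc z tests.

    Returns (H, p, table of pairwise z and Bonferroni-adjusted p).  All
    observations identical is the degenerate H = 0, p = 1 path.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise BilicamError("kruskal_dunn needs >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise BilicamError("kruskal_dunn needs total n >= 3")
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)
        H, p = float(H), float(p)
    # Dunn: z on mean ranks with tie correction
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(groups))]
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p_adj = min(p_raw * n_pairs, 1.0)
            elif adjust == "none":
                p_adj = p_raw
            else:
                raise BilicamError(f"unknown adjustment {adjust!r}")
            rows.append({"group_i": i, "group_j": j, "z": float(z),
                         "p_raw": float(p_raw), "p_adjusted": float(p_adj)})
    return H, p, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Accounting and end-to-end validation
# ---------------------------------------------------------------------------

def cohort_accounting(recruited: int, exclusions: list[tuple[str, int]] | list[int],
                      decimals: int = 1) -> tuple[int, float]:
    """Remaining count and percentage after a chain of exclusions.

    ``decimals=0`` gives integer-style percentages (81 rather than 81.0).
    """
    ns = [e[1] if isinstance(e, tuple) else int(e) for e in exclusions]
    if any(n < 0 for n in ns) or recruited < 0:
        raise BilicamError("counts must be nonnegative")
    remaining = recruited - sum(ns)
    if remaining < 0:
        raise BilicamError("exclusions exceed the recruited count")
    percent = round(100.0 * remaining / recruited, decimals) if recruited else 0.0
    return remaining, percent


@dataclass
class MethodComparison:
    data: pd.DataFrame  # subject_id, device_umol_L, tsb_umol_L [, tcb_umol_L]

    def __post_init__(self) -> None:
        need = {"subject_id", "device_umol_L", "tsb_umol_L"}
        if not need.issubset(self.data.columns):
            raise BilicamError(f"MethodComparison requires columns {sorted(need)}")
        if self.data[["device_umol_L", "tsb_umol_L"]].isna().any().any():
            raise BilicamError("device vs TSB pairs must be complete")
        if (self.data[["device_umol_L", "tsb_umol_L"]] < 0).any().any():
            raise BilicamError("bilirubin values must be >= 0")


def validate_cohort(manifest: pd.DataFrame, results: pd.DataFrame,
                    disease_threshold: float = SEVERE_TSB_UMOL_L) -> dict:
    """Join truth and measurements on subject id, then run the full analysis.

    ``manifest`` needs subject_id and true_tsb_umol_L; ``results`` needs
    subject_id and estimate_umol_L (NaN for rejected sets).  Returns a report
    dict with the comparison table, agreement and screening statistics, and
    per-subject join failures.
    """
    for df, col in ((manifest, "true_tsb_umol_L"), (results, "estimate_umol_L")):
        if "subject_id" not in df.columns or col not in df.columns:
            raise BilicamError(f"missing required columns (subject_id, {col})")
    merged = manifest.merge(results, on="subject_id", how="outer", indicator=True)
    join_failures = merged.loc[merged["_merge"] != "both", "subject_id"].tolist()
    paired = merged[merged["_merge"] == "both"].dropna(
        subset=["true_tsb_umol_L", "estimate_umol_L"])
    if len(paired) == 0:
        raise BilicamError(
            f"no usable subject pairs; join failures: {join_failures}")
    comparison = MethodComparison(pd.DataFrame({
        "subject_id": paired["subject_id"],
        "device_umol_L": paired["estimate_umol_L"].astype(float),
        "tsb_umol_L": paired["true_tsb_umol_L"].astype(float),
    }).reset_index(drop=True))
    x = comparison.data["device_umol_L"].to_numpy()
    y = comparison.data["tsb_umol_L"].to_numpy()
    agreement, ba_plot = bland_altman(x, y)
    labels = y > disease_threshold
    screening = roc(x, labels, disease_threshold) \
        if labels.any() and not labels.all() else None
    return {
        "comparison": comparison,
        "agreement": agreement,
        "bland_altman_plot": ba_plot,
        "screening": screening,
        "join_failures": join_failures,
        "n_pairs": int(len(paired)),
        "median_abs_error_umol_L": float(np.median(np.abs(x - y))),
    }
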