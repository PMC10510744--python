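"""Population-level statistics over electrodes.

Responsive-electrode selection (paired t + Benjamini-Hochberg FDR),
subject-controlled t-tests, mixed-effects prediction of the CNN's
correlation improvement from adaptation indices, Ward clustering of
noise-filtering feature profiles, and group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["select_responsive", "subject_controlled_ttest",
           "fit_improvement_model", "ClusterResult",
           "cluster_noise_filtering", "compare_groups",
           "InsufficientDataError"]


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# electrode selection

def select_responsive(pre: np.ndarray, post: np.ndarray,
                      q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Speech-responsive electrode selection.

    pre, post : (n_electrodes, n_window) response windows immediately
    before / after speech onset (time-point-wise pairing). A per-electrode
    paired t-test is corrected across electrodes with Benjamini-Hochberg at
    rate ``q``; returns (selected boolean mask, adjusted p-values).
    """
    pre = np.atleast_2d(pre)
    post = np.atleast_2d(post)
    if pre.shape != post.shape:
        raise ValueError("pre/post windows must share a shape")
    t, p = stats.ttest_rel(post, pre, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# subject-controlled tests

def subject_controlled_ttest(values: np.ndarray, subject_ids,
                             ) -> tuple[float, float]:
    """One-sample t-test on electrode values with subject identity
    regressed out.

    Implements the linear-model form of the test: values are regressed on
    an intercept plus subject-indicator columns; the returned statistic is
    the intercept's t. Indicator columns are centered so the intercept
    estimates the grand mean — with a single subject this is exactly the
    ordinary one-sample t-test. For paired comparisons pass per-electrode
    differences.
    """
    values = np.asarray(values, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if len(values) != len(subject_ids):
        raise ValueError("one subject label per value required")
    subjects = np.unique(subject_ids)
    n, k = len(values), len(subjects)
    if n - k < 2:
        raise InsufficientDataError(
            "not enough electrodes per subject for a subject-controlled test")
    if np.allclose(values, 0.0):
        return 0.0, 1.0
    x = np.ones((n, k))  # intercept + (k-1) centered indicators
    for j, s in enumerate(subjects[:-1]):
        col = (subject_ids == s).astype(float)
        x[:, j + 1] = col - col.mean()
    import statsmodels.api as sm

    fit = sm.OLS(values, x).fit()
    return float(fit.tvalues[0]), float(fit.pvalues[0])


# ---------------------------------------------------------------------------
# mixed-effects improvement model

def fit_improvement_model(indices: pd.DataFrame, improvement: np.ndarray,
                          subject_ids) -> pd.DataFrame:
    """Predict correlation improvement from adaptation indices with a
    subject random intercept.

    indices : DataFrame of per-electrode predictor columns (e.g.
    ``gain_change`` and ``noise_filtering``); improvement : per-electrode
    CNN-minus-STRF correlation. Fits
    improvement ~ 1 + predictors + (1 | subject) and returns a table of
    fixed effects with 95% CIs, p-values and the model's prediction
    correlation. Falls back to OLS (with a warning flag) if the random
    effect is singular or the data have a single subject.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = indices.copy()
    predictors = list(df.columns)
    df["improvement"] = np.asarray(improvement, dtype=float)
    df["subject"] = np.asarray(subject_ids)
    df = df.dropna()
    if len(df) < 10:
        raise InsufficientDataError("need >= 10 electrodes")
    formula = "improvement ~ " + " + ".join(predictors)
    names = ["Intercept"] + predictors

    def extract(fit, fallback):
        ci = fit.conf_int()
        rows = []
        for name in names:
            rows.append(dict(
                term=name, estimate=float(fit.params[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                p=float(fit.pvalues[name]),
                significant=bool(fit.pvalues[name] < 0.05),
                fallback_ols=fallback))
        return rows, np.asarray(fit.fittedvalues)

    rows = pred = None
    fallback = df["subject"].nunique() < 2
    if not fallback:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, df, groups=df["subject"])
                fit = md.fit(reml=True, method="lbfgs")
                if not np.isfinite(fit.params).all():
                    raise ValueError("non-finite mixed-model fit")
                rows, pred = extract(fit, False)
        except Exception:
            rows, fallback = None, True
    if rows is None:
        fit = smf.ols(formula, df).fit()
        rows, pred = extract(fit, True)
    r = (np.corrcoef(pred, df["improvement"])[0, 1]
         if df["improvement"].std() > 0 else np.nan)
    out = pd.DataFrame(rows)
    out.attrs["prediction_r"] = float(r)
    out.attrs["n"] = int(len(df))
    return out


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterResult:
    """Two-way Ward clustering of noise-filtering feature profiles."""

    features: np.ndarray          # (n_electrodes, 8)
    linkage: np.ndarray
    groups: np.ndarray            # 1 or 2 per electrode
    electrode_index: np.ndarray
    degenerate: bool = False
    n_dropped: int = 0

    def group_members(self, g: int) -> np.ndarray:
        return self.electrode_index[self.groups == g]


def cluster_noise_filtering(features: np.ndarray,
                            electrode_index=None,
                            exc_to_noise_cols=(0, 1, 2)) -> ClusterResult:
    """Ward-linkage (minimum variance, Euclidean) clustering into 2 groups.

    features : (n, 8) matrix of excitatory + inhibitory noise-filtering
    indices across the 4 to-conditions. Rows with missing entries must be
    removed by the caller. Group labels are ordered so group 1 has the
    higher mean excitatory to-noise index, making labels stable for
    planted-population recovery.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 4:
        raise ValueError("need >= 4 complete electrodes to cluster")
    if np.isnan(features).any():
        raise ValueError("features must be complete (drop missing rows)")
    if electrode_index is None:
        electrode_index = np.arange(features.shape[0])
    z = linkage(features, method="ward")
    labels = fcluster(z, t=2, criterion="maxclust")
    degenerate = len(np.unique(labels)) < 2
    exc_cols = list(exc_to_noise_cols)
    if not degenerate:
        m1 = features[labels == 1][:, exc_cols].mean()
        m2 = features[labels == 2][:, exc_cols].mean()
        if m2 > m1:
            labels = 3 - labels
    return ClusterResult(features, z, labels, np.asarray(electrode_index),
                         degenerate=degenerate)


# ---------------------------------------------------------------------------
# group comparison

def compare_groups(group_labels: np.ndarray, adaptation_indices: np.ndarray,
                   aligned_responses: np.ndarray | None = None,
                   rel_times: np.ndarray | None = None,
                   baseline_window: tuple[float, float] = (2.0, 3.0),
                   alpha: float = 0.05) -> dict:
    """Compare the two clustered groups.

    - Wilcoxon rank-sum test on per-electrode mean adaptation indices.
    - Optionally, a timepoint-wise rank-sum on transition-aligned responses
      (per-electrode baseline, the mean over ``baseline_window`` seconds
      post-transition, subtracted first), reporting the longest contiguous
      region with p < alpha. Per the source convention this uses raw
      (uncorrected) p-values; flagged in the report.
    """
    group_labels = np.asarray(group_labels)
    adaptation_indices = np.asarray(adaptation_indices, dtype=float)
    g1 = adaptation_indices[group_labels == 1]
    g2 = adaptation_indices[group_labels == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise InsufficientDataError("each group needs >= 2 electrodes")
    stat, p = stats.ranksums(g2, g1)
    report = dict(
        adaptation_ranksum=float(stat), adaptation_p=float(p),
        n_group1=int(len(g1)), n_group2=int(len(g2)),
        group2_minus_group1_median=float(np.median(g2) - np.median(g1)),
        multiplicity_correction="none (raw p < %.2f per timepoint)" % alpha,
    )
    if aligned_responses is not None:
        if rel_times is None:
            raise ValueError("rel_times required with aligned_responses")
        resp = np.asarray(aligned_responses, dtype=float)
        base = ((rel_times >= baseline_window[0])
                & (rel_times < baseline_window[1]))
        if base.any():
            resp = resp - resp[:, base].mean(axis=1, keepdims=True)
        r1 = resp[group_labels == 1]
        r2 = resp[group_labels == 2]
        pvals = np.array([stats.ranksums(r2[:, i], r1[:, i]).pvalue
                          for i in range(resp.shape[1])])
        sig = pvals < alpha
        start, length = _longest_run(sig)
        region = (None if length == 0 else
                  (float(rel_times[start]),
                   float(rel_times[start + length - 1])))
        report.update(timepoint_p=pvals, significant_mask=sig,
                      significant_region_s=region)
    return report


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    best_start, best_len, cur_start, cur_len = 0, 0, 0, 0
    for i, v in enumerate(mask):
        if v:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    return best_start, best_len
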