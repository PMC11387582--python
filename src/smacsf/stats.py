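"""Group-level and per-protein statistics.

Contrasts and their significance rules:

* PERMANOVA (Euclidean distance, one factor at a time) for whether a design
  factor explains variance in the whole proteome profile.
* ANCOVA screen at baseline: per protein, ``abundance ~ subtype + age``; the
  subtype effect is tested with a partial (Type-II) F adjusted for age, and
  proteins are flagged at raw p < 0.05.
* Paired treatment test: per protein and subtype, two-sided paired t-test of
  T302 vs T0 over patients with both timepoints observed; BH-adjusted within
  the subtype's protein list, flagged at adjusted p < 0.05.
* Responder contrast: per patient log2 fold change Delta = T302 - T0, then an
  unpaired two-sided t-test (Welch by default) of responders vs
  non-responders; flagged at raw p < 0.05.

The sign convention is global: positive effects mean higher at T302, or
higher in responders.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import IntensityMatrix

__all__ = [
    "PermanovaResult",
    "permanova",
    "ancova_screen",
    "paired_treatment_test",
    "responder_contrast",
    "bh_adjust",
    "classify_responders",
    "patient_fold_changes",
]

CHOP_MAX = 64
HFMSE_MAX = 66


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PERMANOVA


class PermanovaResult:
    """Pseudo-F and permutation p for one factor."""

    def __init__(self, factor, pseudo_f, p_value, n_permutations, seed, exhaustive=False):
        self.factor = factor
        self.pseudo_f = float(pseudo_f)
        self.p_value = float(p_value)
        self.n_permutations = n_permutations
        self.seed = seed
        self.exhaustive = exhaustive

    def __repr__(self) -> str:
        return (
            f"PermanovaResult({self.factor!r}, F={self.pseudo_f:.4f}, "
            f"p={self.p_value:.4g}, n_perm={self.n_permutations})"
        )


def euclidean_distance(matrix: IntensityMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns)."""
    X = matrix.values.to_numpy().T
    if np.isnan(X).any():
        raise ValueError("distance computation requires a complete matrix")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances: (SS_b/(a-1)) / (SS_w/(N-a))."""
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    a = n_groups
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    distance: pd.DataFrame,
    labels: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "group",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    p = (#{permuted F >= observed} + 1) / (n_permutations + 1) for Monte
    Carlo permutations; with ``exhaustive=True`` every distinct label
    ordering is enumerated (the identity included) and p is the exact
    fraction with F >= observed.
    """
    d = distance.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.isnan(d).any():
        raise ValueError("NaN distances")
    labels = labels.reindex(distance.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    names, codes = np.unique(labels.to_numpy(), return_inverse=True)
    if len(names) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs at least 2 members")
    d2 = d**2
    f_obs = _pseudo_f(d2, codes, len(names))

    if exhaustive:
        seen = set()
        count = total = 0
        for perm in permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if _pseudo_f(d2, np.array(perm), len(names)) >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(factor, f_obs, count / total, total, None, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _pseudo_f(d2, rng.permutation(codes), len(names)) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(factor, f_obs, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# per-protein contrasts


def _differential_frame(rows: list[dict], adjust: bool, alpha: float, use_adjusted: bool) -> pd.DataFrame:
    table = pd.DataFrame(
        rows, columns=["protein_id", "contrast", "effect", "t", "p"]
    ).set_index("protein_id")
    ok = table["p"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    crit = table["p_adj"] if use_adjusted else table["p"]
    table["significant"] = crit.notna() & (crit < alpha)
    table["direction"] = np.sign(table["effect"].fillna(0.0)).astype(int)
    return table


def ancova_screen(
    matrix: IntensityMatrix, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Age-adjusted subtype screen at baseline.

    Per protein fits ``abundance ~ subtype + age`` on observed values and
    tests the subtype term with a partial F against the age-only model.
    Zero-variance proteins are excluded (p = NaN).  Raw p < alpha flags
    significance, matching the screen's stated rule; BH-adjusted values are
    still reported.
    """
    t0_meta = meta[meta["timepoint"] == "T0"].set_index("sample_id")
    if t0_meta["subtype"].nunique() < 2:
        raise ValueError("ANCOVA needs at least 2 subtypes")
    age = t0_meta["age_years"].to_numpy(float)
    if not np.isfinite(age).all():
        raise ValueError("non-finite ages")
    sub = pd.get_dummies(t0_meta["subtype"], drop_first=True).to_numpy(float)
    t0 = matrix.subset_samples(t0_meta.index)
    n_sub = sub.shape[1]
    rows = []
    for pid, x in t0.values.iterrows():
        obs = x.notna().to_numpy()
        y = x.to_numpy(float)[obs]
        n = obs.sum()
        df_resid = n - (2 + n_sub)
        if n < 3 + n_sub or np.ptp(y) == 0 or df_resid < 1:
            rows.append({"protein_id": pid, "contrast": "subtype|age", "effect": np.nan, "t": np.nan, "p": np.nan})
            continue
        ones = np.ones((n, 1))
        X_full = np.hstack([ones, sub[obs], age[obs, None]])
        X_red = np.hstack([ones, age[obs, None]])
        rss_full = _rss(X_full, y)
        rss_red = _rss(X_red, y)
        f = ((rss_red - rss_full) / n_sub) / (rss_full / df_resid)
        f = max(f, 0.0)
        p = float(sps.f.sf(f, n_sub, df_resid))
        # effect: span of age-adjusted subtype means (descriptive)
        beta = np.linalg.lstsq(X_full, y, rcond=None)[0]
        effect = float(np.ptp(np.concatenate([[0.0], beta[1 : 1 + n_sub]])))
        rows.append({"protein_id": pid, "contrast": "subtype|age", "effect": effect, "t": f, "p": p})
    return _differential_frame(rows, adjust=True, alpha=alpha, use_adjusted=False)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def paired_treatment_test(
    matrix: IntensityMatrix, meta: pd.DataFrame, subtype: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired two-sided t-test of T302 vs T0 within one subtype.

    Uses patients with both timepoints observed for the protein; proteins
    with fewer than 3 complete pairs are reported with NaN p.  BH adjustment
    runs within this subtype's protein list and adjusted p < alpha flags
    significance.  Positive effect = higher at T302.
    """
    sub = meta[meta["subtype"] == subtype]
    if sub.empty:
        raise ValueError(f"no samples for subtype {subtype}")
    t0_ids = sub[sub["timepoint"] == "T0"].set_index("patient_id")["sample_id"]
    t1_ids = sub[sub["timepoint"] == "T302"].set_index("patient_id")["sample_id"]
    patients = t0_ids.index.intersection(t1_ids.index)
    a = matrix.values.loc[:, t0_ids.loc[patients]].to_numpy(float)
    b = matrix.values.loc[:, t1_ids.loc[patients]].to_numpy(float)
    rows = []
    for i, pid in enumerate(matrix.protein_ids):
        ok = ~np.isnan(a[i]) & ~np.isnan(b[i])
        if ok.sum() < 3:
            rows.append({"protein_id": pid, "contrast": f"{subtype}:T302-T0", "effect": np.nan, "t": np.nan, "p": np.nan})
            continue
        diff = b[i, ok] - a[i, ok]
        if np.ptp(diff) == 0 and diff[0] == 0:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = sps.ttest_rel(b[i, ok], a[i, ok])
        rows.append(
            {
                "protein_id": pid,
                "contrast": f"{subtype}:T302-T0",
                "effect": float(diff.mean()),
                "t": float(t_stat),
                "p": float(p),
            }
        )
    return _differential_frame(rows, adjust=True, alpha=alpha, use_adjusted=True)


def patient_fold_changes(matrix: IntensityMatrix, meta: pd.DataFrame, subtype: str) -> pd.DataFrame:
    """Per-patient log2 fold-change matrix Delta = T302 - T0 (proteins x
    patients) for one subtype; cells missing at either timepoint are NaN."""
    sub = meta[meta["subtype"] == subtype]
    t0_ids = sub[sub["timepoint"] == "T0"].set_index("patient_id")["sample_id"]
    t1_ids = sub[sub["timepoint"] == "T302"].set_index("patient_id")["sample_id"]
    patients = list(t0_ids.index.intersection(t1_ids.index))
    a = matrix.values.loc[:, t0_ids.loc[patients]].to_numpy(float)
    b = matrix.values.loc[:, t1_ids.loc[patients]].to_numpy(float)
    return pd.DataFrame(b - a, index=matrix.protein_ids, columns=patients)


def responder_contrast(
    matrix: IntensityMatrix,
    meta: pd.DataFrame,
    subtype: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Responder vs non-responder comparison of per-patient fold changes.

    Effect = mean Delta(responders) - mean Delta(non-responders); unpaired
    two-sided t-test (Welch by default, pooled with ``equal_var=True``);
    raw p < alpha flags significance.
    """
    delta = patient_fold_changes(matrix, meta, subtype)
    flags = (
        meta[(meta["subtype"] == subtype) & (meta["timepoint"] == "T0")]
        .set_index("patient_id")["responder"]
        .reindex(delta.columns)
    )
    if flags.isna().any():
        raise ValueError("responder flags missing for some patients")
    r_cols = flags[flags.astype(bool)].index
    n_cols = flags[~flags.astype(bool)].index
    if len(r_cols) < 2 or len(n_cols) < 2:
        raise ValueError(f"subtype {subtype} needs >=2 patients in each responder class")
    rows = []
    for pid, x in delta.iterrows():
        xr = x[r_cols].dropna().to_numpy()
        xn = x[n_cols].dropna().to_numpy()
        if len(xr) < 2 or len(xn) < 2:
            rows.append({"protein_id": pid, "contrast": f"{subtype}:R-nonR", "effect": np.nan, "t": np.nan, "p": np.nan})
            continue
        t_stat, p = sps.ttest_ind(xr, xn, equal_var=equal_var)
        rows.append(
            {
                "protein_id": pid,
                "contrast": f"{subtype}:R-nonR",
                "effect": float(xr.mean() - xn.mean()),
                "t": float(t_stat),
                "p": float(p),
            }
        )
    return _differential_frame(rows, adjust=True, alpha=alpha, use_adjusted=False)


def classify_responders(meta: pd.DataFrame) -> pd.Series:
    """Responder flags from motor scores: CHOP-INTEND gain >= 4 points for
    SMA1, HFMSE gain >= 3 points for SMA2/SMA3, between T0 and T302.

    Returns a patient-indexed boolean Series (NaN when a score is missing).
    """
    scores = meta.pivot_table(
        index=["patient_id", "subtype"], columns="timepoint", values="motor_score", aggfunc="first"
    ).reset_index()
    out = {}
    for _, row in scores.iterrows():
        subtype = row["subtype"]
        max_score = CHOP_MAX if subtype == "SMA1" else HFMSE_MAX
        s0, s1 = row.get("T0", np.nan), row.get("T302", np.nan)
        if pd.isna(s0) or pd.isna(s1):
            out[row["patient_id"]] = np.nan
            continue
        for s in (s0, s1):
            if s < 0 or s > max_score:
                raise ValueError(
                    f"motor score {s} out of range [0, {max_score}] for {row['patient_id']}"
                )
        gain = s1 - s0
        out[row["patient_id"]] = bool(gain >= (4 if subtype == "SMA1" else 3))
    return pd.Series(out, name="responder")
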