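"""PERMANOVA, ANCOVA screen, paired/responder contrasts, BH, responder rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smacsf import (
    IntensityMatrix,
    ancova_screen,
    bh_adjust,
    classify_responders,
    euclidean_distance,
    paired_treatment_test,
    permanova,
    responder_contrast,
)
from smacsf.cohort import CohortDesign, generate_cohort

from conftest import null_design

# ---------------------------------------------------------------------------
# PERMANOVA


def _dist(points):
    points = np.asarray(points, float)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = [f"S{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


def _labels(groups):
    return pd.Series(groups, index=[f"S{i}" for i in range(len(groups))])


def exhaustive_permanova_p(distance, labels):
    """Independent oracle: enumerate every assignment of group sizes to
    positions (combinations, not permutations) and count F >= observed."""
    d2 = distance.to_numpy() ** 2
    codes = pd.factorize(labels)[0]
    n = len(codes)
    n_groups = codes.max() + 1

    def pseudo_f(assign):
        ss_total = d2.sum() / (2 * n)
        ss_within = 0.0
        for g in range(n_groups):
            idx = np.where(assign == g)[0]
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        a = n_groups
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(codes)
    sizes = np.bincount(codes)
    count = total = 0
    for combo in itertools.combinations(range(n), sizes[0]):
        assign = np.ones(n, dtype=int)
        assign[list(combo)] = 0
        total += 1
        if pseudo_f(assign) >= f_obs - 1e-12:
            count += 1
    return count / total


def test_identical_groups_give_zero_pseudo_f():
    pts = [[0, 0], [1, 1], [2, 0]] * 2  # two groups occupying the same points
    res = permanova(_dist(pts), _labels(["a", "a", "a", "b", "b", "b"]), exhaustive=True)
    assert res.pseudo_f == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_exhaustive_p_matches_combination_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(6, 3))
    labels = _labels(["a"] * 3 + ["b"] * 3)
    ours = permanova(_dist(pts), labels, exhaustive=True)
    assert ours.p_value == pytest.approx(exhaustive_permanova_p(_dist(pts), labels))


def test_monte_carlo_p_converges_to_enumeration():
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(6, 3))
    labels = _labels(["a"] * 3 + ["b"] * 3)
    exact = exhaustive_permanova_p(_dist(pts), labels)
    mc = permanova(_dist(pts), labels, n_permutations=9999, seed=0)
    assert mc.p_value == pytest.approx(exact, abs=0.02)


def test_separated_groups_reach_minimum_attainable_p():
    rng = np.random.default_rng(1)
    pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(50, 0.1, (10, 2))])
    res = permanova(_dist(pts), _labels(["a"] * 10 + ["b"] * 10), n_permutations=999, seed=3)
    assert res.p_value == pytest.approx(1 / 1000)


def test_pseudo_f_matches_scikit_bio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(5)
    pts = rng.normal(size=(12, 4))
    pts[:6] += 1.0
    labels = ["a"] * 6 + ["b"] * 6
    ours = permanova(_dist(pts), _labels(labels), n_permutations=99, seed=0)
    theirs = skbio_permanova(DistanceMatrix(_dist(pts).to_numpy()), labels, permutations=99)
    assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_permanova_input_validation():
    d = _dist([[0, 0], [1, 0], [2, 0], [3, 0]])
    with pytest.raises(ValueError, match="2 groups"):
        permanova(d, _labels(["a"] * 4))
    with pytest.raises(ValueError, match="at least 2 members"):
        permanova(d, _labels(["a", "a", "a", "b"]))
    bad = d.copy()
    bad.iloc[0, 1] = np.nan
    bad.iloc[1, 0] = np.nan
    with pytest.raises(ValueError, match="NaN|symmetric"):
        permanova(bad, _labels(["a", "a", "b", "b"]))


# ---------------------------------------------------------------------------
# ANCOVA screen


def _t0_meta(n_per=10, age_by_subtype=(2.0, 8.0, 15.0), age_spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for k, subtype in enumerate(("SMA1", "SMA2", "SMA3")):
        for j in range(n_per):
            rows.append(
                {
                    "sample_id": f"{subtype}_{j}_T0",
                    "patient_id": f"{subtype}_{j}",
                    "subtype": subtype,
                    "timepoint": "T0",
                    "age_years": age_by_subtype[k] + rng.uniform(-age_spread, age_spread),
                }
            )
    return pd.DataFrame(rows)


def test_pure_age_effect_not_attributed_to_subtype():
    """Proteins that are linear in age (with age confounded with subtype)
    are flagged for subtype at about the nominal alpha rate."""
    meta = _t0_meta(n_per=12, seed=1)
    rng = np.random.default_rng(2)
    age = meta["age_years"].to_numpy()
    n_prot = 400
    vals = 0.3 * age[None, :] + rng.normal(0, 0.5, size=(n_prot, len(age)))
    matrix = IntensityMatrix(
        pd.DataFrame(vals, index=[f"P{i}" for i in range(n_prot)], columns=meta["sample_id"])
    )
    table = ancova_screen(matrix, meta)
    rate = table["significant"].mean()
    # binomial 99.9% band around alpha=0.05 at 400 proteins
    assert 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / n_prot) < rate < 0.05 + 3.3 * np.sqrt(0.05 * 0.95 / n_prot)


def test_subtype_shift_orthogonal_to_age_detected():
    meta = _t0_meta(n_per=10, age_by_subtype=(8.0, 8.0, 8.0), age_spread=4.0, seed=3)
    rng = np.random.default_rng(4)
    shift = meta["subtype"].map({"SMA1": 0.0, "SMA2": 1.5, "SMA3": 3.0}).to_numpy()
    vals = np.vstack(
        [shift + rng.normal(0, 0.5, len(meta)), rng.normal(0, 0.5, len(meta))]
    )
    matrix = IntensityMatrix(
        pd.DataFrame(vals, index=["hit", "null"], columns=meta["sample_id"])
    )
    table = ancova_screen(matrix, meta)
    assert bool(table.loc["hit", "significant"])
    assert table.loc["hit", "p"] < 1e-6


def test_ancova_matches_statsmodels_type2():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    meta = _t0_meta(n_per=8, seed=5)
    rng = np.random.default_rng(6)
    vals = rng.normal(25, 1, size=(3, len(meta)))
    matrix = IntensityMatrix(
        pd.DataFrame(vals, index=["A", "B", "C"], columns=meta["sample_id"])
    )
    ours = ancova_screen(matrix, meta)
    for pid in ("A", "B", "C"):
        frame = pd.DataFrame(
            {
                "y": matrix.values.loc[pid].to_numpy(),
                "subtype": meta["subtype"].to_numpy(),
                "age": meta["age_years"].to_numpy(),
            }
        )
        fit = smf.ols("y ~ C(subtype) + age", data=frame).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        assert ours.loc[pid, "p"] == pytest.approx(anova.loc["C(subtype)", "PR(>F)"], rel=1e-8)


def test_zero_variance_protein_excluded():
    meta = _t0_meta(n_per=5)
    vals = pd.DataFrame(
        [[7.0] * len(meta), np.random.default_rng(0).normal(size=len(meta))],
        index=["flat", "ok"],
        columns=meta["sample_id"],
    )
    table = ancova_screen(IntensityMatrix(vals), meta)
    assert np.isnan(table.loc["flat", "p"]) and not table.loc["flat", "significant"]


# ---------------------------------------------------------------------------
# paired treatment test


def test_no_change_means_no_significant_proteins(toy_metadata):
    rng = np.random.default_rng(7)
    t0_cols = toy_metadata.loc[toy_metadata["timepoint"] == "T0", "sample_id"]
    vals = pd.DataFrame(
        rng.normal(25, 1, size=(30, len(t0_cols))),
        index=[f"P{i}" for i in range(30)],
        columns=t0_cols,
    )
    full = pd.concat(
        [vals, vals.rename(columns=lambda c: c.replace("_T0", "_T302"))], axis=1
    )
    table = paired_treatment_test(IntensityMatrix(full), toy_metadata, "SMA1")
    assert table["significant"].sum() == 0


def test_paired_t_matches_textbook_formula():
    """4 pairs: t = mean(d) / (sd(d)/sqrt(n))."""
    meta = pd.DataFrame(
        [
            {"sample_id": f"p{i}_{tp}", "patient_id": f"p{i}", "subtype": "SMA2",
             "timepoint": tp, "age_years": 5.0}
            for i in range(4)
            for tp in ("T0", "T302")
        ]
    )
    t0 = np.array([10.0, 11.0, 12.0, 13.0])
    t302 = np.array([11.5, 11.2, 13.1, 13.9])
    vals = pd.DataFrame(
        [np.concatenate([[a, b] for a, b in zip(t0, t302)])],
        index=["P"],
        columns=[f"p{i}_{tp}" for i in range(4) for tp in ("T0", "T302")],
    )
    table = paired_treatment_test(IntensityMatrix(vals), meta, "SMA2")
    d = t302 - t0
    expected_t = d.mean() / (d.std(ddof=1) / 2)
    assert table.loc["P", "t"] == pytest.approx(expected_t)
    assert table.loc["P", "effect"] == pytest.approx(d.mean())


def test_planted_shift_survives_bh_with_study_scale_pairs():
    """A +1 log2 shift at sd 0.5 with 19 pairs is detected after BH in the
    vast majority of simulated cohorts (paired-t power at this effect)."""
    detected = total = 0
    false_rates = []
    for seed in range(20):
        design = null_design(
            seed=100 + seed,
            n_proteins=100,
            n_per_subtype=(19, 19, 19),
            treatment_shared_size=5,
            treatment_shared_effect=1.0,
        )
        matrix, meta, truth = generate_cohort(design)
        table = paired_treatment_test(matrix, meta, "SMA1")
        planted = truth.treatment_sets["shared"]["ids"]
        detected += int(table.loc[planted, "significant"].sum())
        total += len(planted)
        assert (table.loc[planted, "direction"] == 1).all()
        false_rates.append(table.drop(index=planted)["significant"].mean())
    assert detected / total >= 0.9
    # BH keeps the false-positive load low among the other proteins
    assert np.mean(false_rates) < 0.05


def test_too_few_pairs_reported_as_missing():
    meta = pd.DataFrame(
        [
            {"sample_id": f"p{i}_{tp}", "patient_id": f"p{i}", "subtype": "SMA3",
             "timepoint": tp, "age_years": 5.0}
            for i in range(3)
            for tp in ("T0", "T302")
        ]
    )
    vals = pd.DataFrame(
        [[1.0, 2.0, np.nan, 2.5, 3.0, 4.0]],
        index=["P"],
        columns=meta["sample_id"],
    )
    table = paired_treatment_test(IntensityMatrix(vals), meta, "SMA3")
    assert np.isnan(table.loc["P", "p"])


# ---------------------------------------------------------------------------
# BH


def test_bh_equal_spacing_collapses_to_largest():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_trivial_cases():
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def _bh_oracle(p):
    """Independent step-up computation: sort, p(i)*m/i, cumulative min from
    the largest rank, cap at 1, undo the sort."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@pytest.mark.parametrize("seed", range(10))
def test_bh_matches_independent_step_up_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(1, 40))
    assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)
    assert (bh_adjust(p) >= p).all()


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_adjust([0.1, np.nan])


# ---------------------------------------------------------------------------
# responder contrast and classification


def test_responder_contrast_toy_welch_and_pooled():
    meta = pd.DataFrame(
        [
            {"sample_id": f"p{i}_{tp}", "patient_id": f"p{i}", "subtype": "SMA1",
             "timepoint": tp, "age_years": 2.0, "responder": i < 3}
            for i in range(6)
            for tp in ("T0", "T302")
        ]
    )
    delta = np.array([1.1, 0.9, 1.3, 0.1, -0.2, 0.2])
    t0 = np.full(6, 20.0)
    cols, vals = [], []
    for i in range(6):
        cols += [f"p{i}_T0", f"p{i}_T302"]
        vals += [t0[i], t0[i] + delta[i]]
    matrix = IntensityMatrix(pd.DataFrame([vals], index=["P"], columns=cols))
    for equal_var in (False, True):
        table = responder_contrast(matrix, meta, "SMA1", equal_var=equal_var)
        expected_t, expected_p = sps.ttest_ind(delta[:3], delta[3:], equal_var=equal_var)
        assert table.loc["P", "t"] == pytest.approx(expected_t)
        assert table.loc["P", "p"] == pytest.approx(expected_p)
        assert table.loc["P", "effect"] == pytest.approx(delta[:3].mean() - delta[3:].mean())


def test_planted_responder_effect_has_largest_magnitude():
    """A +1 responder-only fold-change shift at one protein dominates the
    effect ranking of the responder contrast."""
    design = null_design(
        seed=19,
        n_proteins=150,
        n_per_subtype=(19, 19, 19),
        responder_set_size=1,
        responder_extra_effect=1.0,
        responder_fraction=(0.5, 0.5, 0.5),
        noise_sd=0.25,
    )
    matrix, meta, truth = generate_cohort(design)
    table = responder_contrast(matrix, meta, "SMA1")
    (planted,) = truth.responder_effect_ids
    assert table["effect"].abs().idxmax() == planted
    assert table.loc[planted, "effect"] == pytest.approx(1.0, abs=0.5)


def test_responder_contrast_requires_both_classes(toy_metadata):
    meta = toy_metadata.copy()
    meta["responder"] = True
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(size=(5, len(meta))),
        index=[f"P{i}" for i in range(5)],
        columns=meta["sample_id"],
    )
    with pytest.raises(ValueError, match="responder class"):
        responder_contrast(IntensityMatrix(vals), meta, "SMA1")


def _score_meta(subtype, s0, s1):
    return pd.DataFrame(
        [
            {"sample_id": "x_T0", "patient_id": "x", "subtype": subtype, "timepoint": "T0",
             "motor_score": s0},
            {"sample_id": "x_T302", "patient_id": "x", "subtype": subtype, "timepoint": "T302",
             "motor_score": s1},
        ]
    )


def test_chop_gain_of_4_is_responder_boundary_inclusive():
    assert classify_responders(_score_meta("SMA1", 13, 17))["x"] == True
    assert classify_responders(_score_meta("SMA1", 13, 16))["x"] == False


def test_hfmse_gain_below_3_is_non_responder():
    assert classify_responders(_score_meta("SMA3", 47, 49))["x"] == False
    assert classify_responders(_score_meta("SMA3", 47, 50))["x"] == True


def test_missing_score_gives_missing_flag():
    flags = classify_responders(_score_meta("SMA2", np.nan, 12))
    assert np.isnan(flags["x"])


def test_scores_beyond_scale_maxima_rejected():
    with pytest.raises(ValueError, match="out of range"):
        classify_responders(_score_meta("SMA1", 10, 65))
    with pytest.raises(ValueError, match="out of range"):
        classify_responders(_score_meta("SMA2", -1, 10))


def test_default_cohort_reproduces_study_responder_share():
    """Default responder fractions yield 11/6/6 responders (23 of 61)."""
    _, meta, truth = generate_cohort(CohortDesign(seed=0))
    flags = pd.Series(truth.responder_flags)
    per_subtype = flags.groupby(flags.index.str.slice(0, 4)).sum()
    assert list(per_subtype[["SMA1", "SMA2", "SMA3"]]) == [11, 6, 6]
    assert flags.sum() == 23 and len(flags) == 61
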