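"""Synthetic paired-timepoint CSF proteomics cohorts with planted truth.

Emulates the structure of a three-subtype spinal muscular atrophy (SMA)
treatment study: each patient contributes a baseline (T0) and an on-treatment
(T302) CSF sample; subtype severity is confounded with age (SMA1 patients are
youngest); a subset of proteins discriminates subtypes at both timepoints
("baseline markers"); treatment shifts one shared protein set plus one set
per subtype at T302 only; responders carry an extra T302 shift on a further
set.  Intensities are simulated directly on the log2 scale as Gaussians
around per-protein baselines, with per-sample additive shifts (so that
median-centering is non-trivial) and missing-completely-at-random dropout.

Every planted choice is recorded in a :class:`GroundTruth` sidecar so
downstream stages can be scored for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SUBTYPES, IntensityMatrix

__all__ = ["CohortDesign", "GroundTruth", "generate_cohort", "recovery_report", "write_cohort"]

# Motor scales: CHOP-INTEND (SMA1) tops out at 64, HFMSE (SMA2/3) at 66.
CHOP_MAX = 64
HFMSE_MAX = 66
RESPONDER_GAIN = {"SMA1": 4, "SMA2": 3, "SMA3": 3}
# Baseline medians from the cohort being emulated (CHOP 13; HFMSE 9 and 47).
BASELINE_SCORE = {"SMA1": 13.0, "SMA2": 9.0, "SMA3": 47.0}
SCORE_MAX = {"SMA1": CHOP_MAX, "SMA2": HFMSE_MAX, "SMA3": HFMSE_MAX}


@dataclass
class CohortDesign:
    """Design parameters for one simulated cohort.

    Counts default to the emulated study (19/19/23 patients; 1625 proteins).
    Effects are log2-units; ``baseline_effect`` is the shift between
    *adjacent* severity subtypes, applied monotonically SMA1 -> SMA3.
    """

    n_per_subtype: tuple[int, int, int] = (19, 19, 23)
    n_proteins: int = 1625
    n_baseline_markers: int = 9
    baseline_effect: float = 1.5
    age_means: tuple[float, float, float] = (2.1, 7.7, 15.3)
    age_sd: float = 3.0
    age_effect_proteins: int = 50
    age_slope: float = 0.05
    treatment_shared_size: int = 20
    treatment_shared_effect: float = -1.0
    treatment_subtype_size: int = 20
    treatment_subtype_effect: float = 1.0
    responder_fraction: tuple[float, float, float] = (11 / 19, 6 / 19, 6 / 23)
    responder_set_size: int = 15
    responder_extra_effect: float = 1.0
    baseline_range: tuple[float, float] = (20.0, 35.0)
    sample_shift_sd: float = 0.3
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_subtype, int):
            self.n_per_subtype = (self.n_per_subtype,) * 3
        self.n_per_subtype = tuple(int(n) for n in self.n_per_subtype)
        if any(n < 2 for n in self.n_per_subtype):
            raise ValueError("need at least 2 patients per subtype")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        planted = (
            self.n_baseline_markers
            + self.age_effect_proteins
            + self.treatment_shared_size
            + 3 * self.treatment_subtype_size
            + self.responder_set_size
        )
        if planted > self.n_proteins:
            raise ValueError(
                f"planted sets need {planted} proteins but the design has "
                f"only {self.n_proteins}"
            )
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if not all(0 <= f <= 1 for f in self.responder_fraction):
            raise ValueError("responder fractions must lie in [0, 1]")
        if self.noise_sd < 0 or self.age_sd <= 0:
            raise ValueError("noise_sd must be >= 0 and age_sd > 0")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort, keyed by protein ID."""

    baseline_marker_ids: list[str]
    marker_directions: dict[str, int]
    age_effect_ids: list[str]
    treatment_sets: dict[str, dict]  # name -> {"ids": [...], "effect": float}
    responder_effect_ids: list[str]
    responder_flags: dict[str, bool]  # patient_id -> flag

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_marker_ids": self.baseline_marker_ids,
                "marker_directions": self.marker_directions,
                "age_effect_ids": self.age_effect_ids,
                "treatment_sets": self.treatment_sets,
                "responder_effect_ids": self.responder_effect_ids,
                "responder_flags": self.responder_flags,
            },
            indent=1,
            sort_keys=True,
        )


def _protein_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(design: CohortDesign):
    """Simulate one cohort.

    Returns
    -------
    (IntensityMatrix, pandas.DataFrame, GroundTruth)
        Log2-scale matrix (NaN for dropout), per-sample metadata, and the
        planted ground truth.  Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    p = design.n_proteins
    ids = _protein_ids(p)

    # -- disjoint planted index sets ------------------------------------
    pool = rng.permutation(p)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = np.sort(pool[cursor : cursor + k])
        cursor += k
        return out

    marker_idx = take(design.n_baseline_markers)
    age_idx = take(design.age_effect_proteins)
    shared_idx = take(design.treatment_shared_size)
    subtype_idx = {s: take(design.treatment_subtype_size) for s in SUBTYPES}
    responder_idx = take(design.responder_set_size)
    marker_dir = rng.choice([-1, 1], size=design.n_baseline_markers)

    # -- patients, ages, responder flags --------------------------------
    rows = []
    responder_flags: dict[str, bool] = {}
    for k, subtype in enumerate(SUBTYPES):
        n = design.n_per_subtype[k]
        ages = np.maximum(0.1, rng.normal(design.age_means[k], design.age_sd, size=n))
        n_resp = int(round(design.responder_fraction[k] * n))
        resp = np.zeros(n, bool)
        resp[rng.choice(n, size=n_resp, replace=False)] = True
        gain_thr = RESPONDER_GAIN[subtype]
        for j in range(n):
            pid = f"{subtype}_{j + 1:02d}"
            responder_flags[pid] = bool(resp[j])
            t0_score = float(
                np.clip(rng.normal(BASELINE_SCORE[subtype], 5.0), 0, SCORE_MAX[subtype] - gain_thr - 2)
            )
            if resp[j]:
                gain = gain_thr + rng.integers(0, 5)
            else:
                gain = rng.integers(-2, gain_thr)  # strictly below threshold
            t302_score = float(np.clip(t0_score + gain, 0, SCORE_MAX[subtype]))
            for tp in ("T0", "T302"):
                rows.append(
                    {
                        "sample_id": f"{pid}_{tp}",
                        "patient_id": pid,
                        "subtype": subtype,
                        "timepoint": tp,
                        "age_years": round(float(ages[j]), 3),
                        "sex": rng.choice(["F", "M"]),
                        "smn2_copies": int(rng.choice([2, 3, 4], p=_SMN2_P[subtype])),
                        "bmi_group": rng.choice(["low", "normal", "high"]),
                        "motor_score": t0_score if tp == "T0" else t302_score,
                        "responder": bool(resp[j]),
                    }
                )
    meta = pd.DataFrame(rows)

    # -- expression grid -------------------------------------------------
    n_samples = len(meta)
    base = rng.uniform(*design.baseline_range, size=p)
    values = np.tile(base[:, None], (1, n_samples))
    sample_shift = rng.normal(0.0, design.sample_shift_sd, size=n_samples)
    values += sample_shift[None, :]

    subtype_code = meta["subtype"].map({s: k for k, s in enumerate(SUBTYPES)}).to_numpy()
    is_t302 = (meta["timepoint"] == "T302").to_numpy()
    is_resp = meta["responder"].to_numpy(bool)
    ages_all = meta["age_years"].to_numpy(float)

    # baseline markers: monotone shift across severity, both timepoints
    values[marker_idx, :] += (
        marker_dir[:, None] * design.baseline_effect * subtype_code[None, :]
    )
    # age-correlated proteins (confounder with subtype through age_means)
    mean_age = float(np.mean(ages_all))
    values[age_idx, :] += design.age_slope * (ages_all - mean_age)[None, :]
    # treatment effects at T302 only
    values[np.ix_(shared_idx, np.where(is_t302)[0])] += design.treatment_shared_effect
    for k, subtype in enumerate(SUBTYPES):
        cols = np.where(is_t302 & (subtype_code == k))[0]
        values[np.ix_(subtype_idx[subtype], cols)] += design.treatment_subtype_effect
    # responder-only extra effect at T302
    cols = np.where(is_t302 & is_resp)[0]
    values[np.ix_(responder_idx, cols)] += design.responder_extra_effect

    values += rng.normal(0.0, design.noise_sd, size=values.shape)
    if design.missing_rate > 0:
        drop = rng.random(values.shape) < design.missing_rate
        values[drop] = np.nan

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=ids, columns=meta["sample_id"].tolist())
    )
    truth = GroundTruth(
        baseline_marker_ids=[ids[i] for i in marker_idx],
        marker_directions={ids[i]: int(d) for i, d in zip(marker_idx, marker_dir)},
        age_effect_ids=[ids[i] for i in age_idx],
        treatment_sets={
            "shared": {
                "ids": [ids[i] for i in shared_idx],
                "effect": design.treatment_shared_effect,
            },
            **{
                s: {
                    "ids": [ids[i] for i in subtype_idx[s]],
                    "effect": design.treatment_subtype_effect,
                }
                for s in SUBTYPES
            },
        },
        responder_effect_ids=[ids[i] for i in responder_idx],
        responder_flags=responder_flags,
    )
    return matrix, meta, truth


# SMN2 copy-number composition per subtype (2 / 3 / >3 copies), mirroring the
# strong inverse coupling between copy number and severity.
_SMN2_P = {
    "SMA1": (0.89, 0.11, 0.0),
    "SMA2": (0.10, 0.90, 0.0),
    "SMA3": (0.13, 0.48, 0.39),
}


def recovery_report(truth_ids, selected_ids, universe) -> dict:
    """Confusion counts and sensitivity/specificity of a selected protein set
    against a planted truth set, over a stated protein universe."""
    universe = set(universe)
    truth = set(truth_ids)
    sel = set(selected_ids)
    if not truth <= universe or not sel <= universe:
        raise ValueError("truth or selection contains IDs outside the universe")
    tp = len(truth & sel)
    fp = len(sel - truth)
    fn = len(truth - sel)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


def write_cohort(matrix: IntensityMatrix, meta: pd.DataFrame, truth: GroundTruth, out_dir) -> None:
    """Write the raw-scale matrix TSV, metadata TSV and truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.write_tsv(out / "intensities.tsv", raw_scale=True)
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())
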