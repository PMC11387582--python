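"""Orchestration of the three study workflows with run manifests.

* baseline: preprocess -> per-factor PERMANOVA -> repeated-RF consensus ->
  Spearman age correlation of the consensus proteins.
* treatment: per-subtype paired tests -> Ward-D2 clustering (k=2) of the
  significant proteins -> ORA per cluster against a GMT collection.
* responder: per-patient fold-change matrix -> PERMANOVA on response status
  -> unpaired responder contrast per subtype.

Every workflow writes its tables under an output directory along with a
JSON manifest (config, seeds, config hash, SHA-256 of each artifact) from
which the run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import enrichment as _enrichment
from . import preprocess as _pre
from . import rf as _rf
from . import stats as _stats
from .containers import SUBTYPES, IntensityMatrix

__all__ = [
    "StatsOptions",
    "RunConfig",
    "preprocess_pipeline",
    "run_baseline_workflow",
    "run_treatment_workflow",
    "run_responder_workflow",
]

logger = logging.getLogger(__name__)

PERMANOVA_FACTORS = ["subtype", "sex", "age_group", "bmi_group", "smn2_copies", "responder"]


@dataclass
class StatsOptions:
    n_permutations: int = 999
    permanova_seed: int = 0
    alpha: float = 0.05
    equal_var: bool = False
    age_bins: int = 3  # age enters PERMANOVA as tertiles by default


@dataclass
class RunConfig:
    min_fraction_per_group: float = 0.7
    rf: _rf.RFConfig = field(default_factory=_rf.RFConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    pca_scale: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def preprocess_pipeline(
    raw: pd.DataFrame, meta: pd.DataFrame, config: RunConfig, already_log2: bool = False
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Fixed order: log2 -> median-center -> completeness filter (within
    subtypes) -> min-imputation.  Returns (filtered, imputed)."""
    centered = _pre.log2_median_center(raw, already_log2=already_log2)
    groups = meta.set_index("sample_id")["subtype"]
    filtered = _pre.filter_by_completeness(centered, config.min_fraction_per_group, groups)
    imputed = _pre.impute_min(filtered)
    logger.info(
        "preprocess: %d x %d -> %d proteins retained", *centered.shape, filtered.shape[0]
    )
    return filtered, imputed


def _age_groups(meta: pd.DataFrame, bins: int) -> pd.Series:
    t0 = meta[meta["timepoint"] == "T0"]
    tertile = pd.qcut(t0["age_years"], bins, labels=False, duplicates="drop")
    return pd.Series(tertile.to_numpy(), index=t0["sample_id"].to_numpy(), name="age_group")


def run_baseline_workflow(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    already_log2: bool = False,
) -> dict:
    """Baseline severity-stratification workflow on T0 samples."""
    config = config or RunConfig()
    filtered, imputed = preprocess_pipeline(raw, meta, config, already_log2)
    t0_meta = meta[meta["timepoint"] == "T0"].set_index("sample_id")
    t0 = imputed.subset_samples(t0_meta.index)

    distance = _stats.euclidean_distance(t0)
    factors = {
        "subtype": t0_meta["subtype"],
        "sex": t0_meta["sex"],
        "age_group": _age_groups(meta, config.stats.age_bins),
        "bmi_group": t0_meta["bmi_group"],
        "smn2_copies": t0_meta["smn2_copies"].astype(str),
        "responder": t0_meta["responder"].astype(str),
    }
    permanova_rows = []
    for name, labels in factors.items():
        counts = labels.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            logger.warning("PERMANOVA factor %s degenerate; skipped", name)
            continue
        res = _stats.permanova(
            distance,
            labels,
            n_permutations=config.stats.n_permutations,
            seed=config.stats.permanova_seed,
            factor=name,
        )
        permanova_rows.append(
            {"factor": name, "pseudo_F": res.pseudo_f, "p": res.p_value, "n_permutations": res.n_permutations}
        )
    permanova_table = pd.DataFrame(permanova_rows).set_index("factor")

    consensus = _rf.run_consensus(imputed, meta, config.rf)
    age_table = (
        _rf.correlate_with_age(imputed, meta, consensus.consensus_ids)
        if consensus.consensus_ids
        else pd.DataFrame(columns=["rho", "p", "p_adj"])
    )

    results = {
        "permanova": permanova_table,
        "consensus": consensus,
        "age_correlation": age_table,
    }
    if out_dir is not None:
        _write_baseline(results, config, Path(out_dir))
    return results


def run_treatment_workflow(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    config: RunConfig | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    out_dir: str | Path | None = None,
    already_log2: bool = False,
) -> dict:
    """Per-subtype paired differential abundance, two-cluster Ward-D2 split
    of the significant proteins, and optional per-cluster enrichment."""
    config = config or RunConfig()
    filtered, imputed = preprocess_pipeline(raw, meta, config, already_log2)
    out: dict = {}
    for subtype in SUBTYPES:
        if not (meta["subtype"] == subtype).any():
            continue
        table = _stats.paired_treatment_test(filtered, meta, subtype, alpha=config.stats.alpha)
        entry: dict = {"differential": table}
        sig = table.index[table["significant"]]
        if len(sig) >= 2:
            sub_ids = meta.loc[meta["subtype"] == subtype, "sample_id"]
            z = _cluster.zscore_proteins(
                imputed.subset_proteins(sig).subset_samples(sub_ids)
            )
            assignment = _cluster.ward_cluster_cut2(z, mean_paired_diff=table["effect"])
            entry["clusters"] = assignment
            if gene_sets:
                background = list(filtered.protein_ids)
                entry["enrichment_up"] = _enrichment.enrich(
                    assignment.up_ids, gene_sets, background
                )
                entry["enrichment_down"] = _enrichment.enrich(
                    assignment.down_ids, gene_sets, background
                ) if assignment.down_ids else None
        out[subtype] = entry
    if out_dir is not None:
        _write_treatment(out, config, Path(out_dir))
    return out


def run_responder_workflow(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    already_log2: bool = False,
) -> dict:
    """Responder-vs-non-responder workflow on per-patient fold changes."""
    config = config or RunConfig()
    meta = meta.copy()
    if meta["responder"].isna().any():
        flags = _stats.classify_responders(meta)
        meta["responder"] = meta["patient_id"].map(flags)
    _, imputed = preprocess_pipeline(raw, meta, config, already_log2)
    out: dict = {}
    for subtype in SUBTYPES:
        if not (meta["subtype"] == subtype).any():
            continue
        flags = (
            meta[(meta["subtype"] == subtype) & (meta["timepoint"] == "T0")]
            .set_index("patient_id")["responder"]
            .astype(bool)
        )
        if flags.nunique() < 2:
            raise ValueError(f"subtype {subtype} lacks both responder classes")
        delta = _stats.patient_fold_changes(imputed, meta, subtype)
        dmat = IntensityMatrix(delta)
        distance = _stats.euclidean_distance(dmat)
        res = _stats.permanova(
            distance,
            flags.reindex(delta.columns).astype(str),
            n_permutations=config.stats.n_permutations,
            seed=config.stats.permanova_seed,
            factor="responder",
        )
        table = _stats.responder_contrast(
            imputed, meta, subtype, alpha=config.stats.alpha, equal_var=config.stats.equal_var
        )
        out[subtype] = {
            "permanova": {"pseudo_F": res.pseudo_f, "p": res.p_value},
            "differential": table,
        }
    if out_dir is not None:
        _write_responder(out, config, Path(out_dir))
    return out


# ---------------------------------------------------------------------------
# artifact writing


def _write_manifest(out: Path, config: RunConfig, artifacts: list[Path]) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "artifacts": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))


def _write_baseline(results: dict, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    p = out / "permanova.tsv"
    results["permanova"].to_csv(p, sep="\t")
    artifacts.append(p)
    cons = results["consensus"]
    p = out / "repeats.tsv"
    pd.DataFrame(
        {"seed": [r.seed for r in cons.repeats], "accuracy": [r.accuracy for r in cons.repeats]}
    ).to_csv(p, sep="\t", index=False)
    artifacts.append(p)
    p = out / "consensus.tsv"
    mean_imp = (
        pd.concat([r.importances for r in cons.repeats], axis=1).mean(axis=1)
        if cons.repeats
        else pd.Series(dtype=float)
    )
    pd.DataFrame(
        {
            "protein_id": cons.frequency.index,
            "frequency": cons.frequency.to_numpy(),
            "mean_importance": mean_imp.reindex(cons.frequency.index).to_numpy(),
            "in_consensus": [pid in set(cons.consensus_ids) for pid in cons.frequency.index],
        }
    ).to_csv(p, sep="\t", index=False)
    artifacts.append(p)
    p = out / "age_correlation.tsv"
    results["age_correlation"].to_csv(p, sep="\t")
    artifacts.append(p)
    _write_manifest(out, config, artifacts)


def _write_treatment(out_tables: dict, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    for subtype, entry in out_tables.items():
        p = out / f"paired_{subtype}.tsv"
        entry["differential"].to_csv(p, sep="\t")
        artifacts.append(p)
        if "clusters" in entry:
            p = out / f"clusters_{subtype}.tsv"
            entry["clusters"].labels.rename("cluster").to_csv(p, sep="\t", index_label="protein_id")
            artifacts.append(p)
        for key in ("enrichment_up", "enrichment_down"):
            if entry.get(key) is not None:
                p = out / f"{key}_{subtype}.tsv"
                entry[key].to_csv(p, sep="\t")
                artifacts.append(p)
    _write_manifest(out, config, artifacts)


def _write_responder(out_tables: dict, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    rows = []
    for subtype, entry in out_tables.items():
        p = out / f"responder_{subtype}.tsv"
        entry["differential"].to_csv(p, sep="\t")
        artifacts.append(p)
        rows.append({"subtype": subtype, **entry["permanova"]})
    p = out / "responder_permanova.tsv"
    pd.DataFrame(rows).set_index("subtype").to_csv(p, sep="\t")
    artifacts.append(p)
    _write_manifest(out, config, artifacts)
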