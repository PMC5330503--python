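"""End-to-end orchestration: filters -> RMSD -> IDRs -> classes ->
descriptors -> group statistics.

The pipeline is a pure function of (inputs, config, seed).  Failures are
per-protein (fail-soft): a protein whose computation raises is recorded in
an error table and the run continues; the CLI exits nonzero when more than
a threshold fraction of proteins fail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import confdiv
from confdiv.classify import CLASS_NAMES, classify_protein, evaluate_disorder_predictor, labels_to_frame
from confdiv.descriptors import compute_descriptors
from confdiv.disorder import detect_idrs, ensemble_disorder_summary
from confdiv.io import EnsembleRecord, filter_dataset, load_ensembles, read_manifest
from confdiv.stats import kruskal_wallis_nemenyi
from confdiv.superpose import max_rmsd_pair, pairwise_matrix

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_records", "summarize_by_class"]


@dataclass
class RunConfig:
    manifest: Optional[str] = None
    base_dir: str = "."
    out_dir: str = "results"
    min_conformers: int = 5
    max_resolution: float = 2.5
    xray_only: bool = True
    terminal_run_policy: str = "truncate"
    fraction_denominator: str = "full"
    contact_cutoff: float = 5.0
    do_pockets: bool = True
    do_tunnels: bool = True
    do_hinges: bool = True
    min_heavy_atoms: int = 6
    predictor_cutoffs: tuple[float, ...] = (0.9, 1.2)
    fail_threshold: float = 0.2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_conformers < 1:
            raise ValueError("min_conformers must be >= 1")
        if not (0.0 <= self.fail_threshold <= 1.0):
            raise ValueError("fail_threshold must be in [0, 1]")
        if self.terminal_run_policy not in ("truncate", "discard"):
            raise ValueError(f"bad terminal_run_policy {self.terminal_run_policy!r}")
        if self.fraction_denominator not in ("full", "observed"):
            raise ValueError(f"bad fraction_denominator {self.fraction_denominator!r}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    per_protein: pd.DataFrame
    class_summary: pd.DataFrame
    stats_table: pd.DataFrame
    predictor: dict
    filter_report: pd.DataFrame
    errors: pd.DataFrame
    run_log: dict = field(default_factory=dict)

    @property
    def failed_fraction(self) -> float:
        total = len(self.per_protein) + len(self.errors)
        return len(self.errors) / total if total else 0.0


def _analyse_protein(ens: EnsembleRecord, config: RunConfig) -> dict:
    comps = pairwise_matrix(ens)
    mp = max_rmsd_pair(ens, comps)
    idrs = [
        detect_idrs(c, terminal_run_policy=config.terminal_run_policy,
                    fraction_denominator=config.fraction_denominator)
        for c in ens.conformers
    ]
    summary = ensemble_disorder_summary(ens, idrs)
    label = classify_protein(ens, idrs, mp)
    ds = compute_descriptors(
        ens, idrs, mp,
        contact_cutoff=config.contact_cutoff,
        do_pockets=config.do_pockets,
        do_tunnels=config.do_tunnels,
        do_hinges=config.do_hinges,
        min_heavy_atoms=config.min_heavy_atoms,
    )
    row = {
        "protein_id": ens.protein_id,
        "n_conformers": ens.n_conformers,
        "label": label.label,
        "max_rmsd": mp.rmsd,
        "max_pair_a": mp.pair[0],
        "max_pair_b": mp.pair[1],
        "has_idr_any_conformer": label.has_idr_any_conformer,
        "has_idr_in_max_pair": label.has_idr_in_max_pair,
        "mean_pairwise_rmsd": float(np.mean([c.rmsd for c in comps])),
        "percent_disordered_conformers": summary["percent_disordered_conformers"],
        "max_disorder_fraction": summary["max_disorder_fraction"],
        "longest_idr_length": summary["longest_idr_length"],
        "n_transition_positions": summary["n_transition_positions"],
        "n_mutation_positions": len(ens.mutation_positions),
    }
    row.update({k: v for k, v in ds.as_row().items() if k != "protein_id"})
    row["descriptor_flags"] = ";".join(ds.flags)
    return row


def summarize_by_class(per_protein: pd.DataFrame, class_col: str = "label") -> pd.DataFrame:
    """Mean (with 95% CI), median and sd per class for every numeric column."""
    rows = []
    numeric = per_protein.select_dtypes(include=[np.number]).columns
    for cls, grp in per_protein.groupby(class_col, sort=True):
        n = len(grp)
        for col in numeric:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            if vals.size > 1:
                sd = float(vals.std(ddof=1))
                half = float(sps.t.ppf(0.975, vals.size - 1) * sd / np.sqrt(vals.size))
                ci_low, ci_high = mean - half, mean + half
            else:
                sd = np.nan
                ci_low = ci_high = np.nan
            rows.append(
                dict(label=cls, variable=col, n=int(vals.size), mean=mean,
                     ci_low=ci_low, ci_high=ci_high,
                     median=float(np.median(vals)), sd=sd)
            )
    return pd.DataFrame(rows)


def _class_statistics(per_protein: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis + Nemenyi across classes for each numeric descriptor."""
    rows = []
    classes = [c for c in CLASS_NAMES if c in set(per_protein["label"])]
    if len(classes) < 2:
        return pd.DataFrame(
            columns=["variable", "test", "group_a", "group_b", "statistic", "p_value", "n_a", "n_b"])
    for col in per_protein.select_dtypes(include=[np.number]).columns:
        groups, labels = [], []
        for cls in classes:
            vals = per_protein.loc[per_protein["label"] == cls, col].dropna().to_numpy()
            if vals.size >= 2:
                groups.append(vals)
                labels.append(cls)
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups):
            continue
        try:
            omnibus, pmat = kruskal_wallis_nemenyi(groups, labels)
        except ValueError:
            continue
        rows.append(dict(variable=col, test="kruskal_wallis", group_a="all", group_b="all",
                         statistic=omnibus.statistic, p_value=omnibus.p_value,
                         n_a=sum(g.size for g in groups), n_b=0))
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                rows.append(dict(variable=col, test="nemenyi", group_a=a, group_b=b,
                                 statistic=np.nan, p_value=float(pmat.loc[a, b]),
                                 n_a=int(groups[i].size),
                                 n_b=int(groups[labels.index(b)].size)))
    return pd.DataFrame(rows)


def run_pipeline_records(
    ensembles: Sequence[EnsembleRecord], config: RunConfig
) -> PipelineResult:
    """Run the full analysis over in-memory ensembles."""
    config.validate()
    outcome = filter_dataset(
        ensembles, min_conformers=config.min_conformers,
        max_resolution=config.max_resolution, xray_only=config.xray_only,
    )
    rows, err_rows = [], []
    for ens in outcome.kept:
        try:
            rows.append(_analyse_protein(ens, config))
        except Exception as exc:  # fail-soft per protein
            err_rows.append(dict(protein_id=ens.protein_id, error=f"{type(exc).__name__}: {exc}"))
    per_protein = pd.DataFrame(rows)
    errors = pd.DataFrame(err_rows, columns=["protein_id", "error"])

    if len(per_protein):
        class_summary = summarize_by_class(per_protein)
        stats_table = _class_statistics(per_protein)
    else:
        class_summary = pd.DataFrame()
        stats_table = pd.DataFrame()

    predictor: dict = {}
    if len(per_protein) and per_protein["has_idr_any_conformer"].nunique() == 2:
        predictor = evaluate_disorder_predictor(
            per_protein["max_rmsd"].to_numpy(),
            per_protein["has_idr_any_conformer"].to_numpy(),
            cutoffs=config.predictor_cutoffs,
        )

    run_log = {
        "package_version": confdiv.__version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "n_input_ensembles": len(ensembles),
        "n_kept": len(outcome.kept),
        "n_analysed": len(per_protein),
        "n_failed": len(errors),
    }
    return PipelineResult(per_protein, class_summary, stats_table, predictor,
                          outcome.report, errors, run_log)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load ensembles from the manifest, run the analysis and write the
    output bundle (delimited tables + a JSON run log) to ``out_dir``."""
    config.validate()
    if not config.manifest:
        raise ValueError("config.manifest is required")
    manifest = read_manifest(config.manifest)
    if manifest.empty:
        raise ValueError(f"manifest {config.manifest} lists no conformers")
    ensembles = load_ensembles(manifest, config.base_dir, allow_length_mismatch=True)
    result = run_pipeline_records(ensembles, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_protein.to_csv(out / "per_protein.tsv", sep="\t", index=False)
    result.class_summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    result.stats_table.to_csv(out / "class_statistics.tsv", sep="\t", index=False)
    result.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    result.errors.to_csv(out / "errors.tsv", sep="\t", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump({**result.run_log, "predictor": _jsonable(result.predictor)}, fh, indent=2)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else str(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
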