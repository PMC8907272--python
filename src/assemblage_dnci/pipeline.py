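"""End-to-end per-cell analysis: filter -> split -> coverage -> cluster ->
validate -> balance -> DNCI, with typed per-cell failures and seed control.

A *cell* is one (taxonomic group, region) dataset; after the stage split
each (group, region, stage) entry is analysed independently. A cell whose
cluster partition fails the ANOSIM significance gate is reported as
``clusters-not-significant`` and no DNCI is attempted for it; failures in
one cell never abort the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .clustering import anosim, assign_clusters, jaccard_matrix, upgma
from .coverage import chao2_extrapolate
from .exceptions import AssemblageError, ConfigurationError
from .occurrence import IncidenceMatrix, filter_levels, load_incidence, split_by_stage
from .persimper import dnci_multigroup
from .synthetic import SimulationConfig, generate_study_layout, merge_stage_datasets

logger = logging.getLogger(__name__)


def derive_seed(master: int, *parts: str) -> int:
    """Deterministic per-cell sub-seed: sha256 of the master seed and the
    cell key, reduced below 2**31."""
    digest = hashlib.sha256(
        (f"{master}|" + "|".join(parts)).encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisReport:
    """Per-cell results (or typed failure reasons) plus provenance."""

    per_cell: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_cell": self.per_cell,
            "warnings": list(self.warnings),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(
            per_cell=d.get("per_cell", {}),
            warnings=d.get("warnings", []),
            provenance=d.get("provenance", {}),
        )


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _gather_datasets(config: dict, seed: int) -> dict[tuple[str, str], IncidenceMatrix]:
    """Resolve the `inputs` section into per-(group, region) matrices."""
    inputs = config.get("inputs") or {}
    datasets: dict[tuple[str, str], IncidenceMatrix] = {}
    for cell in inputs.get("cells", []) or []:
        key = (str(cell["group"]), str(cell["region"]))
        if key in datasets:
            raise ConfigurationError(f"duplicate input cell {key}")
        datasets[key] = load_incidence(
            cell["matrix"],
            format=cell.get("format", "wide"),
            metadata=cell.get("metadata"),
        )
    sim = inputs.get("simulate")
    if sim:
        items = []
        for cell in sim.get("cells", []):
            group = str(cell["group"])
            region = str(cell["region"])
            stage = str(cell["stage"])
            overrides = {
                k: v
                for k, v in cell.items()
                if k not in ("group", "region", "stage")
            }
            overrides.setdefault(
                "seed", derive_seed(seed, "simulate", group, region, stage)
            )
            items.append(((group, region, stage), SimulationConfig(**overrides)))
        keys = [k for k, _ in items]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate simulated cell keys")
        cells = generate_study_layout(items)
        for key, merged in merge_stage_datasets(items, cells).items():
            if key in datasets:
                raise ConfigurationError(f"duplicate input cell {key}")
            datasets[key] = merged
    if not datasets:
        raise ConfigurationError("config names no input cells")
    return datasets


def _analyse_stage(
    m: IncidenceMatrix,
    clustering_cfg: dict,
    dnci_cfg: dict,
    seed: int,
    warnings_out: list[str],
    cell_name: str,
) -> dict:
    entry: dict[str, Any] = {"status": "ok", "seed": seed, "n_levels": m.n_levels, "n_taxa": m.n_taxa}
    m = m.drop_empty()
    entry["coverage"] = chao2_extrapolate(m).to_dict()
    d = jaccard_matrix(m)
    tree = upgma(d)
    res = assign_clusters(tree, d, k=clustering_cfg.get("k"))
    if res.removed_levels:
        warnings_out.append(
            f"{cell_name}: removed singleton levels {res.removed_levels}"
        )
    if res.k < 2:
        entry["clustering"] = res.to_dict()
        entry["status"] = "analysis-not-possible"
        entry["reason"] = "fewer than 2 clusters after singleton removal"
        return entry
    rng = np.random.default_rng(seed)
    r, p = anosim(d, res.assignment, n_perm=int(clustering_cfg.get("anosim_permutations", 999)), rng=rng)
    res.anosim_r, res.anosim_p = r, p
    entry["clustering"] = res.to_dict()
    alpha = float(clustering_cfg.get("alpha", 0.05))
    if p >= alpha:
        entry["status"] = "clusters-not-significant"
        entry["reason"] = f"ANOSIM p={p:.4g} >= alpha={alpha}"
        return entry
    overall, pairwise = dnci_multigroup(
        m,
        res.assignment,
        n_perm=int(dnci_cfg.get("n_perm", 1000)),
        n_subsamples=int(dnci_cfg.get("n_subsamples", 100)),
        rng=np.random.default_rng(derive_seed(seed, "dnci")),
        subsample=bool(dnci_cfg.get("subsample", True)),
        ci_multiplier=float(dnci_cfg.get("ci_multiplier", 2.0)),
        imbalance_tolerance=float(dnci_cfg.get("imbalance_tolerance", 0.0)),
    )
    entry["dnci"] = {
        "overall": overall.to_dict(),
        "pairwise": [p_.to_dict() for p_ in pairwise],
    }
    return entry


def run_pipeline(config: dict | str | Path) -> AnalysisReport:
    """Run the full analysis described by a config mapping (or YAML path).

    Config sections: ``seed``; ``inputs`` (``cells`` with CSV paths and/or
    ``simulate`` with per-cell generator settings); ``filters``
    (``predicate``); ``clustering`` (``k``, ``anosim_permutations``,
    ``alpha``); ``dnci`` (``n_perm``, ``n_subsamples``, ``ci_multiplier``,
    ``subsample``, ``imbalance_tolerance``). Deterministic given the seed:
    every (cell, stage) derives its own sub-seed from the global one.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    clustering_cfg = cfg.get("clustering") or {}
    dnci_cfg = cfg.get("dnci") or {}
    predicate = (cfg.get("filters") or {}).get("predicate")

    report = AnalysisReport(
        provenance={
            "seed": seed,
            "package_version": __version__,
            "config": cfg,
        }
    )
    datasets = _gather_datasets(cfg, seed)
    for (group, region), matrix in datasets.items():
        base = f"{group}|{region}"
        try:
            if predicate:
                n_before = matrix.n_levels
                matrix = filter_levels(matrix, predicate)
                logger.info(
                    "%s: filter kept %d/%d levels", base, matrix.n_levels, n_before
                )
            stages = split_by_stage(matrix)
        except AssemblageError as exc:
            report.per_cell[base] = {
                "status": "failed",
                "reason_type": type(exc).__name__,
                "reason": str(exc),
            }
            continue
        for stage, sub in stages.items():
            cell_name = f"{base}|{stage}"
            sub_seed = derive_seed(seed, group, region, stage)
            logger.info(
                "%s: %d levels, %d taxa (seed %d)",
                cell_name, sub.n_levels, sub.n_taxa, sub_seed,
            )
            try:
                report.per_cell[cell_name] = _analyse_stage(
                    sub, clustering_cfg, dnci_cfg, sub_seed, report.warnings, cell_name
                )
            except AssemblageError as exc:
                report.per_cell[cell_name] = {
                    "status": "failed",
                    "reason_type": type(exc).__name__,
                    "reason": str(exc),
                }
    if not report.per_cell:
        report.warnings.append("no analysable cells in input")
    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "group", "region", "stage", "status", "s_obs", "s_ex", "ratio",
    "ratio_ci_low", "ratio_ci_high", "k", "anosim_r", "anosim_p",
    "dnci", "dnci_ci_low", "dnci_ci_high", "classification",
)


def render_report(
    report: AnalysisReport, out_dir: str | Path, plot: bool = True
) -> list[Path]:
    """Write report.json, a one-row-per-cell report.tsv, and (optionally) a
    DNCI interval plot grouped by stage. Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    json_path = out_dir / "report.json"
    json_path.write_text(report.to_json() + "\n", encoding="utf-8")
    written.append(json_path)

    rows = []
    for cell, entry in sorted(report.per_cell.items()):
        parts = cell.split("|")
        group, region = parts[0], parts[1] if len(parts) > 1 else ""
        stage = parts[2] if len(parts) > 2 else ""
        cov = entry.get("coverage") or {}
        clus = entry.get("clustering") or {}
        overall = (entry.get("dnci") or {}).get("overall") or {}
        rows.append(
            {
                "group": group,
                "region": region,
                "stage": stage,
                "status": entry.get("status", "failed"),
                "s_obs": cov.get("s_obs", ""),
                "s_ex": cov.get("s_ex", ""),
                "ratio": cov.get("ratio", ""),
                "ratio_ci_low": cov.get("ci_low", ""),
                "ratio_ci_high": cov.get("ci_high", ""),
                "k": clus.get("k", ""),
                "anosim_r": clus.get("anosim_r", ""),
                "anosim_p": clus.get("anosim_p", ""),
                "dnci": overall.get("dnci", ""),
                "dnci_ci_low": overall.get("ci_low", ""),
                "dnci_ci_high": overall.get("ci_high", ""),
                "classification": overall.get("classification", ""),
            }
        )
    tsv_path = out_dir / "report.tsv"
    with open(tsv_path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in _TSV_COLUMNS) + "\n")
    written.append(tsv_path)

    plotted = [r for r in rows if r["dnci"] != ""]
    if plot and plotted:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 * len(plotted) + 2, 4))
        xs = np.arange(len(plotted))
        for x, r in zip(xs, plotted):
            lo, hi, mid = r["dnci_ci_low"], r["dnci_ci_high"], r["dnci"]
            ax.errorbar(
                x, mid, yerr=[[mid - lo], [hi - mid]], fmt="o", capsize=4,
                color="tab:blue",
            )
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xticks(xs)
        ax.set_xticklabels(
            [f"{r['group']}\n{r['region']}\n{r['stage']}" for r in plotted],
            fontsize=8,
        )
        ax.set_ylabel("DNCI")
        ax.set_title("DNCI intervals per cell (negative = dispersal, positive = niche)")
        fig.tight_layout()
        png_path = out_dir / "dnci_intervals.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        written.append(png_path)
    return written
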