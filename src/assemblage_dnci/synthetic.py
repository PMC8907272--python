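"""Synthetic metacommunities with known assembly regimes.

The generator produces presence/absence level x taxon matrices whose
structure is planted:

* **niche** — groups of levels occupy disjoint segments of a latent
  environmental gradient in [0, 1]; each taxon has a gradient optimum and a
  Gaussian occurrence response (a standard coenocline model), so clusters
  are compositionally distinct and stable;
* **dispersal** — every taxon occurs anywhere with a probability equal to
  its own frequency, independent of group (a dispersal lottery);
* **mixed** — a convex combination of the two occurrence probabilities.

Occurrences are independent Bernoulli draws, optionally thinned (each
occurrence deleted independently with probability ``thinning``) to emulate
incomplete fossil preservation and sampling. The defaults describe a
two-cluster metacommunity of 20 levels per cluster and 80 taxa with a
moderate niche breadth and 20% taphonomic loss.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigurationError, DegenerateConfigurationError
from .occurrence import IncidenceMatrix, LevelMetadata, write_incidence, write_metadata

logger = logging.getLogger(__name__)

REGIMES = ("niche", "dispersal", "mixed")


def _default_frequency_params() -> dict:
    return {
        "mean_log": math.log(0.2),
        "sd_log": 0.7,
        "min_frequency": 0.02,
        "max_frequency": 0.9,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic metacommunity.

    ``mixing_weight`` is the niche share of the occurrence probability
    (0 = pure dispersal, 1 = pure niche); it is forced to 1/0 for the pure
    regimes. ``niche_breadth`` is the Gaussian response SD in gradient
    units; ``occupancy_scale`` the response peak; ``thinning`` the
    per-occurrence deletion probability.
    """

    regime: str = "mixed"
    mixing_weight: float = 0.5
    n_levels_per_group: int = 20
    n_groups: int = 2
    n_taxa: int = 80
    niche_breadth: float = 0.15
    occupancy_scale: float = 0.9
    taxon_frequency_distribution: str = "lognormal"
    frequency_params: Mapping[str, float] = field(default_factory=_default_frequency_params)
    thinning: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ConfigurationError("mixing_weight must be in [0, 1]")
        if self.n_levels_per_group < 2 or self.n_groups < 2 or self.n_taxa < 2:
            raise ConfigurationError("need >= 2 levels per group, groups, and taxa")
        if self.niche_breadth <= 0.0:
            raise ConfigurationError("niche_breadth must be positive")
        if not 0.0 < self.occupancy_scale <= 1.0:
            raise ConfigurationError("occupancy_scale must be in (0, 1]")
        if not 0.0 <= self.thinning < 1.0:
            raise ConfigurationError("thinning must be in [0, 1)")
        if self.taxon_frequency_distribution not in ("uniform", "lognormal"):
            raise ConfigurationError(
                f"unknown frequency distribution {self.taxon_frequency_distribution!r}"
            )

    @property
    def effective_mixing_weight(self) -> float:
        return {"niche": 1.0, "dispersal": 0.0}.get(self.regime, self.mixing_weight)


@dataclass
class SyntheticDataset:
    """A generated incidence matrix plus the latent truth that produced it."""

    matrix: IncidenceMatrix
    truth: dict

    @property
    def groups(self) -> dict[str, list[str]]:
        """True group id -> level ids (only levels retained in the matrix)."""
        out: dict[str, list[str]] = {}
        for lv in self.matrix.level_ids:
            out.setdefault(self.truth["group_of_level"][lv], []).append(lv)
        return out


def _draw_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    p = dict(_default_frequency_params())
    p.update(cfg.frequency_params)
    if cfg.taxon_frequency_distribution == "uniform":
        low = p.get("low", 0.05)
        high = p.get("high", 0.6)
        return rng.uniform(low, high, cfg.n_taxa)
    f = rng.lognormal(p["mean_log"], p["sd_log"], cfg.n_taxa)
    return np.clip(f, p["min_frequency"], p["max_frequency"])


def simulate(
    config: SimulationConfig,
    region: str = "R1",
    stage: str = "S1",
    group_label: str = "sim",
    level_prefix: str | None = None,
) -> SyntheticDataset:
    """Draw one synthetic dataset; identical config (incl. seed) always
    regenerates the identical matrix."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G, npl, T = cfg.n_groups, cfg.n_levels_per_group, cfg.n_taxa
    n = G * npl

    group_of_row = np.repeat(np.arange(G), npl)
    seg_low = group_of_row / G
    positions = seg_low + rng.uniform(0.0, 1.0 / G, n)
    optima = rng.uniform(0.0, 1.0, T)
    freqs = _draw_frequencies(cfg, rng)

    p_niche = cfg.occupancy_scale * np.exp(
        -((positions[:, None] - optima[None, :]) ** 2) / (2.0 * cfg.niche_breadth**2)
    )
    p_disp = np.broadcast_to(freqs, (n, T))
    w = cfg.effective_mixing_weight
    p = w * p_niche + (1.0 - w) * p_disp

    expected_fill = float(p.mean()) * (1.0 - cfg.thinning)
    if expected_fill < 0.01:
        raise DegenerateConfigurationError(
            f"expected matrix fill {expected_fill:.4f} is below 1%"
        )

    def draw_block(prob: np.ndarray) -> np.ndarray:
        occ = rng.random(prob.shape) < prob
        if cfg.thinning > 0.0:
            occ &= rng.random(prob.shape) >= cfg.thinning
        return occ.astype(np.int8)

    X = draw_block(p)
    for _ in range(100):
        empty_rows = np.flatnonzero(X.sum(axis=1) == 0)
        for i in empty_rows:
            X[i] = draw_block(p[i : i + 1])[0]
        empty_cols = np.flatnonzero(X.sum(axis=0) == 0)
        for j in empty_cols:
            X[:, j] = draw_block(p[:, j : j + 1])[:, 0]
        if (X.sum(axis=1) > 0).all() and (X.sum(axis=0) > 0).all():
            break

    prefix = level_prefix or f"{region}:{stage}"
    level_ids = [f"{prefix}:G{g + 1}:L{i:03d}" for i, g in enumerate(group_of_row, 1)]
    taxon_ids = [f"{group_label}_t{j:03d}" for j in range(1, T + 1)]

    dropped_levels = [level_ids[i] for i in np.flatnonzero(X.sum(axis=1) == 0)]
    dropped_taxa = [taxon_ids[j] for j in np.flatnonzero(X.sum(axis=0) == 0)]
    if dropped_levels or dropped_taxa:
        msg = (
            f"dropping {len(dropped_levels)} empty levels and "
            f"{len(dropped_taxa)} empty taxa after 100 redraw attempts"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    keep_rows = np.flatnonzero(X.sum(axis=1) > 0)
    keep_cols = np.flatnonzero(X.sum(axis=0) > 0)
    X = X[np.ix_(keep_rows, keep_cols)]
    kept_levels = [level_ids[i] for i in keep_rows]
    kept_taxa = [taxon_ids[j] for j in keep_cols]

    metadata = {
        level_ids[i]: LevelMetadata(
            level_id=level_ids[i],
            region=region,
            stage=stage,
            site=f"{region}-G{group_of_row[i] + 1}",
            depositional_setting="offshore",
            oxygen_stress=False,
            extra={"true_group": str(group_of_row[i] + 1)},
        )
        for i in keep_rows
    }
    matrix = IncidenceMatrix(X, kept_levels, kept_taxa, metadata)
    truth = {
        "config": _config_dict(cfg),
        "group_of_level": {
            level_ids[i]: str(group_of_row[i] + 1) for i in range(n)
        },
        "level_positions": {level_ids[i]: float(positions[i]) for i in range(n)},
        "taxon_optima": {taxon_ids[j]: float(optima[j]) for j in range(T)},
        "taxon_frequencies": {taxon_ids[j]: float(freqs[j]) for j in range(T)},
        "dropped_levels": dropped_levels,
        "dropped_taxa": dropped_taxa,
        "region": region,
        "stage": stage,
        "group_label": group_label,
    }
    return SyntheticDataset(matrix=matrix, truth=truth)


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["frequency_params"] = dict(d["frequency_params"])
    return d


# ---------------------------------------------------------------------------
# Study layout
# ---------------------------------------------------------------------------

CellKey = tuple[str, str, str]  # (taxonomic group, region, stage)


def generate_study_layout(
    per_cell_config: Mapping[CellKey, SimulationConfig] | Iterable[tuple[CellKey, SimulationConfig]],
    out_dir: str | Path | None = None,
) -> list[SyntheticDataset]:
    """One synthetic dataset per (group, region, stage) cell.

    When ``out_dir`` is given, cells are merged per (group, region) — the
    shape of a multi-stage regional occurrence table — and written as wide
    incidence + metadata CSVs together with a ``manifest.json`` recording
    every config and seed.
    """
    if isinstance(per_cell_config, Mapping):
        items = list(per_cell_config.items())
    else:
        items = list(per_cell_config)
        keys = [k for k, _ in items]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate cell keys in study layout")
    if not items:
        raise ConfigurationError("study layout is empty")

    datasets: list[SyntheticDataset] = []
    for (group, region, stage), cfg in items:
        datasets.append(simulate(cfg, region=region, stage=stage, group_label=group))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"cells": {}}
        for (key, cfg), ds in zip(items, datasets):
            manifest["cells"]["|".join(key)] = {
                "config": _config_dict(cfg),
                "n_levels": ds.matrix.n_levels,
                "n_taxa": ds.matrix.n_taxa,
                "n_occurrences": ds.matrix.n_occurrences,
            }
        for (group, region), merged in merge_stage_datasets(items, datasets).items():
            stem = f"{group}_{region}".replace(" ", "_")
            write_incidence(merged, out_dir / f"{stem}_incidence.csv", format="wide")
            write_metadata(merged, out_dir / f"{stem}_metadata.csv")
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return datasets


def merge_stage_datasets(
    items: list[tuple[CellKey, SimulationConfig]],
    datasets: list[SyntheticDataset],
) -> dict[tuple[str, str], IncidenceMatrix]:
    """Stack per-stage cells into one matrix per (group, region); taxon sets
    are unioned, absent combinations filled with zeros."""
    grouped: dict[tuple[str, str], list[SyntheticDataset]] = {}
    for ((group, region, _stage), _cfg), ds in zip(items, datasets):
        grouped.setdefault((group, region), []).append(ds)
    out: dict[tuple[str, str], IncidenceMatrix] = {}
    for key, dss in grouped.items():
        taxa: list[str] = []
        for ds in dss:
            for tx in ds.matrix.taxon_ids:
                if tx not in taxa:
                    taxa.append(tx)
        levels: list[str] = []
        rows = []
        metadata: dict[str, LevelMetadata] = {}
        for ds in dss:
            tidx = {tx: j for j, tx in enumerate(ds.matrix.taxon_ids)}
            block = np.zeros((ds.matrix.n_levels, len(taxa)), dtype=np.int8)
            for j, tx in enumerate(taxa):
                if tx in tidx:
                    block[:, j] = ds.matrix.values[:, tidx[tx]]
            rows.append(block)
            levels.extend(ds.matrix.level_ids)
            metadata.update(ds.matrix.metadata)
        out[key] = IncidenceMatrix(np.vstack(rows), levels, taxa, metadata)
    return out


def default_study_cells(
    seed: int = 0,
    n_levels_per_group: int = 20,
    n_taxa: int = 80,
) -> dict[CellKey, SimulationConfig]:
    """A 5-dataset x 2-stage layout emulating a two-clade, three-region,
    two-stage regional study: one clade recorded in all three regions, the
    second in two of them. Regimes differ per cell (one region mixed
    throughout, one dispersal throughout, one shifting from mixed to
    dispersal between stages; the second clade mixed everywhere)."""
    regimes = {
        ("cladeA", "R1"): ("mixed", "mixed"),
        ("cladeA", "R2"): ("dispersal", "dispersal"),
        ("cladeA", "R3"): ("mixed", "dispersal"),
        ("cladeB", "R1"): ("mixed", "mixed"),
        ("cladeB", "R2"): ("mixed", "mixed"),
    }
    stages = ("stage1", "stage2")
    cells: dict[CellKey, SimulationConfig] = {}
    for i, ((group, region), (reg1, reg2)) in enumerate(sorted(regimes.items())):
        for s, regime in zip(stages, (reg1, reg2)):
            cells[(group, region, s)] = SimulationConfig(
                regime=regime,
                n_levels_per_group=n_levels_per_group,
                n_taxa=n_taxa,
                seed=(seed * 104729 + i * 211 + (0 if s == "stage1" else 1)) % (2**31),
            )
    return cells
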