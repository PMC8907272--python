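"""Presence/absence occurrence data: loading, validation, filtering, writing.

The sampling unit is the *level* — a spatially and stratigraphically bounded
fossiliferous interval. Data are held as a binary incidence matrix with rows
= levels and columns = taxa; this orientation is fixed package-wide so the
permutation null models in :mod:`assemblage_dnci.persimper` are unambiguous.
Abundance is deliberately discarded: any recorded (level, taxon) occurrence
counts as presence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ValidationError

#: Required columns of a metadata CSV, in canonical order.
CORE_METADATA_FIELDS = (
    "region",
    "stage",
    "site",
    "depositional_setting",
    "oxygen_stress",
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(raw: str, context: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean {raw!r} for {context}")


@dataclass(frozen=True)
class LevelMetadata:
    """Per-level descriptors used for filtering and stage splitting."""

    level_id: str
    region: str
    stage: str
    site: str = ""
    depositional_setting: str = ""
    oxygen_stress: bool = False
    extra: Mapping[str, str] = field(default_factory=dict)

    def namespace(self) -> dict:
        """Field name -> value map used to evaluate predicate expressions."""
        ns = {
            "level_id": self.level_id,
            "region": self.region,
            "stage": self.stage,
            "site": self.site,
            "depositional_setting": self.depositional_setting,
            "oxygen_stress": self.oxygen_stress,
            "extra": dict(self.extra),
        }
        for key, value in self.extra.items():
            ns.setdefault(key, value)
        return ns


@dataclass
class IncidenceMatrix:
    """Binary levels x taxa matrix with labels and optional level metadata.

    ``values[i, j] == 1`` iff taxon ``taxon_ids[j]`` was observed in level
    ``level_ids[i]``. When ``metadata`` is non-empty it must carry an entry
    for every level.
    """

    values: np.ndarray
    level_ids: list[str]
    taxon_ids: list[str]
    metadata: dict[str, LevelMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.level_ids = [str(x).strip() for x in self.level_ids]
        self.taxon_ids = [str(x).strip() for x in self.taxon_ids]
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("incidence values must be a 2-D matrix")
        n, t = self.values.shape
        if n != len(self.level_ids) or t != len(self.taxon_ids):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.level_ids)} levels x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.level_ids)) != n:
            raise ValidationError("duplicate level_id")
        if len(set(self.taxon_ids)) != t:
            raise ValidationError("duplicate taxon_id")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at level {self.level_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}: {self.values[i, j]}"
            )
        if self.metadata:
            missing = [lv for lv in self.level_ids if lv not in self.metadata]
            if missing:
                raise ValidationError(f"metadata missing for levels {missing[:5]}")

    @property
    def n_levels(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def n_occurrences(self) -> int:
        return int(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.level_ids, columns=self.taxon_ids)

    # -- derived matrices --------------------------------------------------
    def subset(
        self,
        levels: Iterable[str] | None = None,
        taxa: Iterable[str] | None = None,
    ) -> "IncidenceMatrix":
        """New matrix restricted to the given levels/taxa (input order kept)."""
        lv = list(levels) if levels is not None else list(self.level_ids)
        tx = list(taxa) if taxa is not None else list(self.taxon_ids)
        li = {x: i for i, x in enumerate(self.level_ids)}
        ti = {x: i for i, x in enumerate(self.taxon_ids)}
        try:
            rows = [li[x] for x in lv]
            cols = [ti[x] for x in tx]
        except KeyError as exc:  # pragma: no cover - guarded by callers
            raise ValidationError(f"unknown label {exc.args[0]!r}") from exc
        meta = {x: self.metadata[x] for x in lv} if self.metadata else {}
        return IncidenceMatrix(
            self.values[np.ix_(rows, cols)].copy(), lv, tx, meta
        )

    def drop_empty(self) -> "IncidenceMatrix":
        """Drop all-zero rows and columns; returns a new matrix."""
        keep_lv = [lv for lv, s in zip(self.level_ids, self.values.sum(axis=1)) if s > 0]
        keep_tx = [tx for tx, s in zip(self.taxon_ids, self.values.sum(axis=0)) if s > 0]
        return self.subset(keep_lv, keep_tx)


def summary(m: IncidenceMatrix) -> dict:
    """Validation report: sizes, occurrences, metadata completeness."""
    complete = 1.0 if m.metadata else 0.0
    if m.metadata:
        have = sum(1 for lv in m.level_ids if lv in m.metadata)
        complete = have / m.n_levels
    return {
        "n_levels": m.n_levels,
        "n_taxa": m.n_taxa,
        "n_occurrences": m.n_occurrences,
        "metadata_completeness": complete,
    }


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _read_header(path: Path) -> list[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
    return [h.strip() for h in header]


def load_metadata(path: str | Path) -> dict[str, LevelMetadata]:
    """Read a metadata CSV (`level_id,region,stage,site,depositional_setting,
    oxygen_stress[,extra...]`) into a level_id -> LevelMetadata map."""
    path = Path(path)
    header = _read_header(path)
    if not header or header[0] != "level_id":
        raise FormatError(f"{path}: metadata header must start with 'level_id'")
    missing = [c for c in CORE_METADATA_FIELDS if c not in header]
    if missing:
        raise FormatError(f"{path}: metadata header missing columns {missing}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    extra_cols = [c for c in df.columns if c != "level_id" and c not in CORE_METADATA_FIELDS]
    out: dict[str, LevelMetadata] = {}
    for _, row in df.iterrows():
        lid = row["level_id"].strip()
        if lid in out:
            raise ValidationError(f"duplicate level_id {lid!r} in metadata")
        out[lid] = LevelMetadata(
            level_id=lid,
            region=row["region"].strip(),
            stage=row["stage"].strip(),
            site=row["site"].strip(),
            depositional_setting=row["depositional_setting"].strip(),
            oxygen_stress=_parse_bool(row["oxygen_stress"], f"level {lid}"),
            extra={c: row[c].strip() for c in extra_cols},
        )
    return out


def load_incidence(
    path: str | Path,
    format: str = "wide",
    metadata: str | Path | Mapping[str, LevelMetadata] | None = None,
) -> IncidenceMatrix:
    """Load an incidence matrix from a wide or long CSV.

    Wide: header ``level_id,<taxon_1>,...``, body strictly 0/1.
    Long: header ``level_id,taxon_id``, one occurrence record per row;
    duplicate records collapse to a single presence.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    meta: dict[str, LevelMetadata] = {}
    if metadata is not None:
        meta = dict(metadata) if isinstance(metadata, Mapping) else load_metadata(metadata)

    if format == "wide":
        header = _read_header(path)
        if not header or header[0] != "level_id":
            raise FormatError(f"{path}: wide header must start with 'level_id'")
        taxa = header[1:]
        if len(set(taxa)) != len(taxa):
            raise ValidationError(f"{path}: duplicate taxon column in header")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        level_ids = [x.strip() for x in df.iloc[:, 0]]
        if len(set(level_ids)) != len(level_ids):
            raise ValidationError(f"{path}: duplicate level_id")
        body = df.iloc[:, 1:].map(lambda s: s.strip())
        flat = body.to_numpy().ravel()
        bad = ~np.isin(flat, ("0", "1"))
        if bad.any():
            raise ValidationError(
                f"{path}: non-binary cell value {flat[bad][0]!r} in wide matrix"
            )
        values = body.to_numpy().astype(np.int8)
        return IncidenceMatrix(values, level_ids, taxa, meta)

    if format == "long":
        header = _read_header(path)
        if header != ["level_id", "taxon_id"]:
            raise FormatError(f"{path}: long header must be 'level_id,taxon_id'")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        levels: list[str] = []
        taxa_order: list[str] = []
        seen_lv: dict[str, int] = {}
        seen_tx: dict[str, int] = {}
        records = []
        for lid_raw, tid_raw in zip(df["level_id"], df["taxon_id"]):
            lid, tid = lid_raw.strip(), tid_raw.strip()
            if not lid or not tid:
                raise ValidationError(f"{path}: blank level_id or taxon_id")
            if lid not in seen_lv:
                seen_lv[lid] = len(levels)
                levels.append(lid)
            if tid not in seen_tx:
                seen_tx[tid] = len(taxa_order)
                taxa_order.append(tid)
            records.append((seen_lv[lid], seen_tx[tid]))
        values = np.zeros((len(levels), len(taxa_order)), dtype=np.int8)
        for i, j in records:
            values[i, j] = 1
        return IncidenceMatrix(values, levels, taxa_order, meta)

    raise ConfigurationError(f"unknown incidence format {format!r}")


def write_incidence(m: IncidenceMatrix, path: str | Path, format: str = "wide") -> None:
    """Write the canonical CSV dialect (UTF-8, comma, LF newlines)."""
    path = Path(path)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        if format == "wide":
            writer.writerow(["level_id", *m.taxon_ids])
            for lid, row in zip(m.level_ids, m.values):
                writer.writerow([lid, *(int(x) for x in row)])
        elif format == "long":
            writer.writerow(["level_id", "taxon_id"])
            for i, lid in enumerate(m.level_ids):
                for j in np.flatnonzero(m.values[i]):
                    writer.writerow([lid, m.taxon_ids[j]])
        else:
            raise ConfigurationError(f"unknown incidence format {format!r}")


def write_metadata(m: IncidenceMatrix, path: str | Path) -> None:
    """Write the metadata CSV companion of an incidence matrix."""
    extra_keys: list[str] = []
    for lv in m.level_ids:
        for k in m.metadata[lv].extra:
            if k not in extra_keys:
                extra_keys.append(k)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["level_id", *CORE_METADATA_FIELDS, *extra_keys])
        for lv in m.level_ids:
            md = m.metadata[lv]
            writer.writerow(
                [
                    md.level_id,
                    md.region,
                    md.stage,
                    md.site,
                    md.depositional_setting,
                    "true" if md.oxygen_stress else "false",
                    *(md.extra.get(k, "") for k in extra_keys),
                ]
            )


# ---------------------------------------------------------------------------
# Filtering and splitting
# ---------------------------------------------------------------------------

Predicate = Callable[[LevelMetadata], bool]


def compile_predicate(expr: str) -> Predicate:
    """Compile a metadata predicate expression, e.g.
    ``"depositional_setting == 'offshore' and not oxygen_stress"``.

    The expression is evaluated against the declared metadata fields only;
    referencing an unknown name raises :class:`ConfigurationError`.
    """
    try:
        code = compile(expr, "<predicate>", "eval")
    except SyntaxError as exc:
        raise ConfigurationError(f"invalid predicate {expr!r}: {exc}") from exc

    def predicate(md: LevelMetadata) -> bool:
        try:
            return bool(eval(code, {"__builtins__": {}}, md.namespace()))
        except NameError as exc:
            raise ConfigurationError(
                f"predicate {expr!r} references unknown metadata field: {exc}"
            ) from exc

    return predicate


def filter_levels(m: IncidenceMatrix, predicate: Predicate | str) -> IncidenceMatrix:
    """Keep levels satisfying the predicate; drop taxa left with no
    occurrences. The input matrix is not modified."""
    if isinstance(predicate, str):
        predicate = compile_predicate(predicate)
    if not m.metadata:
        raise ValidationError("cannot filter a matrix without level metadata")
    keep = [lv for lv in m.level_ids if predicate(m.metadata[lv])]
    out = m.subset(levels=keep)
    keep_tx = [tx for tx, s in zip(out.taxon_ids, out.values.sum(axis=0)) if s > 0]
    return out.subset(taxa=keep_tx)


def split_by_stage(m: IncidenceMatrix) -> dict[str, IncidenceMatrix]:
    """Partition levels by their metadata stage; empty taxa dropped per
    stage. Outputs are disjoint and jointly exhaustive over levels."""
    if not m.metadata:
        raise ValidationError("cannot split a matrix without level metadata")
    stages: dict[str, list[str]] = {}
    for lv in m.level_ids:
        stage = m.metadata[lv].stage
        if not stage:
            raise ValidationError(f"level {lv!r} has no stage label")
        stages.setdefault(stage, []).append(lv)
    out: dict[str, IncidenceMatrix] = {}
    for stage, levels in stages.items():
        sub = m.subset(levels=levels)
        keep_tx = [tx for tx, s in zip(sub.taxon_ids, sub.values.sum(axis=0)) if s > 0]
        out[stage] = sub.subset(taxa=keep_tx)
    return out
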