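"""Shared data types and on-disk formats.

Connectivity matrices are dense CSV ('.' decimal, comma separator, optional
single header row of node ids; row order defines node order). Subject and
atlas tables are TSV. Results are JSON documents with a schema version, the
seed used, and full-precision numbers, so that write→read is the identity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9
SCHEMA_VERSION = "1.0"

GROUPS = ("patient", "control")

#: columns every subject must provide (finite values required)
COVARIATE_COLUMNS = ("age", "education", "ftnd")

#: clinical scores; required for patients, optional for controls
CLINICAL_COLUMNS = (
    "bprs_total",
    "bprs_anxiety_depression",
    "bprs_lack_of_vitality",
    "bprs_thinking_disorder",
    "bprs_activity",
    "bprs_hostility_suspicion",
    "hama",
)


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates a data-model invariant."""


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric nonnegative connection-probability matrix.

    ``weights[i, j]`` is the probability of a white-matter connection between
    parcels ``node_ids[i]`` and ``node_ids[j]`` (unitless, in [0, 1] by
    convention, though only nonnegativity is enforced). Zero diagonal.
    """

    subject_id: str
    weights: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 nodes, got {n}")
        if len(self.node_ids) != n:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for a {n}x{n} matrix"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("node ids must be unique")
        if np.isnan(w).any():
            i, j = np.argwhere(np.isnan(w))[0]
            raise ValidationError(f"NaN entry at ({i}, {j})")
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise ValidationError(f"negative entry {w[i, j]} at ({i}, {j})")
        asym = np.abs(w - w.T)
        if asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"asymmetry {asym[i, j]:.3g} at ({i}, {j})/({j}, {i}) exceeds "
                f"tolerance {SYMMETRY_TOL}"
            )
        # symmetrize residual float noise by averaging
        self.weights = (w + w.T) / 2.0
        if np.diagonal(self.weights).any():
            logger.warning(
                "subject %s: nonzero diagonal forced to 0", self.subject_id
            )
            np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class SubjectRecord:
    """Group label, covariates and clinical scores for one subject."""

    subject_id: str
    group: str
    age: float
    education: float
    ftnd: float
    bprs_total: float = np.nan
    bprs_factors: dict[str, float] = field(default_factory=dict)
    hama: float = np.nan

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for {self.subject_id}"
            )
        for name in COVARIATE_COLUMNS:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValidationError(
                    f"subject {self.subject_id}: covariate {name!r} missing"
                )
        if self.group == "patient":
            missing = [
                c
                for c, v in self.clinical_items()
                if v is None or not np.isfinite(v)
            ]
            if missing:
                raise ValidationError(
                    f"patient {self.subject_id}: clinical scores missing: "
                    f"{missing}"
                )

    def clinical_items(self) -> list[tuple[str, float]]:
        items = [("bprs_total", self.bprs_total), ("hama", self.hama)]
        for c in CLINICAL_COLUMNS[1:-1]:
            items.append((c, self.bprs_factors.get(c[len("bprs_") :], np.nan)))
        return items


@dataclass
class AtlasTable:
    """Node id → region name, hemisphere (L/R) and subnetwork membership."""

    table: pd.DataFrame

    REQUIRED = ("node_id", "region_name", "hemisphere", "subnetwork")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"atlas table lacks column {col!r}")
        ids = self.table["node_id"].astype(str)
        if ids.duplicated().any():
            raise ValidationError("duplicate node_id in atlas table")
        bad = set(self.table["hemisphere"]) - {"L", "R"}
        if bad:
            raise ValidationError(f"hemisphere labels must be L/R, got {bad}")
        self.table = self.table.assign(node_id=ids).reset_index(drop=True)

    @property
    def node_ids(self) -> list[str]:
        return self.table["node_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Cohort:
    """A matched set of records, matrices and (optionally) an atlas."""

    records: list[SubjectRecord]
    matrices: dict[str, ConnectivityMatrix]
    atlas: AtlasTable | None = None

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in cohort")
        dims = set()
        node_orders = set()
        for r in self.records:
            m = self.matrices.get(r.subject_id)
            if m is None:
                raise ValidationError(f"no matrix for subject {r.subject_id}")
            dims.add(m.n_nodes)
            node_orders.add(tuple(m.node_ids))
        if len(dims) > 1:
            raise ValidationError(f"inconsistent matrix dimensions: {dims}")
        if len(node_orders) > 1:
            raise ValidationError("inconsistent node ordering across subjects")
        if self.atlas is not None and self.records:
            n = next(iter(dims))
            if len(self.atlas) != n:
                raise ValidationError(
                    f"atlas has {len(self.atlas)} rows for {n}-node matrices"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def node_ids(self) -> list[str]:
        return self.matrices[self.records[0].subject_id].node_ids

    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def covariates(self) -> np.ndarray:
        """n_subjects × 3 array of (age, education, ftnd)."""
        return np.array(
            [[r.age, r.education, r.ftnd] for r in self.records], dtype=float
        )


# ---------------------------------------------------------------------------
# readers


def _looks_numeric(fields: Sequence[str]) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def read_matrix(
    path: str | Path, node_ids: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Read a dense CSV connectivity matrix.

    An optional single header row supplies node ids; otherwise ``node_ids``
    or positional labels ``n000…`` are used. Asymmetries within 1e-9 are
    averaged away; anything larger is rejected with the offending cell.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    header_fields = [f.strip() for f in first.split(",")]
    has_header = not _looks_numeric(header_fields)
    data = pd.read_csv(path, header=0 if has_header else None).to_numpy(
        dtype=float
    )
    if has_header and node_ids is None:
        node_ids = header_fields
    if node_ids is None:
        node_ids = [f"n{i:03d}" for i in range(data.shape[0])]
    return ConnectivityMatrix(path.stem, data, list(node_ids))


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.weights, columns=matrix.node_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the TSV subject metadata table into typed records."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "group", *COVARIATE_COLUMNS):
        if col not in df.columns:
            raise ValidationError(f"subject table lacks column {col!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r}")
    records = []
    for _, row in df.iterrows():
        factors = {
            c[len("bprs_") :]: float(row[c])
            for c in CLINICAL_COLUMNS[1:-1]
            if c in df.columns and pd.notna(row[c])
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                education=float(row["education"]),
                ftnd=float(row["ftnd"]),
                bprs_total=float(row.get("bprs_total", np.nan))
                if pd.notna(row.get("bprs_total", np.nan))
                else np.nan,
                bprs_factors=factors,
                hama=float(row.get("hama", np.nan))
                if pd.notna(row.get("hama", np.nan))
                else np.nan,
            )
        )
    return records


def write_subject_table(
    records: Sequence[SubjectRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "education": r.education,
            "ftnd": r.ftnd,
            "bprs_total": r.bprs_total,
            "hama": r.hama,
        }
        for c in CLINICAL_COLUMNS[1:-1]:
            row[c] = r.bprs_factors.get(c[len("bprs_") :], np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_atlas_table(path: str | Path) -> AtlasTable:
    return AtlasTable(pd.read_csv(path, sep="\t", dtype=str))


def write_atlas_table(atlas: AtlasTable, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort directory layout: matrices/<subject_id>.csv + subjects.tsv + atlas.tsv


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    (directory / "matrices").mkdir(parents=True, exist_ok=True)
    write_subject_table(cohort.records, directory / "subjects.tsv")
    if cohort.atlas is not None:
        write_atlas_table(cohort.atlas, directory / "atlas.tsv")
    for sid, m in cohort.matrices.items():
        write_matrix(m, directory / "matrices" / f"{sid}.csv")


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    records = read_subject_table(directory / "subjects.tsv")
    atlas = None
    if (directory / "atlas.tsv").exists():
        atlas = read_atlas_table(directory / "atlas.tsv")
    matrices = {}
    for r in records:
        mpath = directory / "matrices" / f"{r.subject_id}.csv"
        if not mpath.exists():
            raise ValidationError(f"missing matrix file for {r.subject_id}")
        matrices[r.subject_id] = read_matrix(
            mpath, node_ids=atlas.node_ids if atlas is not None else None
        )
    return Cohort(records, matrices, atlas)


# ---------------------------------------------------------------------------
# JSON result reports


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            **{
                f.name: _jsonify(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.to_dict(orient="tight")}
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def _dejsonify(obj: Any, types: Mapping[str, type]) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.array(obj["__ndarray__"], dtype=obj["dtype"])
        if "__dataframe__" in obj:
            return pd.DataFrame.from_dict(obj["__dataframe__"], orient="tight")
        if "__type__" in obj:
            cls = types[obj["__type__"]]
            kwargs = {
                k: _dejsonify(v, types)
                for k, v in obj.items()
                if k != "__type__"
            }
            return cls(**kwargs)
        return {k: _dejsonify(v, types) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_dejsonify(v, types) for v in obj]
    return obj


def write_report(
    result: Any,
    path: str | Path,
    *,
    seed: int | None = None,
    inputs: Mapping[str, str] | None = None,
    timestamp: str | None = None,
) -> None:
    """Serialize a result object to JSON (schema-versioned, full precision)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "inputs": dict(inputs or {}),
        "timestamp": timestamp,
        "payload": _jsonify(result),
    }
    try:
        text = json.dumps(doc, indent=1, allow_nan=True, sort_keys=True)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"unserializable payload: {exc}") from exc
    Path(path).write_text(text + "\n")


def read_report(path: str | Path, types: Mapping[str, type] | None = None) -> Any:
    """Inverse of :func:`write_report`; returns the payload object."""
    doc = json.loads(Path(path).read_text())
    return _dejsonify(doc["payload"], types or _known_types())


def read_report_document(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _known_types() -> dict[str, type]:
    from . import classify, inference, nbs

    return {
        "ClassifierReport": classify.ClassifierReport,
        "ComparisonResult": inference.ComparisonResult,
        "PartialCorrelationResult": inference.PartialCorrelationResult,
        "NBSResult": nbs.NBSResult,
        "NBSComponent": nbs.NBSComponent,
        "LeakageAuditReport": classify.LeakageAuditReport,
    }
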