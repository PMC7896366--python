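"""Loading, validation, filtering, and serialization of multi-omic datasets.

A dataset is a cohort of samples measured on several "omes" (assay layers,
e.g. microbial relative abundances, metabolite intensities in ppm, enzyme
abundances in ppm), together with a binary group label and numeric clinical
covariates per sample. Analytes are addressed by a globally unique prefixed
name (``mb_``, ``met_``, ``e_`` by default) so that analytes from different
omes can coexist in one network and one regression design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NETWORK_SCHEMA = "cantare-net/1"

#: default ome-name -> analyte-name prefix map
DEFAULT_PREFIXES = {"mb": "mb_", "met": "met_", "e": "e_"}


@dataclass
class OmicsDataset:
    """Aligned per-ome analyte matrices plus sample metadata for one cohort.

    Attributes
    ----------
    sample_ids : list of str
        Ordered sample identifiers, shared by every ome matrix.
    group : numpy.ndarray
        Binary outcome per sample (0 = control, 1 = case).
    covariates : pandas.DataFrame
        Numeric covariates (rows = samples, in ``sample_ids`` order).
    omes : dict of str -> pandas.DataFrame
        One samples x analytes matrix per ome; columns carry the global
        (prefixed) analyte names; values are non-negative reals.
    registry : dict of str -> (str, str)
        Global analyte name -> (ome name, local analyte name).
    """

    sample_ids: list[str]
    group: np.ndarray
    covariates: pd.DataFrame
    omes: dict[str, pd.DataFrame]
    registry: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        levels = np.unique(self.group)
        if len(levels) != 2:
            raise ValueError(
                f"group must take exactly two levels, found {list(levels)}"
            )
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        for ome, mat in self.omes.items():
            if list(mat.index) != list(self.sample_ids):
                raise ValueError(f"ome {ome!r} is not aligned to sample_ids")
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"ome {ome!r} contains negative values")
        if not self.registry:
            self.registry = {
                name: (ome, name.split("_", 1)[1] if "_" in name else name)
                for ome, mat in self.omes.items()
                for name in mat.columns
            }
        all_names = [c for mat in self.omes.values() for c in mat.columns]
        if len(set(all_names)) != len(all_names):
            raise ValueError("global analyte names are not unique across omes")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def analyte_ome(self, name: str) -> str:
        return self.registry[name][0]

    def analyte_vector(self, name: str) -> np.ndarray:
        ome = self.analyte_ome(name)
        return self.omes[ome][name].to_numpy(dtype=float)

    def analyte_frame(self, names: Sequence[str]) -> pd.DataFrame:
        """Assemble selected analytes (any ome) into one samples x names frame."""
        cols = {name: self.analyte_vector(name) for name in names}
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))

    def predictor_frame(
        self, analytes: Sequence[str], covariates: Sequence[str] = ()
    ) -> pd.DataFrame:
        """Analytes plus named covariate columns, aligned on samples."""
        frame = self.analyte_frame(analytes)
        for cov in covariates:
            if cov not in self.covariates.columns:
                raise KeyError(f"unknown covariate {cov!r}")
            frame[cov] = self.covariates[cov].to_numpy(dtype=float)
        return frame


@dataclass
class PreprocessSpec:
    """Analyte-level preprocessing rules applied before the pairwise sweep.

    ``cv_dedup_groups`` maps a standard identifier to the candidate analyte
    columns measuring it (e.g. the same metabolite standard hit by several
    LC/MS clusters); only the highest-CV candidate is retained.
    ``mean_floor``/``variance_floor`` keep an analyte only when its mean and
    sample variance strictly exceed both floors, unless whitelisted.
    """

    cv_dedup_groups: dict[str, list[str]] = field(default_factory=dict)
    mean_floor: float = 0.0
    variance_floor: float = 0.0
    whitelist: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_floor < 0 or self.variance_floor < 0:
            raise ValueError("floors must be >= 0")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # round_trip parsing keeps load -> write -> load bit-stable on values
    frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    return frame


def load_dataset(
    ome_tables: Mapping[str, str | Path],
    metadata_table: str | Path,
    group_column: str,
    covariate_columns: Sequence[str] = (),
    prefixes: Mapping[str, str] | None = None,
) -> OmicsDataset:
    """Load per-ome CSV/TSV tables and a metadata table into one dataset.

    Each ome table has sample ids in its first column and one analyte per
    remaining column. Samples are aligned on the intersection of ids across
    all tables (dropped ids are logged), preserving the metadata row order.
    Analyte columns are renamed to their global prefixed form.
    """
    prefixes = dict(DEFAULT_PREFIXES) | dict(prefixes or {})
    meta = _read_table(metadata_table)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if group_column not in meta.columns:
        raise KeyError(f"group column {group_column!r} not in metadata")
    for cov in covariate_columns:
        if cov not in meta.columns:
            raise KeyError(f"covariate column {cov!r} not in metadata")

    raw: dict[str, pd.DataFrame] = {}
    common = set(meta.index)
    for ome, path in ome_tables.items():
        table = _read_table(path)
        if table.index.duplicated().any():
            raise ValueError(f"duplicate sample ids in ome table {ome!r}")
        bad = table.columns[
            ~table.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
        ]
        if len(bad):
            rows = table[bad[0]][
                pd.to_numeric(table[bad[0]], errors="coerce").isna()
            ].index.tolist()
            raise ValueError(
                f"non-numeric value in ome {ome!r}, column {bad[0]!r}, rows {rows}"
            )
        raw[ome] = table.astype(float)
        common &= set(table.index)

    ids = [s for s in meta.index if s in common]
    dropped = sorted(set(meta.index) - common)
    if dropped:
        logger.warning(
            "dropping %d sample id(s) absent from some table: %s", len(dropped), dropped
        )
    if not ids:
        raise ValueError("no sample ids common to all tables")

    levels = sorted(pd.unique(meta.loc[ids, group_column]))
    if len(levels) != 2:
        raise ValueError(
            f"group column {group_column!r} must have exactly 2 levels, "
            f"found {levels}"
        )
    group = (meta.loc[ids, group_column] == levels[1]).to_numpy(dtype=int)
    logger.info("group coding: %r -> 0 (control), %r -> 1 (case)", levels[0], levels[1])

    omes: dict[str, pd.DataFrame] = {}
    registry: dict[str, tuple[str, str]] = {}
    for ome, table in raw.items():
        prefix = prefixes.get(ome, f"{ome}_")
        mat = table.loc[ids]
        mat.columns = [f"{prefix}{c}" for c in table.columns]
        for gname, local in zip(mat.columns, table.columns):
            registry[gname] = (ome, str(local))
        omes[ome] = mat

    covs = meta.loc[ids, list(covariate_columns)].astype(float)
    return OmicsDataset(
        sample_ids=ids, group=group, covariates=covs, omes=omes, registry=registry
    )


def dedup_by_cv(
    matrix: pd.DataFrame, cv_dedup_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Collapse each candidate group to its single highest-CV column.

    CV = sample standard deviation / mean. A zero-mean column has undefined
    CV and is never selected unless every candidate is undefined, in which
    case the lexicographically first column is kept. Exact CV ties also go
    to the lexicographically first name. Ungrouped columns pass through.
    """
    drop: set[str] = set()
    for gid, members in cv_dedup_groups.items():
        members = list(members)
        missing = [m for m in members if m not in matrix.columns]
        if missing:
            raise KeyError(f"dedup group {gid!r} references missing columns {missing}")
        if not members:
            raise ValueError(f"dedup group {gid!r} is empty")
        means = matrix[members].mean(axis=0)
        sds = matrix[members].std(axis=0, ddof=1)
        cv = sds / means.where(means != 0)  # zero mean -> NaN (undefined)
        if cv.notna().any():
            best_cv = cv.max()
            winner = min(c for c in members if cv[c] == best_cv)
        else:
            winner = min(members)
        drop.update(m for m in members if m != winner)
    return matrix.drop(columns=sorted(drop))


def mean_variance_filter(
    matrix: pd.DataFrame,
    mean_floor: float,
    variance_floor: float,
    whitelist: Sequence[str] = (),
) -> pd.DataFrame:
    """Keep columns with mean > mean_floor AND variance > variance_floor.

    Both inequalities are strict; sample variance uses the n-1 denominator.
    Whitelisted columns are always retained regardless of the floors.
    """
    missing = [w for w in whitelist if w not in matrix.columns]
    if missing:
        raise KeyError(f"whitelist names absent from matrix: {missing}")
    means = matrix.mean(axis=0)
    variances = matrix.var(axis=0, ddof=1)
    keep = [
        c
        for c in matrix.columns
        if (means[c] > mean_floor and variances[c] > variance_floor)
        or c in set(whitelist)
    ]
    return matrix[keep]


# ---------------------------------------------------------------------------
# dataset directory round trip (one CSV per ome + metadata.csv)
# ---------------------------------------------------------------------------


def write_dataset_dir(dataset: OmicsDataset, out_dir: str | Path) -> Path:
    """Persist a dataset as one CSV per ome plus metadata.csv.

    Ome CSVs keep the *local* analyte names so the directory can be
    reloaded through :func:`load_dataset` (which re-applies the prefixes);
    metadata.csv holds the group label (column ``group``) and covariates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ome, mat in dataset.omes.items():
        local = mat.copy()
        local.columns = [dataset.registry[c][1] for c in mat.columns]
        local.index.name = "sample_id"
        local.to_csv(out_dir / f"{ome}.csv")
    meta = dataset.covariates.copy()
    meta.insert(0, "group", dataset.group)
    meta.index.name = "sample_id"
    meta.to_csv(out_dir / "metadata.csv")
    return out_dir


def read_dataset_dir(in_dir: str | Path) -> OmicsDataset:
    """Reload a dataset directory written by :func:`write_dataset_dir`."""
    in_dir = Path(in_dir)
    meta_path = in_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv in {in_dir}")
    covariate_columns = [
        c for c in _read_table(meta_path).columns if c != "group"
    ]
    ome_tables = {
        p.stem: p for p in sorted(in_dir.glob("*.csv")) if p.name != "metadata.csv"
    }
    return load_dataset(ome_tables, meta_path, "group", covariate_columns)


# ---------------------------------------------------------------------------
# Network JSON (node-link, versioned): cantare-net/1
# ---------------------------------------------------------------------------

_EDGE_FIELDS = (
    "mode",
    "beta0",
    "beta1",
    "beta2",
    "beta3",
    "p_target",
    "max_abs_dffits",
    "n",
)


def write_network_json(network, path: str | Path) -> None:
    """Serialize an analyte network as versioned node-link JSON.

    Schema: ``{"schema": "cantare-net/1", "nodes": [{"id","ome","label"}],
    "links": [{"source","target","mode","beta0".."beta3","p_target",
    "max_abs_dffits","n"}]}``. NaN statistics are written as null.
    """

    def scrub(value):
        if value is None:
            return None
        if isinstance(value, float) and not np.isfinite(value):
            return None
        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        return value

    graph = network.graph
    nodes = [
        {
            "id": node,
            "ome": graph.nodes[node].get("ome", ""),
            "label": graph.nodes[node].get("label", node),
        }
        for node in sorted(graph.nodes)
    ]
    links = []
    for u, v in sorted(map(lambda e: tuple(sorted(e)), graph.edges)):
        attrs = graph.edges[u, v]
        link = {"source": u, "target": v}
        link.update({f: scrub(attrs.get(f)) for f in _EDGE_FIELDS})
        links.append(link)
    payload = {"schema": NETWORK_SCHEMA, "nodes": nodes, "links": links}
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=False) + "\n")


def read_network_json(path: str | Path):
    """Read a cantare-net/1 JSON file back into an :class:`AnalyteNetwork`."""
    from cantare.network import AnalyteNetwork

    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != NETWORK_SCHEMA:
        raise ValueError(
            f"unknown network schema {payload.get('schema')!r}; "
            f"expected {NETWORK_SCHEMA!r}"
        )
    net = AnalyteNetwork()
    ids = set()
    for node in payload["nodes"]:
        net.graph.add_node(
            node["id"], ome=node.get("ome", ""), label=node.get("label", node["id"])
        )
        ids.add(node["id"])
    for link in payload["links"]:
        u, v = link["source"], link["target"]
        missing = {u, v} - ids
        if missing:
            raise ValueError(f"edge {u!r}--{v!r} references missing node(s) {missing}")
        attrs = {
            f: (np.nan if link.get(f) is None and f != "mode" else link.get(f))
            for f in _EDGE_FIELDS
        }
        net.graph.add_edge(u, v, **attrs)
    return net
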