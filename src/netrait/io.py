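"""Reading and writing connectomes, cohorts, and result tables.

Connectivity matrices are dense, symmetric, non-negative N x N arrays with a
zero diagonal; node order is always the order of the :class:`RegionTable`.
Files that carry region names are reconciled by name, never by position.
Weights are accepted as given (streamline count, density, ...); no unit is
imposed — only a free-form metadata string records what the producer claims.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .association import AssociationModel
    from .threshold import EntropyScan

SYMMETRY_TOL = 1e-9

HEMISPHERES = ("left", "right", "none")

#: Desikan-Killiany cortical parcels (34 per hemisphere).
_DK_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: Subcortical segmentation structures (7 per hemisphere).
_SUBCORTICAL = (
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens",
)


class ConnectomeIOError(ValueError):
    """Raised when an input file violates a connectome invariant."""


@dataclass(frozen=True)
class RegionTable:
    """Ordered node labels: (0-based index, region name, hemisphere)."""

    entries: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        idx = [e[0] for e in self.entries]
        if idx != list(range(len(self.entries))):
            raise ConnectomeIOError("node indices must be 0..N-1 without gaps")
        names = [e[1] for e in self.entries]
        if len(set(names)) != len(names):
            raise ConnectomeIOError("region names must be unique")
        for _, _, hemi in self.entries:
            if hemi not in HEMISPHERES:
                raise ConnectomeIOError(f"unknown hemisphere {hemi!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e[1] for e in self.entries]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConnectomeIOError(f"unknown region name {name!r}") from None

    @classmethod
    def from_names(cls, names: Sequence[str],
                   hemispheres: Sequence[str] | None = None) -> "RegionTable":
        if hemispheres is None:
            hemispheres = ["none"] * len(names)
        return cls(tuple(
            (i, n, h) for i, (n, h) in enumerate(zip(names, hemispheres))
        ))


def default_region_table() -> RegionTable:
    """83-region parcellation: 41 per hemisphere plus the brainstem.

    Desikan-Killiany cortex (34 parcels/hemisphere) with subcortical
    segmentation (7 structures/hemisphere) and a single brainstem node.
    """
    entries: list[tuple[int, str, str]] = []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for name in _DK_CORTICAL + _SUBCORTICAL:
            entries.append((len(entries), f"{prefix}_{name}", hemi))
    entries.append((len(entries), "brainstem", "none"))
    return RegionTable(tuple(entries))


@dataclass
class WeightedConnectome:
    """One subject's N x N non-negative symmetric connectivity matrix."""

    subject_id: str
    weights: np.ndarray
    regions: RegionTable
    weight_unit: str = "unspecified"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        w = self.weights
        n = len(self.regions)
        if w.shape != (n, n):
            raise ConnectomeIOError(
                f"weight matrix shape {w.shape} does not match "
                f"{n}-entry region table")
        if not np.all(np.isfinite(w)):
            raise ConnectomeIOError("non-finite weight")
        asym = np.abs(w - w.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ConnectomeIOError(
                f"matrix asymmetric beyond tolerance ({asym:g} > {SYMMETRY_TOL:g})")
        if np.any(np.diag(w) != 0):
            raise ConnectomeIOError("diagonal must be exactly 0")
        if np.any(w < 0):
            raise ConnectomeIOError("negative weight")

    @property
    def n_nodes(self) -> int:
        return len(self.regions)

    def positive_pairs(self) -> int:
        """Number of unordered node pairs with strictly positive weight."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu] > 0))


@dataclass
class Cohort:
    """Subject-indexed connectomes plus a covariate table.

    ``covariates`` is a DataFrame indexed by subject_id with columns
    age, sex ('male'/'female'), trait_score, and optional item_1..item_k.
    """

    connectomes: list[WeightedConnectome]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [c.subject_id for c in self.connectomes]
        if len(set(ids)) != len(ids):
            raise ConnectomeIOError("duplicate subject_id among connectomes")
        if set(ids) != set(self.covariates.index):
            raise ConnectomeIOError("subject_ids differ between connectomes "
                                    "and covariates")
        regions = self.connectomes[0].regions
        for c in self.connectomes:
            if c.regions.names != regions.names:
                raise ConnectomeIOError("connectomes do not share a region table")
        required = {"age", "sex", "trait_score"}
        missing = required - set(self.covariates.columns)
        if missing:
            raise ConnectomeIOError(f"missing covariate columns: {sorted(missing)}")
        if self.covariates[sorted(required)].isna().any().any():
            raise ConnectomeIOError("missing covariate values")
        bad = set(self.covariates["sex"]) - {"male", "female"}
        if bad:
            raise ConnectomeIOError(f"sex values outside vocabulary: {sorted(bad)}")
        # covariate row order follows the connectome list
        self.covariates = self.covariates.loc[ids]

    @property
    def subject_ids(self) -> list[str]:
        return [c.subject_id for c in self.connectomes]

    @property
    def regions(self) -> RegionTable:
        return self.connectomes[0].regions

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.covariates.columns if c.startswith("item_")]

    def item_matrix(self) -> np.ndarray | None:
        cols = self.item_columns
        if not cols:
            return None
        return self.covariates[cols].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.connectomes)


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------

def read_weight_matrix(path: str | Path, format: str,
                       regions: RegionTable,
                       subject_id: str | None = None) -> WeightedConnectome:
    """Read one connectivity matrix in ``matrix-csv``, ``edge-list`` or
    ``graphml`` format.

    Files carrying region names are reconciled against ``regions`` by name.
    Invariant violations (asymmetry beyond 1e-9, negative weights, non-zero
    diagonal, unknown names) raise :class:`ConnectomeIOError` — the reader
    never repairs.
    """
    path = Path(path)
    if not path.exists():
        raise ConnectomeIOError(f"no such file: {path}")
    sid = subject_id if subject_id is not None else path.stem
    if format == "matrix-csv":
        w = _read_matrix_csv(path, regions)
    elif format == "edge-list":
        w = _read_edge_list(path, regions)
    elif format == "graphml":
        w = _read_graphml(path, regions)
    else:
        raise ConnectomeIOError(f"unknown format {format!r}")
    return WeightedConnectome(subject_id=sid, weights=w, regions=regions)


def _infer_regions(path: Path, fmt: str) -> RegionTable:
    """Region table from the node names in a matrix file; falls back to the
    bundled 83-region table when the file carries no names."""
    names: list[str] | None = None
    if fmt == "matrix-csv":
        with open(path, newline="") as fh:
            first = next(csv.reader(fh), None)
        if first is not None:
            try:
                float(first[-1])
            except ValueError:
                names = [c.strip() for c in (first[1:] if first[0] == ""
                                             else first)]
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        names = [d.get("region_name", str(v)) for v, d in
                 sorted(g.nodes(data=True), key=lambda t: str(t[0]))]
    if names is None:
        return default_region_table()
    hemis = ["left" if n.startswith("lh_") else
             "right" if n.startswith("rh_") else "none" for n in names]
    return RegionTable.from_names(names, hemis)


def _read_matrix_csv(path: Path, regions: RegionTable) -> np.ndarray:
    n = len(regions)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise ConnectomeIOError(f"empty file: {path}")

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    has_header = not _numeric(rows[0][-1])
    order = list(range(n))
    if has_header:
        header = rows[0]
        body = rows[1:]
        has_rownames = not _numeric(body[0][0]) if body else False
        names = header[1:] if has_rownames else header
        if len(names) != n:
            raise ConnectomeIOError(
                f"matrix has {len(names)} columns, region table has {n}")
        order = [regions.index_of(nm.strip()) for nm in names]
        data = [r[1:] if has_rownames else r for r in body]
    else:
        data = rows
    if len(data) != n or any(len(r) != n for r in data):
        raise ConnectomeIOError(
            f"expected a {n}x{n} grid in {path}")
    raw = np.array([[float(c) for c in r] for r in data])
    # permute file order into region-table order
    w = np.zeros_like(raw)
    for fi, ti in enumerate(order):
        for fj, tj in enumerate(order):
            w[ti, tj] = raw[fi, fj]
    return w


def _read_edge_list(path: Path, regions: RegionTable) -> np.ndarray:
    n = len(regions)
    w = np.zeros((n, n))
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 3:
        raise ConnectomeIOError("edge-list needs columns source, target, weight")
    for src, dst, wt in df.itertuples(index=False, name=None):
        i, j = regions.index_of(str(src)), regions.index_of(str(dst))
        if i == j:
            raise ConnectomeIOError(f"self-loop on region {src!r}")
        wt = float(wt)
        prev = w[i, j]
        if prev != 0 and abs(prev - wt) > SYMMETRY_TOL:
            raise ConnectomeIOError(
                f"conflicting weights for pair ({src}, {dst})")
        w[i, j] = w[j, i] = wt
    return w


def _read_graphml(path: Path, regions: RegionTable) -> np.ndarray:
    g = nx.read_graphml(path)
    n = len(regions)
    w = np.zeros((n, n))
    name_of = {}
    for node, data in g.nodes(data=True):
        name = data.get("region_name", str(node))
        name_of[node] = regions.index_of(name)
    for u, v, data in g.edges(data=True):
        i, j = name_of[u], name_of[v]
        if i == j:
            raise ConnectomeIOError("self-loop in graphml input")
        w[i, j] = w[j, i] = float(data["weight"])
    return w


def write_weight_matrix(conn: WeightedConnectome, path: str | Path,
                        format: str = "matrix-csv") -> Path:
    """Write a connectome in any of the supported formats."""
    path = Path(path)
    names = conn.regions.names
    if format == "matrix-csv":
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow([""] + names)
            for name, row in zip(names, conn.weights):
                wr.writerow([name] + [repr(float(x)) for x in row])
    elif format == "edge-list":
        iu = np.triu_indices(conn.n_nodes, k=1)
        with open(path, "w", newline="") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j in zip(*iu):
                if conn.weights[i, j] > 0:
                    fh.write(f"{names[i]}\t{names[j]}\t"
                             f"{float(conn.weights[i, j])!r}\n")
    elif format == "graphml":
        g = nx.Graph()
        for i, name in enumerate(names):
            g.add_node(i, region_name=name)
        iu = np.triu_indices(conn.n_nodes, k=1)
        for i, j in zip(*iu):
            if conn.weights[i, j] > 0:
                g.add_edge(int(i), int(j), weight=float(conn.weights[i, j]))
        nx.write_graphml(g, path)
    else:
        raise ConnectomeIOError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def read_cohort(manifest_path: str | Path,
                regions: RegionTable | None = None) -> Cohort:
    """Load a cohort from a manifest CSV.

    Columns: subject_id, matrix_path (relative to the manifest), age, sex,
    trait_score, plus optional item_1..item_k. One connectome per row.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"subject_id": str},
                     float_precision="round_trip")
    required = {"subject_id", "matrix_path", "age", "sex", "trait_score"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeIOError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ConnectomeIOError(f"duplicate subject_id {dup!r}")
    base = manifest_path.parent
    connectomes = []
    for row in df.itertuples(index=False):
        mpath = base / row.matrix_path
        fmt = {".csv": "matrix-csv", ".tsv": "edge-list",
               ".graphml": "graphml"}.get(mpath.suffix)
        if fmt is None:
            raise ConnectomeIOError(f"cannot infer format of {mpath}")
        if regions is None:
            regions = _infer_regions(mpath, fmt)
        connectomes.append(read_weight_matrix(mpath, fmt, regions,
                                              subject_id=row.subject_id))
    cov = df.drop(columns=["matrix_path"]).set_index("subject_id")
    return Cohort(connectomes=connectomes, covariates=cov)


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 matrix_format: str = "matrix-csv") -> Path:
    """Write matrices plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    suffix = {"matrix-csv": ".csv", "edge-list": ".tsv",
              "graphml": ".graphml"}[matrix_format]
    rows = []
    for conn in cohort.connectomes:
        rel = Path("matrices") / f"{conn.subject_id}{suffix}"
        write_weight_matrix(conn, out_dir / rel, matrix_format)
        cov = cohort.covariates.loc[conn.subject_id]
        rows.append({"subject_id": conn.subject_id,
                     "matrix_path": rel.as_posix(), **cov.to_dict()})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(model: "AssociationModel", scan: "EntropyScan | None",
                  metrics_table: pd.DataFrame | None,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write stage outputs: metrics CSV, entropy-scan CSV, and the
    association report (CSV + JSON) in Table-1 column order
    (Standardized β, S.E. (β), t value, Pr (>|t|)) with a p < threshold
    significance flag.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if metrics_table is not None:
        p = out_dir / "metrics.csv"
        metrics_table.to_csv(p, index=False)
        written["metrics"] = p
    if scan is not None:
        p = out_dir / "entropy_scan.csv"
        pd.DataFrame({"k": scan.k_grid, "h_actual": scan.h_actual,
                      "h_null": scan.h_null, "delta": scan.delta}
                     ).to_csv(p, index=False)
        written["entropy_scan"] = p
    coef = model.coefficient_table()
    p = out_dir / "association.csv"
    coef.to_csv(p, index=False)
    written["association_csv"] = p
    p = out_dir / "association.json"
    with open(p, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
    written["association_json"] = p
    return written
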