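"""Reading and writing the tabular and graph formats the pipeline touches.

OTU tables and sample metadata travel as TSV, networks as edge-list CSV or
GraphML, and run reports as JSON.  All readers validate strictly: duplicate
identifiers, ragged rows, and non-integer counts are rejected with errors
that name the offending item rather than silently coerced.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "OtuTable",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "write_network",
    "read_network",
    "write_report",
]


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates the format contract."""


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU-by-sample count matrix, the pipeline's universal input.

    Rows are OTUs, columns are samples (the common amplicon-table dialect).
    Counts must be non-negative integers; OTU and sample identifiers must be
    unique non-empty strings.
    """

    counts: np.ndarray
    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise FormatError(
                    f"counts must be integers; cell ({self.otu_ids[bad[0]]!r}, "
                    f"{self.sample_ids[bad[1]]!r}) = {counts[bad[0], bad[1]]}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise FormatError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "otu_ids", tuple(str(i) for i in self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(str(i) for i in self.sample_ids))
        for name, ids, n in (
            ("OTU", self.otu_ids, counts.shape[0]),
            ("sample", self.sample_ids, counts.shape[1]),
        ):
            if len(ids) != n:
                raise FormatError(f"{name} ids ({len(ids)}) do not match matrix ({n})")
            dupes = _duplicates(ids)
            if dupes:
                raise FormatError(f"duplicate {name} id: {dupes[0]!r}")
        if counts.size == 0:
            raise FormatError("empty table")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        """Column subset preserving order of `sample_ids`."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample id: {missing[0]!r}")
        idx = [pos[s] for s in sample_ids]
        return OtuTable(self.counts[:, idx], self.otu_ids, tuple(sample_ids))


@dataclass(frozen=True)
class SampleMetadata:
    """Mapping from sample id to treatment-group label."""

    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = dict(self.groups)
        for sid, g in groups.items():
            if not str(g):
                raise FormatError(f"empty group label for sample {sid!r}")
        object.__setattr__(self, "groups", groups)

    def __getitem__(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise KeyError(f"sample {missing[0]!r} missing from metadata")
        return np.asarray([self.groups[s] for s in sample_ids])

    def samples_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.groups.items() if g == group)


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dupes = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    return dupes


# ---------------------------------------------------------------------------
# OTU tables and metadata (TSV)
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, transpose: bool = False) -> OtuTable:
    """Read a tab-separated count table (first column OTU ids, header sample ids).

    A leading ``#`` on the header line (QIIME convention) is tolerated.  With
    ``transpose=True`` the file is interpreted as samples-in-rows and flipped
    into the OTUs-as-rows orientation.
    """
    path = Path(path)
    with path.open() as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise FormatError(f"{path}: empty table")
    header = [c.strip() for c in rows[0]]
    if header[0].startswith("#"):
        header[0] = header[0].lstrip("#").strip()
    sample_ids = header[1:]
    width = len(rows[0])
    otu_ids: list[str] = []
    data: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(f"{path}:{lineno}: ragged row ({len(row)} != {width} fields)")
        otu_ids.append(row[0].strip())
        values = []
        for sid, cell in zip(sample_ids, row[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric count {cell!r}") from exc
            if v != int(v):
                raise FormatError(
                    f"{path}:{lineno}: counts must be integers, got {cell!r} "
                    f"(OTU {row[0].strip()!r}, sample {sid!r})"
                )
            values.append(int(v))
        data.append(values)
    table = OtuTable(np.asarray(data, dtype=np.int64), tuple(otu_ids), tuple(sample_ids))
    if transpose:
        table = OtuTable(table.counts.T, table.sample_ids, table.otu_ids)
    return table


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a count table as TSV, OTUs as rows."""
    df = table.to_dataframe()
    df.index.name = "OTU_ID"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column TSV mapping sample id to group label (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: metadata needs sample-id and group columns")
    sids = df.iloc[:, 0].tolist()
    dupes = _duplicates(sids)
    if dupes:
        raise FormatError(f"{path}: duplicate sample id {dupes[0]!r}")
    return SampleMetadata(dict(zip(sids, df.iloc[:, 1].tolist())))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(metadata.groups), "group": list(metadata.groups.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks (edge-list CSV, GraphML)
# ---------------------------------------------------------------------------

_RHO_DECIMALS = 6


def write_network(network, path: str | Path, format: str = "edgelist",
                  modules: Mapping[str, int] | None = None) -> None:
    """Serialize a co-occurrence network.

    ``format="edgelist"`` writes a CSV with columns source, target, rho, sign;
    ``format="graphml"`` writes GraphML with the same edge attributes plus
    per-node degree (and module id when `modules` is given).  Correlations are
    written at 6 decimal places.
    """
    graph = network.graph if hasattr(network, "graph") else network
    path = Path(path)
    if format == "edgelist":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "rho", "sign"])
            for u, v, attrs in graph.edges(data=True):
                w.writerow([u, v, f"{attrs['rho']:.{_RHO_DECIMALS}f}", attrs["sign"]])
    elif format == "graphml":
        g = nx.Graph()
        for node in graph.nodes:
            attrs = {"degree": graph.degree(node)}
            if modules is not None and node in modules:
                attrs["module"] = int(modules[node])
            g.add_node(node, **attrs)
        for u, v, attrs in graph.edges(data=True):
            g.add_edge(u, v, rho=round(float(attrs["rho"]), _RHO_DECIMALS),
                       sign=attrs["sign"])
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network` back into a graph."""
    if format == "graphml":
        return nx.read_graphml(Path(path))
    if format == "edgelist":
        g = nx.Graph()
        with Path(path).open() as fh:
            for row in csv.DictReader(fh):
                g.add_edge(row["source"], row["target"],
                           rho=float(row["rho"]), sign=row["sign"])
        return g
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Reports (JSON)
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, numbers.Number)) or obj is None:
        return obj
    return str(obj)


def write_report(results, path: str | Path) -> None:
    """Write a machine-readable JSON report of any pipeline result object.

    Dataclass results (topology, ANOSIM, PCoA, node roles ...) serialize with
    all their parameters, seeds, and metric values; NaN metrics become null.
    """
    payload = _jsonable(results)
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
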