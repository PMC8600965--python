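"""File I/O: delimited time-series matrices, spike tables, graph exports.

Formats are plain text: CSV/TSV matrices (rows = time, columns =
channels, optional header of channel names), two-column spike tables
(unit id, spike time in seconds), TSV edge lists and JSON graph files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import DIGraph, EdgeRecord
from .timeseries import TimeSeriesSet

__all__ = ["read_timeseries", "read_spikes", "write_graph", "read_graph",
           "RunConfig"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_timeseries(path, fmt: str | None = None) -> TimeSeriesSet:
    """Read a delimited matrix into a :class:`TimeSeriesSet`.

    Binary vs continuous is auto-detected (all values in {0, 1} means
    binary); channel names come from the header row when present,
    otherwise channels are auto-numbered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if fmt == "tsv" else ("," if fmt == "csv" else _sep_for(path))
    try:
        head = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    has_header = pd.to_numeric(head.iloc[0], errors="coerce").isna().any()
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    if values.size == 0:
        raise ValueError(f"{path}: no data rows")
    names = [str(c) for c in df.columns] if has_header else None
    kind = "binary" if np.isin(values, (0.0, 1.0)).all() else "continuous"
    return TimeSeriesSet(values, channel_names=names or [],
                         kind=kind)


def read_spikes(path) -> pd.DataFrame:
    """Read a two-column (unit, time-seconds) spike table; header optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    first = df.iloc[0]
    if pd.isna(pd.to_numeric(first.iloc[1], errors="coerce")):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: spike table needs two columns (unit, time)")
    out = pd.DataFrame({"unit": df.iloc[:, 0],
                        "time": pd.to_numeric(df.iloc[:, 1])})
    return out


_NA = "NA"


def write_graph(graph: DIGraph, tsv_path=None, json_path=None) -> None:
    """Write a graph as a TSV edge list and/or a JSON document.

    The sign of an undetermined edge is serialized as "NA"; a TSV/JSON
    round trip reproduces the graph exactly.
    """
    if tsv_path is not None:
        df = graph.to_dataframe()
        df["sign"] = df["sign"].map(lambda s: _NA if pd.isna(s) else int(s))
        df.to_csv(tsv_path, sep="\t", index=False, na_rep=_NA,
                  float_format="%.10g")
    if json_path is not None:
        doc = {
            "nodes": graph.nodes,
            "edges": [
                {"source": j, "target": k, **{f: getattr(rec, f) for f in (
                    "raw_di", "raw_gdi", "normalized", "sign", "weight",
                    "tau_star")}, "conditioning": list(rec.conditioning)}
                for (j, k), rec in sorted(graph.edges.items())
            ],
            "config": graph.config,
        }
        Path(json_path).write_text(json.dumps(doc, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not serializable: {type(o)}")


def read_graph(json_path) -> DIGraph:
    """Rebuild a :class:`DIGraph` from its JSON export."""
    doc = json.loads(Path(json_path).read_text())
    edges = {}
    for e in doc["edges"]:
        rec = EdgeRecord(raw_di=e["raw_di"], raw_gdi=e["raw_gdi"],
                         normalized=e["normalized"], sign=e["sign"] or 0,
                         weight=e["weight"], tau_star=e["tau_star"],
                         conditioning=tuple(e.get("conditioning", ())))
        edges[(e["source"], e["target"])] = rec
    return DIGraph(nodes=list(doc["nodes"]), edges=edges,
                   config=doc.get("config", {}))


@dataclass
class RunConfig:
    """Resolved settings of one end-to-end pipeline run."""

    input_path: str
    input_format: str = "auto"        # auto | csv | tsv | spikes
    mode: str = "graphical"
    M: int = 3
    bootstrap_iters: int = 10
    di_threshold: float = 0.01
    bin_widths: list = field(default_factory=list)
    seed: int = 0
    output_tsv: str | None = None
    output_json: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
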