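"""Tabular result output with provenance metadata.

CSV files carry '#'-prefixed comment header lines (package version and
configuration hash); JSON output wraps the same metadata and records in
one object.  Floats are written at 12 significant digits, enough to
round-trip solver-tolerance-level differences.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__

__all__ = ["write_results", "read_results"]


def _normalize(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(list(records))


def write_results(records, path: str | Path, fmt: str = "csv",
                  metadata: Mapping[str, Any] | None = None) -> None:
    """Write records (DataFrame or iterable of mappings) to csv or json."""
    df = _normalize(records)
    path = Path(path)
    meta = {"package": "fragcycles", "version": __version__}
    if metadata:
        meta.update(metadata)
    if fmt == "csv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, index=False, float_format="%.12g")
    elif fmt == "json":
        payload = {"metadata": meta,
                   "records": json.loads(df.to_json(orient="records"))}
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["records"])
    return pd.read_csv(path, comment="#")
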