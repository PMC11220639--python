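"""TSV readers/writers, flat config files and run manifests.

Every table the pipeline touches is UTF-8 TSV with a header row, '.' decimal
separator and a fixed column order, so outputs are diff-able and
language-neutral.  Floats are written with 17 significant digits, which
makes write-then-read the identity on values; angles are serialized with 3
decimals and efficiencies with 4 in the human-facing summary tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import FluorescenceTrace

__all__ = [
    "ParseError",
    "SchemaError",
    "read_table",
    "write_table",
    "read_trace",
    "write_trace",
    "read_traces",
    "write_traces",
    "read_flat_config",
    "write_flat_config",
    "RunManifest",
]

FLOAT_FMT = "%.17g"

TRACE_SCHEMA = {"frame": int, "donor": float, "acceptor": float}
MANIFEST_SCHEMA = {"trace_id": str, "file": str, "true_pattern": str}


class ParseError(ValueError):
    """A cell could not be parsed; carries file and line context."""


class SchemaError(ValueError):
    """A table is missing or mistyping declared columns."""


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a TSV with a declared schema, naming file/line/column on failure.

    An empty file (or header-only file) yields an empty frame with the
    schema's columns, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in schema.items()})
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )
    out = {}
    for col, typ in schema.items():
        if typ is str:
            out[col] = df[col]
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}, line {row + 2}, column {col!r}: "
                f"cannot parse {df[col].iloc[row]!r} as {typ.__name__}"
            )
        # convert from the strings with numpy's correctly-rounded parser
        # (pandas' fast parser can be off by one ulp, breaking round trips)
        strings = df[col].replace("", "nan").to_numpy()
        values = np.asarray(strings, dtype=float)
        if typ is int and not np.isnan(values).any():
            out[col] = values.astype(int)
        else:
            out[col] = values
    return pd.DataFrame(out)


def write_table(path: str | Path, df: pd.DataFrame, columns: Sequence[str] | None = None) -> None:
    """Write a TSV with full-precision floats and a fixed column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"cannot write {path}: missing column(s) {missing}")
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_trace(path: str | Path, trace: FluorescenceTrace) -> None:
    df = pd.DataFrame(
        {"frame": trace.frames, "donor": trace.donor, "acceptor": trace.acceptor}
    )
    write_table(path, df)


def read_trace(path: str | Path, trace_id: str | None = None) -> FluorescenceTrace:
    df = read_table(path, TRACE_SCHEMA)
    if len(df) and not np.array_equal(df["frame"].to_numpy(), np.arange(len(df))):
        raise SchemaError(f"{path}: frames must be contiguous from 0")
    return FluorescenceTrace(
        donor=df["donor"].to_numpy(dtype=float),
        acceptor=df["acceptor"].to_numpy(dtype=float),
        trace_id=trace_id or Path(path).stem,
    )


def write_traces(
    directory: str | Path, traces: Sequence[FluorescenceTrace]
) -> Path:
    """Write one TSV per trace plus an ensemble manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in traces:
        fname = f"{tr.trace_id}.tsv"
        write_trace(directory / fname, tr)
        rows.append(
            {
                "trace_id": tr.trace_id,
                "file": fname,
                "true_pattern": tr.metadata.get("pattern", ""),
            }
        )
    manifest = directory / "manifest.tsv"
    write_table(manifest, pd.DataFrame(rows))
    return manifest


def read_traces(manifest_path: str | Path) -> list[FluorescenceTrace]:
    manifest_path = Path(manifest_path)
    manifest = read_table(manifest_path, MANIFEST_SCHEMA)
    traces = []
    for _, row in manifest.iterrows():
        tr = read_trace(manifest_path.parent / row["file"], row["trace_id"])
        if row["true_pattern"]:
            tr.metadata["pattern"] = row["true_pattern"]
        traces.append(tr)
    return traces


def read_flat_config(path: str | Path, allowed: set[str] | None = None) -> dict:
    """Parse a flat key = value config file (str values; '#' comments).

    Unknown keys are rejected when ``allowed`` is given (strict parsing).
    """
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}, line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ParseError(f"{path}, line {lineno}: empty key")
        if key in out:
            raise ParseError(f"{path}, line {lineno}: duplicate key {key!r}")
        out[key] = value
    if allowed is not None:
        unknown = sorted(set(out) - allowed)
        if unknown:
            raise SchemaError(
                f"{path}: unknown config key(s): {', '.join(unknown)}"
            )
    return out


def write_flat_config(path: str | Path, config: Mapping[str, object]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k} = {config[k]}" for k in sorted(config)]
    path.write_text("\n".join(lines) + "\n")


class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    def __init__(self, version: str, config: Mapping[str, object], inputs: Sequence[Path] = ()):
        self.version = version
        self.config_hash = hashlib.sha256(
            json.dumps({k: str(v) for k, v in sorted(config.items())}).encode()
        ).hexdigest()
        self.input_checksums = {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in inputs
        }
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "input_checksums": self.input_checksums,
                    "timestamp": self.timestamp,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
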