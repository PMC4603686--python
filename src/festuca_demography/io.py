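"""Plain-text round-tripping for parameters, matrices and results.

Vital-rate sets travel as flat key-value configs (JSON or YAML by file
extension, keys exactly the vital-rate names); matrices as whitespace-
delimited text with '.' decimals.  Every result file written by the
pipeline carries a machine-readable provenance header in '#'-prefixed
lines (parameters, seed, package version) so any output can be
regenerated from the file alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .matrix import StageMatrix
from .vitalrates import VitalRates, VitalRateUncertainty


def read_vital_rates(path: "str | Path") -> VitalRates:
    """Read a vital-rate config; format chosen by extension
    (.json vs .yaml/.yml)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError("vital-rate config must be a flat mapping")
    sems = data.pop("sem", None)
    rates = VitalRates.from_dict(data)
    if sems is not None:
        return rates, VitalRateUncertainty.from_dict(sems)
    return rates


def write_vital_rates(
    v: VitalRates,
    path: "str | Path",
    sems: "VitalRateUncertainty | None" = None,
) -> None:
    path = Path(path)
    data: dict = v.to_dict()
    if sems is not None:
        data["sem"] = sems.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r}")


def read_matrix(path: "str | Path") -> StageMatrix:
    """Read a 4x4 projection matrix from whitespace-delimited text."""
    A = np.loadtxt(path, comments="#")
    return StageMatrix(A)


def write_matrix(
    M: "StageMatrix | np.ndarray",
    path: "str | Path",
    header: "dict | None" = None,
) -> None:
    A = M.A if isinstance(M, StageMatrix) else np.asarray(M, dtype=float)
    lines = provenance_header(header or {})
    body = "\n".join(
        " ".join(format(x, ".12g") for x in row) for row in A
    )
    Path(path).write_text(lines + body + "\n")


def provenance_header(params: dict) -> str:
    """'#'-prefixed provenance block recording package version and the
    run parameters (seed included by the callers)."""
    record = {"package": "festuca-demography", "version": __version__}
    record.update(params)
    return "".join(f"# {k}: {v}\n" for k, v in record.items())


def write_table(df, path: "str | Path", header: "dict | None" = None) -> None:
    """Write a DataFrame as TSV under a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(header or {}))
        df.to_csv(fh, sep="\t", index=False)
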