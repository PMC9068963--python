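"""Panel table I/O and schema validation.

Panels travel as delimited text (comma-separated, one row per city-year,
``#``-prefixed header comments allowed).  Reading validates the schema and
produces informative, column-named errors; writing can stamp a manifest
hash into a header comment so every output is traceable to its run.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .errors import BalanceError, SchemaError

__all__ = ["REQUIRED_COLUMNS", "read_panel", "write_table", "load_config"]

REQUIRED_COLUMNS = {
    "city_id": str,
    "year": int,
    "u": float,
    "v": float,
    "population": float,
}

INDICATOR_COLUMNS = ("institutions", "beds", "doctors", "health_expenditure")
COVARIATE_COLUMNS = ("Pgdp", "Pfin", "Dens", "Urba", "Disp", "Inru")


def read_panel(
    path,
    require_indicators: bool = True,
    require_covariates: bool = True,
    require_balanced: bool = False,
) -> pd.DataFrame:
    """Read and validate a city-year panel from delimited text."""
    panel = pd.read_csv(path, comment="#")
    required = list(REQUIRED_COLUMNS)
    if require_indicators:
        required += list(INDICATOR_COLUMNS)
    if require_covariates:
        required += list(COVARIATE_COLUMNS)
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")

    dup = panel.duplicated(subset=["city_id", "year"])
    if dup.any():
        rows = panel.loc[dup, ["city_id", "year"]].head(5).to_records(index=False)
        raise SchemaError(f"duplicate (city_id, year) pairs, e.g. {list(rows)}")

    for col in ("year",):
        if not np.issubdtype(panel[col].dtype, np.integer):
            try:
                panel[col] = panel[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"column 'year' is not integer-valued") from exc
    numeric = ["u", "v", "population"]
    if require_indicators:
        numeric += list(INDICATOR_COLUMNS)
    if require_covariates:
        numeric += list(COVARIATE_COLUMNS)
    for col in numeric:
        vals = pd.to_numeric(panel[col], errors="coerce")
        bad = vals.isna() & panel[col].notna()
        if bad.any() or panel[col].isna().any():
            raise SchemaError(f"column {col!r} has missing or non-numeric entries")
        panel[col] = vals.astype(float)

    if (panel["population"] <= 0).any():
        rows = panel.index[panel["population"] <= 0][:5].tolist()
        raise SchemaError(f"non-positive population at rows {rows}")
    if require_indicators and (panel[list(INDICATOR_COLUMNS)] < 0).any().any():
        raise SchemaError("indicator columns must be nonnegative")

    if require_balanced:
        check_balanced(panel)
    return panel


def check_balanced(panel: pd.DataFrame) -> None:
    """Raise :class:`BalanceError` unless every city has every year."""
    counts = panel.pivot_table(index="city_id", columns="year", values="u", aggfunc="size")
    if counts.isna().any().any():
        missing = counts.isna().stack()
        bad = list(missing[missing].index[:5])
        raise BalanceError(f"panel is unbalanced; missing city-years include {bad}")


def write_table(df: pd.DataFrame, path, manifest_hash: str | None = None) -> None:
    """Write a DataFrame as CSV, stamping the run-manifest hash as a comment."""
    with open(path, "w") as fh:
        if manifest_hash is not None:
            fh.write(f"# manifest={manifest_hash}\n")
        df.to_csv(fh, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping (for output provenance stamps)."""
    import hashlib

    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
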