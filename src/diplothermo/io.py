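"""Table writers, run manifests and basic heatmap export.

All tabular output is tab-delimited UTF-8 with '.' decimals and a stable
column order; a JSON manifest records the config hash, package and library
versions and any run-summary counts so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .config import RunConfig, config_to_dict

__all__ = ["config_hash", "write_results", "export_heatmap"]


def config_hash(cfg: RunConfig | Mapping) -> str:
    """sha256 of the canonical JSON form of a config."""
    d = config_to_dict(cfg) if isinstance(cfg, RunConfig) else dict(cfg)
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    destination: str | Path,
    *,
    config: RunConfig | Mapping | None = None,
    summary: Mapping | None = None,
) -> dict:
    """Write each table as ``<name>.tsv`` plus a ``manifest.json``.

    Returns the manifest dict.  Empty tables are written header-only and
    noted in the manifest.
    """
    import numpy
    import scipy

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    table_info = {}
    for name, df in tables.items():
        path = dest / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        table_info[name] = {
            "file": path.name,
            "n_rows": int(len(df)),
            "columns": list(df.columns),
        }
        if len(df) == 0:
            table_info[name]["note"] = "empty table: header only"
    manifest = {
        "diplothermo_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config_hash": config_hash(config) if config is not None else None,
        "config": (
            config_to_dict(config)
            if isinstance(config, RunConfig)
            else (dict(config) if config is not None else None)
        ),
        "summary": dict(summary) if summary else {},
        "tables": table_info,
    }
    (dest / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def export_heatmap(
    table: pd.DataFrame,
    value_column: str,
    path: str | Path,
    *,
    index: str = "ddG_A",
    columns: str = "ddG_B",
    cmap: str = "RdBu_r",
) -> Path:
    """Render a pair-grid column as a PNG heatmap keyed by the two mutant axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index=index, columns=columns, values=value_column)
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = [
        pivot.columns.min(), pivot.columns.max(),
        pivot.index.min(), pivot.index.max(),
    ]
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto", cmap=cmap, extent=extent)
    ax.set_xlabel(columns)
    ax.set_ylabel(index)
    ax.set_title(value_column)
    fig.colorbar(im, ax=ax, label=value_column)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
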