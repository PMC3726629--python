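"""Plain-text readers/writers for pipeline inputs and outputs.

Tables are TSV/CSV with an optional ``# key=value`` comment header carrying
provenance (seed, config hash); JSON outputs embed the same keys under
``_meta``.  Readers skip comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml


def write_table(
    df: pd.DataFrame,
    path,
    sep: str = "\t",
    index: bool = False,
    meta: dict | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_expression(expr: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Expression matrix as TSV: transcripts in rows, header = sample ids."""
    write_table(expr, path, sep="\t", index=True, meta=meta)


def read_expression(path) -> pd.DataFrame:
    return read_table(path, sep="\t", index_col=0)


def write_json(obj, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["_meta"] = dict(meta)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_coerce) + "\n")


def _coerce(x):
    try:
        import numpy as np

        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serialisable: {type(x)}")


def write_tissue_sets(tissue_sets: dict[str, set], path, meta: dict | None = None) -> None:
    """Tissue-specific transcript sets as named lists in YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {str(k): sorted(str(x) for x in v) for k, v in tissue_sets.items()}
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        yaml.safe_dump(doc, fh, default_flow_style=False)


def read_tissue_sets(path) -> dict[str, set]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {k: set(v) for k, v in (doc or {}).items()}
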