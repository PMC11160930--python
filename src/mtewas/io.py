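"""TSV interchange formats.

All tables move between pipeline stages as plain tab-separated text with a
small block of ``# key=value`` header comments carrying provenance (seed,
config hash, stage).  Floats are written with a fixed repr so that reruns of
the same configuration produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_tsv_meta(path) -> dict:
    """Parse the ``# key=value`` header comments of a TSV written here."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_beta_matrix(values: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CpG x sample methylation matrix; first column cpg_id."""
    out = values.copy()
    out.index.name = "cpg_id"
    write_tsv(out, path, meta=meta, index=True)


def read_beta_matrix(path) -> pd.DataFrame:
    return read_tsv(path, index_col="cpg_id")
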