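"""TSV table I/O with a versioned comment header.

Every table the pipeline writes starts with ``# befpipe-table v1`` plus
optional ``# key=value`` provenance lines (seeds, config hash).  Readers
skip comment lines, so the files stay plain TSV for any downstream tool.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

TABLE_FORMAT = "befpipe-table v1"


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {TABLE_FORMAT}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_meta(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta
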