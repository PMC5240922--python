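"""Plain-text artifact I/O with provenance headers.

Every stage output is TSV or JSON carrying the full serialized run
configuration (plus its hash and the seed), so any artifact can be
reproduced from its own header. Headers contain no timestamps: reruns
with identical config and seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InputError


def provenance_lines(config_items: dict, config_hash: str, version: str) -> list[str]:
    lines = [f"allonet {version}", f"config_hash {config_hash}"]
    lines += [f"{k} {v}" for k, v in sorted(config_items.items())]
    return lines


def write_tsv(path: str | Path, df: pd.DataFrame, header_lines: list[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"required artifact missing: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(path: str | Path, obj: dict, header_lines: list[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_provenance": header_lines, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"required artifact missing: {path}")
    with open(path) as fh:
        return json.load(fh)
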