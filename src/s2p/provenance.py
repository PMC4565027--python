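"""Versioned provenance headers for TSV outputs.

Every table the toolkit writes carries two comment lines: the package
version and the JSON-serialized parameters that produced it, so results
remain traceable to their configuration.
"""

from __future__ import annotations

import json
from typing import Dict, Optional, Tuple

import pandas as pd


def _version() -> str:
    from . import __version__

    return __version__


def write_table(df: pd.DataFrame, path: str, params: Optional[Dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# s2p {_version()}\n")
        fh.write(f"# params: {json.dumps(params or {}, sort_keys=True, default=str)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> Tuple[pd.DataFrame, Dict]:
    params: Dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# params:"):
                params = json.loads(line[len("# params:"):].strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, params
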