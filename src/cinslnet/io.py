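"""TSV input/output with provenance headers.

Every table written by the pipeline carries '#'-prefixed header lines
recording the tool version, a hash of the active configuration, and the
random seed, so that any output file can be traced back to the exact run
that produced it. Readers skip these lines transparently.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__


def config_hash(items: Mapping[str, object]) -> str:
    """Stable short hash of a flat key-value configuration mapping."""
    canonical = "\n".join(f"{k}={items[k]!r}" for k in sorted(items))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, object] | None = None) -> None:
    """Write *df* as TSV with a provenance comment header."""
    path = Path(path)
    lines = [f"# cinslnet {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (or any plain TSV)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
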