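"""Report emission: TSV tables, markdown summaries, and run provenance.

Every workflow writes its tables as plain TSV, a human-readable markdown
summary, and a ``run_manifest.json`` embedding the fully resolved
configuration plus content hashes of all inputs, so reruns on identical
inputs reproduce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Mapping, Sequence

__all__ = ["sha256_file", "write_tsv", "write_manifest"]


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(path: str, header: Sequence[str], rows: Sequence[Sequence[object]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_manifest(
    out_dir: str, config: Mapping[str, object], inputs: Mapping[str, str]
) -> str:
    """Write run provenance: resolved config and sha256 of each input file."""
    manifest = {
        "config": dict(config),
        "inputs": {name: sha256_file(path) for name, path in sorted(inputs.items())},
    }
    path = os.path.join(out_dir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj: object):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"Object of type {type(obj).__name__} is not JSON serializable")
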