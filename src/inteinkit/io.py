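"""Table/FASTA/config readers and JSON report writing.

Thin wrappers over pandas, Biopython and PyYAML that add schema validation
with named diagnostics, plus a schema-versioned JSON report carrying enough
provenance (inputs, config hash, seed, package version) to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .exceptions import ConfigurationError

__all__ = ["read_table", "write_table", "read_fasta", "read_config",
           "write_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1.0"

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def read_table(path, required_columns=(), sep=None) -> pd.DataFrame:
    """Read a delimited table, auto-detecting comma vs tab.

    ``required_columns`` are checked and reported by name when missing.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s): {', '.join(missing)}; "
            f"found: {', '.join(frame.columns)}")
    return frame


def write_table(frame: pd.DataFrame, path, sep=",") -> None:
    frame.to_csv(path, sep=sep, index=False)


def read_fasta(path):
    """Parse FASTA records, uppercase, validated against the 20 amino acids.

    Returns a list of ``(id, sequence)`` preserving file order.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = [(i, c) for i, c in enumerate(seq) if c not in _AA]
        if bad:
            i, c = bad[0]
            raise ConfigurationError(
                f"{path}: record {rec.id!r} has illegal residue {c!r} at "
                f"position {i + 1}")
        records.append((rec.id, seq))
    if not records:
        raise ConfigurationError(f"{path}: no FASTA records found")
    return records


def read_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results: dict, path=None, inputs=None, config=None,
                 seed=None) -> dict:
    """Assemble (and optionally write) a schema-versioned JSON report.

    The report is reproducible from (inputs, config, seed); all three are
    recorded, the config by content hash.  Keys are written sorted so
    byte-identical runs give byte-identical reports.
    """
    from . import __version__

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "provenance": {
            "inputs": [str(p) for p in (inputs or [])],
            "config_hash": _config_hash(config or {}),
            "seed": seed,
        },
        "results": results,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    return report
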