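"""Readers and writers shared by the command-line entry points.

Trait tables are TSV with a header line, either

    species<TAB>n0<TAB>n1      (observed state counts), or
    species<TAB>state          (one individual per species, state in {0,1})

Results are written as schema-stable JSON (G-XRF) or TSV (tables), with the
seed and parameters echoed so any run can be reproduced from its output.
"""

from __future__ import annotations

import json
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .likelihood import TraitCounts

__all__ = ["read_trait_table", "write_result_json", "write_table_tsv"]


def _version() -> str:
    try:
        return _pkg_version("xenorisk")
    except Exception:  # pragma: no cover
        return "unknown"


def read_trait_table(path) -> TraitCounts:
    """Read a trait TSV (see module docstring) into :class:`TraitCounts`."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.strip().lower() for c in df.columns]
    if len(cols) >= 3 and cols[:3] == ["species", "n0", "n1"]:
        pairs = zip(df.iloc[:, 1].astype(int), df.iloc[:, 2].astype(int))
    elif len(cols) >= 2 and cols[:2] == ["species", "state"]:
        states = df.iloc[:, 1].astype(int)
        if not states.isin([0, 1]).all():
            raise ValueError("state column must contain only 0/1")
        pairs = ((1 - s, s) for s in states)
    else:
        raise ValueError(
            f"expected header 'species\\tn0\\tn1' or 'species\\tstate', "
            f"got {list(df.columns)}")
    species = df.iloc[:, 0].str.strip()
    if species.duplicated().any():
        raise ValueError("duplicate species in trait table")
    counts = {}
    for sp, (n0, n1) in zip(species, pairs):
        if n0 < 0 or n1 < 0:
            raise ValueError(f"negative counts for species {sp!r}")
        if n0 + n1 == 0:
            raise ValueError(f"species {sp!r} has no sampled individuals")
        counts[sp] = (int(n0), int(n1))
    return TraitCounts(counts)


def write_result_json(result, path, seed: Optional[int] = None,
                      params: Optional[dict] = None) -> dict:
    """Write a G-XRF result (or any mapping) as JSON with provenance echo."""
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
    elif isinstance(result, dict):
        payload = dict(result)
    else:
        raise TypeError(f"cannot serialize {type(result)!r}")
    payload["seed"] = seed
    payload["xenorisk_version"] = _version()
    if params:
        payload["params"] = dict(params)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def write_table_tsv(df: pd.DataFrame, path, seed: Optional[int] = None,
                    params: Optional[dict] = None) -> None:
    """Write a result table as TSV, with seed/params echoed in '#' comments."""
    with open(path, "w") as fh:
        fh.write(f"# xenorisk {_version()}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if params:
            for k, v in params.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
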