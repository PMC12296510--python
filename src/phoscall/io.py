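"""Reading and writing the plain-text formats the pipeline touches.

Phosphosite tables travel as TSV in either a wide dialect (one intensity
column per sample) or a long dialect (one ``sample``/``intensity`` row per
measurement). Missing values are the empty string or "NA" on read and are
always written as the empty string. Every result written through
:func:`write_results` gets a JSON sidecar recording the run metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .tables import SITE_COLUMNS, PhosphoSiteTable, design_from_sample_names

log = logging.getLogger(__name__)

_META_COLS = ["accession", "position", "residue", "localization_prob"]
_NA_VALUES = ["", "NA"]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


def _finish_table(sites: pd.DataFrame, values: pd.DataFrame,
                  design: pd.DataFrame | None) -> PhosphoSiteTable:
    if "multiplicity" not in sites.columns:
        sites = sites.assign(multiplicity=1)
    sites = sites[SITE_COLUMNS].reset_index(drop=True)
    sites["position"] = sites["position"].astype(int)
    sites["multiplicity"] = sites["multiplicity"].astype(int)
    values = values.reset_index(drop=True).astype(float)
    if design is None:
        design = design_from_sample_names(values.columns)
    return PhosphoSiteTable(sites=sites, values=values, design=design)


def read_phospho_table(path: str | Path, format_dialect: str = "wide",
                       design: pd.DataFrame | None = None) -> PhosphoSiteTable:
    """Read a phosphosite TSV in the ``wide`` or ``long`` dialect.

    Without an explicit ``design``, sample-to-condition mapping is inferred
    from the ``condition_replicate`` column-name convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)

    if format_dialect == "wide":
        required = _META_COLS
    elif format_dialect == "long":
        required = _META_COLS + ["sample", "intensity"]
    else:
        raise ValueError(f"unknown dialect {format_dialect!r}; use 'wide' or 'long'")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    if format_dialect == "wide":
        sample_cols = [c for c in df.columns if c not in _META_COLS + ["multiplicity"]]
        if not sample_cols:
            raise FormatError(f"{path}: no intensity columns found")
        for col in sample_cols:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise FormatError(
                    f"{path}: non-numeric intensity in column {col!r} at row "
                    f"{int(np.flatnonzero(bad)[0])}"
                )
        sites = df[[c for c in SITE_COLUMNS if c in df.columns]]
        values = df[sample_cols].apply(pd.to_numeric)
        return _finish_table(sites, values, design)

    # long dialect: pivot to wide, preserving first-appearance order
    bad = pd.to_numeric(df["intensity"], errors="coerce").isna() & df["intensity"].notna()
    if bad.any():
        raise FormatError(
            f"{path}: non-numeric intensity at row {int(np.flatnonzero(bad)[0])}"
        )
    key_cols = [c for c in SITE_COLUMNS if c in df.columns]
    site_order = df[key_cols].drop_duplicates()
    sample_order = list(dict.fromkeys(df["sample"]))
    pivot = df.pivot_table(
        index=key_cols, columns="sample", values="intensity", aggfunc="first"
    )
    # detect duplicated measurements (same site, same sample, >1 row)
    n_cells = df.groupby(key_cols + ["sample"]).size()
    if (n_cells > 1).any():
        raise FormatError(f"{path}: duplicated (site, sample) measurement rows")
    pivot = pivot.reindex(pd.MultiIndex.from_frame(site_order))[sample_order]
    sites = site_order.reset_index(drop=True)
    values = pivot.reset_index(drop=True)
    values.columns.name = None
    return _finish_table(sites, values, design)


def write_phospho_table(table: PhosphoSiteTable, path: str | Path) -> None:
    """Write a table in the wide TSV dialect (missing cells as empty string)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.concat([table.sites, table.values], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession -> uppercase sequence mapping.

    The accession is the first whitespace-delimited token of the header.
    Non-standard letters are preserved but reported in the log.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: dict[str, str] = {}
    for rec in records:
        acc = rec.id.split()[0]
        if acc in out:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seq = str(rec.seq).upper()
        odd = sorted(set(seq) - set(STANDARD_AA))
        if odd:
            log.warning("%s: non-standard letters %s in %s", path, odd, acc)
        out[acc] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_disorder_tracks(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-residue disorder scores from a long-format TSV.

    Columns: ``accession``, ``position`` (1-based), ``score`` in [0,1].
    Positions must form a contiguous 1..L run per accession.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("accession", "position", "score") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    tracks: dict[str, np.ndarray] = {}
    for acc, grp in df.groupby("accession", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise FormatError(f"{path}: positions for {acc!r} are not contiguous from 1")
        scores = grp["score"].to_numpy(dtype=float)
        if ((scores < 0) | (scores > 1)).any():
            raise FormatError(f"{path}: disorder scores outside [0,1] for {acc!r}")
        tracks[acc] = scores
    return tracks


def write_disorder_tracks(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for acc, scores in tracks.items():
        for i, s in enumerate(scores, start=1):
            rows.append((acc, i, float(s)))
    pd.DataFrame(rows, columns=["accession", "position", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


# -- results and metadata -------------------------------------------------


def _config_hash(params: Mapping[str, Any]) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(table: pd.DataFrame, path: str | Path, fmt: str = "tsv", *,
                  seed: int | None = None,
                  params: Mapping[str, Any] | None = None) -> None:
    """Write a results table as TSV or JSON plus a run-metadata sidecar.

    Column order is preserved deterministically; missing values become the
    empty string in TSV and ``null`` in JSON. The sidecar ``<path>.meta.json``
    records seed, parameters and a config hash for reproducibility.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False, na_rep="")
    elif fmt == "json":
        records = json.loads(table.to_json(orient="records"))
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown results format {fmt!r}")
    params = dict(params or {})
    meta = {
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "rows": int(len(table)),
        "columns": list(map(str, table.columns)),
        "seed": seed,
        "params": params,
        "config_hash": _config_hash(params),
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a hierarchical YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    return cfg


def dump_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
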