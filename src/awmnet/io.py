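"""File dialects shared by all pipeline stages.

All tables are plain tab-separated text.  Files written by the package carry
``#``-prefixed header lines naming the package version, a config hash and the
seed used; every reader skips such lines, so all files round-trip.

Dialects
--------
genotypes
    PLINK-RAW-like: columns ``FID IID`` then one column per marker holding
    {0,1,2} minor-allele counts (``NA`` for missing).  A companion map table
    holds ``chrom  marker  bp`` (1-based positions).
evaluations
    long format, one row per bull x trait:
    ``bull  trait  pta  rel  sire_pta  mgs_pta  ayb_pta [pa rel_pa]``;
    de-regression appends ``dpta  w  rel_dpta``.
intervals (genes / QTL)
    BED-like but 1-based **inclusive** on both ends:
    ``chrom  start  end  name``.
pedigree
    ``animal  sire  dam  birth_year [mgs]``; unknown parents are ``0``.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd

from . import __version__

MISSING_PARENT = "0"
NA_VALUES = ["NA", ""]


def _header_lines(seed=None, config_hash=None) -> str:
    parts = [f"# awmnet v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(_header_lines(seed=seed, config_hash=config_hash))
    df.to_csv(buf, sep="\t", index=False, na_rep="NA")
    path.write_text(buf.getvalue())


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=NA_VALUES, keep_default_na=False, **kwargs
    )


# -- genotypes ---------------------------------------------------------------

def write_genotypes(codes_df: pd.DataFrame, path, **hdr) -> None:
    """``codes_df``: index = bull ids, columns = marker ids, values {0,1,2,NaN}."""
    out = codes_df.reset_index(names="IID")
    out.insert(0, "FID", "F0")
    write_table(out, path, **hdr)


def read_genotypes(path) -> pd.DataFrame:
    df = read_table(path, dtype={"FID": str, "IID": str})
    df = df.drop(columns=["FID"]).set_index("IID")
    df.index.name = "bull"
    return df.astype(float)


def write_map(map_df: pd.DataFrame, path, **hdr) -> None:
    write_table(map_df[["chrom", "marker", "bp"]], path, **hdr)


def read_map(path) -> pd.DataFrame:
    return read_table(path, dtype={"chrom": str, "marker": str, "bp": int})


# -- evaluations -------------------------------------------------------------

EVAL_COLUMNS = ["bull", "trait", "pta", "rel", "sire_pta", "mgs_pta", "ayb_pta"]


def write_evaluations(df: pd.DataFrame, path, **hdr) -> None:
    cols = [c for c in EVAL_COLUMNS + ["pa", "rel_pa", "dpta", "w", "rel_dpta"] if c in df]
    write_table(df[cols], path, **hdr)


def read_evaluations(path) -> pd.DataFrame:
    return read_table(path, dtype={"bull": str, "trait": str})


# -- intervals (genes, QTL) --------------------------------------------------

def write_intervals(df: pd.DataFrame, path, **hdr) -> None:
    write_table(df[["chrom", "start", "end", "name"]], path, **hdr)


def read_intervals(path) -> pd.DataFrame:
    return read_table(path, dtype={"chrom": str, "start": int, "end": int, "name": str})


# -- pedigree ----------------------------------------------------------------

def write_pedigree(df: pd.DataFrame, path, **hdr) -> None:
    cols = ["animal", "sire", "dam", "birth_year"] + (["mgs"] if "mgs" in df else [])
    out = df[cols].copy()
    for c in ("sire", "dam", "mgs"):
        if c in out:
            out[c] = out[c].fillna(MISSING_PARENT)
    write_table(out, path, **hdr)


def read_pedigree(path) -> pd.DataFrame:
    df = read_table(path, dtype=str)
    df["birth_year"] = df["birth_year"].astype(int)
    for c in ("sire", "dam", "mgs"):
        if c in df:
            df[c] = df[c].replace(MISSING_PARENT, pd.NA)
    return df
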