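"""Readers and writers for the toolkit's file formats.

Formats: TSV (abundance, metadata, per-KO stats, result tables), GMT
pathway sets, two-column KO->pathway mappings, and JSON (full-precision
result sidecars, run manifests). Result TSVs serialize numbers at 6 decimal
places; an optional JSON sidecar keeps full precision, and readers prefer
the sidecar when it sits next to the TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .diffstats import AbundanceTable, GroupAssignment, KOStat
from .errors import ParseError, ValidationError
from .reporter import PathwaySet

logger = logging.getLogger(__name__)

TSV_FLOAT_FORMAT = "%.6f"


# ---------------------------------------------------------------- abundance

def read_abundance(path: str | Path) -> AbundanceTable:
    """Abundance TSV: first column feature id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"abundance table {path} is empty")
    try:
        return AbundanceTable.from_dataframe(df.astype(float))
    except ValueError as exc:
        raise ParseError(f"non-numeric cells in abundance table {path}: {exc}") from exc


def read_metadata(path: str | Path, reference: str) -> GroupAssignment:
    """Metadata TSV with columns `sample` and `group`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ParseError(f"metadata {path} lacks required column {col!r}")
    return GroupAssignment(
        dict(zip(df["sample"], df["group"])), reference=reference
    )


# ------------------------------------------------------------ per-KO stats

def read_ko_stats(path: str | Path) -> list[KOStat]:
    """Per-KO stats TSV: columns `ko`, `p_value` and optional `statistic`, `test`.

    A missing statistic column yields sign-less stats (statistic 0), which
    restricts downstream analysis to the undirected mode.
    """
    df = pd.read_csv(path, sep="\t")
    if "ko" not in df.columns or "p_value" not in df.columns:
        raise ParseError(f"stats table {path} needs columns `ko` and `p_value`")
    has_stat = "statistic" in df.columns
    test = df["test"] if "test" in df.columns else [""] * len(df)
    return [
        KOStat(
            str(row.ko),
            float(row.p_value),
            float(row.statistic) if has_stat else 0.0,
            str(t),
        )
        for row, t in zip(df.itertuples(index=False), test)
    ]


def write_ko_stats(ko_stats: list[KOStat], path: str | Path) -> None:
    from .diffstats import stats_to_frame

    stats_to_frame(ko_stats).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ pathway sets

def read_gmt(path: str | Path) -> PathwaySet:
    """GMT: one pathway per line, `name TAB description TAB member...`.

    Duplicate members within a line are deduplicated with a warning;
    duplicate pathway names are an error; a line with fewer than three
    fields is a parse error naming the line number.
    """
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate member(s) in pathway %s deduplicated",
                    path, lineno, len(members) - len(unique), name,
                )
            pathways[name] = frozenset(unique)
            names[name] = desc
    if not pathways:
        raise ValidationError(f"GMT file {path} contains no pathways")
    return PathwaySet(pathways, names)


def write_gmt(sets: PathwaySet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sets.pathways):
            members = "\t".join(sorted(sets.pathways[pid]))
            fh.write(f"{pid}\t{sets.names[pid]}\t{members}\n")


def read_pairs(path: str | Path) -> PathwaySet:
    """Two-column KO -> pathway TSV; header row `ko	pathway` auto-detected."""
    pathways: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            ko, pw = fields
            if lineno == 1 and (ko.lower(), pw.lower()) == ("ko", "pathway"):
                continue  # header row
            if (ko, pw) in seen:
                logger.warning(
                    "%s:%d: duplicate mapping (%s, %s) deduplicated",
                    path, lineno, ko, pw,
                )
                continue
            seen.add((ko, pw))
            pathways.setdefault(pw, set()).add(ko)
    if not pathways:
        raise ValidationError(f"mapping file {path} contains no KO->pathway pairs")
    return PathwaySet({pw: frozenset(m) for pw, m in pathways.items()})


# ------------------------------------------------------------ result tables

def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_results(df: pd.DataFrame, path: str | Path, sidecar: bool = True) -> None:
    """Result table as TSV (6 decimals) plus full-precision JSON sidecar."""
    df.to_csv(path, sep="\t", index=False, float_format=TSV_FLOAT_FORMAT)
    if sidecar:
        records = df.to_dict(orient="list")
        clean = {
            col: [None if isinstance(v, float) and np.isnan(v) else v for v in vals]
            for col, vals in records.items()
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(clean, fh, indent=1)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table; the full-precision sidecar wins when present."""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- manifest

def write_manifest(path: str | Path, params: dict) -> None:
    """Run manifest: every parameter plus library versions, for reproduction.

    No timestamp: manifests of identical runs are byte-identical.
    """
    from importlib.metadata import version as _dist_version

    import scipy

    from . import __version__

    manifest = {
        "parameters": params,
        "versions": {
            "reporterscore": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "click": _dist_version("click"),
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
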