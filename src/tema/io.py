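"""File-format plumbing: configs, TSV/CSV serialization, and run manifests.

Conventions: peak tables are CSV (fragment-analysis exports are CSV-like);
matrices and summary tables are TSV; everything is UTF-8 with Unix
newlines and mandatory headers.  Fragment sizes serialize as integer bp;
rates as scientific notation with 4 significant digits.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .scoring import PeakCall, PresenceMatrix
from .simulate import LineageRecord, PeakTable, SimulationConfig

__all__ = [
    "load_config",
    "write_lineages_tsv",
    "read_lineage_metadata",
    "write_events_tsv",
    "write_peaks_csv",
    "read_peaks_csv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_calls_csv",
    "read_calls_csv",
    "write_rate_table_tsv",
    "write_expected_losses_tsv",
    "write_manifest",
    "file_digest",
]

RATE_FMT = "{:.4g}"


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML (or JSON-compatible) mapping.

    Every config field is addressable by name; unknown keys are an error
    so that typos never silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    known = set(SimulationConfig.field_names())
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    if "fragment_size_range" in raw:
        raw["fragment_size_range"] = tuple(raw["fragment_size_range"])
    return SimulationConfig(**raw)


def write_lineages_tsv(lines: Iterable[LineageRecord], path: str | Path) -> None:
    rows = [
        {
            "lineage_id": ln.lineage_id,
            "treatment": ln.treatment,
            "generations": ln.generations,
            "selfing_generations": ",".join(str(g) for g in ln.selfing_generations),
        }
        for ln in lines
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_lineage_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"lineage_id": str})
    df["selfing_generations"] = df["selfing_generations"].fillna("").astype(str)
    return df.set_index("lineage_id")


def write_events_tsv(lines: Iterable[LineageRecord], path: str | Path) -> None:
    rows = [
        {
            "lineage_id": ln.lineage_id,
            "generation": ev.generation,
            "locus_id": ev.locus_id,
            "event": ev.event,
        }
        for ln in lines
        for ev in ln.event_log
    ]
    pd.DataFrame(rows, columns=["lineage_id", "generation", "locus_id", "event"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_peaks_csv(tables: Iterable[PeakTable], path: str | Path) -> None:
    rows = [
        {
            "lineage_id": t.lineage_id,
            "replicate": t.replicate,
            "fragment_bp": bp,
            "height": f"{h:.2f}",
        }
        for t in tables
        for bp, h in t.peaks
    ]
    pd.DataFrame(rows, columns=["lineage_id", "replicate", "fragment_bp", "height"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_peaks_csv(path: str | Path) -> list[PeakTable]:
    df = pd.read_csv(path, dtype={"lineage_id": str})
    tables: list[PeakTable] = []
    for (lid, rep), grp in df.groupby(["lineage_id", "replicate"], sort=True):
        peaks = [(int(bp), float(h)) for bp, h in zip(grp["fragment_bp"], grp["height"])]
        tables.append(PeakTable(lineage_id=str(lid), replicate=int(rep), peaks=peaks))
    # Lineages whose every peak fell below threshold upstream still need
    # their three (empty) replicates; absent rows mean absent lineages here.
    return tables


def write_matrix_tsv(matrix: PresenceMatrix, path: str | Path) -> None:
    out = matrix.presence.astype(int).copy()
    out.insert(0, "treatment", matrix.treatments)
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    treatments = df["treatment"]
    presence = df.drop(columns=["treatment"]).astype(bool)
    presence.columns = presence.columns.astype(int)
    presence.columns.name = "fragment_bp"
    return PresenceMatrix(presence=presence, treatments=treatments, new_calls=[])


def write_calls_csv(calls: Iterable[PeakCall], path: str | Path) -> None:
    rows = [
        {
            "lineage_id": c.lineage_id,
            "fragment_bp": c.fragment_bp,
            "category": c.category,
            "replicate_count": c.replicate_count,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["lineage_id", "fragment_bp", "category", "replicate_count"]
    ).to_csv(path, index=False, lineterminator="\n")


def read_calls_csv(path: str | Path) -> list[PeakCall]:
    df = pd.read_csv(path, dtype={"lineage_id": str})
    return [
        PeakCall(str(r.lineage_id), int(r.fragment_bp), str(r.category),
                 int(r.replicate_count))
        for r in df.itertuples(index=False)
    ]


def write_rate_table_tsv(rows: list[dict], path: str | Path) -> None:
    """Write a loss-rate summary table (one row per family)."""
    cols = [
        "family", "n_sexual", "n_asexual", "n_high_loss_loci",
        "rate_sexual", "se_sexual", "rate_asexual", "se_asexual", "t", "p",
    ]
    formatted = []
    for r in rows:
        r = dict(r)
        for k in ("rate_sexual", "se_sexual", "rate_asexual", "se_asexual", "t", "p"):
            r[k] = RATE_FMT.format(r[k])
        formatted.append(r)
    pd.DataFrame(formatted, columns=cols).to_csv(path, sep="\t", index=False,
                                                 lineterminator="\n")


def write_expected_losses_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    seed: int | None,
    config: Mapping | None,
    outputs: Iterable[str | Path],
) -> Path:
    """Record what a stage produced: config snapshot, seed, file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config is not None else None,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": {
            str(Path(p).name): file_digest(p) for p in outputs
        },
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
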