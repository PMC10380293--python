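"""CSV dialects, run manifests and report writers.

Units at file boundaries: µM for concentrations, °C for temperatures,
M for urea, kcal/mol for work and free energies.  Temperatures are
converted to K on ingest.  Delimiter is ``,``, decimal separator ``.``;
no locale handling.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _version
from .chemdenat import DenaturationCurve
from .constants import celsius_to_kelvin
from .errors import InvalidInputError, ParseError, SchemaError
from .fret import CHANNELS, ChannelReading
from .neq import CycleEdge, ThermoCycle, WorkSet
from .thermal import MeltCurve

__all__ = [
    "PLATE_COLUMNS",
    "RunManifest",
    "read_plate_csv",
    "write_plate_csv",
    "read_melt_csv",
    "read_urea_csv",
    "read_work_csv",
    "read_cycle_file",
    "report",
    "write_manifest",
]

PLATE_COLUMNS = [
    "sample_id",
    "well",
    "replicate",
    "donor_conc_uM",
    "acceptor_conc_uM",
    "inhibitor_conc_uM",
    "channel",
    "intensity",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _float_cell(value, column: str, row: int, path) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"{path}: row {row}: non-numeric {column} value {value!r}"
        ) from exc


def read_plate_csv(path) -> list[ChannelReading]:
    """Read the long-format plate dialect into typed records.

    Unknown columns are preserved on each record as string annotations;
    row numbers (1-based, excluding the header) are used in error
    messages.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    _require_columns(df, PLATE_COLUMNS, path)
    extra_cols = [c for c in df.columns if c not in PLATE_COLUMNS]
    readings = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        channel = str(rec["channel"]).strip()
        if channel not in CHANNELS:
            raise ParseError(
                f"{path}: row {i}: channel must be one of {CHANNELS}, "
                f"got {channel!r}"
            )
        try:
            replicate = int(rec["replicate"])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: row {i}: non-integer replicate {rec['replicate']!r}"
            ) from exc
        try:
            readings.append(
                ChannelReading(
                    sample_id=str(rec["sample_id"]),
                    well=str(rec["well"]),
                    replicate=replicate,
                    donor_conc=_float_cell(rec["donor_conc_uM"], "donor_conc_uM", i, path),
                    acceptor_conc=_float_cell(
                        rec["acceptor_conc_uM"], "acceptor_conc_uM", i, path
                    ),
                    inhibitor_conc=_float_cell(
                        rec["inhibitor_conc_uM"], "inhibitor_conc_uM", i, path
                    ),
                    channel=channel,
                    intensity=_float_cell(rec["intensity"], "intensity", i, path),
                    extra={c: rec[c] for c in extra_cols},
                )
            )
        except InvalidInputError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return readings


def write_plate_csv(path, readings: Sequence[ChannelReading], header_comment: str = ""):
    """Write readings in the plate dialect; inverse of `read_plate_csv`."""
    rows = []
    extra_cols: list[str] = []
    for r in readings:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    for r in readings:
        row = {
            "sample_id": r.sample_id,
            "well": r.well,
            "replicate": r.replicate,
            "donor_conc_uM": repr(r.donor_conc),
            "acceptor_conc_uM": repr(r.acceptor_conc),
            "inhibitor_conc_uM": repr(r.inhibitor_conc),
            "channel": r.channel,
            "intensity": repr(r.intensity),
        }
        for c in extra_cols:
            row[c] = r.extra.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS + extra_cols)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_melt_csv(path) -> dict[tuple, MeltCurve]:
    """Read melt curves (`sample_id,replicate,temperature_C,intensity`).

    Temperatures are converted to K; per-curve ordering must be strictly
    increasing.  Returns curves keyed by (sample_id, replicate).
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["sample_id", "replicate", "temperature_C", "intensity"], path)
    curves = {}
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        t_c = grp["temperature_C"].to_numpy(dtype=float)
        if (t_c[1:] <= t_c[:-1]).any():
            raise InvalidInputError(
                f"{path}: temperatures for sample {sid!r} replicate {rep} "
                "must be strictly increasing"
            )
        curves[(str(sid), int(rep))] = MeltCurve(
            sample_id=str(sid),
            replicate=int(rep),
            temperatures=celsius_to_kelvin(t_c),
            intensities=grp["intensity"].to_numpy(dtype=float),
        )
    return curves


def write_melt_csv(path, curves: Sequence[MeltCurve], header_comment: str = ""):
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "replicate": c.replicate,
                    "temperature_C": c.temperatures - 273.15,
                    "intensity": c.intensities,
                }
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.concat(frames).to_csv(fh, index=False)


def read_urea_csv(path) -> dict[tuple, DenaturationCurve]:
    """Read urea curves (`sample_id,replicate,urea_M,intensity`)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["sample_id", "replicate", "urea_M", "intensity"], path)
    curves = {}
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        x = grp["urea_M"].to_numpy(dtype=float)
        if (x[1:] < x[:-1]).any():
            raise InvalidInputError(
                f"{path}: urea concentrations for sample {sid!r} replicate {rep} "
                "must be ascending"
            )
        curves[(str(sid), int(rep))] = DenaturationCurve(
            sample_id=str(sid),
            replicate=int(rep),
            urea_concs=x,
            normalized_fluorescence=grp["intensity"].to_numpy(dtype=float),
        )
    return curves


def write_urea_csv(path, curves: Sequence[DenaturationCurve], header_comment: str = ""):
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "replicate": c.replicate,
                    "urea_M": c.urea_concs,
                    "intensity": c.normalized_fluorescence,
                }
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.concat(frames).to_csv(fh, index=False)


def read_work_csv(path, temperature: float = 300.0, edge_label: Optional[str] = None) -> WorkSet:
    """Read a work table (`direction,work_kcal_mol`) for one edge.

    Files with only forward rows are valid (Jarzynski accepts them);
    two-sided estimators reject the resulting WorkSet themselves.
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["direction", "work_kcal_mol"], path)
    directions = df["direction"].astype(str).str.strip().str.lower()
    bad = sorted(set(directions) - {"forward", "reverse"})
    if bad:
        raise ParseError(f"{path}: unknown direction value(s) {bad}")
    w = df["work_kcal_mol"].to_numpy(dtype=float)
    return WorkSet(
        edge_label=edge_label or str(path),
        forward_work=w[directions == "forward"],
        reverse_work=w[directions == "reverse"],
        temperature=temperature,
    )


def write_work_csv(path, workset: WorkSet, header_comment: str = ""):
    rows = [("forward", w) for w in workset.forward_work]
    rows += [("reverse", w) for w in workset.reverse_work]
    df = pd.DataFrame(rows, columns=["direction", "work_kcal_mol"])
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_cycle_file(path) -> ThermoCycle:
    """Read a cycle description: TSV lines `from,to,ddg,uncertainty`."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",")]
            if len(parts) not in (3, 4):
                raise ParseError(
                    f"{path}: line {i}: expected `from,to,ddg[,uncertainty]`, "
                    f"got {line!r}"
                )
            unc = float(parts[3]) if len(parts) == 4 else 0.0
            edges.append(
                CycleEdge(
                    from_state=parts[0],
                    to_state=parts[1],
                    ddg=float(parts[2]),
                    uncertainty=unc,
                )
            )
    return ThermoCycle(edges=tuple(edges))


def report(results: Sequence[Mapping], path, fmt: str = "tsv") -> None:
    """Write a result table; full precision plus display-rounded columns.

    Rounded columns are presentation only and never feed back into any
    computation.
    """
    df = pd.DataFrame(list(results))
    if fmt == "tsv":
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[f"{col}_display"] = df[col].round(3)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "structured-text":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(list(results), fh, indent=2, default=str)
            fh.write("\n")
    else:
        raise InvalidInputError(f"unknown report format {fmt!r}")


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict
    input_digests: dict
    seed: Optional[int]
    tool_version: str
    timestamp: str


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config: Mapping,
    inputs: Sequence = (),
    seed: Optional[int] = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=dict(config),
        input_digests={str(p): _digest(p) for p in inputs},
        seed=seed,
        tool_version=_version,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")
    return path
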