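"""Readers, writers and run manifests shared by the CLI and the library.

All on-disk formats are plain: CSV for tables, YAML for configuration and
image sidecars, TIFF for images, FASTA for sequences, JSON for manifests.
Error messages from the readers always name the offending file, row and
column and what was expected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import datetime as _dt
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import barrier_assays as ba
from .constants import T_BODY_K
from .errors import ParacellError
from .junction_quant import GenotypeField, MonolayerImage, QuantResult

__all__ = [
    "TOOL_VERSION",
    "builtin_solutions",
    "read_solutions",
    "read_ephys_table",
    "write_ephys_table",
    "write_barrier_results",
    "write_condition_summaries",
    "load_image_with_sidecar",
    "save_image_with_sidecar",
    "load_genotype_labels",
    "read_fasta",
    "write_fasta",
    "read_roi_csv",
    "write_quant_result",
    "write_manifest",
]

TOOL_VERSION = "0.1.0"

_EPHYS_COLUMNS = [
    "condition",
    "day",
    "replicate_id",
    "raw_ohm",
    "blank_ohm",
    "area_cm2",
    "potential_mV",
    "apical_solution",
    "basolateral_solution",
    "temperature_K",
]


def builtin_solutions() -> dict[str, ba.IonicSolution]:
    return {"A": ba.IonicSolution.solution_a(), "B": ba.IonicSolution.solution_b()}


def read_solutions(path: str | Path) -> dict[str, ba.IonicSolution]:
    """Solution recipes from a YAML/JSON mapping name -> ion fields (mM).

    The built-in recipes "A" and "B" are always available and can be
    overridden.
    """
    solutions = builtin_solutions()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParacellError(f"{path}: expected a mapping of solution name -> ion fields")
    for name, fields in data.items():
        try:
            solutions[str(name)] = ba.IonicSolution(
                na_mM=float(fields["na_mM"]),
                k_mM=float(fields.get("k_mM", 0.0)),
                cl_mM=float(fields["cl_mM"]),
                ca_mM=float(fields.get("ca_mM", 0.0)),
                mg_mM=float(fields.get("mg_mM", 0.0)),
                label=str(name),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParacellError(f"{path}: solution {name!r}: {exc}") from exc
    return solutions


def read_ephys_table(
    path: str | Path,
    solutions: Optional[Mapping[str, ba.IonicSolution]] = None,
) -> list[ba.EphysMeasurement]:
    """Typed electrophysiology records from a one-row-per-filter CSV."""
    solutions = dict(solutions or builtin_solutions())
    df = pd.read_csv(path)
    missing = [c for c in _EPHYS_COLUMNS if c not in df.columns and c != "replicate_id"]
    if missing:
        raise ParacellError(f"{path}: missing required column(s) {missing}")
    records: list[ba.EphysMeasurement] = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        for sol_col in ("apical_solution", "basolateral_solution"):
            if str(row[sol_col]) not in solutions:
                raise ParacellError(
                    f"{path}: row {rownum}, column {sol_col!r}: unknown solution "
                    f"{row[sol_col]!r} (known: {sorted(solutions)})"
                )
        try:
            records.append(
                ba.EphysMeasurement(
                    raw_resistance_ohm=float(row["raw_ohm"]),
                    blank_resistance_ohm=float(row["blank_ohm"]),
                    filter_area_cm2=float(row["area_cm2"]),
                    dilution_potential_mV=float(row["potential_mV"]),
                    apical=solutions[str(row["apical_solution"])],
                    basolateral=solutions[str(row["basolateral_solution"])],
                    condition=str(row["condition"]),
                    day=int(row["day"]),
                    replicate_id=str(row.get("replicate_id", i)),
                    temperature_K=float(row.get("temperature_K", T_BODY_K)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParacellError(f"{path}: row {rownum}: {exc}") from exc
    return records


def write_ephys_table(path: str | Path, records: Sequence[ba.EphysMeasurement]) -> None:
    rows = [
        {
            "condition": r.condition,
            "day": r.day,
            "replicate_id": r.replicate_id,
            "raw_ohm": r.raw_resistance_ohm,
            "blank_ohm": r.blank_resistance_ohm,
            "area_cm2": r.filter_area_cm2,
            "potential_mV": r.dilution_potential_mV,
            "apical_solution": r.apical.label,
            "basolateral_solution": r.basolateral.label,
            "temperature_K": r.temperature_K,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_EPHYS_COLUMNS).to_csv(path, index=False)


def write_barrier_results(path: str | Path, results: Sequence[ba.BarrierResult]) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(path, index=False)


def write_condition_summaries(path: str | Path, summaries: Sequence[ba.ConditionSummary]) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def load_image_with_sidecar(image_path: str | Path, sidecar_path: str | Path) -> MonolayerImage:
    """Multichannel TIFF plus a YAML sidecar naming channels and pixel size.

    The sidecar must declare ``pixel_size_um``, ``channel_names`` (in page
    order) and ``channel_roles``; the pixel size is never guessed from the
    file.
    """
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh) or {}
    if "pixel_size_um" not in meta:
        raise ParacellError(f"{sidecar_path}: sidecar must declare pixel_size_um")
    if "channel_names" not in meta or "channel_roles" not in meta:
        raise ParacellError(f"{sidecar_path}: sidecar must declare channel_names and channel_roles")
    arr = tifffile.imread(image_path)
    if arr.ndim == 2:
        arr = arr[None]
    names = list(meta["channel_names"])
    if arr.shape[0] != len(names):
        raise ParacellError(
            f"{image_path}: {arr.shape[0]} channel page(s) but sidecar names {len(names)}"
        )
    channels = {name: arr[i].astype(float) for i, name in enumerate(names)}
    return MonolayerImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_roles={str(k): str(v) for k, v in meta["channel_roles"].items()},
    )


def save_image_with_sidecar(
    image: MonolayerImage,
    image_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    names = list(image.channels)
    stack = np.stack([image.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(image_path, stack)
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size_um": float(image.pixel_size_um),
                "channel_names": names,
                "channel_roles": dict(image.channel_roles),
            },
            fh,
        )


def load_genotype_labels(path: str | Path, provenance: str = "ground_truth") -> GenotypeField:
    arr = tifffile.imread(path)
    return GenotypeField(labels=arr.astype(np.int32), provenance=provenance)


def read_roi_csv(path: str | Path) -> dict[str, np.ndarray]:
    """User-supplied polylines: CSV with columns roi_id, x, y (0-based
    pixel coordinates, origin top-left, vertices in order)."""
    df = pd.read_csv(path)
    for col in ("roi_id", "x", "y"):
        if col not in df.columns:
            raise ParacellError(f"{path}: missing required column {col!r}")
    rois: dict[str, np.ndarray] = {}
    for roi_id, grp in df.groupby("roi_id", sort=False):
        rois[str(roi_id)] = np.column_stack([grp["y"].to_numpy(float), grp["x"].to_numpy(float)])
    return rois


def write_quant_result(out_dir: str | Path, result: QuantResult) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {
        k: getattr(result, k)
        for k in ("image_id", "d_ctl", "d_ko", "d_boundary", "rel_ko", "rel_boundary",
                  "n_sides_per_class", "seed")
    }
    summary["shortfall"] = json.dumps(result.shortfall)
    pd.DataFrame([summary]).to_csv(out_dir / "quant_result.csv", index=False)
    if result.ribbon_table is not None:
        result.ribbon_table.to_csv(out_dir / "ribbons.csv", index=False)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping,
    seed: Optional[int] = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Record what was run: command, resolved config, seed, input digests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_echo": dict(config),
        "seed": seed,
        "tool_version": TOOL_VERSION,
        "input_digests": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
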