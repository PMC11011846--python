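"""Delimited-text readers and writers for chromatograms, calibrations,
registries and ground-truth sidecars.

Chromatograms are CSV with a ``volume_mL,RI,UV280,RALS,LALS,DP`` header
and ``# key: value`` metadata lines; calibration files use the same
key-value dialect; registries and sidecars are YAML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .calibration import ColumnCalibration, DetectorCalibration
from .chromatogram import CHANNELS, Chromatogram
from .species import ProteinSpecies, Registry

__all__ = [
    "read_chromatogram",
    "write_chromatogram",
    "load_calibration",
    "save_calibration",
    "load_registry",
    "save_registry",
    "write_sidecar",
    "read_sidecar",
]

_COLUMNS = ("volume_mL",) + CHANNELS


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_chromatogram(path) -> Chromatogram:
    """Read the delimited chromatogram format; errors name missing channels."""
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").partition(":")
            if value:
                metadata[key.strip()] = _parse_scalar(value.strip())
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chromatogram {path} missing column(s): {', '.join(missing)}")
    volume = df["volume_mL"].to_numpy(dtype=float)
    if not np.all(np.diff(volume) > 0):
        raise ValueError(f"chromatogram {path}: volume grid is not strictly increasing")
    channels = {ch: df[ch].to_numpy(dtype=float) for ch in CHANNELS}
    return Chromatogram(volume, channels, metadata)


def write_chromatogram(chrom: Chromatogram, path, force: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    lines = [f"# {k}: {v}" for k, v in sorted(chrom.metadata.items(),
                                              key=lambda kv: str(kv[0]))]
    header = "\n".join(lines) + ("\n" if lines else "")
    with open(path, "w") as fh:
        fh.write(header)
        chrom.to_frame().to_csv(fh, index=False, float_format="%.10g")
    return path


def save_calibration(cal: DetectorCalibration, path, force: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    lines = [f"standard_id: {cal.standard_id}",
             f"dn_dc_standard: {cal.dn_dc_standard!r}"]
    for ch in CHANNELS:
        lines.append(f"k_{ch}: {cal.constants[ch]!r}")
    for ch, d in sorted(cal.delays.items()):
        lines.append(f"delay_{ch}: {d!r}")
    if cal.column is not None:
        lines.append(f"column_intercept_a: {cal.column.intercept_a!r}")
        lines.append(f"column_slope_b: {cal.column.slope_b!r}")
        lines.append(f"column_range: {cal.column.volume_range[0]!r} "
                     f"{cal.column.volume_range[1]!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_calibration(path) -> DetectorCalibration:
    data: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        data[key.strip()] = value.strip()
    constants = {ch: float(data[f"k_{ch}"]) for ch in CHANNELS}
    delays = {ch: float(data[f"delay_{ch}"]) for ch in CHANNELS
              if f"delay_{ch}" in data}
    column = None
    if "column_intercept_a" in data:
        lo, hi = (float(x) for x in data.get("column_range", "8 20").split())
        column = ColumnCalibration(float(data["column_intercept_a"]),
                                   float(data["column_slope_b"]), (lo, hi))
    return DetectorCalibration(constants, delays, column,
                               standard_id=data.get("standard_id", ""),
                               dn_dc_standard=float(data.get("dn_dc_standard", 0.185)))


def save_registry(registry: Registry, path, force: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    entries = []
    for name in registry:
        sp = registry[name]
        entries.append({
            "name": sp.name, "role": sp.role, "mw_kda": sp.mw_kda,
            "dn_dc": sp.dn_dc, "da_dc": sp.da_dc,
            "intrinsic_viscosity": sp.intrinsic_viscosity, "rh_nm": sp.rh_nm,
            "paratope_valence": sp.paratope_valence,
            "epitope_domains": sorted(sp.epitope_domains),
            "cognate_domain": sp.cognate_domain,
        })
    path.write_text(yaml.safe_dump({"species": entries}, sort_keys=False))
    return path


def load_registry(path) -> Registry:
    data = yaml.safe_load(Path(path).read_text())
    species = []
    for entry in data["species"]:
        entry = dict(entry)
        entry["epitope_domains"] = frozenset(entry.get("epitope_domains") or ())
        species.append(ProteinSpecies(**entry))
    return Registry(species)


def write_sidecar(truth: dict, path, seed: Optional[int] = None,
                  force: bool = False) -> Path:
    """Ground-truth sidecar: every generator parameter plus provenance."""
    from . import __version__

    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    payload = dict(truth)
    payload["sectd_version"] = __version__
    if seed is not None:
        payload["seed"] = seed
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_sidecar(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
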