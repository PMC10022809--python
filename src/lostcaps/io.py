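"""CSV/YAML I/O for outline tables, histograms, profiles and configs.

All files are plain CSV with a header; units travel in a ``# units:``
comment line at the top of each file written by this package and are
re-read on load. Validation errors name the offending rows (1-based,
counted over data rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import DiameterHistogram, equivalent_diameter

__all__ = [
    "OutlineTable",
    "read_outlines",
    "write_histogram",
    "read_histogram",
    "read_profiles",
    "write_profiles",
    "load_config",
    "dump_config",
]


class ValidationError(ValueError):
    pass


@dataclass
class OutlineTable:
    """Per-particle 2D outline measurements.

    ``table`` columns: image_id, particle_id, and either ``area`` or
    ``d_area`` (optionally both; d_area is derived from area when
    absent), plus an optional z_index.
    """

    table: pd.DataFrame
    units: str

    @property
    def diameters(self) -> np.ndarray:
        return self.table["d_area"].to_numpy()


def _read_units_header(path: Path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# units:"):
        return first.split(":", 1)[1].strip()
    return None


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_outlines(path: str | Path, units: str | None = None) -> OutlineTable:
    """Read an outline table; areas are converted to equivalent diameters."""
    path = Path(path)
    file_units = _read_units_header(path)
    units = units or file_units
    if units is None:
        raise ValidationError(f"{path}: no units declared (header or argument)")
    df = _read_csv(path)
    if "area" not in df.columns and "d_area" not in df.columns:
        raise ValidationError(f"{path}: need an 'area' or 'd_area' column")
    for col in ("area", "d_area"):
        if col in df.columns:
            bad = np.nonzero(~(df[col].to_numpy() > 0))[0]
            if bad.size:
                rows = ", ".join(str(b + 1) for b in bad[:10])
                raise ValidationError(f"{path}: non-positive {col} in data row(s) {rows}")
    if "d_area" not in df.columns:
        df["d_area"] = equivalent_diameter(df["area"].to_numpy())
    return OutlineTable(table=df, units=units)


def write_histogram(hist: DiameterHistogram, path: str | Path) -> None:
    """Write (bin_center, density) CSV at full float precision."""
    path = Path(path)
    df = pd.DataFrame({"bin_center": hist.centers, "density": hist.density})
    with open(path, "w") as fh:
        fh.write(f"# units: {hist.units}\n")
        fh.write(f"# n: {hist.n}\n")
        fh.write(f"# zstack: {int(hist.zstack_provenance)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_histogram(path: str | Path) -> DiameterHistogram:
    path = Path(path)
    units = _read_units_header(path) or "u.d."
    n = 1
    zstack = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# n:"):
                n = int(line.split(":", 1)[1])
            if line.startswith("# zstack:"):
                zstack = bool(int(line.split(":", 1)[1]))
    df = _read_csv(path)
    if not {"bin_center", "density"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns bin_center, density")
    centers = df["bin_center"].to_numpy(dtype=float)
    density = df["density"].to_numpy(dtype=float)
    bad = np.nonzero(density < 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: negative density in data row(s) "
            + ", ".join(str(b + 1) for b in bad[:10])
        )
    h = np.diff(centers)
    if centers.size < 2 or not np.allclose(h, h[0], rtol=1e-6):
        raise ValidationError(f"{path}: bin centers must be uniformly spaced")
    edges = np.concatenate([centers - h[0] / 2.0, [centers[-1] + h[0] / 2.0]])
    # renormalise away round-trip float dust
    density = density / np.sum(density * h[0])
    return DiameterHistogram(
        bin_edges=edges, density=density, n=n, units=units, zstack_provenance=zstack
    )


def write_profiles(profiles: pd.DataFrame, path: str | Path, units: str = "u.d.") -> None:
    """Write a long-format z-profile table (particle_id, z_index, radius)."""
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        profiles.to_csv(fh, index=False, float_format="%.17g")


def read_profiles(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path)
    need = {"particle_id", "z_index", "radius"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(need)}")
    bad = np.nonzero(df["radius"].to_numpy() < 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: negative radius in data row(s) "
            + ", ".join(str(b + 1) for b in bad[:10])
        )
    return df


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a flat mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
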