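"""Readers, writers, and run configuration.

Formats: NIfTI-1 volumes (via :mod:`hgpair.phantom`), CSV sample tables
(pandas), and a YAML key-value run configuration.  Configuration parsing
is strict: unknown keys are rejected and errors name the offending
block/key so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd
import yaml

from .biodist import BiodistSample, GammaWindowSet
from .decay import ActivityPair, IsomerConstants
from .phantom import ImagingModel, VoxelImage, read_phantom, write_phantom

__all__ = [
    "SAMPLE_COLUMNS",
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_samples",
    "write_samples",
    "elapsed_hours",
]

SAMPLE_COLUMNS = (
    "organ",
    "mass_g",
    "counts_g_window",
    "counts_m_window",
    "count_time_s",
    "measure_time_h",
)


def read_volume(path) -> VoxelImage:
    """Read an isotropic NIfTI-1 volume with units metadata."""
    return read_phantom(path)


def write_volume(image: VoxelImage, path) -> None:
    write_phantom(image, path)


def read_samples(path) -> list[BiodistSample]:
    """Read a gamma-counter sample table.

    Expected columns: organ, mass_g (empty for extrapolated organs),
    counts_g_window, counts_m_window, count_time_s, measure_time_h.
    Missing columns and malformed numbers are reported by name and
    row/column address.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if len(df.columns) and missing:
        raise ValueError(f"sample table is missing column(s): {', '.join(missing)}")
    samples = []
    for idx, row in df.iterrows():
        vals = {}
        for col in SAMPLE_COLUMNS[1:]:
            raw = row[col]
            if col == "mass_g" and (pd.isna(raw) or raw == ""):
                vals[col] = None
                continue
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {idx + 2}, column {col!r}: cannot parse {raw!r} as a number"
                ) from None
        samples.append(
            BiodistSample(
                organ=str(row["organ"]),
                mass=vals["mass_g"],
                counts_g=vals["counts_g_window"],
                counts_m=vals["counts_m_window"],
                count_time=vals["count_time_s"],
                measure_time=vals["measure_time_h"],
            )
        )
    return samples


def write_samples(samples, path) -> None:
    rows = [
        {
            "organ": s.organ,
            "mass_g": "" if s.mass is None else s.mass,
            "counts_g_window": s.counts_g,
            "counts_m_window": s.counts_m,
            "count_time_s": s.count_time,
            "measure_time_h": s.measure_time,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).to_csv(path, index=False)


def elapsed_hours(value, reference=None) -> float:
    """Interpret a timestamp as decimal hours or ISO-8601.

    Plain numbers pass through as hours; ISO-8601 strings are converted
    to hours elapsed since ``reference`` (itself ISO-8601), which is
    required in that case.
    """
    try:
        return float(value)
    except (TypeError, ValueError):
        pass
    t = datetime.fromisoformat(str(value))
    if reference is None:
        raise ValueError(
            "an ISO-8601 timestamp needs a reference time (--ref-time) to "
            "compute elapsed hours"
        )
    t0 = datetime.fromisoformat(str(reference))
    return (t - t0).total_seconds() / 3600.0


# ---------------------------------------------------------------------------
# run configuration

_NUCLIDE_KEYS = {"half_life_m_h", "half_life_g_h", "branch_it"}
_PHANTOM_KEYS = {
    "kind", "radius_mm", "length_mm", "volume_ml", "rod_diameters_mm",
    "bore_radius_mm", "rod_length_mm", "conc_m_mbq_ml", "conc_g_mbq_ml",
}
_IMAGING_KEYS = {
    "psf_fwhm_mm", "counts_per_mbq_s", "scan_time_s", "noise",
}
_WINDOWS_KEYS = {
    "g_window_kev", "m_window_kev", "efficiency_g", "efficiency_m",
}
_TOP_KEYS = {"nuclide", "phantom", "imaging", "windows", "seed", "verbosity",
             "injection"}
_INJECTION_KEYS = {"a_m_mbq", "a_g_mbq", "body_weight_g"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {where}: {', '.join(sorted(map(str, unknown)))}"
        )


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    nuclide: IsomerConstants = field(default_factory=IsomerConstants)
    phantom: dict = field(default_factory=dict)
    imaging: ImagingModel = field(default_factory=ImagingModel)
    windows: GammaWindowSet = field(default_factory=GammaWindowSet)
    injection: dict = field(default_factory=dict)
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: top level must be a mapping")
        return cls.from_dict(raw, where=str(path))

    @classmethod
    def from_dict(cls, raw: dict, where: str = "config") -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, where)
        cfg = cls()
        nuc = raw.get("nuclide", {})
        _check_keys(nuc, _NUCLIDE_KEYS, f"{where}: nuclide")
        cfg.nuclide = IsomerConstants(
            half_life_m=float(nuc.get("half_life_m_h", 23.8)),
            half_life_g=float(nuc.get("half_life_g_h", 64.14)),
            branch_it=float(nuc.get("branch_it", 0.914)),
        )
        ph = raw.get("phantom", {})
        _check_keys(ph, _PHANTOM_KEYS, f"{where}: phantom")
        cfg.phantom = dict(ph)
        im = raw.get("imaging", {})
        _check_keys(im, _IMAGING_KEYS, f"{where}: imaging")
        cfg.imaging = ImagingModel(
            psf_fwhm=float(im.get("psf_fwhm_mm", 0.0)),
            counts_per_mbq_s=float(im.get("counts_per_mbq_s", 100.0)),
            scan_time=float(im.get("scan_time_s", 600.0)),
            noise=str(im.get("noise", "none")),
            seed=int(raw.get("seed", 0)),
        )
        win = raw.get("windows", {})
        _check_keys(win, _WINDOWS_KEYS, f"{where}: windows")
        cfg.windows = GammaWindowSet(
            g_window=tuple(win.get("g_window_kev", (55.0, 93.0))),
            m_window=tuple(win.get("m_window_kev", (110.0, 160.0))),
            efficiency_g=float(win.get("efficiency_g", 5000.0)),
            efficiency_m=float(win.get("efficiency_m", 5000.0)),
        )
        injection = raw.get("injection", {})
        _check_keys(injection, _INJECTION_KEYS, f"{where}: injection")
        cfg.injection = dict(injection)
        cfg.seed = int(raw.get("seed", 0))
        cfg.verbosity = str(raw.get("verbosity", "info"))
        return cfg

    def injection_record(self):
        from .biodist import InjectionRecord

        if not self.injection:
            raise ValueError("config has no injection block")
        return InjectionRecord(
            injected=ActivityPair(
                a_m=float(self.injection["a_m_mbq"]),
                a_g=float(self.injection["a_g_mbq"]),
            ),
            body_weight=float(self.injection["body_weight_g"]),
        )
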