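"""Delimited-text table readers/writers and the TOML run configuration.

Table formats (tab-separated, one header line):

* profile table: residue_id, B1_Hz, scheme, dante_window_Hz, offset_Hz,
  intensity, sigma, is_reference — reference rows carry the unsaturated
  intensity at a sentinel offset;
* decay table: residue_id, delay_s, intensity, plane_sigma;
* injection table: temperature_K, injection_index, volume_uL, heat_uJ,
  segment_id.

Writers format floats with repr-level precision so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .exchange import MixtureComposition
from .forward import CestExperiment, CestProfile
from .analysis import CestDataset, ResidueMeta
from .itc import InjectionSeries
from .relaxation import DecayCurve

__all__ = [
    "write_profile_table",
    "read_profile_table",
    "write_decay_table",
    "read_decay_table",
    "write_injection_table",
    "read_injection_table",
    "RunConfig",
]

_PROFILE_COLS = ["residue_id", "B1_Hz", "scheme", "dante_window_Hz",
                 "offset_Hz", "intensity", "sigma", "is_reference"]


def write_profile_table(dataset: CestDataset, path) -> None:
    rows = []
    for p in dataset.profiles:
        e = p.experiment
        window = e.dante_window if e.scheme == "dante" else 0.0
        sig = p.sigmas if p.sigmas is not None else np.zeros(p.offsets.size)
        rows.append({"residue_id": p.residue_id, "B1_Hz": e.b1,
                     "scheme": e.scheme, "dante_window_Hz": window,
                     "offset_Hz": np.nan, "intensity": 1.0,
                     "sigma": float(sig[0]) if sig.size else 0.0,
                     "is_reference": 1})
        for off, inten, s in zip(p.offsets, p.intensities, sig):
            rows.append({"residue_id": p.residue_id, "B1_Hz": e.b1,
                         "scheme": e.scheme, "dante_window_Hz": window,
                         "offset_Hz": off, "intensity": inten, "sigma": s,
                         "is_reference": 0})
    pd.DataFrame(rows, columns=_PROFILE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_profile_table(
    path,
    composition: MixtureComposition,
    residue_shifts: dict,
    tsat: float = 0.4,
    larmor: float = 96.3,
    carrier: float = 118.5,
    classes: dict | None = None,
) -> CestDataset:
    """Rebuild a CestDataset from a profile table plus experiment constants.

    ``residue_shifts`` maps residue_id -> major-state shift (ppm); the
    saturation time, field and carrier are config constants not stored per
    row.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_PROFILE_COLS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"profile table lacks columns {sorted(missing)}")
    profiles = []
    df = df[df["is_reference"] == 0]
    for (rid, b1, scheme, window), grp in df.groupby(
        ["residue_id", "B1_Hz", "scheme", "dante_window_Hz"], sort=True
    ):
        grp = grp.sort_values("offset_Hz")
        expt = CestExperiment(
            b1=float(b1), tsat=tsat,
            offsets=grp["offset_Hz"].to_numpy(),
            scheme=str(scheme),
            dante_window=float(window) if scheme == "dante" else None,
            larmor_15n=larmor, carrier=carrier,
        )
        profiles.append(CestProfile(
            residue_id=int(rid), experiment=expt,
            offsets=grp["offset_Hz"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            sigmas=grp["sigma"].to_numpy(),
        ))
    residues = {}
    for rid in sorted({p.residue_id for p in profiles}):
        if rid not in residue_shifts:
            raise InvalidInputError(f"no major-state shift for residue {rid}")
        residues[rid] = ResidueMeta(
            residue_id=rid, shift_f=float(residue_shifts[rid]),
            class_label=(classes or {}).get(rid, "unknown"),
        )
    return CestDataset(profiles=profiles, composition=composition,
                       residues=residues)


def write_decay_table(curves: list, path) -> None:
    rows = [
        {"residue_id": c.residue_id, "delay_s": d, "intensity": i,
         "plane_sigma": s}
        for c in curves
        for d, i, s in zip(c.delays, c.intensities,
                           c.plane_noise if c.plane_noise is not None
                           else np.zeros(c.delays.size))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def read_decay_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    curves = []
    for rid, grp in df.groupby("residue_id", sort=True):
        curves.append(DecayCurve(
            residue_id=int(rid), delays=grp["delay_s"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            plane_noise=grp["plane_sigma"].to_numpy(),
        ))
    return curves


def write_injection_table(series: list, path) -> None:
    """One row per injection; ``series_id`` separates duplicate titrations
    recorded at the same temperature."""
    rows = []
    for sid, s in enumerate(series):
        seg = np.zeros(s.volumes.size, dtype=int)
        for b in s.segments:
            seg[b:] += 1
        for i, (v, q) in enumerate(zip(s.volumes, s.heats)):
            rows.append({"series_id": sid, "temperature_K": s.temperature,
                         "injection_index": i, "volume_uL": v,
                         "heat_uJ": q, "segment_id": seg[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def read_injection_table(path, v0: float, cell_conc: float,
                         syringe_conc: float) -> list:
    df = pd.read_csv(path, sep="\t")
    if "series_id" not in df.columns:
        df = df.assign(series_id=0)
    series = []
    for (sid, t), grp in df.groupby(["series_id", "temperature_K"],
                                    sort=True):
        grp = grp.sort_values("injection_index")
        seg = grp["segment_id"].to_numpy()
        boundaries = tuple(np.nonzero(np.diff(seg) > 0)[0] + 1)
        series.append(InjectionSeries(
            temperature=float(t), v0=v0, cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            volumes=grp["volume_uL"].to_numpy(),
            heats=grp["heat_uJ"].to_numpy(),
            segments=boundaries,
        ))
    return series


@dataclass
class RunConfig:
    """Parsed pipeline configuration (TOML).

    Sections: [experiment] (tsat_s, larmor_MHz, carrier_ppm),
    [constraint] (Kd_uM, P0_uM, R0_uM), [model] (model, crib_range,
    crib_set, excluded_residues, r2b_eq_r2c), [bootstrap] (n, seed),
    [itc] (cell_volume_uL, cell_conc_uM, syringe_conc_uM), [paths]
    (profile_table, shift_table, decay_table, injection_table, outdir).
    """

    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    @property
    def composition(self) -> MixtureComposition:
        c = self.section("constraint")
        try:
            return MixtureComposition(p0=c["P0_uM"], r0=c["R0_uM"],
                                      kd=c["Kd_uM"])
        except KeyError as e:
            raise InvalidInputError(f"[constraint] missing key {e}") from e
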