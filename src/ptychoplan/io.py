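"""Calibration-table and acquisition-plan file loading.

Calibration files describe what a given microscope offers.  Two open
formats are accepted:

* TOML with the sections shown below, or
* a tidy CSV with columns ``section, key, value`` carrying the same
  entries (list values are semicolon-separated).

TOML schema::

    [beam]
    voltages_kv = [80.0, 200.0]

    [apertures]           # aperture name -> convergence semi-angle (mrad)
    "40um" = 27.42

    [magnifications]      # magnification -> field of view (Å)
    "30M" = 80.0

    [camera_lengths]      # nominal (cm) -> effective (cm)
    "8" = 12.12

    [detector]
    n_pixels = 192
    pitch_um = 100.0
    binnings = [1, 2, 4]
    paar_mrad = 100.0     # optional

Plan files are TOML or JSON with tables ``beam``, ``scan``, ``detector``
and a top-level ``method``, using the field names of the corresponding
:mod:`ptychoplan.instrument` classes.
"""

from __future__ import annotations

import csv
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .instrument import AcquisitionPlan, BeamSetting, DetectorModel, Method, ScanSetting

__all__ = ["Calibrations", "load_calibrations", "load_plan", "save_calibrations_csv"]


@dataclass(frozen=True)
class Calibrations:
    """Microscope capabilities loaded from a calibration file."""

    voltages_kv: tuple[float, ...]
    apertures_mrad: dict[str, float]
    magnification_fov_A: dict[str, float]
    camera_lengths_cm: dict[str, float]  # nominal label -> effective cm
    detector_n_pixels: int
    detector_pitch_um: float
    detector_binnings: tuple[int, ...]
    paar_mrad: float | None = None

    def camera_length_pairs(self) -> list[tuple[float, float]]:
        """(nominal, effective) pairs sorted by nominal length."""
        pairs = [(float(k), v) for k, v in self.camera_lengths_cm.items()]
        return sorted(pairs)


def _from_mapping(doc: dict) -> Calibrations:
    det = doc["detector"]
    return Calibrations(
        voltages_kv=tuple(float(v) for v in doc["beam"]["voltages_kv"]),
        apertures_mrad={k: float(v) for k, v in doc["apertures"].items()},
        magnification_fov_A={
            k: float(v) for k, v in doc.get("magnifications", {}).items()
        },
        camera_lengths_cm={k: float(v) for k, v in doc["camera_lengths"].items()},
        detector_n_pixels=int(det["n_pixels"]),
        detector_pitch_um=float(det["pitch_um"]),
        detector_binnings=tuple(int(b) for b in det.get("binnings", [1])),
        paar_mrad=float(det["paar_mrad"]) if "paar_mrad" in det else None,
    )


def load_calibrations(path: str | Path) -> Calibrations:
    """Load a calibration table from TOML or CSV (decided by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        doc: dict = {"beam": {}, "apertures": {}, "magnifications": {},
                     "camera_lengths": {}, "detector": {}}
        with open(path, newline="") as f:
            for row in csv.DictReader(f):
                section, key, value = row["section"], row["key"], row["value"]
                if ";" in value:
                    parsed: object = [float(v) for v in value.split(";")]
                elif section == "detector" and key in ("n_pixels",):
                    parsed = int(value)
                else:
                    try:
                        parsed = float(value)
                    except ValueError:
                        parsed = value
                doc.setdefault(section, {})[key] = parsed
        if "binnings" in doc["detector"] and not isinstance(
            doc["detector"]["binnings"], list
        ):
            doc["detector"]["binnings"] = [doc["detector"]["binnings"]]
        return _from_mapping(doc)
    with open(path, "rb") as f:
        return _from_mapping(tomllib.load(f))


def save_calibrations_csv(cal: Calibrations, path: str | Path) -> None:
    """Write a calibration table in the tidy CSV dialect."""
    rows: list[tuple[str, str, str]] = [
        ("beam", "voltages_kv", ";".join(str(v) for v in cal.voltages_kv))
    ]
    rows += [("apertures", k, str(v)) for k, v in cal.apertures_mrad.items()]
    rows += [("magnifications", k, str(v)) for k, v in cal.magnification_fov_A.items()]
    rows += [("camera_lengths", k, str(v)) for k, v in cal.camera_lengths_cm.items()]
    rows.append(("detector", "n_pixels", str(cal.detector_n_pixels)))
    rows.append(("detector", "pitch_um", str(cal.detector_pitch_um)))
    rows.append(("detector", "binnings", ";".join(str(b) for b in cal.detector_binnings)))
    if cal.paar_mrad is not None:
        rows.append(("detector", "paar_mrad", str(cal.paar_mrad)))
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["section", "key", "value"])
        writer.writerows(rows)


def load_plan(path: str | Path, **overrides) -> AcquisitionPlan:
    """Load an acquisition plan from TOML or JSON.

    Keyword overrides replace individual fields, dotted per section:
    ``beam_alpha_mrad=...``, ``scan_step_A=...``, ``detector_binning=...``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as f:
            doc = json.load(f)
    else:
        with open(path, "rb") as f:
            doc = tomllib.load(f)
    beam = dict(doc["beam"])
    scan = dict(doc["scan"])
    detector = dict(doc["detector"])
    method = doc.get("method", "ITR")
    for key, value in overrides.items():
        if value is None:
            continue
        section, _, field = key.partition("_")
        target = {"beam": beam, "scan": scan, "detector": detector}.get(section)
        if target is None:
            raise KeyError(f"unknown plan override {key!r}")
        target[field] = value
    return AcquisitionPlan(
        beam=BeamSetting(**beam),
        scan=ScanSetting(**scan),
        detector=DetectorModel(**detector),
        method=Method(method),
    )
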