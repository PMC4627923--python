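"""Reading and writing the pipeline's file formats.

Measurements travel as YAML (one document with ``measurements``, optional
``dls`` rows and optional extras) or as a flat two-column CSV of
``key,value`` pairs; DLS tables and refractometry readings as CSV.  A
packaged fixture carries the reference Cos-7 TGN/endosome cyclodextrin
dataset so the full analysis runs out of the box.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .core import SizeObservation, TreatmentMeasurements
from .errors import InvariantError

__all__ = [
    "read_measurements",
    "read_dls_table",
    "read_ri_readings",
    "load_reference_dataset",
    "write_report",
]

_MEASUREMENT_KEYS = (
    "rho_pre",
    "rho_pre_sem",
    "rho_post",
    "rho_post_sem",
    "mass_remaining_M",
    "mass_remaining_M_sem",
)

_FIXTURE_RESOURCE = "cos7_tgn_vesicles.yaml"


def _measurements_from_mapping(mapping: dict) -> TreatmentMeasurements:
    missing = [k for k in _MEASUREMENT_KEYS if k not in mapping]
    if missing:
        raise InvariantError(f"measurements are missing required keys: {missing}")
    kwargs = {k: float(mapping[k]) for k in _MEASUREMENT_KEYS}
    if "rho_sensitive" in mapping:
        kwargs["rho_sensitive"] = float(mapping["rho_sensitive"])
    return TreatmentMeasurements(**kwargs)


def _dls_from_records(records: list[dict]) -> list[SizeObservation]:
    return [
        SizeObservation(
            condition=str(row["condition"]),
            fraction_class=str(row["fraction_class"]),
            diameter_mean=float(row["diameter_mean_nm"]),
            diameter_sd=float(row["diameter_sd_nm"]),
        )
        for row in records
    ]


def _parse_document(doc: dict) -> dict:
    """Normalize a parsed YAML document into measurements/dls/extras."""
    out = {
        "measurements": _measurements_from_mapping(doc.get("measurements", doc)),
        "dls": _dls_from_records(doc.get("dls", [])),
    }
    if "reported_observed_volume_decline_pct" in doc:
        out["reported_observed_volume_decline_pct"] = float(
            doc["reported_observed_volume_decline_pct"]
        )
    return out


def read_measurements(path: str | Path) -> dict:
    """Read a measurements file (YAML document or key,value CSV).

    Returns a dict with keys ``measurements`` (:class:`TreatmentMeasurements`),
    ``dls`` (list of :class:`SizeObservation`, possibly empty) and, when
    present, ``reported_observed_volume_decline_pct``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise InvariantError(f"{path} does not contain a YAML mapping")
        return _parse_document(doc)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, comment="#", header=None, names=["key", "value"])
        mapping = dict(zip(frame["key"].astype(str), frame["value"]))
        return _parse_document({"measurements": mapping})
    raise InvariantError(f"unsupported measurements format: {path.suffix!r}")


def read_dls_table(path: str | Path) -> list[SizeObservation]:
    """Read a DLS CSV with columns condition, fraction_class, diameter_mean_nm, diameter_sd_nm."""
    frame = pd.read_csv(path, comment="#")
    return _dls_from_records(frame.to_dict("records"))


def read_ri_readings(path: str | Path) -> list[tuple[int, float]]:
    """Read refractometer readings CSV with columns fraction_index, refractive_index."""
    frame = pd.read_csv(path, comment="#")
    return [
        (int(row["fraction_index"]), float(row["refractive_index"]))
        for _, row in frame.iterrows()
    ]


def load_reference_dataset() -> dict:
    """The packaged Cos-7 TGN/endosome cyclodextrin reference dataset."""
    with resources.files("vesidens.data").joinpath(_FIXTURE_RESOURCE).open() as fh:
        doc = yaml.safe_load(fh)
    return _parse_document(doc)


def reference_dataset_path() -> Path:
    """Filesystem path of the packaged reference dataset (for CLI defaults)."""
    return Path(str(resources.files("vesidens.data").joinpath(_FIXTURE_RESOURCE)))


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict to pretty-printed JSON (stable key order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
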