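"""CSV reading/writing for the documented dataset schemas.

Files are comma-separated UTF-8 with a mandatory header row and a "."
decimal separator.  Assay metadata travels in leading comment lines of
the form ``# key = value`` so a file round-trips to the exact typed
dataset it was written from.  Documented kinds and columns:

====================  =========================================
kind                  columns
====================  =========================================
saturation            substrate_mM, rate_per_s, replicate
titration             Z_uM, rate_per_s
trace                 time_s, signal
dose_response         inhibitor_uM, fractional_activity
melt                  T_C, fluorescence
viscosity             eta_rel, kcat_per_s
profile               T_K, kcat_per_s
====================  =========================================
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets as ds

__all__ = ["ParseError", "read_csv_dataset", "write_csv_dataset", "dataset_kind"]


class ParseError(ValueError):
    """A dataset file violated its documented schema."""


@dataclasses.dataclass(frozen=True)
class _KindSpec:
    cls: type
    columns: dict[str, str]  # CSV column -> dataclass field
    nonneg_columns: tuple[str, ...]
    meta_fields: tuple[str, ...]
    strictly_increasing: tuple[str, ...] = ()


_KINDS: dict[str, _KindSpec] = {
    "saturation": _KindSpec(
        ds.RateDataset,
        {"substrate_mM": "substrate_mM", "rate_per_s": "rate_per_s",
         "replicate": "replicate"},
        ("substrate_mM",),
        ("varied_substrate", "fixed_substrate", "fixed_conc_mM", "enzyme_conc_uM",
         "temperature_C", "nucleotide", "isotopologue", "mass_increase_percent"),
    ),
    "titration": _KindSpec(
        ds.TitrationDataset,
        {"Z_uM": "z_uM", "rate_per_s": "rate_per_s"},
        ("Z_uM",),
        ("g_uM", "temperature_C", "glycerol_percent"),
    ),
    "trace": _KindSpec(
        ds.ProgressTrace,
        {"time_s": "time_s", "signal": "signal"},
        ("time_s",),
        ("signal_unit", "path_length_cm", "epsilon_290", "dead_time_s",
         "enzyme_uM", "substrate_uM", "temperature_C", "isotopologue"),
        strictly_increasing=("time_s",),
    ),
    "dose_response": _KindSpec(
        ds.DoseResponseDataset,
        {"inhibitor_uM": "inhibitor_uM", "fractional_activity": "fractional_activity"},
        ("inhibitor_uM",),
        ("temperature_C", "isotopologue"),
    ),
    "melt": _KindSpec(
        ds.MeltCurve,
        {"T_C": "temp_C", "fluorescence": "fluorescence"},
        (),
        ("isotopologue",),
    ),
    "viscosity": _KindSpec(
        ds.ViscosityDataset,
        {"eta_rel": "eta_rel", "kcat_per_s": "kcat_per_s"},
        ("eta_rel",),
        ("temperature_C", "nucleotide"),
    ),
    "profile": _KindSpec(
        ds.TemperatureProfile,
        {"T_K": "temp_K", "kcat_per_s": "kcat_per_s"},
        ("T_K",),
        ("enzyme",),
    ),
}

_CLS_TO_KIND = {spec.cls: kind for kind, spec in _KINDS.items()}


def dataset_kind(dataset) -> str:
    """The schema kind string for a typed dataset instance."""
    try:
        return _CLS_TO_KIND[type(dataset)]
    except KeyError:
        raise ParseError(f"no CSV schema for {type(dataset).__name__}") from None


def write_csv_dataset(dataset, path) -> Path:
    """Write a typed dataset with its metadata comment block; returns path."""
    kind = dataset_kind(dataset)
    spec = _KINDS[kind]
    frame = pd.DataFrame(
        {col: np.asarray(getattr(dataset, field))
         for col, field in spec.columns.items()}
    )
    buf = _io.StringIO()
    buf.write(f"# kind = {kind}\n")
    for field in spec.meta_fields:
        buf.write(f"# {field} = {getattr(dataset, field)}\n")
    frame.to_csv(buf, index=False)
    path = Path(path)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def _coerce_meta(value: str):
    try:
        return float(value)
    except ValueError:
        return value


def read_csv_dataset(path, kind: str | None = None):
    """Read and validate a dataset file, returning the typed object.

    Malformed rows are reported with their 1-based file line numbers.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    n_comment = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_comment += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()

    file_kind = meta.pop("kind", None)
    if kind is None:
        kind = file_kind
    if kind is None:
        raise ParseError(f"{path}: no kind given and none recorded in the file")
    if file_kind is not None and file_kind != kind:
        raise ParseError(f"{path}: file records kind {file_kind!r}, expected {kind!r}")
    if kind not in _KINDS:
        raise ParseError(f"unknown dataset kind {kind!r}; known: {sorted(_KINDS)}")
    spec = _KINDS[kind]

    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc

    missing = [c for c in spec.columns if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing} for kind {kind!r}")

    # data rows start right after the comment block and the header line
    first_data_line = n_comment + 2

    def _lines(mask: np.ndarray) -> list[int]:
        return [first_data_line + int(i) for i in np.flatnonzero(mask)]

    values: dict[str, np.ndarray] = {}
    for col, field in spec.columns.items():
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna().to_numpy()
        if bad.any():
            raise ParseError(
                f"{path}: non-numeric value(s) in column {col!r} at line(s) {_lines(bad)}"
            )
        values[field] = numeric.to_numpy(dtype=float)

    for col in spec.nonneg_columns:
        arr = values[spec.columns[col]]
        neg = arr < 0
        if neg.any():
            raise ParseError(
                f"{path}: negative value(s) in column {col!r} at line(s) {_lines(neg)}"
            )
    for col in spec.strictly_increasing:
        arr = values[spec.columns[col]]
        if np.any(np.diff(arr) <= 0):
            bad = np.concatenate([[False], np.diff(arr) <= 0])
            raise ParseError(
                f"{path}: column {col!r} must be strictly increasing; "
                f"violation at line(s) {_lines(bad)}"
            )

    kwargs = dict(values)
    field_names = {f.name for f in dataclasses.fields(spec.cls)}
    for key, raw in meta.items():
        if key in field_names and key not in kwargs:
            kwargs[key] = _coerce_meta(raw)
    return spec.cls(**kwargs)
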