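"""Read/write reference parametrizations (JSON or HDF5 containers).

The container holds, for one anchor: spin-free energies, gradients,
interstate coupling vectors, the three complex SOC operator matrices, the
reference geometry with per-site atom/point-charge flags, the spin quantum
number and the anchor time.  JSON stores floats at full shortest-round-trip
precision and complex arrays as real/imag pairs, so a write/read cycle is
bit-faithful; HDF5 stores native float64/complex128 datasets.  Malformed
files are rejected with a message naming the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError
from .lvc import ReferenceParametrization

__all__ = ["save_parametrization", "load_parametrization", "validate_payload"]

_REQUIRED = (
    "energies",
    "gradients",
    "nacs",
    "soc_x",
    "soc_y",
    "soc_z",
    "geometry",
    "site_is_atom",
    "elements",
    "spin_S",
    "anchor_time",
)


def _complex_to_json(arr: np.ndarray) -> dict:
    return {"real": arr.real.tolist(), "imag": arr.imag.tolist()}


def _complex_from_json(obj, fieldname: str) -> np.ndarray:
    try:
        return np.asarray(obj["real"], dtype=float) + 1j * np.asarray(
            obj["imag"], dtype=float
        )
    except (TypeError, KeyError) as exc:
        raise FormatError(f"field '{fieldname}': expected real/imag object") from exc


def save_parametrization(param: ReferenceParametrization, path) -> None:
    """Write a parametrization container; format chosen by extension
    (.json for text, .h5/.hdf5 for HDF5)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "format": "lvcspin-parametrization",
            "version": 1,
            "spin_S": param.spin_S,
            "anchor_time": param.anchor_time,
            "energies": param.reference_energies.tolist(),
            "gradients": param.gradients.tolist(),
            "nacs": param.nacs.tolist(),
            "soc_x": _complex_to_json(param.soc_operators[0]),
            "soc_y": _complex_to_json(param.soc_operators[1]),
            "soc_z": _complex_to_json(param.soc_operators[2]),
            "geometry": param.reference_geometry.tolist(),
            "site_is_atom": param.site_is_atom.astype(int).tolist(),
            "elements": list(param.elements),
            "ml_labels": None
            if param.ml_labels is None
            else param.ml_labels.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = "lvcspin-parametrization"
            fh.attrs["version"] = 1
            fh.attrs["spin_S"] = param.spin_S
            fh.attrs["anchor_time"] = param.anchor_time
            fh.create_dataset("energies", data=param.reference_energies)
            fh.create_dataset("gradients", data=param.gradients)
            fh.create_dataset("nacs", data=param.nacs)
            for name, v in zip(("soc_x", "soc_y", "soc_z"), param.soc_operators):
                fh.create_dataset(name, data=v)
            fh.create_dataset("geometry", data=param.reference_geometry)
            fh.create_dataset("site_is_atom", data=param.site_is_atom.astype(np.int8))
            fh.create_dataset(
                "elements", data=np.array(param.elements, dtype=h5py.string_dtype())
            )
            if param.ml_labels is not None:
                fh.create_dataset("ml_labels", data=param.ml_labels)
        return
    raise FormatError(f"unsupported container extension {path.suffix!r}")


def validate_payload(payload: dict) -> None:
    """Field-level schema validation of a decoded JSON payload."""
    for key in _REQUIRED:
        if key not in payload:
            raise FormatError(f"field '{key}': missing from container")
    n = len(payload["energies"])
    geom = np.asarray(payload["geometry"], dtype=float)
    if geom.ndim != 2 or geom.shape[1] != 3:
        raise FormatError(f"field 'geometry': expected (N, 3) shape, got {geom.shape}")
    dof = 3 * geom.shape[0]
    grads = np.asarray(payload["gradients"], dtype=float)
    if grads.shape != (n, dof):
        raise FormatError(
            f"field 'gradients': expected shape {(n, dof)}, got {grads.shape}"
        )
    nacs = np.asarray(payload["nacs"], dtype=float)
    if nacs.shape != (n, n, dof):
        raise FormatError(f"field 'nacs': expected shape {(n, n, dof)}, got {nacs.shape}")
    for name in ("soc_x", "soc_y", "soc_z"):
        v = _complex_from_json(payload[name], name)
        if v.shape != (n, n):
            raise FormatError(f"field '{name}': expected shape {(n, n)}, got {v.shape}")
    if len(payload["site_is_atom"]) != geom.shape[0]:
        raise FormatError("field 'site_is_atom': length must match geometry")
    if len(payload["elements"]) != geom.shape[0]:
        raise FormatError("field 'elements': length must match geometry")
    twos = 2 * float(payload["spin_S"])
    if abs(twos - round(twos)) > 1e-12 or twos < 0:
        raise FormatError("field 'spin_S': must be a nonnegative half-integer")


def load_parametrization(path) -> ReferenceParametrization:
    """Read a container written by :func:`save_parametrization`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"not valid JSON: {exc}") from exc
        validate_payload(payload)
        soc = np.stack(
            [_complex_from_json(payload[k], k) for k in ("soc_x", "soc_y", "soc_z")]
        )
        ml = payload.get("ml_labels")
        return ReferenceParametrization(
            reference_geometry=np.asarray(payload["geometry"], dtype=float),
            site_is_atom=np.asarray(payload["site_is_atom"], dtype=bool),
            elements=tuple(payload["elements"]),
            reference_energies=np.asarray(payload["energies"], dtype=float),
            gradients=np.asarray(payload["gradients"], dtype=float),
            nacs=np.asarray(payload["nacs"], dtype=float),
            soc_operators=soc,
            spin_S=float(payload["spin_S"]),
            anchor_time=float(payload["anchor_time"]),
            ml_labels=None if ml is None else np.asarray(ml, dtype=int),
        )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            for key in _REQUIRED:
                if key not in fh and key not in fh.attrs:
                    raise FormatError(f"field '{key}': missing from container")
            ml = fh["ml_labels"][()] if "ml_labels" in fh else None
            return ReferenceParametrization(
                reference_geometry=fh["geometry"][()],
                site_is_atom=fh["site_is_atom"][()].astype(bool),
                elements=tuple(e.decode() for e in fh["elements"][()]),
                reference_energies=fh["energies"][()],
                gradients=fh["gradients"][()],
                nacs=fh["nacs"][()],
                soc_operators=np.stack(
                    [fh[k][()].astype(complex) for k in ("soc_x", "soc_y", "soc_z")]
                ),
                spin_S=float(fh.attrs["spin_S"]),
                anchor_time=float(fh.attrs["anchor_time"]),
                ml_labels=ml,
            )
    raise FormatError(f"unsupported container extension {path.suffix!r}")
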