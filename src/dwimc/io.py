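"""Reading and writing DWI stacks and derived volumes.

Two on-disk layouts are supported for multi-repetition input:

* **NIfTI + JSON sidecar** — a single 4D NIfTI whose fourth axis
  concatenates all acquired volumes (every b-value, direction and
  repetition), with a sidecar JSON of equal-length lists ``b_values``,
  ``direction_ids`` and ``repetition_ids`` describing each volume, plus
  ``voxel_size``.  NIfTI stores ``(x, y, z, vol)``; in memory everything
  is ``(z, i, y, x)``.
* **HDF5** — one group per b-value (``/b600/data`` etc.) holding the
  ``(z, i, y, x)`` array directly, with direction/repetition labels as
  attributes.

Derived 3D volumes (combined DW images, ADC maps, weight/rejection maps)
are written as NIfTI with the voxel size in the header; invalid ADC
voxels are stored as NaN.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .adc import AdcVolume
from .core import AveragedVolume, DwiStack

__all__ = [
    "load_dwi",
    "save_volume",
    "load_volume",
    "write_stacks_nifti",
    "write_stacks_hdf5",
]


def _affine(voxel_size) -> np.ndarray:
    dx, dy, dz = voxel_size
    return np.diag([dx, dy, dz, 1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_dwi(path) -> dict[float, DwiStack]:
    """Load multi-repetition DW data, one :class:`DwiStack` per b-value.

    ``path`` may be a 4D NIfTI (with its JSON sidecar next to it) or an
    HDF5 container.  Magnitudes are taken as stored — no rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_hdf5(path)
    return _load_nifti(path)


def _load_nifti(path: Path) -> dict[float, DwiStack]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("b_values", "direction_ids", "repetition_ids"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required field {key!r}")
    img = nib.load(path)
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {arr.shape}")
    n_vol = arr.shape[3]
    b_values = meta["b_values"]
    dir_ids = meta["direction_ids"]
    rep_ids = meta["repetition_ids"]
    for key, lst in (
        ("b_values", b_values),
        ("direction_ids", dir_ids),
        ("repetition_ids", rep_ids),
    ):
        if len(lst) != n_vol:
            raise ValueError(
                f"sidecar field {key!r} lists {len(lst)} volumes but the "
                f"image holds {n_vol}"
            )
    if np.any(arr < 0):
        raise ValueError("magnitude data must be non-negative")
    voxel_size = tuple(meta.get("voxel_size", img.header.get_zooms()[:3]))

    data = np.transpose(arr, (2, 3, 1, 0))  # (z, vol, y, x)
    stacks: dict[float, DwiStack] = {}
    for b in sorted(set(b_values)):
        idx = [i for i, bv in enumerate(b_values) if bv == b]
        stacks[float(b)] = DwiStack(
            data=data[:, idx],
            b_value=float(b),
            rep_labels=[(int(dir_ids[i]), int(rep_ids[i])) for i in idx],
            voxel_size=voxel_size,
        )
    return stacks


def _load_hdf5(path: Path) -> dict[float, DwiStack]:
    stacks: dict[float, DwiStack] = {}
    with h5py.File(path, "r") as f:
        voxel_size = tuple(f.attrs.get("voxel_size", (3.0, 3.0, 4.0)))
        for name, grp in f.items():
            if not name.startswith("b") or "data" not in grp:
                raise ValueError(f"unexpected HDF5 group {name!r}; expected b<value>/data")
            b = float(name[1:])
            data = np.asarray(grp["data"], dtype=float)
            if np.any(data < 0):
                raise ValueError(f"negative magnitudes in group {name!r}")
            n = data.shape[1]
            dir_ids = list(grp.attrs.get("direction_ids", [0] * n))
            rep_ids = list(grp.attrs.get("repetition_ids", range(n)))
            if len(dir_ids) != n or len(rep_ids) != n:
                raise ValueError(
                    f"group {name!r}: label attributes do not match the "
                    f"{n} stored repetitions"
                )
            stacks[b] = DwiStack(
                data=data,
                b_value=b,
                rep_labels=[(int(d), int(r)) for d, r in zip(dir_ids, rep_ids)],
                voxel_size=voxel_size,
            )
    return stacks


def save_volume(vol, path, voxel_size=None) -> None:
    """Write a 3D volume (combined DWI, ADC map, or bare array) as NIfTI.

    ADC volumes store NaN at invalid voxels.  Values are written as
    float32.
    """
    path = Path(path)
    if isinstance(vol, AveragedVolume):
        data = vol.data
        voxel_size = voxel_size or vol.voxel_size
    elif isinstance(vol, AdcVolume):
        data = np.where(vol.valid, vol.adc, np.nan)
    else:
        data = np.asarray(vol, dtype=float)
    voxel_size = voxel_size or (3.0, 3.0, 4.0)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) volume, got shape {data.shape}")
    img = nib.Nifti1Image(
        np.transpose(data, (2, 1, 0)).astype(np.float32), _affine(voxel_size)
    )
    try:
        nib.save(img, path)
    except OSError as exc:
        raise OSError(f"could not write volume to {path}: {exc}") from exc


def load_volume(path) -> np.ndarray:
    """Read a 3D NIfTI volume back into ``(z, y, x)`` order."""
    arr = np.asarray(nib.load(path).dataobj, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume at {path}, got shape {arr.shape}")
    return np.transpose(arr, (2, 1, 0))


def write_stacks_nifti(stacks: dict[float, DwiStack], stem) -> tuple[Path, Path]:
    """Write stacks as one concatenated 4D NIfTI plus JSON sidecar.

    ``stem`` is the output path without extension; returns the image and
    sidecar paths.  The layout round-trips through :func:`load_dwi`.
    """
    stem = Path(stem)
    b_sorted = sorted(stacks)
    vols, b_values, dir_ids, rep_ids = [], [], [], []
    for b in b_sorted:
        st = stacks[b]
        for i, (d, r) in enumerate(st.rep_labels):
            vols.append(st.data[:, i])
            b_values.append(b)
            dir_ids.append(int(d))
            rep_ids.append(int(r))
    data = np.stack(vols, axis=1)  # (z, vol, y, x)
    voxel_size = stacks[b_sorted[0]].voxel_size
    img = nib.Nifti1Image(
        np.transpose(data, (3, 2, 0, 1)).astype(np.float32), _affine(voxel_size)
    )
    img_path = stem.with_suffix(".nii.gz")
    nib.save(img, img_path)
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "b_values": b_values,
                "direction_ids": dir_ids,
                "repetition_ids": rep_ids,
                "voxel_size": list(voxel_size),
            },
            indent=2,
        )
    )
    return img_path, sidecar


def write_stacks_hdf5(stacks: dict[float, DwiStack], path) -> Path:
    """Write stacks in the hierarchical ``/b<value>/data`` HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        first = next(iter(stacks.values()))
        f.attrs["voxel_size"] = list(first.voxel_size)
        for b, st in stacks.items():
            grp = f.create_group(f"b{b:g}")
            grp.create_dataset("data", data=st.data)
            grp.attrs["b_value"] = b
            grp.attrs["direction_ids"] = [d for d, _ in st.rep_labels]
            grp.attrs["repetition_ids"] = [r for _, r in st.rep_labels]
    return path
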