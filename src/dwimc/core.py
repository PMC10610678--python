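"""Core containers for multi-repetition diffusion-weighted image stacks.

The central object is :class:`DwiStack`: all magnitude repetitions of one
slice stack acquired at a single b-value, indexed ``(z, i, y, x)`` where
``z`` is the slice, ``i`` the repetition, and ``(y, x)`` the in-plane voxel.
When the isotropic-diffusion assumption holds (liver parenchyma), images
acquired along different diffusion-encoding directions are pooled into the
repetition axis; ``rep_labels`` keeps track of the original
(direction, repetition) identity of each entry so that the per-direction
processing mode can split them apart again.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DwiStack", "AveragedVolume", "standard_average"]


@dataclass
class DwiStack:
    """Magnitude DW repetitions of one slice stack at one b-value.

    Parameters
    ----------
    data:
        4D non-negative array indexed ``(z, i, y, x)``.
    b_value:
        Diffusion weighting in s/mm².
    rep_labels:
        One ``(direction_id, repetition_id)`` pair per repetition entry.
        Defaults to a single direction with running repetition ids.
    voxel_size:
        In-plane and through-plane voxel size in mm, ``(dy, dx, dz)`` order
        is not used internally; stored as ``(dx, dy, dz)`` for headers.
    """

    data: np.ndarray
    b_value: float
    rep_labels: list[tuple[int, int]] | None = None
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"DwiStack data must be 4D (z, i, y, x); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DwiStack data must be finite")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")
        if self.rep_labels is None:
            self.rep_labels = [(0, i) for i in range(self.data.shape[1])]
        self.rep_labels = [tuple(lbl) for lbl in self.rep_labels]
        if len(self.rep_labels) != self.data.shape[1]:
            raise ValueError(
                f"rep_labels has {len(self.rep_labels)} entries but the stack "
                f"holds {self.data.shape[1]} repetitions"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_reps(self) -> int:
        return self.data.shape[1]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def direction_ids(self) -> list[int]:
        """Distinct direction ids in acquisition order."""
        seen: dict[int, None] = {}
        for d, _ in self.rep_labels:
            seen.setdefault(d, None)
        return list(seen)

    def select_direction(self, direction_id: int) -> "DwiStack":
        """Sub-stack holding only the repetitions of one encoding direction."""
        idx = [i for i, (d, _) in enumerate(self.rep_labels) if d == direction_id]
        if not idx:
            raise ValueError(f"no repetitions with direction id {direction_id}")
        return DwiStack(
            data=self.data[:, idx],
            b_value=self.b_value,
            rep_labels=[self.rep_labels[i] for i in idx],
            voxel_size=self.voxel_size,
        )

    def with_data(self, data: np.ndarray) -> "DwiStack":
        """Copy of this stack with ``data`` replaced (labels/metadata kept)."""
        return DwiStack(
            data=data,
            b_value=self.b_value,
            rep_labels=list(self.rep_labels),
            voxel_size=self.voxel_size,
        )


@dataclass
class AveragedVolume:
    """A repetition-combined DW image, one 2D image per slice.

    ``method`` records how the combination was done: ``"standard"`` for the
    plain arithmetic mean of magnitudes, ``"proposed"`` for the spatially
    scaled average.  ``fallback`` marks voxels where the scaled average was
    undefined (aggregate weight zero) and the standard mean was used instead.
    """

    data: np.ndarray
    b_value: float
    method: str = "standard"
    fallback: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"AveragedVolume data must be 3D (z, y, x); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("averaged volume must be finite and non-negative")
        if self.method not in ("standard", "proposed"):
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.fallback is not None:
            self.fallback = np.asarray(self.fallback, dtype=bool)
            if self.fallback.shape != self.data.shape:
                raise ValueError("fallback mask shape must match data")


def standard_average(stack: DwiStack) -> AveragedVolume:
    """Arithmetic mean of the magnitudes over the repetition axis.

    This is the conventional multi-average combination: at every voxel the
    N repetition magnitudes are summed and divided by N.
    """
    if stack.n_reps < 1:
        raise ValueError("need at least one repetition")
    return AveragedVolume(
        data=stack.data.mean(axis=1),
        b_value=stack.b_value,
        method="standard",
        voxel_size=stack.voxel_size,
    )
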