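"""Kymograph containers.

A kymograph is a scalar field over arc length *s* (mm, measured from the
apex, ``s = 0``) and time *t* (hours).  Because the organ elongates, the
spatial support grows with time; cells beyond the organ's current length
``L(t)`` carry no data and are masked out.

Fields are stored time-major: ``values[i, j]`` is the value at
``t_grid[i]``, ``s_grid[j]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Units of the supported kymograph quantities.
QUANTITY_UNITS = {
    "orientation": "rad",
    "curvature": "mm^-1",
    "regr": "h^-1",
    "curvature_rate": "mm^-1 h^-1",
    "wave": "arbitrary",
}


@dataclass
class KinematicField:
    """A masked (s, t) kymograph of one kinematic quantity.

    Parameters
    ----------
    s_grid : ndarray
        Uniformly spaced arc-length grid in mm, apex at ``s = 0``.
    t_grid : ndarray
        Strictly increasing time grid in hours.
    values : ndarray, shape (nt, ns)
        Field values; entries outside the support mask are meaningless
        (stored as NaN by convention).
    mask : ndarray of bool, shape (nt, ns)
        True where the cell lies on the organ (``s <= L(t)``) and the
        value is defined.
    quantity : str
        One of :data:`QUANTITY_UNITS`.
    """

    s_grid: np.ndarray
    t_grid: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    quantity: str = "wave"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.t_grid.size, self.s_grid.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(nt, ns) = ({self.t_grid.size}, {self.s_grid.size})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if self.s_grid.size > 1 and np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if self.t_grid.size > 1 and np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if self.quantity not in QUANTITY_UNITS:
            raise ValueError(f"unknown quantity {self.quantity!r}")

    # -- convenience ---------------------------------------------------

    @property
    def ds(self) -> float:
        return float(self.s_grid[1] - self.s_grid[0]) if self.s_grid.size > 1 else np.nan

    @property
    def units(self) -> str:
        return QUANTITY_UNITS[self.quantity]

    @property
    def n_supported(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Values with unsupported cells replaced by NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def supported(self) -> np.ndarray:
        """1-D array of the supported cell values."""
        return self.values[self.mask]

    def support_length(self) -> np.ndarray:
        """Per-frame supported extent L(t) in mm (max supported s)."""
        L = np.full(self.t_grid.size, np.nan)
        for i in range(self.t_grid.size):
            idx = np.flatnonzero(self.mask[i])
            if idx.size:
                L[i] = self.s_grid[idx[-1]]
        return L

    def copy_like(self, values: np.ndarray, quantity: str | None = None,
                  mask: np.ndarray | None = None) -> "KinematicField":
        return KinematicField(
            self.s_grid.copy(), self.t_grid.copy(), np.asarray(values, float),
            self.mask.copy() if mask is None else np.asarray(mask, bool),
            quantity or self.quantity, dict(self.meta),
        )

    def same_grid(self, other: "KinematicField", atol: float = 1e-9) -> bool:
        return (
            self.s_grid.size == other.s_grid.size
            and self.t_grid.size == other.t_grid.size
            and np.allclose(self.s_grid, other.s_grid, atol=atol)
            and np.allclose(self.t_grid, other.t_grid, atol=atol)
        )

    # -- file I/O ------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write the kymograph as a delimited-text matrix plus JSON sidecar.

        Layout: first row is the s grid (first cell blank), each following
        row starts with its time value.  Masked cells are written as NaN.
        The sidecar ``<path>.json`` records quantity, units and the mask
        as per-row run lengths of valid cells.
        """
        path = Path(path)
        header = "," + ",".join(f"{s:.10g}" for s in self.s_grid)
        rows = [header]
        vals = self.masked_values()
        for i, t in enumerate(self.t_grid):
            rows.append(f"{t:.10g}," + ",".join(f"{v:.10g}" for v in vals[i]))
        path.write_text("\n".join(rows) + "\n")
        runs = [_run_lengths(row) for row in self.mask]
        sidecar = {
            "quantity": self.quantity,
            "units": self.units,
            "s_units": "mm",
            "t_units": "h",
            "mask_runs": runs,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read(cls, path: str | Path) -> "KinematicField":
        path = Path(path)
        raw = np.genfromtxt(path, delimiter=",", dtype=float)
        s_grid = raw[0, 1:]
        t_grid = raw[1:, 0]
        values = raw[1:, 1:]
        sidecar_path = path.with_suffix(path.suffix + ".json")
        quantity, meta = "wave", {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            quantity = sidecar.get("quantity", "wave")
            meta = sidecar.get("meta", {})
            mask = np.array(
                [_runs_to_mask(r, s_grid.size) for r in sidecar["mask_runs"]]
            )
        else:
            mask = np.isfinite(values)
        return cls(s_grid, t_grid, values, mask, quantity, meta)


def _run_lengths(row: np.ndarray) -> list[list[int]]:
    """[start, length] runs of True in a boolean row."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], row.astype(int), [0]])))
    for a, b in zip(idx[::2], idx[1::2]):
        runs.append([int(a), int(b - a)])
    return runs


def _runs_to_mask(runs: list[list[int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, ln in runs:
        mask[a : a + ln] = True
    return mask
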