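"""Adhesion-map I/O, quadrant decomposition and quality control.

An :class:`AdhesionMap` is a rectangular raster of AFM pull-off (adhesion)
forces recorded over a cell surface.  Values are stored in nanoNewtons and
lateral pixel spacing in nanometers; those units are fixed at load time
because the downstream texture parameters mix force and length dimensions
and therefore depend on the unit convention.

Maps are exchanged in two plain formats:

* ``matrix_txt`` — a whitespace-separated numeric matrix preceded by
  ``#``-prefixed header lines of ``key=value`` pairs (keys: ``scan_nm``,
  ``units``, ``cell_id``, ``class``).
* ``tiff`` — a single-channel 32-bit float TIFF with the same keys in a
  JSON sidecar file (``<path>.json``).

Pixel-spacing convention: a scan of physical width *w* sampled at *N*
columns has ``dx = w / (N - 1)`` (sample-point spacing).  Row index is *y*,
column index is *x*, origin at the top-left corner.

Each full scan is split into four equal quadrants which are analysed
independently; a mean-vs-median consistency check across the four
per-quadrant parameter values flags cells whose quadrants disagree
strongly — the signature of a localized artifact such as a piece of dirt
on the cell surface or on the probe.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical class labels.
PRECANCEROUS = "precancerous"
CANCEROUS = "cancerous"

_HEADER_KEYS = ("scan_nm", "units", "cell_id", "class")


class MapFormatError(ValueError):
    """Raised when a map file cannot be parsed or violates an invariant."""


@dataclass
class AdhesionMap:
    """A single-cell adhesion-force raster.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Adhesion force per pixel, nN.  Row index is y, column index is x.
    dx, dy : float
        Pixel spacing along x and y, nm.
    cell_id : str
        Identifier of the source cell (and, for quadrants, the quadrant).
    class_label : str or None
        ``"precancerous"`` / ``"cancerous"`` when known.
    """

    values: np.ndarray
    dx: float
    dy: float
    cell_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MapFormatError("adhesion map must be a 2-D array")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise MapFormatError(
                f"adhesion map must be at least 2x2, got {self.values.shape}"
            )
        if not (self.dx > 0 and self.dy > 0):
            raise MapFormatError("pixel spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MapFormatError(
                f"non-finite adhesion value at row {bad[0]}, column {bad[1]}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def scan_width_nm(self) -> float:
        """Physical width along x, nm (sample-point convention)."""
        return self.dx * (self.n_cols - 1)

    @property
    def scan_height_nm(self) -> float:
        return self.dy * (self.n_rows - 1)

    def with_values(self, values: np.ndarray) -> "AdhesionMap":
        return replace(self, values=values)


@dataclass
class QuadrantSet:
    """The four non-overlapping quarters of a parent map.

    Quadrant indices: 0 = top-left, 1 = top-right, 2 = bottom-left,
    3 = bottom-right (row-major over the 2x2 block layout).
    """

    quadrants: list[AdhesionMap]
    parent_id: str

    def __iter__(self):
        return iter(self.quadrants)

    def __len__(self) -> int:
        return len(self.quadrants)

    def __getitem__(self, i: int) -> AdhesionMap:
        return self.quadrants[i]


@dataclass
class QCReport:
    """Mean-vs-median consistency check over the four quadrant values.

    ``relative_difference[p] = |mean - median| / |median|`` of the four
    per-quadrant values of parameter ``p``; infinite when the median is
    zero but the mean is not.  ``flag`` is ``"review"`` as soon as any
    parameter exceeds the 50 % threshold, else ``"pass"``.
    """

    mean: dict[str, float]
    median: dict[str, float]
    relative_difference: dict[str, float]
    flag: str
    failed_parameters: list[str] = field(default_factory=list)
    excluded_quadrants: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "flag": self.flag,
            "failed_parameters": list(self.failed_parameters),
            "excluded_quadrants": list(self.excluded_quadrants),
            "mean": dict(self.mean),
            "median": dict(self.median),
            "relative_difference": {
                k: (v if math.isfinite(v) else "inf")
                for k, v in self.relative_difference.items()
            },
        }


# ---------------------------------------------------------------------------
# reading / writing


def _parse_header(lines: Iterable[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def _map_from_grid(grid: np.ndarray, meta: Mapping[str, str], path: Path) -> AdhesionMap:
    if "scan_nm" not in meta:
        raise MapFormatError(f"{path}: missing 'scan_nm' spacing metadata")
    units = meta.get("units", "nN")
    if units not in ("nN",):
        raise MapFormatError(f"{path}: unsupported units {units!r}; expected nN")
    scan_nm = float(meta["scan_nm"])
    if scan_nm <= 0:
        raise MapFormatError(f"{path}: scan_nm must be positive")
    n_rows, n_cols = grid.shape
    dx = scan_nm / (n_cols - 1)
    dy = scan_nm / (n_rows - 1)
    return AdhesionMap(
        values=grid,
        dx=dx,
        dy=dy,
        cell_id=meta.get("cell_id", path.stem),
        class_label=meta.get("class") or None,
    )


def read_map(path: str | Path, format: str | None = None) -> AdhesionMap:
    """Read one adhesion map from ``matrix_txt`` or ``tiff``.

    The format is inferred from the file suffix when not given.  Values
    are normalized to nN and spacing to nm on load.
    """
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "matrix_txt"

    if format == "matrix_txt":
        header: list[str] = []
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("#"):
                header.append(line)
        meta = _parse_header(header)
        try:
            grid = np.loadtxt(path, comments="#", ndmin=2)
        except ValueError as exc:
            raise MapFormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
        if not np.all(np.isfinite(grid)):
            bad = np.argwhere(~np.isfinite(grid))[0]
            raise MapFormatError(
                f"{path}: non-finite value at matrix row {bad[0]}, column {bad[1]}"
            )
        return _map_from_grid(grid, meta, path)

    if format == "tiff":
        import tifffile

        grid = np.asarray(tifffile.imread(path), dtype=float)
        if grid.ndim != 2:
            raise MapFormatError(f"{path}: expected a single-channel image")
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise MapFormatError(f"{path}: missing metadata sidecar {sidecar}")
        meta = {k: str(v) for k, v in json.loads(sidecar.read_text()).items()}
        if not np.all(np.isfinite(grid)):
            bad = np.argwhere(~np.isfinite(grid))[0]
            raise MapFormatError(
                f"{path}: non-finite value at row {bad[0]}, column {bad[1]}"
            )
        return _map_from_grid(grid, meta, path)

    raise MapFormatError(f"unknown map format {format!r}")


def write_map(amap: AdhesionMap, path: str | Path, format: str | None = None) -> Path:
    """Write a map in ``matrix_txt`` or ``tiff`` form (with JSON sidecar).

    The inverse of :func:`read_map`: a write/read round trip reproduces
    values to full stored precision and metadata exactly.
    """
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "matrix_txt"

    meta = {
        "scan_nm": repr(amap.scan_width_nm),
        "units": "nN",
        "cell_id": amap.cell_id,
        "class": amap.class_label or "",
    }
    if format == "matrix_txt":
        with open(path, "w") as fh:
            for key in _HEADER_KEYS:
                fh.write(f"# {key}={meta[key]}\n")
            np.savetxt(fh, amap.values, fmt="%.17g")
    elif format == "tiff":
        import tifffile

        tifffile.imwrite(path, amap.values.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=1))
    else:
        raise MapFormatError(f"unknown map format {format!r}")
    return path


# ---------------------------------------------------------------------------
# quadrants


def split_quadrants(amap: AdhesionMap) -> QuadrantSet:
    """Split a map into its four equal quadrants.

    A 512x512 scan of 10x10 um^2 yields four 256x256 quadrants of
    5x5 um^2 each.  Dimensions must be even; pixel spacing is inherited.
    """
    n_rows, n_cols = amap.values.shape
    if n_rows % 2 or n_cols % 2:
        raise MapFormatError(
            f"quadrant split requires even dimensions, got {n_rows}x{n_cols}"
        )
    hr, hc = n_rows // 2, n_cols // 2
    blocks = [
        amap.values[:hr, :hc],
        amap.values[:hr, hc:],
        amap.values[hr:, :hc],
        amap.values[hr:, hc:],
    ]
    quadrants = [
        AdhesionMap(
            values=block.copy(),
            dx=amap.dx,
            dy=amap.dy,
            cell_id=f"{amap.cell_id}/q{i}",
            class_label=amap.class_label,
        )
        for i, block in enumerate(blocks)
    ]
    return QuadrantSet(quadrants=quadrants, parent_id=amap.cell_id)


def reassemble_quadrants(qs: QuadrantSet) -> np.ndarray:
    """Tile the four quadrants back into the parent grid (test utility)."""
    q = [m.values for m in qs.quadrants]
    return np.block([[q[0], q[1]], [q[2], q[3]]])


# ---------------------------------------------------------------------------
# quality control


def _relative_difference(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(np.mean(arr))
    median = float(np.median(arr))
    if median == 0.0:
        rel = 0.0 if mean == 0.0 else math.inf
    else:
        rel = abs(mean - median) / abs(median)
    return mean, median, rel


def qc_check(
    quadrant_values: Mapping[str, Sequence[float]],
    threshold: float = 0.5,
    auto_exclude: bool = False,
    max_exclusions: int = 2,
) -> QCReport:
    """Flag cells whose four quadrant parameter values are inconsistent.

    For each parameter the relative difference ``|mean - median| /
    |median|`` over the four quadrants is compared against ``threshold``
    (default 50 %).  Any exceedance flags the cell for review.  With
    ``auto_exclude`` the single quadrant deviating most from the median
    of the other three (for the worst failing parameter) is dropped, the
    check repeated, at most ``max_exclusions`` times — a reproducible
    stand-in for the manual inspection of flagged maps.
    """
    values = {p: np.asarray(v, dtype=float) for p, v in quadrant_values.items()}
    for p, arr in values.items():
        if arr.shape != (4,):
            raise ValueError(f"parameter {p!r}: expected exactly four quadrant values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"parameter {p!r}: non-finite quadrant value")

    retained = [0, 1, 2, 3]
    excluded: list[int] = []

    def evaluate(idx: list[int]):
        mean_d, median_d, rel_d, failed = {}, {}, {}, []
        for p, arr in values.items():
            mean, median, rel = _relative_difference(arr[idx])
            mean_d[p], median_d[p], rel_d[p] = mean, median, rel
            if rel > threshold:
                failed.append(p)
        return mean_d, median_d, rel_d, failed

    mean_d, median_d, rel_d, failed = evaluate(retained)

    if auto_exclude:
        rounds = 0
        while failed and rounds < max_exclusions and len(retained) > 1:
            worst_param = max(failed, key=lambda p: rel_d[p])
            arr = values[worst_param]
            # deviation of each retained quadrant from the median of the others
            dev = {}
            for q in retained:
                others = [r for r in retained if r != q]
                dev[q] = abs(arr[q] - float(np.median(arr[others])))
            drop = max(retained, key=lambda q: dev[q])
            retained.remove(drop)
            excluded.append(drop)
            rounds += 1
            mean_d, median_d, rel_d, failed = evaluate(retained)

    flag = "review" if failed else "pass"
    return QCReport(
        mean=mean_d,
        median=median_d,
        relative_difference=rel_d,
        flag=flag,
        failed_parameters=sorted(failed),
        excluded_quadrants=excluded,
    )


def aggregate_cell(
    quadrant_params: Sequence[Mapping[str, float]],
    retained: Sequence[int] | None = None,
) -> dict[str, float]:
    """Average per-quadrant parameters into one record per cell.

    ``retained`` selects the quadrants that survive QC (all four by
    default).  Raises when nothing is retained; the caller excludes the
    cell and logs the reason.
    """
    if retained is None:
        retained = range(len(quadrant_params))
    retained = list(retained)
    if not retained:
        raise ValueError("no retained quadrants: cell must be excluded")
    keys = quadrant_params[0].keys()
    out = {
        k: float(np.mean([quadrant_params[i][k] for i in retained])) for k in keys
    }
    out["n_quadrants"] = len(retained)
    return out
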