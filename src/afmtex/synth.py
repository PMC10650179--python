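"""Synthetic adhesion-map cohorts with prescribed spectral structure.

Real adhesion maps of epithelial cells show an approximately power-law
direction-averaged Fourier amplitude, ``A(Q) ~ Q^b``, with different
behaviour for features larger and smaller than ~300 nm.  The generator
realises exactly that statistical model by inverse-FFT spectral
synthesis: Gaussian white noise is shaped in Fourier space by a
two-segment power-law amplitude profile (continuous at the crossover
frequency), transformed back, rescaled to a target RMS in nN, offset to
a mean adhesion and clipped at zero (adhesion force is nonnegative).

Cohorts of two classes are produced by drawing each cell's spectral
exponents and amplitude from class templates with per-cell jitter, so
that downstream feature extraction and classification can be exercised
end to end without instrument data.  Optional localized Gaussian bumps
emulate dirt artifacts for testing the quadrant QC rule.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_qc import CANCEROUS, PRECANCEROUS, AdhesionMap, write_map
from .surfparams import Q_SPLIT_DEFAULT


def _child_seed(*keys: int) -> int:
    """Deterministic 31-bit child seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass
class SpectralSurfaceSpec:
    """Recipe for one synthetic map.

    Parameters
    ----------
    grid_n : int
        Pixels per side (power of two, >= 16).
    scan_size : float
        Physical side length, nm.
    b_low, b_high : float
        Spectral exponents below / above the crossover ``q_split``.
    q_split : float
        Crossover spatial frequency, nm^-1.
    mean_adhesion, amplitude_rms : float
        Offset and RMS roughness of the adhesion values, nN.
    seed : int
        Seed of the per-map random phases.
    """

    grid_n: int = 512
    scan_size: float = 10_000.0
    b_low: float = -0.5
    b_high: float = -0.9
    q_split: float = Q_SPLIT_DEFAULT
    mean_adhesion: float = 1.0
    amplitude_rms: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        n = self.grid_n
        if n < 16 or (n & (n - 1)) != 0:
            raise ValueError(f"grid_n must be a power of 2 >= 16, got {n}")
        if not self.scan_size > 0:
            raise ValueError("scan_size must be positive")
        if self.amplitude_rms < 0:
            raise ValueError("amplitude_rms must be nonnegative")
        if not (math.isfinite(self.b_low) and math.isfinite(self.b_high)):
            raise ValueError("spectral exponents must be finite")
        if not self.q_split > 0:
            raise ValueError("q_split must be positive")


@dataclass
class ArtifactSpec:
    """A localized smooth bump emulating a piece of dirt on the surface.

    ``center`` is an (x, y) position in nm, or ``"random"`` to place the
    bump uniformly inside the scan with a margin of one radius.
    """

    radius: float
    amplitude: float
    center: tuple[float, float] | str = "random"


@dataclass
class CohortSpec:
    """A two-class cohort of synthetic maps.

    Class A is precancerous (HPV-immortalized), class B cancerous; the
    default counts 108 / 64 match a realistic screening-study cohort.
    Per-cell Gaussian ``jitter`` (one standard deviation) is applied to
    ``b_low``, ``b_high`` and ``amplitude_rms`` of the class template.
    """

    n_class_a: int = 108
    n_class_b: int = 64
    spec_a: SpectralSurfaceSpec = field(
        default_factory=lambda: SpectralSurfaceSpec(b_low=-0.5, b_high=-0.9)
    )
    spec_b: SpectralSurfaceSpec = field(
        default_factory=lambda: SpectralSurfaceSpec(b_low=-0.8, b_high=-1.2)
    )
    jitter: float = 0.1
    artifact_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_class_a < 1 or self.n_class_b < 1:
            raise ValueError("class counts must be >= 1")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        self.spec_a.validate()
        self.spec_b.validate()


def generate_map(spec: SpectralSurfaceSpec, cell_id: str = "synthetic") -> AdhesionMap:
    """Synthesize one map by inverse-FFT spectral shaping.

    The Fourier amplitude profile is ``Q^b_low`` below ``q_split`` and a
    continuously matched ``Q^b_high`` branch above it; phases come from
    Gaussian white noise, so the field is (before clipping) Gaussian
    with the requested radially averaged amplitude spectrum.  Output is
    deterministic for a fixed seed.
    """
    spec.validate()
    n = spec.grid_n
    dx = spec.scan_size / (n - 1)
    if spec.amplitude_rms == 0:
        values = np.full((n, n), spec.mean_adhesion)
        return AdhesionMap(values=values, dx=dx, dy=dx, cell_id=cell_id)

    rng = np.random.default_rng(spec.seed)
    white = rng.normal(size=(n, n))
    q1 = np.fft.fftfreq(n, d=dx)
    q = np.sqrt(q1[None, :] ** 2 + q1[:, None] ** 2)

    profile = np.zeros_like(q)
    nz = q > 0
    low = nz & (q < spec.q_split)
    high = q >= spec.q_split
    profile[low] = q[low] ** spec.b_low
    # continuity at the crossover: match the two power laws there
    c_high = spec.q_split ** (spec.b_low - spec.b_high)
    profile[high] = c_high * q[high] ** spec.b_high

    shaped = np.fft.ifft2(np.fft.fft2(white) * profile).real
    shaped *= spec.amplitude_rms / shaped.std()
    values = np.clip(shaped + spec.mean_adhesion, 0.0, None)
    return AdhesionMap(values=values, dx=dx, dy=dx, cell_id=cell_id)


def inject_artifact(
    amap: AdhesionMap, artifact: ArtifactSpec, seed: int = 0
) -> AdhesionMap:
    """Add a localized Gaussian bump to a copy of the map.

    The bump has peak ``amplitude`` (nN) and Gaussian sigma of half the
    ``radius``, so it is essentially confined within ``radius`` of the
    centre.  A zero amplitude returns the map unchanged.
    """
    if artifact.radius <= 0:
        raise ValueError("artifact radius must be positive")
    scan_x, scan_y = amap.scan_width_nm, amap.scan_height_nm
    if 2 * artifact.radius > min(scan_x, scan_y):
        raise ValueError(
            f"artifact diameter {2 * artifact.radius:g} nm exceeds the scan"
        )
    if artifact.amplitude == 0:
        return amap.with_values(amap.values.copy())

    if artifact.center == "random":
        rng = np.random.default_rng(seed)
        r = artifact.radius
        cx = rng.uniform(r, scan_x - r)
        cy = rng.uniform(r, scan_y - r)
    else:
        cx, cy = artifact.center
        if not (0 <= cx <= scan_x and 0 <= cy <= scan_y):
            raise ValueError("artifact centre lies outside the scan")

    x = np.arange(amap.n_cols) * amap.dx
    y = np.arange(amap.n_rows) * amap.dy
    d2 = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2
    sigma = artifact.radius / 2.0
    bump = artifact.amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return amap.with_values(amap.values + bump)


def generate_cohort(spec: CohortSpec) -> list[AdhesionMap]:
    """Generate the labelled two-class cohort.

    One cohort seed deterministically spawns independent per-cell seeds
    (for jitter, phases and artifact placement), so a cohort is
    reproducible as a whole while cells remain independent draws.
    """
    spec.validate()
    maps: list[AdhesionMap] = []
    plan = [(PRECANCEROUS, spec.spec_a, "a", spec.n_class_a),
            (CANCEROUS, spec.spec_b, "b", spec.n_class_b)]
    index = 0
    for label, template, tag, count in plan:
        for i in range(count):
            jit_rng = np.random.default_rng(_child_seed(spec.seed, index, 0))
            cell_spec = replace(
                template,
                b_low=template.b_low + spec.jitter * jit_rng.standard_normal(),
                b_high=template.b_high + spec.jitter * jit_rng.standard_normal(),
                amplitude_rms=max(
                    template.amplitude_rms
                    + spec.jitter * jit_rng.standard_normal(),
                    0.1 * template.amplitude_rms,
                ),
                seed=_child_seed(spec.seed, index, 1),
            )
            amap = generate_map(cell_spec, cell_id=f"cell_{tag}{i:03d}")
            amap.class_label = label
            if spec.artifact_prob > 0:
                art_rng = np.random.default_rng(_child_seed(spec.seed, index, 2))
                if art_rng.uniform() < spec.artifact_prob:
                    artifact = ArtifactSpec(
                        radius=template.scan_size / 10.0,
                        amplitude=10.0 * template.amplitude_rms,
                    )
                    amap = inject_artifact(
                        amap, artifact, seed=_child_seed(spec.seed, index, 3)
                    )
            maps.append(amap)
            index += 1
    return maps


def write_cohort(
    maps: Sequence[AdhesionMap],
    outdir: str | Path,
    format: str = "matrix_txt",
    cohort_seed: int | None = None,
) -> Path:
    """Write one file per cell plus a manifest CSV.

    Manifest columns: ``cell_id, class_label, seed, path``.  Returns the
    manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".tif" if format == "tiff" else ".txt"
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "class_label", "seed", "path"])
        for amap in maps:
            fname = f"{amap.cell_id}{suffix}"
            write_map(amap, outdir / fname, format=format)
            writer.writerow(
                [amap.cell_id, amap.class_label or "", cohort_seed, fname]
            )
    return manifest


def read_cohort(manifest: str | Path) -> list[AdhesionMap]:
    """Read every map listed in a cohort manifest CSV."""
    from .io_qc import read_map

    manifest = Path(manifest)
    maps = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            amap = read_map(manifest.parent / row["path"])
            amap.cell_id = row["cell_id"]
            amap.class_label = row["class_label"] or None
            maps.append(amap)
    return maps
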