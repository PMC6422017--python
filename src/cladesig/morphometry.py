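"""Geometric morphometrics: TPS input, centroid size, GPA and shape PCA.

This is the upstream quantification the signal tests consume: raw 2-D
landmark configurations are superimposed by Generalized Procrustes
Analysis (translation to centroid, scaling to unit centroid size,
iterative rotation to the mean shape, reflections disallowed) and the
aligned coordinates are summarized by principal components.  Centroid
size is recorded before scaling and analysed separately as the size
variable.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapes",
    "ShapePCA",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa",
    "shape_pca",
]


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen: k landmarks in 2-D, consistent units within a dataset."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
            raise ValueError(
                f"{self.specimen_id}: coords must be (k >= 3, 2), got {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class AlignedShapes:
    """GPA output: each configuration centered at the origin, unit size."""

    aligned: np.ndarray  # (s, k, 2)
    centroid_sizes: np.ndarray  # (s,) sizes of the raw inputs
    mean_shape: np.ndarray  # (k, 2)
    specimen_ids: tuple[str, ...]
    iterations: int
    converged: bool


@dataclass(frozen=True)
class ShapePCA:
    scores: np.ndarray  # (s, c)
    explained_fraction: np.ndarray  # (c,)
    loadings: np.ndarray  # (c, 2k)
    mean_flat: np.ndarray  # (2k,)


# ----------------------------------------------------------------------
# TPS format
# ----------------------------------------------------------------------


def read_tps(source) -> list[LandmarkConfiguration]:
    """Read a TPS file (LM=, coordinate lines, ID=/IMAGE=/SCALE= keys).

    ``source`` is a path or a text file object.  SCALE is applied
    multiplicatively when present; the specimen id comes from ID, then
    IMAGE (basename without extension), else the 0-based record index.
    All records must share the same landmark count.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i, record = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"record {record}: expected LM=, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ValueError(f"record {record}: bad LM count in {line!r}") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break  # a keyword line arrived before k coordinates
            parts = row.split()
            if len(parts) != 2:
                raise ValueError(f"record {record}: bad coordinate line {row!r}")
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(coords) != k:
            raise ValueError(
                f"record {record}: LM={k} but found {len(coords)} coordinate lines"
            )
        spec_id, image, scale = None, None, None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            key, _, value = row.partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "IMAGE":
                image = os.path.splitext(os.path.basename(value.strip()))[0]
            elif key == "SCALE":
                scale = float(value)
            i += 1
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        name = spec_id if spec_id else (image if image else str(record))
        configs.append(LandmarkConfiguration(specimen_id=name, coords=arr))
        record += 1

    if not configs:
        raise ValueError("no TPS records found")
    ks = {c.coords.shape[0] for c in configs}
    if len(ks) > 1:
        raise ValueError(f"inconsistent landmark counts across records: {sorted(ks)}")
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS records with ID= lines."""
    out = io.StringIO()
    for c in configs:
        out.write(f"LM={c.coords.shape[0]}\n")
        for x, y in c.coords:
            out.write(f"{x:.10g} {y:.10g}\n")
        out.write(f"ID={c.specimen_id}\n")
    text = out.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ----------------------------------------------------------------------
# Superimposition
# ----------------------------------------------------------------------


def centroid_size(config) -> float:
    """CS = sqrt(sum of squared landmark distances to the centroid)."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise ValueError("centroid size requires >= 2 landmarks")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _rotation_to(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimizing ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes Analysis of 2-D configurations.

    Each configuration is translated to centroid origin and scaled to
    unit centroid size, then iteratively rotated to the current mean
    shape (itself re-scaled to unit size each round) until the mean
    changes by less than ``tol`` in Frobenius norm.
    """
    if len(configs) < 2:
        raise ValueError("GPA requires >= 2 configurations")
    ks = {c.coords.shape[0] for c in configs}
    if len(ks) > 1:
        raise ValueError(f"landmark counts differ: {sorted(ks)}")
    sizes = []
    shapes = []
    for c in configs:
        cs = centroid_size(c)
        if cs == 0:
            raise ValueError(f"degenerate configuration (zero centroid size): {c.specimen_id}")
        sizes.append(cs)
        shapes.append((c.coords - c.coords.mean(axis=0)) / cs)
    X = np.array(shapes)

    # start from the average of the scaled configs so that GPA output is a
    # fixed point (idempotence); fall back to the first specimen if input
    # orientations cancel out
    mean = X.mean(axis=0)
    norm = np.sqrt((mean**2).sum())
    mean = mean / norm if norm > 1e-6 else X[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for s in range(X.shape[0]):
            X[s] = X[s] @ _rotation_to(X[s], mean)
        new_mean = X.mean(axis=0)
        new_mean = new_mean / np.sqrt((new_mean**2).sum())
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            converged = True
            break
        mean = new_mean
    return AlignedShapes(
        aligned=X,
        centroid_sizes=np.asarray(sizes),
        mean_shape=X.mean(axis=0),
        specimen_ids=tuple(c.specimen_id for c in configs),
        iterations=iterations,
        converged=converged,
    )


def shape_pca(aligned: AlignedShapes) -> ShapePCA:
    """PCA of the covariance of flattened Procrustes coordinates."""
    s = aligned.aligned.shape[0]
    if s < 3:
        raise ValueError(f"shape PCA requires >= 3 specimens, got {s}")
    flat = aligned.aligned.reshape(s, -1)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * sv
    total = (sv**2).sum()
    explained = sv**2 / total if total > 0 else np.zeros_like(sv)
    return ShapePCA(scores=scores, explained_fraction=explained, loadings=vt, mean_flat=mean_flat)
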