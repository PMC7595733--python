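"""Landmark-based similarity transforms between imaging coordinate frames.

Locating an EM sub-ROI inside a whole-heart micro-CT scan is a chain of
frame-to-frame mappings (micro-CT ← semithin section ← EM overview ← sub-ROI)
estimated from corresponding landmarks such as blood vessels and trabeculae.
Sections rotate, translate and shrink approximately isotropically, so each
link is a similarity transform q ≈ s·R·p + t fitted by least squares
(the closed-form SVD / Umeyama solution); a full affine fit is available
behind a flag for sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SimilarityMap:
    """q = scale · R · p + t between two named frames."""

    scale: float
    rotation: np.ndarray          # (d, d) orthonormal
    translation: np.ndarray       # (d,)
    source_frame: str
    target_frame: str
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        d = self.rotation.shape[0]
        if self.rotation.shape != (d, d) or self.translation.shape != (d,):
            raise ValueError("rotation/translation dimensions disagree")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(d), atol=1e-8):
            raise ValueError("rotation must be orthonormal")

    @property
    def ndim(self) -> int:
        return self.rotation.shape[0]

    @classmethod
    def identity(cls, ndim: int, source: str = "src",
                 target: str = "dst") -> "SimilarityMap":
        return cls(1.0, np.eye(ndim), np.zeros(ndim), source, target)

    @property
    def rotation_angle_deg(self) -> float:
        """Rotation angle (2D maps only)."""
        if self.ndim != 2:
            raise ValueError("rotation angle is only scalar in 2D")
        return float(np.degrees(np.arctan2(self.rotation[1, 0],
                                           self.rotation[0, 0])))

    def inverse(self) -> "SimilarityMap":
        rt = self.rotation.T
        return SimilarityMap(
            1.0 / self.scale, rt, -rt @ self.translation / self.scale,
            self.target_frame, self.source_frame, self.residual_rms)

    def compose(self, inner: "SimilarityMap") -> "SimilarityMap":
        """self ∘ inner: apply ``inner`` first, then ``self``.

        Requires ``inner.target_frame == self.source_frame``.
        """
        if inner.target_frame != self.source_frame:
            raise ValueError(
                f"cannot compose: inner targets {inner.target_frame!r} but "
                f"outer expects {self.source_frame!r}")
        return SimilarityMap(
            self.scale * inner.scale,
            self.rotation @ inner.rotation,
            self.scale * self.rotation @ inner.translation + self.translation,
            inner.source_frame, self.target_frame,
            max(self.residual_rms, inner.residual_rms))

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "source_frame": self.source_frame,
            "target_frame": self.target_frame,
            "residual_rms": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityMap":
        return cls(d["scale"], np.asarray(d["rotation"]),
                   np.asarray(d["translation"]), d["source_frame"],
                   d["target_frame"], d.get("residual_rms", 0.0))


def estimate_similarity(source: np.ndarray, target: np.ndarray,
                        source_frame: str = "src", target_frame: str = "dst",
                        allow_reflection: bool = False) -> SimilarityMap:
    """Least-squares similarity transform from paired landmarks.

    Solves min Σ‖s·R·p_i + t − q_i‖² in closed form (SVD of the centered
    cross-covariance).  Needs ≥ 2 non-coincident pairs in 2D and ≥ 3
    non-collinear pairs in 3D; degenerate configurations raise with the
    degeneracy named.
    """
    p = np.atleast_2d(np.asarray(source, dtype=float))
    q = np.atleast_2d(np.asarray(target, dtype=float))
    if p.shape != q.shape:
        raise ValueError("source and target landmark arrays differ in shape")
    n, d = p.shape
    if d not in (2, 3):
        raise ValueError("landmarks must be 2D or 3D")
    if n < d:
        raise ValueError(f"need at least {d} landmark pairs in {d}D, got {n}")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    var_p = float((p0 ** 2).sum()) / n
    if var_p == 0:
        raise ValueError("degenerate landmarks: all source points coincide")
    cov = q0.T @ p0 / n
    U, sing, Vt = np.linalg.svd(cov)
    rank = int(np.sum(sing > 1e-12 * max(sing[0], 1e-300)))
    if d == 3 and rank < 2:
        raise ValueError("degenerate landmarks: source points are collinear")
    sgn = np.ones(d)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        sgn[-1] = -1.0
    R = U @ np.diag(sgn) @ Vt
    scale = float((sing * sgn).sum() / var_p)
    if scale <= 0:
        raise ValueError("degenerate landmarks: non-positive scale")
    t = qc - scale * R @ pc
    residual = q - (scale * (R @ p.T).T + t)
    rms = float(np.sqrt((residual ** 2).sum() / (n * d)))  # per coordinate
    return SimilarityMap(scale, R, t, source_frame, target_frame, rms)


def map_points(tmap: SimilarityMap, points: np.ndarray,
               frame: str | None = None) -> np.ndarray:
    """Apply a similarity map to points (N, d) given in the source frame."""
    if frame is not None and frame != tmap.source_frame:
        raise ValueError(
            f"points are in frame {frame!r} but map expects {tmap.source_frame!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != tmap.ndim:
        raise ValueError("point dimensionality does not match the map")
    return tmap.scale * (tmap.rotation @ pts.T).T + tmap.translation


def compose_chain(maps: list[SimilarityMap]) -> SimilarityMap:
    """Compose a chain of maps; ``maps[0]`` is applied first.

    Frames must connect (each map's target is the next map's source);
    a broken chain raises naming the missing link.
    """
    if not maps:
        raise ValueError("empty transform chain")
    combined = maps[0]
    for m in maps[1:]:
        if m.source_frame != combined.target_frame:
            raise ValueError(
                f"broken chain: no link from {combined.target_frame!r} to "
                f"{m.source_frame!r}")
        combined = m.compose(combined)
    return combined


def locate_subroi(maps: list[SimilarityMap],
                  rectangle: np.ndarray) -> np.ndarray:
    """Map a sub-ROI rectangle's corners through a chain into the final frame.

    ``rectangle`` is (4, d) corner coordinates in the first map's source
    frame (for an axis-aligned box, pass its corners); returns the mapped
    polygon, corner order preserved.
    """
    combined = compose_chain(maps)
    corners = np.atleast_2d(np.asarray(rectangle, dtype=float))
    return map_points(combined, corners)


def estimate_affine(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Full least-squares affine fit q = A·p + t (sanity-check alternative).

    Sections deform approximately isotropically, so the similarity model is
    the default; the affine fit is provided to let a user compare residuals
    and detect anisotropic distortion.  Returns (A, t, residual RMS per
    coordinate).
    """
    p = np.atleast_2d(np.asarray(source, dtype=float))
    q = np.atleast_2d(np.asarray(target, dtype=float))
    n, d = p.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} landmark pairs for a {d}D affine fit")
    X = np.hstack([p, np.ones((n, 1))])
    coef, _, rank, _ = np.linalg.lstsq(X, q, rcond=None)
    if rank < d + 1:
        raise ValueError("degenerate landmarks: affine fit is rank-deficient")
    A, t = coef[:d].T, coef[d]
    residual = q - (p @ A.T + t)
    rms = float(np.sqrt((residual ** 2).sum() / (n * d)))
    return A, t, rms


# ---------------------------------------------------------------------------
# landmark CSV schema: frame, x, y[, z], unit


def read_landmarks(path) -> tuple[np.ndarray, str, str]:
    """Read a landmark CSV with explicit frame/unit columns.

    Returns (points, frame, unit); mixed frames or units in one file raise.
    """
    df = pd.read_csv(path)
    required = {"frame", "x", "y", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark file {path} missing columns {sorted(missing)}")
    frames = df["frame"].unique()
    units = df["unit"].unique()
    if len(frames) != 1 or len(units) != 1:
        raise ValueError(f"landmark file {path} mixes frames or units")
    cols = ["x", "y", "z"] if "z" in df.columns and df["z"].notna().all() else ["x", "y"]
    return df[cols].to_numpy(dtype=float), str(frames[0]), str(units[0])
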