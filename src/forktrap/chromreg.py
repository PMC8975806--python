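"""Two-color chromatic channel registration.

Chromatic aberration between the far-red (AF647, reference) and orange
(JF549, moving) detection paths is corrected with a full second-order
polynomial warp solved from a field of pan-spectrum beads imaged in both
channels.  For bead i in the moving channel the design row is

    A[i, j] = x_i**(j // 3) * y_i**(j % 3),  j = 0..8

i.e. the tensor basis [1, y, y^2, x, x*y, x*y^2, x^2, x^2*y, x^2*y^2],
and the mapping coefficients kx, ky solve the linear least-squares system
A @ [kx ky] = [x_ref y_ref].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RegistrationModel",
    "build_design",
    "solve_mapping",
    "apply_mapping",
    "pair_beads",
    "identity_model",
]

#: exponent table (x_power, y_power) for columns j = 0..8
_EXPONENTS = [(j // 3, j % 3) for j in range(9)]


@dataclass
class RegistrationModel:
    """Second-order polynomial mapping from the moving to the reference channel."""

    kx: np.ndarray  # 9 coefficients, column order above
    ky: np.ndarray
    residual_rms: float  # nm, against the reference beads
    n_beads: int

    def __post_init__(self) -> None:
        self.kx = np.asarray(self.kx, dtype=float)
        self.ky = np.asarray(self.ky, dtype=float)
        if self.kx.shape != (9,) or self.ky.shape != (9,):
            raise ValueError("kx and ky must each hold exactly 9 coefficients")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")

    def save(self, path) -> None:
        """20-line plain-text format: 9 kx, 9 ky, residual, bead count."""
        with open(path, "w") as fh:
            for v in self.kx:
                fh.write(f"{float(v)!r}\n")
            for v in self.ky:
                fh.write(f"{float(v)!r}\n")
            fh.write(f"{float(self.residual_rms)!r}\n")
            fh.write(f"{self.n_beads}\n")

    @classmethod
    def load(cls, path) -> "RegistrationModel":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if len(lines) != 20:
            raise ValueError(f"expected 20 lines in registration model file, got {len(lines)}")
        vals = [float(x) for x in lines]
        return cls(
            kx=np.array(vals[:9]),
            ky=np.array(vals[9:18]),
            residual_rms=vals[18],
            n_beads=int(vals[19]),
        )


def identity_model() -> RegistrationModel:
    kx = np.zeros(9)
    ky = np.zeros(9)
    kx[3] = 1.0  # x term
    ky[1] = 1.0  # y term
    return RegistrationModel(kx=kx, ky=ky, residual_rms=0.0, n_beads=0)


def build_design(points: np.ndarray) -> np.ndarray:
    """Design matrix (n x 9) of second-order monomials for (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in design points")
    x, y = pts[:, 0], pts[:, 1]
    cols = [x**px * y**py for px, py in _EXPONENTS]
    return np.column_stack(cols)


def _shift_matrix(mx: float, my: float) -> np.ndarray:
    """Expansion of centered monomials (x-mx)^a (y-my)^b onto the original basis.

    Returns M with column j the original-basis coefficients of centered
    monomial j, so that k_original = M @ k_centered.
    """
    from math import comb

    M = np.zeros((9, 9))
    idx = {exp: j for j, exp in enumerate(_EXPONENTS)}
    for j, (a, b) in enumerate(_EXPONENTS):
        for p in range(a + 1):
            for q in range(b + 1):
                coef = comb(a, p) * comb(b, q) * (-mx) ** (a - p) * (-my) ** (b - q)
                M[idx[(p, q)], j] += coef
    return M


def solve_mapping(src: np.ndarray, dst: np.ndarray) -> RegistrationModel:
    """Least-squares second-order warp taking `src` beads onto `dst` beads.

    Coordinates are mean-centered before solving to condition the normal
    equations; the returned coefficients are re-expanded into the original
    (uncentered) frame, so apply_mapping consumes raw nm coordinates.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape:
        raise ValueError("src and dst bead lists must have identical shape")
    n = src.shape[0]
    if n < 9:
        raise ValueError(f"need >= 9 paired beads to solve a 9-coefficient warp, got {n}")

    mx, my = src[:, 0].mean(), src[:, 1].mean()
    scale = float(max(src[:, 0].std(), src[:, 1].std(), 1.0))
    A = build_design((src - [mx, my]) / scale)
    rank = np.linalg.matrix_rank(A)
    if rank < 9:
        raise ValueError(
            f"degenerate bead layout: design matrix rank {rank} < 9 "
            "(beads collinear or otherwise non-generic)"
        )
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    fitted = A @ coef
    # rms per coordinate, so a bead noise of sd s reports residual_rms ~= s
    residual_rms = float(np.sqrt(np.mean((fitted - dst) ** 2)))

    # undo the coordinate scaling, then re-expand around the origin
    powers = np.array([px + py for px, py in _EXPONENTS], dtype=float)
    coef = coef / scale**powers[:, None]
    M = _shift_matrix(mx, my)
    kx = M @ coef[:, 0]
    ky = M @ coef[:, 1]
    return RegistrationModel(kx=kx, ky=ky, residual_rms=residual_rms, n_beads=n)


def warp_points(points: np.ndarray, kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
    """Evaluate the polynomial warp at (x, y) points."""
    A = build_design(points)
    return np.column_stack([A @ np.asarray(kx, float), A @ np.asarray(ky, float)])


def apply_mapping(records: pd.DataFrame, model: RegistrationModel) -> pd.DataFrame:
    """Map localization records into the reference channel frame.

    Replaces x_nm/y_nm by the warped coordinates; all other columns pass
    through untouched.
    """
    out = records.copy()
    pts = out[["x_nm", "y_nm"]].to_numpy(dtype=float)
    warped = warp_points(pts, model.kx, model.ky)
    out["x_nm"] = warped[:, 0]
    out["y_nm"] = warped[:, 1]
    return out


def pair_beads(
    src: np.ndarray, dst: np.ndarray, gate_nm: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor bead pairing across channels within a distance gate.

    Each dst bead is matched to its nearest src bead; ambiguous (shared)
    matches keep the closer pair.  Returns matched (src, dst) arrays.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    tree = cKDTree(src)
    dist, idx = tree.query(dst, distance_upper_bound=gate_nm)
    ok = np.isfinite(dist)
    best: dict[int, tuple[float, int]] = {}
    for j in np.flatnonzero(ok):
        i = int(idx[j])
        if i not in best or dist[j] < best[i][0]:
            best[i] = (dist[j], j)
    src_idx = np.array(sorted(best), dtype=int)
    dst_idx = np.array([best[i][1] for i in src_idx], dtype=int)
    return src[src_idx], dst[dst_idx]
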