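"""Spot detection and multi-fluorophore MLE localization on sCMOS frames.

The detection stage follows the DAOSTORM recipe: each frame is filtered with
a small and a large Gaussian kernel (defaults 143 and 286 nm), both weighted
by the inverse of the per-pixel readout variance, and candidates are local
maxima of the difference image.  A 9x9 crop around each candidate is then
fit with one or more pixel-integrated 2D Gaussian PSFs by maximum-likelihood
estimation under the variance-stabilized sCMOS model: photon-converted data
are augmented with ``variance / gain^2`` pseudo-counts so the Poisson
likelihood absorbs the Gaussian read noise.  The number of emitters per crop
is chosen by a push-and-pull rule (add emitters while the BIC improves,
remove any whose removal improves it).  Per-emitter precision is the
Cramer-Rao lower bound of the same likelihood; the distribution of CRLB
values is summarized by the location of a skew-Gaussian fit, and
localizations recurring in consecutive frames within ``merge_factor`` times
that precision are averaged into single blink events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.special import erf

from .camera import CameraModel

__all__ = [
    "DetectionConfig",
    "detect_candidates",
    "fit_crop",
    "crlb_precision",
    "localize_stack",
    "summarize_precision",
    "merge_blinks",
    "render",
]

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "background", "crlb_nm", "channel", "n_merged"]


@dataclass
class DetectionConfig:
    sigma_small_nm: float = 143.0
    sigma_big_nm: float = 286.0
    crop_size: int = 9
    threshold_sd: float = 4.0
    merge_factor: float = 2.5
    psf_sigma_px: float = 1.3
    max_emitters: int = 3

    def __post_init__(self) -> None:
        if self.sigma_small_nm >= self.sigma_big_nm:
            raise ValueError("sigma_small must be below sigma_big")
        if self.crop_size % 2 == 0:
            raise ValueError("crop_size must be odd")


def detect_candidates(
    frame: np.ndarray, camera: CameraModel, cfg: DetectionConfig | None = None
) -> np.ndarray:
    """Candidate emitter pixels from a variance-weighted difference of Gaussians.

    Returns an (n, 2) array of (row, col) pixel indices.  Pixels closer to
    the border than half a crop are excluded so every candidate yields a
    full crop.
    """
    cfg = cfg or DetectionConfig()
    if frame.shape != camera.shape:
        raise ValueError("frame shape does not match calibration maps")
    photons = (frame - camera.offset_map) / camera.gain_map
    w = camera.gain_map**2 / camera.variance_map  # inverse variance in photon units

    def smooth(sig_nm):
        s = sig_nm / camera.pixel_size
        num = ndimage.gaussian_filter(photons * w, s)
        den = ndimage.gaussian_filter(w, s)
        return num / den

    dog = smooth(cfg.sigma_small_nm) - smooth(cfg.sigma_big_nm)
    noise_sd = 1.4826 * np.median(np.abs(dog - np.median(dog)))
    thresh = cfg.threshold_sd * noise_sd
    footprint = np.ones((3, 3), bool)
    is_max = (dog == ndimage.maximum_filter(dog, footprint=footprint)) & (dog > thresh)
    half = cfg.crop_size // 2
    is_max[:half, :] = is_max[-half:, :] = False
    is_max[:, :half] = is_max[:, -half:] = False
    return np.argwhere(is_max)


# ---------------------------------------------------------------------------
# MLE crop fitting
# ---------------------------------------------------------------------------

def _psf_1d(grid, center, sigma):
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((grid + 0.5 - center) / s) - erf((grid - 0.5 - center) / s))


def _dpsf_1d(grid, center, sigma):
    s = np.sqrt(2.0) * sigma
    return -(
        np.exp(-((grid + 0.5 - center) ** 2) / s**2)
        - np.exp(-((grid - 0.5 - center) ** 2) / s**2)
    ) / (np.sqrt(np.pi) * s)


def _model_image(params, size, sigma, pseudo):
    """Expected augmented-photon image: bg + emitters + pseudo-counts."""
    bg = params[0]
    mu = np.full((size, size), bg, dtype=float) + pseudo
    grid = np.arange(size)
    for k in range((len(params) - 1) // 3):
        x, y, n = params[1 + 3 * k : 4 + 3 * k]
        mu += n * np.outer(_psf_1d(grid, y, sigma), _psf_1d(grid, x, sigma))
    return mu


def _nll(params, data_aug, size, sigma, pseudo):
    mu = np.clip(_model_image(params, size, sigma, pseudo), 1e-9, None)
    return float(np.sum(mu - data_aug * np.log(mu)))


def _fit_k(data_aug, size, sigma, pseudo, inits, bg0):
    """Fit a fixed number of emitters; inits is a list of (x, y, n)."""
    p0 = [max(bg0, 1e-3)]
    bounds = [(0.0, None)]
    for x, y, n in inits:
        p0 += [x, y, max(n, 10.0)]
        bounds += [(-1.0, size), (-1.0, size), (1.0, None)]
    res = optimize.minimize(
        _nll,
        np.array(p0),
        args=(data_aug, size, sigma, pseudo),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 400},
    )
    return res


def fit_crop(
    crop: np.ndarray,
    camera: CameraModel,
    max_emitters: int = 3,
    psf_sigma_px: float = 1.3,
):
    """Maximum-likelihood multi-emitter fit of one square crop.

    ``camera`` must carry the calibration sub-maps of the same crop.
    Returns (emitters, background, loglik) where ``emitters`` is a list of
    (x_px, y_px, photons) in crop-local pixel coordinates (pixel centers at
    integer coordinates), or None if no acceptable fit converged.
    """
    crop = np.asarray(crop, dtype=float)
    size = crop.shape[0]
    if crop.shape != (size, size) or crop.shape != camera.shape:
        raise ValueError("crop must be square and match its calibration maps")
    pseudo = camera.variance_map / camera.gain_map**2
    data_aug = (crop - camera.offset_map) / camera.gain_map + pseudo

    bg0 = max(float(np.median(data_aug - pseudo)), 0.0)
    resid = crop - camera.offset_map
    cy, cx = np.unravel_index(np.argmax(resid), resid.shape)
    n0 = max(float(resid.sum() / camera.gain_map.mean() - bg0 * size * size), 50.0)
    inits = [(float(cx), float(cy), n0)]

    n_pix = size * size

    def bic(res, k):
        return 2.0 * res.fun + (1 + 3 * k) * np.log(n_pix)

    best = _fit_k(data_aug, size, psf_sigma_px, pseudo, inits, bg0)
    best_k = 1
    # push: add emitters at the residual maximum while BIC improves
    while best_k < max_emitters:
        mu = _model_image(best.x, size, psf_sigma_px, pseudo)
        r = data_aug - mu
        ry, rx = np.unravel_index(np.argmax(r), r.shape)
        cur = [tuple(best.x[1 + 3 * k : 4 + 3 * k]) for k in range(best_k)]
        cand = _fit_k(
            data_aug, size, psf_sigma_px, pseudo,
            cur + [(float(rx), float(ry), max(float(r[ry, rx]) * 5, 100.0))], best.x[0],
        )
        if bic(cand, best_k + 1) < bic(best, best_k) - 1e-9:
            best, best_k = cand, best_k + 1
        else:
            break
    # pull: drop any emitter whose removal improves BIC
    improved = True
    while improved and best_k > 1:
        improved = False
        for drop in range(best_k):
            keep = [
                tuple(best.x[1 + 3 * k : 4 + 3 * k]) for k in range(best_k) if k != drop
            ]
            cand = _fit_k(data_aug, size, psf_sigma_px, pseudo, keep, best.x[0])
            if bic(cand, best_k - 1) < bic(best, best_k) - 1e-9:
                best, best_k = cand, best_k - 1
                improved = True
                break
    if not best.success and not np.isfinite(best.fun):
        return None
    emitters = [
        (float(best.x[1 + 3 * k]), float(best.x[2 + 3 * k]), float(best.x[3 + 3 * k]))
        for k in range(best_k)
    ]
    return emitters, float(best.x[0]), -float(best.fun)


def crlb_precision(
    emitters,
    background: float,
    camera: CameraModel,
    psf_sigma_px: float = 1.3,
) -> np.ndarray:
    """Per-emitter CRLB position precision (nm) from the Fisher information.

    The information matrix of the augmented-Poisson likelihood is assembled
    from analytic PSF derivatives over all parameters (background, and
    x/y/photons per emitter); the returned precision is the rms of the x and
    y CRLBs.  A singular information matrix yields NaN for the affected
    emitters.
    """
    size = camera.shape[0]
    pseudo = camera.variance_map / camera.gain_map**2
    grid = np.arange(size)
    n_par = 1 + 3 * len(emitters)
    params = [background]
    for e in emitters:
        params.extend(e)
    mu = np.clip(_model_image(np.array(params), size, psf_sigma_px, pseudo), 1e-12, None)

    derivs = [np.ones((size, size))]  # d mu / d bg
    for x, y, n in emitters:
        ex, ey = _psf_1d(grid, x, psf_sigma_px), _psf_1d(grid, y, psf_sigma_px)
        dex, dey = _dpsf_1d(grid, x, psf_sigma_px), _dpsf_1d(grid, y, psf_sigma_px)
        derivs.append(n * np.outer(ey, dex))  # d/dx
        derivs.append(n * np.outer(dey, ex))  # d/dy
        derivs.append(np.outer(ey, ex))  # d/dN
    info = np.empty((n_par, n_par))
    for i in range(n_par):
        for j in range(i, n_par):
            info[i, j] = info[j, i] = np.sum(derivs[i] * derivs[j] / mu)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.full(len(emitters), np.nan)
    out = []
    for k in range(len(emitters)):
        vx, vy = cov[1 + 3 * k, 1 + 3 * k], cov[2 + 3 * k, 2 + 3 * k]
        if vx <= 0 or vy <= 0:
            out.append(np.nan)
        else:
            out.append(np.sqrt((vx + vy) / 2.0) * camera.pixel_size)
    return np.array(out)


def localize_stack(
    stack: np.ndarray,
    camera: CameraModel,
    cfg: DetectionConfig | None = None,
    channel: str = "ch0",
) -> pd.DataFrame:
    """Detect and fit all frames of a stack into a localization table.

    Coordinates follow the continuous-nm convention: the center of pixel
    (0, 0) sits at (pixel_size/2, pixel_size/2) nm.
    """
    cfg = cfg or DetectionConfig()
    half = cfg.crop_size // 2
    px = camera.pixel_size
    rows = []
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    for f, frame in enumerate(stack):
        for r, c in detect_candidates(frame, camera, cfg):
            y0, x0 = r - half, c - half
            crop = frame[y0 : y0 + cfg.crop_size, x0 : x0 + cfg.crop_size]
            cam_crop = camera.crop(y0, x0, cfg.crop_size)
            result = fit_crop(crop, cam_crop, cfg.max_emitters, cfg.psf_sigma_px)
            if result is None:
                continue
            emitters, bg, _ = result
            crlbs = crlb_precision(emitters, bg, cam_crop, cfg.psf_sigma_px)
            for (ex, ey, n), crlb in zip(emitters, crlbs):
                # keep only emitters localized within the inner pixel of the crop
                if abs(ex - half) > 1.5 or abs(ey - half) > 1.5:
                    continue
                rows.append(
                    (
                        f,
                        (x0 + ex + 0.5) * px,
                        (y0 + ey + 0.5) * px,
                        n,
                        bg,
                        crlb,
                        channel,
                        1,
                    )
                )
    df = pd.DataFrame(rows, columns=LOC_COLUMNS)
    # collapse duplicate fits of one emitter from adjacent candidate pixels
    return _dedupe(df, radius_nm=px)


def _dedupe(df: pd.DataFrame, radius_nm: float) -> pd.DataFrame:
    if df.empty:
        return df
    keep = []
    for _, sub in df.groupby("frame", sort=True):
        sub = sub.sort_values("photons", ascending=False)
        taken: list[np.ndarray] = []
        for idx, row in sub.iterrows():
            p = np.array([row["x_nm"], row["y_nm"]])
            if all(np.linalg.norm(p - q) > radius_nm for q in taken):
                taken.append(p)
                keep.append(idx)
    return df.loc[sorted(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# precision summary and blink merging
# ---------------------------------------------------------------------------

def summarize_precision(crlb_values) -> float:
    """Center of a maximum-likelihood skew-Gaussian fit to CRLB values (nm).

    The center is the mode (density peak) of the fitted skew-normal, which
    coincides with the mean for a symmetric sample and sits below the
    arithmetic mean for right-skewed precision distributions.  Falls back to
    the median when the fit fails (e.g. degenerate all-identical samples).
    """
    from scipy.optimize import minimize_scalar

    vals = np.asarray(crlb_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite precision values to summarize")
    if np.ptp(vals) == 0:
        return float(vals[0])
    try:
        a, loc, scale = stats.skewnorm.fit(vals)
        if not np.isfinite(loc) or scale <= 0:
            raise ValueError
        res = minimize_scalar(
            lambda x: -stats.skewnorm.pdf(x, a, loc, scale),
            bounds=(loc - 3 * scale, loc + 3 * scale),
            method="bounded",
        )
        mode = float(res.x)
        if not np.isfinite(mode):
            raise ValueError
        return mode
    except Exception:
        return float(np.median(vals))


def merge_blinks(
    records: pd.DataFrame, avg_precision: float, factor: float = 2.5
) -> pd.DataFrame:
    """Collapse consecutive-frame localization chains into blink events.

    Greedy frame-to-frame rule: a localization in frame f joins a chain
    whose latest member is in frame f-1 and within ``factor * avg_precision``
    nm.  Chains collapse to a photon-weighted mean position with summed
    photons; ``n_merged`` counts the merged frames and ``frame`` keeps the
    chain's first frame.
    """
    if records.empty:
        return records.copy()
    thr = factor * avg_precision
    df = records.sort_values("frame", kind="stable").reset_index(drop=True)
    chains: list[dict] = []  # each: {rows: [idx], last_frame, last_xy}
    open_chains: list[dict] = []
    for frame, sub in df.groupby("frame", sort=True):
        frame = int(frame)
        candidates = [c for c in open_chains if c["last_frame"] == frame - 1]
        used = set()
        assigned = {}
        entries = [(i, np.array([r["x_nm"], r["y_nm"]])) for i, r in sub.iterrows()]
        # nearest-pair greedy assignment
        pairs = []
        for ci, c in enumerate(candidates):
            for i, p in entries:
                d = np.linalg.norm(p - c["last_xy"])
                if d <= thr:
                    pairs.append((d, ci, i))
        for d, ci, i in sorted(pairs):
            if ci in used or i in assigned:
                continue
            used.add(ci)
            assigned[i] = candidates[ci]
        new_open = [c for c in open_chains if c["last_frame"] >= frame - 1]
        for i, p in entries:
            if i in assigned:
                c = assigned[i]
                c["rows"].append(i)
                c["last_frame"], c["last_xy"] = frame, p
            else:
                c = {"rows": [i], "last_frame": frame, "last_xy": p}
                chains.append(c)
                new_open.append(c)
        open_chains = [c for c in new_open if c["last_frame"] >= frame - 1]

    out = []
    for c in chains:
        sub = df.loc[c["rows"]]
        w = sub["photons"].to_numpy(dtype=float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(sub), 1.0 / len(sub))
        out.append(
            {
                "frame": int(sub["frame"].iloc[0]),
                "x_nm": float(np.sum(w * sub["x_nm"])),
                "y_nm": float(np.sum(w * sub["y_nm"])),
                "photons": float(sub["photons"].sum()),
                "background": float(sub["background"].mean()),
                "crlb_nm": float(np.sum(w * sub["crlb_nm"])),
                "channel": sub["channel"].iloc[0],
                "n_merged": int(sub["n_merged"].sum()),
            }
        )
    return (
        pd.DataFrame(out, columns=LOC_COLUMNS)
        .sort_values(["frame", "x_nm"], kind="stable")
        .reset_index(drop=True)
    )


def render(
    records: pd.DataFrame,
    canvas_nm: float = 10.0,
    blur_sigma_nm: float = 10.0,
    extent=None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Histogram rendering of localizations on a fine canvas with Gaussian blur.

    Returns (image, (x_origin_nm, y_origin_nm)).  Total image mass equals the
    record count (up to blur leakage at the padded border).
    """
    if records.empty:
        raise ValueError("cannot render an empty localization list")
    x = records["x_nm"].to_numpy(dtype=float)
    y = records["y_nm"].to_numpy(dtype=float)
    pad = 5.0 * max(blur_sigma_nm, canvas_nm)
    if extent is None:
        x0, x1 = x.min() - pad, x.max() + pad
        y0, y1 = y.min() - pad, y.max() + pad
    else:
        x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / canvas_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / canvas_nm)), 1)
    img, _, _ = np.histogram2d(
        y, x, bins=[ny, nx], range=[[y0, y0 + ny * canvas_nm], [x0, x0 + nx * canvas_nm]]
    )
    if blur_sigma_nm > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_nm / canvas_nm, mode="constant")
    return img, (x0, y0)
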