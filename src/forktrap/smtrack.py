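"""Live-cell single-molecule tracking and dwell-time kinetics.

Raw movies are block-averaged every ``n_avg`` frames (which suppresses
fast-diffusing molecules and sets the effective frame time, e.g. 0.12 s from
30 ms frames) and background-subtracted with a rolling-ball filter.
Detections are linked frame-to-frame by globally optimal (Hungarian)
nearest assignment with a distance gate and no gap closing; each track's
on-time is tau_on = (last frame - first frame + 1) * effective frame time.

The normalized tau_on survival curve of a population of tracked molecules
shows two exponential decays: the fast lifetime is the average chromatin
dwell duration and the slow one the photobleaching time of the fluorophore.
Both are estimated by a two-exponential least-squares fit; molecules dwelling
longer than a threshold (default 0.6 s) are counted per cell as "persistent".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment

from .camera import CameraModel
from .locfit import DetectionConfig, detect_candidates

__all__ = [
    "preprocess",
    "track_spots",
    "Track",
    "tau_on_distribution",
    "TwoExponentialModel",
    "DwellFit",
    "fit_two_exponential",
    "count_persistent",
    "localizations_per_frame",
]


def preprocess(
    movie: np.ndarray,
    camera: CameraModel | None = None,
    n_avg: int = 4,
    rollball_radius_px: int = 10,
) -> tuple[np.ndarray, float]:
    """Block-average frames and subtract rolling-ball background.

    Returns (processed stack, effective frame time in s).  Non-overlapping
    blocks of ``n_avg`` raw frames are averaged (a trailing partial block is
    dropped), then a grayscale rolling-ball background is removed from each
    averaged frame.
    """
    from skimage.restoration import rolling_ball

    movie = np.asarray(movie, dtype=float)
    if movie.ndim == 2:
        movie = movie[None]
    if movie.shape[0] < n_avg:
        raise ValueError("movie must hold at least n_avg frames")
    n_blocks = movie.shape[0] // n_avg
    avg = movie[: n_blocks * n_avg].reshape(n_blocks, n_avg, *movie.shape[1:]).mean(axis=1)
    out = np.empty_like(avg)
    for i, frame in enumerate(avg):
        bg = rolling_ball(frame, radius=rollball_radius_px)
        out[i] = frame - bg
    frame_time = (camera.frame_time if camera is not None else 0.03) * n_avg
    return out, frame_time


@dataclass
class Track:
    id: int
    cell_id: int
    frames: np.ndarray  # contiguous effective-frame indices
    positions: np.ndarray  # (n, 2) nm
    mean_intensity: float
    frame_time: float  # effective, s

    @property
    def tau_on(self) -> float:
        """On-time in s: (span + 1) x effective frame time."""
        return (int(self.frames[-1]) - int(self.frames[0]) + 1) * self.frame_time


def _detect_positions(frame, camera, cfg):
    """Candidate detections refined to intensity-weighted centroids (nm)."""
    px = camera.pixel_size
    out = []
    for r, c in detect_candidates(frame, camera, cfg):
        win = frame[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3]
        ys, xs = np.mgrid[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3][:, : win.shape[0], : win.shape[1]]
        w = np.clip(win, 0, None)
        tot = w.sum()
        if tot <= 0:
            cy, cx = float(r), float(c)
        else:
            cy, cx = float((ys * w).sum() / tot), float((xs * w).sum() / tot)
        out.append((cx * px + px / 2, cy * px + px / 2, float(frame[r, c])))
    return out


def track_spots(
    processed: np.ndarray,
    camera: CameraModel,
    cfg: DetectionConfig | None = None,
    max_link_nm: float = 500.0,
    min_len: int = 2,
    frame_time: float = 0.12,
    cell_id: int = 0,
) -> list[Track]:
    """Link per-frame detections into tracks (no gap closing).

    Assignment between consecutive frames is the global minimum-cost
    matching under the ``max_link_nm`` gate; a detection missing for a
    single frame therefore terminates its track.  Tracks shorter than
    ``min_len`` effective frames are dropped.
    """
    cfg = cfg or DetectionConfig()
    processed = np.asarray(processed, dtype=float)
    if processed.ndim == 2:
        processed = processed[None]
    # detection on background-subtracted frames: offset 0, unity gain
    det_cam = CameraModel(
        offset_map=np.zeros(camera.shape),
        variance_map=camera.variance_map,
        gain_map=camera.gain_map,
        pixel_size=camera.pixel_size,
        frame_time=camera.frame_time,
    )

    active: list[dict] = []
    done: list[dict] = []
    for f, frame in enumerate(processed):
        dets = _detect_positions(frame, det_cam, cfg)
        pos = np.array([(x, y) for x, y, _ in dets]) if dets else np.empty((0, 2))
        inten = np.array([i for _, _, i in dets])
        assigned_det = set()
        still_active = []
        if active and len(pos):
            last = np.array([t["positions"][-1] for t in active])
            cost = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            big = 1e9
            cost_gated = np.where(cost <= max_link_nm, cost, big)
            rows, cols = linear_sum_assignment(cost_gated)
            for ri, ci in zip(rows, cols):
                if cost_gated[ri, ci] >= big:
                    continue
                t = active[ri]
                t["frames"].append(f)
                t["positions"].append(tuple(pos[ci]))
                t["intensity"].append(float(inten[ci]))
                t["linked"] = True
                assigned_det.add(ci)
        for t in active:
            if t.get("linked"):
                t["linked"] = False
                still_active.append(t)
            else:
                done.append(t)
        for ci in range(len(pos)):
            if ci not in assigned_det:
                still_active.append(
                    {
                        "frames": [f],
                        "positions": [tuple(pos[ci])],
                        "intensity": [float(inten[ci])],
                        "linked": False,
                    }
                )
        active = still_active
    done.extend(active)

    tracks = []
    tid = 0
    for t in done:
        if len(t["frames"]) < min_len:
            continue
        tracks.append(
            Track(
                id=tid,
                cell_id=cell_id,
                frames=np.array(t["frames"]),
                positions=np.array(t["positions"]),
                mean_intensity=float(np.mean(t["intensity"])),
                frame_time=frame_time,
            )
        )
        tid += 1
    return tracks


# ---------------------------------------------------------------------------
# dwell-time analysis
# ---------------------------------------------------------------------------

def tau_on_distribution(
    tau_on, frame_time: float | None = None, mode: str = "survival"
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized tau_on distribution on the effective frame grid.

    ``tau_on`` may be an array of on-times in seconds or a list of
    :class:`Track`.  In ``survival`` mode (default) returns S(t) =
    P(tau_on > t) evaluated at t = 0, dt, 2*dt, ...; the first point is 1
    and the curve is monotone non-increasing.  ``histogram`` mode returns
    the normalized counts per frame-grid bin instead.
    """
    if len(tau_on) and isinstance(tau_on[0], Track):
        frame_time = frame_time or tau_on[0].frame_time
        tau = np.array([t.tau_on for t in tau_on])
    else:
        tau = np.asarray(tau_on, dtype=float)
        if frame_time is None:
            raise ValueError("frame_time required when passing raw on-times")
    if len(tau) == 0:
        raise ValueError("no on-times provided")
    n_max = int(np.ceil(tau.max() / frame_time))
    t = np.arange(n_max + 1) * frame_time
    if mode == "survival":
        s = np.array([(tau > ti + 1e-12).mean() for ti in t])
        s[0] = 1.0
        return t, s
    if mode == "histogram":
        edges = (np.arange(n_max + 1) + 0.5) * frame_time
        hist, _ = np.histogram(tau, bins=edges)
        return np.arange(1, n_max + 1) * frame_time, hist / hist.sum()
    raise ValueError("mode must be 'survival' or 'histogram'")


@dataclass
class DwellFit:
    """Two-exponential decomposition of the tau_on distribution."""

    tau_fast: float  # s, dwell duration
    tau_slow: float  # s, photobleaching
    amplitude_fast: float
    amplitude_slow: float
    cov: np.ndarray | None
    collapsed: bool = False  # true when the two components merged

    @property
    def tau_dwell(self) -> float:
        return self.tau_fast

    @property
    def tau_bleach(self) -> float:
        return self.tau_slow

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude_fast * np.exp(-t / self.tau_fast) + (
            self.amplitude_slow * np.exp(-t / self.tau_slow)
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-exponential dwell fit",
                f"  tau_fast (dwell)     : {self.tau_fast:8.3f} s  (amp {self.amplitude_fast:.3f})",
                f"  tau_slow (bleaching) : {self.tau_slow:8.3f} s  (amp {self.amplitude_slow:.3f})",
                f"  collapsed            : {self.collapsed}",
            ]
        )


class TwoExponentialModel:
    """a1*exp(-t/tau1) + a2*exp(-t/tau2) fit to a normalized decay curve."""

    def __init__(self, t, y):
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.t) < 10:
            raise ValueError("curve must span at least 10 points for a stable fit")

    def fit(self, collapse_ratio: float = 1.5) -> DwellFit:
        t, y = self.t, self.y

        def two_exp(t, a1, tau1, a2, tau2):
            return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

        # moment-based starts: tail slope for slow, early slope for fast
        tau_slow0 = max(np.trapezoid(y, t) / max(y[0], 1e-9), t[1])
        starts = [
            (0.7, tau_slow0 / 5, 0.3, tau_slow0 * 2),
            (0.8, t[1], 0.2, t[-1] / 2),
            (0.5, tau_slow0 / 10, 0.5, tau_slow0),
        ]
        best = None
        for p0 in starts:
            try:
                popt, pcov = curve_fit(
                    two_exp, t, y, p0=p0,
                    bounds=([0, 1e-4, 0, 1e-4], [np.inf, np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except Exception:
                continue
            rss = float(np.sum((two_exp(t, *popt) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
        if best is None:
            raise RuntimeError("two-exponential fit failed from every start")
        _, popt, pcov = best
        a1, tau1, a2, tau2 = popt
        if tau1 > tau2:
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
            perm = [2, 3, 0, 1]
            pcov = pcov[np.ix_(perm, perm)]
        collapsed = tau2 / max(tau1, 1e-12) < collapse_ratio
        if collapsed:
            # single-exponential fallback
            def one_exp(t, a, tau):
                return a * np.exp(-t / tau)

            popt1, pcov1 = curve_fit(one_exp, t, y, p0=[y[0], tau_slow0], maxfev=20000)
            a, tau = popt1
            return DwellFit(
                tau_fast=float(tau), tau_slow=float(tau),
                amplitude_fast=float(a), amplitude_slow=0.0,
                cov=pcov1, collapsed=True,
            )
        return DwellFit(
            tau_fast=float(tau1), tau_slow=float(tau2),
            amplitude_fast=float(a1), amplitude_slow=float(a2),
            cov=pcov, collapsed=False,
        )


def fit_two_exponential(t, y, **kwargs) -> DwellFit:
    """Functional wrapper over :class:`TwoExponentialModel`."""
    return TwoExponentialModel(t, y).fit(**kwargs)


def count_persistent(tracks, threshold_s: float = 0.6) -> pd.DataFrame:
    """Per-cell count of molecules dwelling longer than ``threshold_s``.

    ``tracks`` is a list of :class:`Track` or a DataFrame with ``cell_id``
    and ``tau_on_s`` columns.  Returns one row per cell plus summary
    attributes (median, quartiles, min, max) in ``DataFrame.attrs``.
    """
    if isinstance(tracks, pd.DataFrame):
        df = tracks[["cell_id", "tau_on_s"]]
    else:
        df = pd.DataFrame(
            {"cell_id": [t.cell_id for t in tracks], "tau_on_s": [t.tau_on for t in tracks]}
        )
    counts = (
        df.assign(persistent=df["tau_on_s"] > threshold_s)
        .groupby("cell_id")["persistent"]
        .sum()
        .astype(int)
        .reset_index(name="n_persistent")
    )
    vals = counts["n_persistent"].to_numpy()
    counts.attrs["summary"] = {
        "median": float(np.median(vals)),
        "q1": float(np.percentile(vals, 25)),
        "q3": float(np.percentile(vals, 75)),
        "min": float(vals.min()) if len(vals) else np.nan,
        "max": float(vals.max()) if len(vals) else np.nan,
    }
    return counts


def localizations_per_frame(tracks, n_frames: int | None = None) -> np.ndarray:
    """Number of active detections per effective frame.

    Accepts a list of :class:`Track` (counts frames covered by each track)
    or a detections DataFrame with a ``frame`` column.
    """
    if isinstance(tracks, pd.DataFrame):
        frames = tracks["frame"].to_numpy(dtype=int)
    else:
        frames = np.concatenate([t.frames for t in tracks]) if tracks else np.array([], int)
    n = n_frames if n_frames is not None else (frames.max() + 1 if len(frames) else 0)
    return np.bincount(frames, minlength=int(n)) if len(frames) else np.zeros(int(n or 0), int)
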