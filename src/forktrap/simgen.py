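"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline (localization, registration,
pair-correlation, dwell-time kinetics, Ok-seq strand bias, fiber statistics)
is exercised against data produced here, so each generator records the true
parameters it used in a :class:`GroundTruth` sidecar.  All generators are
pure functions of (parameters, seed): the same seed reproduces byte-identical
output.

Scientific content of the generators
------------------------------------
* Bead fields for chromatic registration follow an exact second-order
  polynomial warp plus isotropic Gaussian localization noise.
* Clustered localization patterns are a Thomas process (Poisson focus
  centers, Poisson-distributed molecules per focus displaced by an isotropic
  Gaussian of sd ``r_app``) superposed on a homogeneous Poisson background;
  the implied auto-correlation amplitude has the closed form
  ``A = kappa * N^2 / (4 pi rho_tot^2 (sigma^2 + r_app^2))``.
* Camera frames integrate a pixel-averaged 2D Gaussian PSF, apply per-pixel
  gain/offset and add Poisson shot noise plus Gaussian read noise.
* Single-molecule on-times are a two-population mixture: transient molecules
  unbind (exponential dwell) while a persistent fraction stays bound and is
  terminated only by photobleaching (exponential bleach); observed durations
  are quantized to the effective frame grid.
* Ok-seq counts follow a programmed replication-fork-directionality profile:
  the Crick-strand fraction steps up by the origin efficiency at each
  TSS-proximal origin and relaxes back to background across a termination
  zone at the TTS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraModel
from .chromreg import build_design, warp_points

__all__ = [
    "GroundTruth",
    "RFDModel",
    "gen_bead_field",
    "gen_clustered_localizations",
    "gen_two_channel_pattern",
    "gen_smlm_frames",
    "gen_track_movie",
    "gen_smt_tracks",
    "gen_okseq_counts",
    "gen_okseq_fragments",
    "gen_fiber_tracts",
]

UM2_PER_NM2 = 1e-6


@dataclass
class GroundTruth:
    """Plain key-value record of the true parameters behind a simulation."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def __setitem__(self, key, value):
        self.values[key] = value

    def __contains__(self, key):
        return key in self.values

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k in sorted(self.values):
                v = self.values[k]
                if isinstance(v, np.ndarray):
                    v = ",".join(repr(float(x)) for x in np.ravel(v))
                fh.write(f"{k}={v}\n")

    @classmethod
    def load(cls, path) -> "GroundTruth":
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                k, _, v = line.partition("=")
                if "," in v:
                    values[k] = np.array([float(x) for x in v.split(",")])
                else:
                    try:
                        values[k] = float(v)
                    except ValueError:
                        values[k] = v
        return cls(values)


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# registration bead fields
# ---------------------------------------------------------------------------

def gen_bead_field(
    n_beads: int,
    kx: np.ndarray | None = None,
    ky: np.ndarray | None = None,
    noise_sd: float = 0.0,
    field_nm: tuple[float, float] = (40000.0, 40000.0),
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired bead localizations in a reference and a warped channel.

    The warped channel is the exact second-order polynomial (coefficients
    ``kx``, ``ky`` in the registration column order) of the reference
    coordinates, plus isotropic Gaussian noise of sd ``noise_sd`` nm.
    Defaults to the identity warp.
    """
    if n_beads < 9:
        raise ValueError("need at least 9 beads for a solvable 9-coefficient mapping")
    rng = _rng(seed)
    if kx is None:
        kx = np.array([0, 0, 0, 1, 0, 0, 0, 0, 0], dtype=float)
    if ky is None:
        ky = np.array([0, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    ref = rng.uniform([0, 0], field_nm, size=(n_beads, 2))
    unit = (ref - ref.mean(axis=0)) / max(ref.std(axis=0).max(), 1.0)
    if np.linalg.matrix_rank(build_design(unit)) < 9:
        raise ValueError("degenerate bead layout (collinear or non-generic)")
    warped = warp_points(ref, kx, ky)
    if noise_sd > 0:
        warped = warped + rng.normal(0.0, noise_sd, size=warped.shape)
    truth = GroundTruth(
        {
            "kx": np.asarray(kx, float),
            "ky": np.asarray(ky, float),
            "noise_sd_nm": float(noise_sd),
            "n_beads": float(n_beads),
        }
    )
    ref_df = pd.DataFrame({"x_nm": ref[:, 0], "y_nm": ref[:, 1]})
    warp_df = pd.DataFrame({"x_nm": warped[:, 0], "y_nm": warped[:, 1]})
    return ref_df, warp_df, truth


# ---------------------------------------------------------------------------
# clustered / paired point patterns
# ---------------------------------------------------------------------------

def _csr(rng, roi_nm, density_nm2):
    """Homogeneous Poisson points in a rectangle (nm units)."""
    w, h = roi_nm
    n = rng.poisson(density_nm2 * w * h)
    return rng.uniform([0, 0], [w, h], size=(n, 2))


def gen_clustered_localizations(
    roi_um: tuple[float, float] = (6.0, 6.0),
    rho: float = 50.0,
    focus_density: float = 2.0,
    n_per_focus: float = 20.0,
    r_app: float = 100.0,
    sigma_loc: float = 15.0,
    extra_locs_per_mol: float = 0.0,
    seed=0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Thomas-process foci plus CSR background inside a rectangular ROI.

    Parameters use the field's conventions: densities ``rho`` (background
    molecules) and ``focus_density`` in um^-2, focus radius ``r_app`` and
    localization jitter ``sigma_loc`` in nm.  Each molecule emits
    ``1 + Poisson(extra_locs_per_mol)`` localizations (default exactly one,
    i.e. blink-merged input).  Foci are generated on a guard-padded region
    and localizations cropped to the ROI so the pattern is stationary within
    the window.
    """
    for name, v in [("rho", rho), ("focus_density", focus_density),
                    ("n_per_focus", n_per_focus), ("r_app", r_app),
                    ("sigma_loc", sigma_loc), ("extra_locs_per_mol", extra_locs_per_mol)]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = _rng(seed)
    w_nm, h_nm = roi_um[0] * 1000.0, roi_um[1] * 1000.0
    pad = 4.0 * (r_app + sigma_loc)

    mols = [_csr(rng, (w_nm, h_nm), rho * UM2_PER_NM2)]
    kappa_nm2 = focus_density * UM2_PER_NM2
    n_foci = rng.poisson(kappa_nm2 * (w_nm + 2 * pad) * (h_nm + 2 * pad))
    centers = rng.uniform([-pad, -pad], [w_nm + pad, h_nm + pad], size=(n_foci, 2))
    for c in centers:
        k = rng.poisson(n_per_focus)
        if k:
            mols.append(c + rng.normal(0.0, r_app, size=(k, 2)))
    mols = np.vstack(mols) if mols else np.empty((0, 2))

    reps = 1 + (rng.poisson(extra_locs_per_mol, size=len(mols))
                if extra_locs_per_mol > 0 else np.zeros(len(mols), dtype=int))
    pts = np.repeat(mols, reps, axis=0)
    if sigma_loc > 0 and len(pts):
        pts = pts + rng.normal(0.0, sigma_loc, size=pts.shape)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < w_nm) & (pts[:, 1] >= 0) & (pts[:, 1] < h_nm)
    )
    pts = pts[inside]

    rho_total = rho + focus_density * n_per_focus  # um^-2, molecular
    sig2 = (sigma_loc**2 + r_app**2)
    a_true = (
        kappa_nm2 * n_per_focus**2
        / (4.0 * np.pi * (rho_total * UM2_PER_NM2) ** 2 * sig2)
        / 1.0
    )
    truth = GroundTruth(
        {
            "rho_background_um2": rho,
            "rho_total_um2": rho_total,
            "focus_density_um2": focus_density,
            "n_per_focus": n_per_focus,
            "r_app_nm": r_app,
            "sigma_loc_nm": sigma_loc,
            "A_true": float(a_true),
            "roi_w_nm": w_nm,
            "roi_h_nm": h_nm,
        }
    )
    df = pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1]})
    return df, truth


def gen_two_channel_pattern(
    roi_um: tuple[float, float] = (6.0, 6.0),
    rho_p: float = 200.0,
    rho_q: float = 200.0,
    paired_fraction: float = 0.8,
    x_c: float = 50.0,
    sigma_pair: float = 20.0,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two-channel pattern where a fraction of Q sits at distance x_c from a P.

    Paired Q molecules are displaced from a uniformly chosen P by a vector of
    length ``x_c`` in a uniform direction plus 2D Gaussian jitter
    ``sigma_pair``; the rest of Q (and all of P) are CSR.
    """
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must lie in [0, 1]")
    if min(rho_p, rho_q, x_c, sigma_pair) < 0:
        raise ValueError("densities, x_c and sigma_pair must be non-negative")
    rng = _rng(seed)
    w_nm, h_nm = roi_um[0] * 1000.0, roi_um[1] * 1000.0
    pad = 4.0 * sigma_pair + x_c

    # P generated on the padded region so edge Q keep their partners
    n_p = rng.poisson(rho_p * UM2_PER_NM2 * (w_nm + 2 * pad) * (h_nm + 2 * pad))
    p = rng.uniform([-pad, -pad], [w_nm + pad, h_nm + pad], size=(n_p, 2))

    n_q = rng.poisson(rho_q * UM2_PER_NM2 * w_nm * h_nm)
    n_paired = rng.binomial(n_q, paired_fraction) if n_p else 0
    q_free = rng.uniform([0, 0], [w_nm, h_nm], size=(n_q - n_paired, 2))
    if n_paired:
        partners = p[rng.integers(0, n_p, size=n_paired)]
        theta = rng.uniform(0, 2 * np.pi, size=n_paired)
        offset = x_c * np.column_stack([np.cos(theta), np.sin(theta)])
        q_paired = partners + offset + rng.normal(0.0, sigma_pair, size=(n_paired, 2))
        q = np.vstack([q_free, q_paired])
    else:
        q = q_free

    def _crop(a):
        m = (a[:, 0] >= 0) & (a[:, 0] < w_nm) & (a[:, 1] >= 0) & (a[:, 1] < h_nm)
        return a[m]

    p, q = _crop(p), _crop(q)
    truth = GroundTruth(
        {
            "rho_p_um2": rho_p,
            "rho_q_um2": rho_q,
            "paired_fraction": paired_fraction,
            "x_c_nm": x_c,
            "sigma_pair_nm": sigma_pair,
            "roi_w_nm": w_nm,
            "roi_h_nm": h_nm,
        }
    )
    return (
        pd.DataFrame({"x_nm": p[:, 0], "y_nm": p[:, 1]}),
        pd.DataFrame({"x_nm": q[:, 0], "y_nm": q[:, 1]}),
        truth,
    )


# ---------------------------------------------------------------------------
# camera frames
# ---------------------------------------------------------------------------

def _integrated_gaussian_image(shape, x_px, y_px, photons, sigma_px):
    """Expected photon image of emitters with a pixel-integrated Gaussian PSF."""
    from scipy.special import erf

    ny, nx = shape
    img = np.zeros(shape)
    xs = np.arange(nx)
    ys = np.arange(ny)
    s = np.sqrt(2.0) * sigma_px
    for xe, ye, n in zip(np.atleast_1d(x_px), np.atleast_1d(y_px), np.atleast_1d(photons)):
        ex = 0.5 * (erf((xs + 0.5 - xe) / s) - erf((xs - 0.5 - xe) / s))
        ey = 0.5 * (erf((ys + 0.5 - ye) / s) - erf((ys - 0.5 - ye) / s))
        img += n * np.outer(ey, ex)
    return img


def gen_smlm_frames(
    positions_nm: np.ndarray,
    photons,
    camera: CameraModel,
    n_frames: int = 1,
    background: float = 10.0,
    psf_sigma_px: float = 1.3,
    on_prob: float = 1.0,
    seed=0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate sCMOS frames of blinking emitters.

    Pixel values are ``offset + gain * Poisson(PSF + background) +
    Normal(0, sqrt(variance))``; the PSF is a pixel-integrated 2D Gaussian
    of sd ``psf_sigma_px``.  Each emitter is independently on in each frame
    with probability ``on_prob``.  Positions follow the continuous-nm
    convention with the center of pixel (0, 0) at (pixel_size/2,
    pixel_size/2) nm.
    """
    rng = _rng(seed)
    positions_nm = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    photons = np.broadcast_to(np.asarray(photons, dtype=float), (len(positions_nm),))
    px = camera.pixel_size
    if len(positions_nm):
        if positions_nm[:, 0].max() > camera.shape[1] * px or positions_nm[:, 1].max() > camera.shape[0] * px:
            raise ValueError("emitter positions outside the camera field")
    x_px = positions_nm[:, 0] / px - 0.5 if len(positions_nm) else np.array([])
    y_px = positions_nm[:, 1] / px - 0.5 if len(positions_nm) else np.array([])

    frames = np.empty((n_frames,) + camera.shape)
    rows = []
    for f in range(n_frames):
        on = rng.random(len(positions_nm)) < on_prob if len(positions_nm) else np.array([], bool)
        mu = np.full(camera.shape, float(background))
        if on.any():
            mu = mu + _integrated_gaussian_image(
                camera.shape, x_px[on], y_px[on], photons[on], psf_sigma_px
            )
        shot = rng.poisson(mu)
        read = rng.normal(0.0, np.sqrt(camera.variance_map))
        frames[f] = camera.offset_map + camera.gain_map * shot + read
        for i in np.flatnonzero(on):
            rows.append((f, positions_nm[i, 0], positions_nm[i, 1], photons[i]))
    truth = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "photons"])
    return frames, truth


def gen_track_movie(
    events,
    camera: CameraModel,
    n_frames: int,
    photons: float = 2000.0,
    background: float = 5.0,
    psf_sigma_px: float = 1.3,
    seed=0,
) -> np.ndarray:
    """Movie of immobile spots visible over stated frame spans.

    ``events`` is an iterable of (first_frame, last_frame, x_nm, y_nm); both
    span ends are inclusive.
    """
    rng = _rng(seed)
    stack = np.empty((n_frames,) + camera.shape)
    for f in range(n_frames):
        active = [(x, y) for (f0, f1, x, y) in events if f0 <= f <= f1]
        if active:
            pos = np.array(active)
            frame, _ = gen_smlm_frames(
                pos, photons, camera, n_frames=1, background=background,
                psf_sigma_px=psf_sigma_px, seed=rng,
            )
        else:
            frame, _ = gen_smlm_frames(
                np.empty((0, 2)), [], camera, n_frames=1, background=background,
                psf_sigma_px=psf_sigma_px, seed=rng,
            )
        stack[f] = frame[0]
    return stack


# ---------------------------------------------------------------------------
# single-molecule on-times
# ---------------------------------------------------------------------------

def gen_smt_tracks(
    n_mol: int = 5000,
    dwell_mean: float = 0.51,
    bleach_mean: float = 3.8,
    persistent_fraction: float = 0.2,
    frame_time: float = 0.12,
    n_cells: int = 16,
    quantize: bool = True,
    seed=0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-population on-time samples on the effective frame grid.

    Transient molecules end their track by unbinding (exponential with mean
    ``dwell_mean``); a ``persistent_fraction`` of molecules stays bound and
    ends only by photobleaching (exponential with mean ``bleach_mean``).
    Observed tau_on is quantized upward to whole effective frames.
    """
    if dwell_mean <= 0 or bleach_mean <= 0 or frame_time <= 0:
        raise ValueError("means and frame_time must be positive")
    if not 0.0 <= persistent_fraction <= 1.0:
        raise ValueError("persistent_fraction must lie in [0, 1]")
    rng = _rng(seed)
    persistent = rng.random(n_mol) < persistent_fraction
    t = np.where(
        persistent,
        rng.exponential(bleach_mean, size=n_mol),
        rng.exponential(dwell_mean, size=n_mol),
    )
    if quantize:
        tau = np.ceil(t / frame_time) * frame_time
    else:
        tau = t
    cells = rng.integers(0, n_cells, size=n_mol)
    df = pd.DataFrame(
        {
            "cell_id": cells,
            "tau_on_s": tau,
            "population": np.where(persistent, "persistent", "transient"),
        }
    )
    truth = GroundTruth(
        {
            "dwell_mean_s": dwell_mean,
            "bleach_mean_s": bleach_mean,
            "persistent_fraction": persistent_fraction,
            "frame_time_s": frame_time,
        }
    )
    return df, truth


# ---------------------------------------------------------------------------
# Ok-seq counts
# ---------------------------------------------------------------------------

BIN_BP = 1000


@dataclass
class RFDModel:
    """Programmed replication-fork directionality over one synthetic genome.

    Each gene carries an origin at its TSS firing with ``efficiency``
    (column in ``genes``); the Crick-strand fraction steps up by that
    efficiency across the origin (half below baseline upstream, half above
    downstream), holds through the gene body and relaxes linearly back to
    background across a termination zone centered on the TTS.
    """

    genes: pd.DataFrame  # id, chrom, tss, tts, strand, length, fpkm, efficiency
    chrom_sizes: dict
    termination_width: int = 20000
    upstream_flank: int = 15000
    background_rfd: float = 0.5
    fragment_cap: int = 200

    def __post_init__(self) -> None:
        g = self.genes
        eff = np.asarray(g["efficiency"], dtype=float)
        if np.any((eff < 0) | (eff > 1)):
            raise ValueError("origin efficiencies must lie in [0, 1]")
        plus = g["strand"] == "+"
        if np.any(g.loc[plus, "tss"] >= g.loc[plus, "tts"]):
            raise ValueError("TSS must precede TTS on the plus strand")
        if self.fragment_cap > 200:
            raise ValueError("fragment length cap must be <= 200 bp")

    def rfd_profile(self, chrom: str) -> np.ndarray:
        """Per-1-kb-bin Crick fraction for one chromosome.

        Overlapping gene contributions are resolved by summing each gene's
        deviation from background and clipping to [0.05, 0.95] (later genes
        do not override earlier ones; deviations superpose).
        """
        n_bins = int(np.ceil(self.chrom_sizes[chrom] / BIN_BP))
        centers = (np.arange(n_bins) + 0.5) * BIN_BP
        dev = np.zeros(n_bins)
        for _, gene in self.genes[self.genes["chrom"] == chrom].iterrows():
            e = float(gene["efficiency"])
            if e == 0:
                continue
            if gene["strand"] == "+":
                tss, tts, sign = gene["tss"], gene["tts"], 1.0
            else:
                tss, tts, sign = gene["tss"], gene["tts"], -1.0
            # transcription-direction coordinate: + genes go right
            d = np.zeros(n_bins)
            if sign > 0:
                up = (centers >= tss - self.upstream_flank) & (centers < tss)
                body = (centers >= tss) & (centers < tts - self.termination_width / 2)
                term = (centers >= tts - self.termination_width / 2) & (
                    centers < tts + self.termination_width / 2
                )
                d[up] = -e / 2
                d[body] = +e / 2
                frac = (centers[term] - (tts - self.termination_width / 2)) / self.termination_width
                d[term] = e / 2 * (1 - frac) - 0.0 * frac
            else:
                up = (centers <= tss + self.upstream_flank) & (centers > tss)
                body = (centers <= tss) & (centers > tts + self.termination_width / 2)
                term = (centers <= tts + self.termination_width / 2) & (
                    centers > tts - self.termination_width / 2
                )
                d[up] = +e / 2
                d[body] = -e / 2
                frac = ((tts + self.termination_width / 2) - centers[term]) / self.termination_width
                d[term] = -e / 2 * (1 - frac)
            dev += d
        return np.clip(self.background_rfd + dev, 0.05, 0.95)


def gen_okseq_counts(
    model: RFDModel, coverage: float = 100.0, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-1-kb Watson/Crick fragment counts following the programmed RFD.

    ``coverage`` is the mean fragment count per kb.  Bin totals are
    multinomial over bins with uniform rates; the Crick share of each bin is
    binomial with probability equal to the programmed Crick fraction.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = _rng(seed)
    rows = []
    for chrom, size in model.chrom_sizes.items():
        rfd = model.rfd_profile(chrom)
        n_bins = len(rfd)
        total = int(round(coverage * n_bins))
        per_bin = rng.multinomial(total, np.full(n_bins, 1.0 / n_bins))
        crick = rng.binomial(per_bin, rfd)
        watson = per_bin - crick
        starts = np.arange(n_bins) * BIN_BP
        for s, w, c in zip(starts, watson, crick):
            rows.append((chrom, int(s), int(w), int(c)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "watson_count", "crick_count"])
    truth = GroundTruth({"coverage_per_kb": coverage})
    return bins, model.genes.copy(), truth


def gen_okseq_fragments(
    model: RFDModel, coverage: float = 100.0, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual stranded fragments whose midpoint binning reproduces
    gen_okseq_counts for the same seed.

    Returns (fragments BED-like frame, bin table).  Fragment lengths are
    uniform in [100, cap]; Crick-strand fragments are '-' by the convention
    that rightward forks deposit fragments counted on the Crick strand.
    """
    bins, _, _ = gen_okseq_counts(model, coverage, seed)
    frags = []
    place_rng = _rng(seed)
    for _, row in bins.iterrows():
        for strand, count in (("+", row["watson_count"]), ("-", row["crick_count"])):
            if count == 0:
                continue
            mids = place_rng.integers(row["start"], row["start"] + BIN_BP, size=count)
            lens = place_rng.integers(100, model.fragment_cap + 1, size=count)
            # start/end chosen so the integer midpoint is exactly `mid`
            starts = np.maximum(0, mids - lens // 2)
            ends = starts + lens
            for s, e in zip(starts, ends):
                frags.append((row["chrom"], int(s), int(e), strand))
    frag_df = pd.DataFrame(frags, columns=["chrom", "start", "end", "strand"])
    return frag_df, bins


# ---------------------------------------------------------------------------
# fiber tracts
# ---------------------------------------------------------------------------

KB_PER_UM = 2.59


def gen_fiber_tracts(
    n: int = 200,
    fork_speed_kb_min: tuple[float, float] = (1.3, 0.3),
    pulse_min: float = 20.0,
    stall_prob: float = 0.0,
    asym_sd: float = 0.0,
    class_probs: dict | None = None,
    seed=0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthetic dual-label fiber tracts.

    ``n`` counts replication structures; bidirectional origins contribute
    two tract rows sharing an ``origin_pair_id``.  CldU length in um is
    speed * pulse / 2.59.  Left/right forks of one origin share a base speed
    and diverge by lognormal noise of sd ``asym_sd``; with probability
    ``stall_prob`` one side additionally stalls (speed scaled by U(0.2,0.6)).
    """
    if pulse_min <= 0:
        raise ValueError("pulse_min must be positive")
    rng = _rng(seed)
    if class_probs is None:
        class_probs = {
            "elongating": 0.70,
            "origin_bidirectional": 0.15,
            "origin_second_label_only": 0.05,
            "termination": 0.10,
        }
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    mean_v, sd_v = fork_speed_kb_min

    draw = rng.choice(len(classes), size=n, p=probs)
    rows = []
    fiber_id = 0
    pair_id = 0
    for c_idx in draw:
        cls = classes[c_idx]
        v = max(rng.normal(mean_v, sd_v), 0.05)
        if cls == "origin_bidirectional":
            pair_id += 1
            sides = []
            for _ in range(2):
                vv = v * (np.exp(rng.normal(0.0, asym_sd)) if asym_sd > 0 else 1.0)
                if stall_prob > 0 and rng.random() < stall_prob:
                    vv *= rng.uniform(0.2, 0.6)
                sides.append(vv)
            for vv in sides:
                cldu = vv * pulse_min / KB_PER_UM
                idu = vv * pulse_min / KB_PER_UM
                rows.append((fiber_id, cls, idu, cldu, pair_id))
                fiber_id += 1
        else:
            vv = v
            if stall_prob > 0 and rng.random() < stall_prob:
                vv *= rng.uniform(0.2, 0.6)
            cldu = vv * pulse_min / KB_PER_UM
            idu = 0.0 if cls == "origin_second_label_only" else vv * pulse_min / KB_PER_UM
            rows.append((fiber_id, cls, idu, cldu, -1))
            fiber_id += 1
    df = pd.DataFrame(
        rows, columns=["fiber_id", "class", "idu_um", "cldu_um", "origin_pair_id"]
    )
    origin_share = class_probs["origin_bidirectional"] + class_probs["origin_second_label_only"]
    truth = GroundTruth(
        {
            "mean_speed_kb_min": mean_v,
            "pulse_min": pulse_min,
            "stall_prob": stall_prob,
            "asym_sd": asym_sd,
            "origin_fraction_true": origin_share / sum(class_probs.values()),
        }
    )
    return df, truth
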