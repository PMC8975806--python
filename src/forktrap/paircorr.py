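"""Auto- and cross-pair-correlation analysis of localization patterns.

The auto-correlation g(r) of a blink-merged localization list measures
clustering of a single molecular species: it is estimated from the pairwise
distance histogram normalized by the expected pair count of a
complete-spatial-randomness (CSR) pattern in the same rectangular ROI, with
an analytic isotropic edge correction (annulus-rectangle intersection via
the isotropized set covariance of the rectangle).  Under CSR, g(r) = 1.

Fitted models
-------------
Auto-correlation (two-Gaussian model):

    g(r) = 1/(4 pi sigma^2 rho) exp(-r^2 / 4 sigma^2)
         + A exp(-r^2 / (4 (sigma^2 + r_app^2))) + 1

where sigma is the localization precision, rho the average molecular
density, A the focus correlation amplitude and r_app the apparent focus
radius.  The mean molecular content per focus is the closed-form integral
N = 2 pi rho A r_app^2, and the foci density is rho / N.

Cross-correlation (symmetric displaced-Gaussian model):

    c(r) = A [exp(-(r - x_c)^2 / 2 sigma^2) + exp(-(r + x_c)^2 / 2 sigma^2)] + 1

with x_c the center-to-center correlation distance and sigma the dispersion
radius; A * rho_Q estimates the local density of Q around each P and
A * rho_P the local density of P around each Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "CorrelationCurve",
    "autocorr",
    "crosscorr",
    "AutoCorrelationModel",
    "AutoCorrResults",
    "CrossCorrelationModel",
    "CrossCorrResults",
    "FocusMetrics",
    "focus_metrics",
]

NM2_PER_UM2 = 1e6


@dataclass
class CorrelationCurve:
    """Radial correlation estimate with its pair-count provenance."""

    r: np.ndarray  # bin centers, nm
    value: np.ndarray  # g(r) or c(r)
    pairs: np.ndarray  # observed pair counts per bin
    roi_area_um2: float
    n_points: tuple  # per-channel localization counts
    kind: str = "auto"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r, "value": self.value, "pairs": self.pairs})


def _roi_geometry(roi):
    x0, y0, x1, y1 = (float(v) for v in roi)
    w, h = x1 - x0, y1 - y0
    if w <= 0 or h <= 0:
        raise ValueError("ROI must have positive width and height")
    return x0, y0, w, h


def _csr_pair_mass(edges: np.ndarray, w: float, h: float) -> np.ndarray:
    """Expected CSR mass per radial bin for one ordered point pair.

    Integrates 2 pi r * gamma(r) over each bin, where gamma is the
    isotropized set covariance of the W x H rectangle
    (gamma(r) = WH - 2(W+H)r/pi + r^2/pi, valid for r <= min(W, H)),
    divided by (WH)^2.
    """
    if edges[-1] > min(w, h):
        raise ValueError("r_max must not exceed the shorter ROI side")

    def F(r):
        return np.pi * w * h * r**2 - (4.0 / 3.0) * (w + h) * r**3 + 0.5 * r**4

    mass = np.diff(F(edges))
    return mass / (w * h) ** 2


def _points_in_roi(records: pd.DataFrame, roi) -> np.ndarray:
    x0, y0, w, h = _roi_geometry(roi)
    x = records["x_nm"].to_numpy(dtype=float)
    y = records["y_nm"].to_numpy(dtype=float)
    m = (x >= x0) & (x < x0 + w) & (y >= y0) & (y < y0 + h)
    return np.column_stack([x[m] - x0, y[m] - y0])


def autocorr(
    records: pd.DataFrame, roi, r_max: float = 1000.0, dr: float = 10.0
) -> CorrelationCurve:
    """Radial auto-correlation g(r) of localizations within a rectangular ROI.

    ``roi`` is (x0, y0, x1, y1) in nm.  Input should be blink-merged so
    repeated localizations of one fluorophore do not masquerade as structure.
    """
    pts = _points_in_roi(records, roi)
    if len(pts) == 0:
        raise ValueError("no localizations inside the ROI")
    _, _, w, h = _roi_geometry(roi)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    tree = cKDTree(pts)
    cum = tree.count_neighbors(tree, edges)  # ordered pairs incl. self at r=0
    counts = np.diff(cum) / 2.0  # unordered pairs per bin (self pairs sit in cum[0])
    n = len(pts)
    expected = 0.5 * n * (n - 1) * _csr_pair_mass(edges, w, h)
    value = counts / expected
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CorrelationCurve(
        r=centers,
        value=value,
        pairs=counts,
        roi_area_um2=w * h / NM2_PER_UM2,
        n_points=(n,),
        kind="auto",
    )


def crosscorr(
    records_p: pd.DataFrame,
    records_q: pd.DataFrame,
    roi,
    r_max: float = 1000.0,
    dr: float = 10.0,
) -> CorrelationCurve:
    """Radialized cross-correlation c(r) between two registered channels."""
    pts_p = _points_in_roi(records_p, roi)
    pts_q = _points_in_roi(records_q, roi)
    if len(pts_p) == 0 or len(pts_q) == 0:
        raise ValueError("one of the channels has no localizations inside the ROI")
    _, _, w, h = _roi_geometry(roi)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    tp, tq = cKDTree(pts_p), cKDTree(pts_q)
    cum = tp.count_neighbors(tq, edges)
    counts = np.diff(cum).astype(float)
    expected = len(pts_p) * len(pts_q) * _csr_pair_mass(edges, w, h)
    value = counts / expected
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CorrelationCurve(
        r=centers,
        value=value,
        pairs=counts,
        roi_area_um2=w * h / NM2_PER_UM2,
        n_points=(len(pts_p), len(pts_q)),
        kind="cross",
    )


# ---------------------------------------------------------------------------
# auto-correlation fit
# ---------------------------------------------------------------------------

def autocorr_model(r, sigma, rho_um2, amp, r_app, self_term: bool = True):
    """Two-Gaussian auto-correlation model evaluated at radii r (nm).

    ``self_term=False`` drops the short-range repeated-localization
    (blinking) term, appropriate for input that is already blink-merged to
    one localization per molecule.
    """
    term2 = amp * np.exp(-(r**2) / (4.0 * (sigma**2 + r_app**2)))
    if not self_term:
        return term2 + 1.0
    rho_nm2 = rho_um2 / NM2_PER_UM2
    term1 = np.exp(-(r**2) / (4.0 * sigma**2)) / (4.0 * np.pi * sigma**2 * rho_nm2)
    return term1 + term2 + 1.0


@dataclass
class AutoCorrResults:
    sigma: float  # nm
    rho_mean: float  # um^-2
    amplitude: float
    r_app: float  # nm
    cov: np.ndarray | None
    curve: CorrelationCurve
    fixed: dict = field(default_factory=dict)
    converged: bool = True
    self_term: bool = True

    @property
    def g0(self) -> float:
        return autocorr_model(np.array([0.0]), self.sigma, self.rho_mean,
                              self.amplitude, self.r_app, self.self_term)[0]

    def predict(self, r=None) -> np.ndarray:
        r = self.curve.r if r is None else np.asarray(r, dtype=float)
        return autocorr_model(
            r, self.sigma, self.rho_mean, self.amplitude, self.r_app, self.self_term
        )

    def summary(self) -> str:
        lines = [
            "Auto-correlation fit (two-Gaussian model)",
            f"  sigma (localization precision) : {self.sigma:10.3f} nm"
            + ("  [fixed]" if "sigma" in self.fixed else ""),
            f"  <rho> (molecular density)      : {self.rho_mean:10.3f} um^-2"
            + ("  [fixed]" if "rho" in self.fixed else ""),
            f"  A (focus amplitude)            : {self.amplitude:10.4f}",
            f"  r_app (apparent focus radius)  : {self.r_app:10.3f} nm",
            f"  g(0)                           : {self.g0:10.3f}",
            f"  converged                      : {self.converged}",
        ]
        m = focus_metrics(self)
        lines.append(f"  <N> (molecules per focus)      : {m.n_mean:10.3f}")
        if m.foci_density is not None:
            lines.append(f"  foci density                   : {m.foci_density:10.4f} um^-2")
        return "\n".join(lines)


class AutoCorrelationModel:
    """Weighted nonlinear least-squares fit of the two-Gaussian g(r) model.

    Per-bin weights are sqrt(pair count) (Poisson).  ``fix_sigma`` /
    ``fix_rho`` pin those parameters (e.g. sigma from the CRLB summary, rho
    from the empirical count density), which is required for
    identifiability when the input is blink-merged and the short-range
    self-pair term is absent.
    """

    def __init__(self, curve: CorrelationCurve):
        self.curve = curve

    def fit(
        self,
        init: dict | None = None,
        fix_sigma: float | None = None,
        fix_rho: float | None = None,
        r_min: float = 0.0,
        self_term: bool = True,
    ) -> AutoCorrResults:
        c = self.curve
        m = (c.pairs > 0) & (c.r >= r_min)
        r, g, wgt = c.r[m], c.value[m], np.sqrt(c.pairs[m])
        if not self_term and fix_sigma is None:
            raise ValueError(
                "with self_term=False sigma only enters the focus width and must "
                "be fixed (e.g. at the CRLB-summary precision)"
            )
        fixed = {}
        if fix_sigma is not None:
            fixed["sigma"] = float(fix_sigma)
        if fix_rho is not None:
            fixed["rho"] = float(fix_rho)

        rho_emp = c.n_points[0] / c.roi_area_um2
        init = init or {}
        sigma0 = fixed.get("sigma", init.get("sigma", 15.0))
        rho0 = fixed.get("rho", init.get("rho", rho_emp))
        a0 = init.get("A", max(float(np.max(g) - 1.0), 0.01))
        rapp_grid = [init["r_app"]] if "r_app" in init else [30.0, 100.0, 300.0]
        sigma_grid = [sigma0] if ("sigma" in fixed or "sigma" in init) else [5.0, 15.0, 40.0]

        def pack(theta):
            vals = {}
            i = 0
            for name, fx in (("sigma", "sigma"), ("rho", "rho")):
                if name in fixed:
                    vals[name] = fixed[name]
                else:
                    vals[name] = theta[i]
                    i += 1
            vals["A"], vals["r_app"] = theta[i], theta[i + 1]
            return vals

        def resid(theta):
            v = pack(theta)
            return wgt * (
                autocorr_model(r, v["sigma"], v["rho"], v["A"], v["r_app"], self_term) - g
            )

        best = None
        for s0 in sigma_grid:
            for ra0 in rapp_grid:
                theta0, lo, hi = [], [], []
                if "sigma" not in fixed:
                    theta0.append(s0), lo.append(1e-2), hi.append(500.0)
                if "rho" not in fixed:
                    theta0.append(rho0), lo.append(1e-6), hi.append(np.inf)
                theta0 += [a0, ra0]
                lo += [0.0, 1.0]
                hi += [np.inf, 5000.0]
                try:
                    res = least_squares(resid, theta0, bounds=(lo, hi), max_nfev=2000)
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None:
            raise RuntimeError("auto-correlation fit failed from every start")
        v = pack(best.x)
        try:
            jtj = best.jac.T @ best.jac
            dof = max(len(r) - len(best.x), 1)
            cov = np.linalg.inv(jtj) * 2 * best.cost / dof
        except np.linalg.LinAlgError:
            cov = None
        return AutoCorrResults(
            sigma=float(v["sigma"]),
            rho_mean=float(v["rho"]),
            amplitude=float(v["A"]),
            r_app=float(v["r_app"]),
            cov=cov,
            curve=c,
            fixed=fixed,
            converged=bool(best.success),
            self_term=self_term,
        )


def fit_autocorr(curve: CorrelationCurve, **kwargs) -> AutoCorrResults:
    """Functional wrapper over :class:`AutoCorrelationModel`."""
    return AutoCorrelationModel(curve).fit(**kwargs)


@dataclass
class FocusMetrics:
    n_mean: float
    foci_density: float | None  # um^-2; None when n_mean == 0


def focus_metrics(fit: AutoCorrResults) -> FocusMetrics:
    """Mean molecular content per focus and foci density.

    N = 2 pi <rho> A r_app^2 with rho in um^-2 and r_app converted to um;
    foci density is <rho> / N, undefined (None) when N = 0.
    """
    r_app_um = fit.r_app / 1000.0
    n_mean = 2.0 * np.pi * fit.rho_mean * fit.amplitude * r_app_um**2
    if n_mean <= 0:
        return FocusMetrics(n_mean=float(n_mean), foci_density=None)
    return FocusMetrics(n_mean=float(n_mean), foci_density=float(fit.rho_mean / n_mean))


# ---------------------------------------------------------------------------
# cross-correlation fit
# ---------------------------------------------------------------------------

def crosscorr_model(r, amp, x_c, sigma):
    return amp * (
        np.exp(-((r - x_c) ** 2) / (2.0 * sigma**2))
        + np.exp(-((r + x_c) ** 2) / (2.0 * sigma**2))
    ) + 1.0


@dataclass
class CrossCorrResults:
    amplitude: float
    x_c: float  # nm
    sigma: float  # nm
    cov: np.ndarray | None
    curve: CorrelationCurve
    converged: bool = True

    @property
    def rho_p(self) -> float:
        return self.curve.n_points[0] / self.curve.roi_area_um2

    @property
    def rho_q(self) -> float:
        return self.curve.n_points[1] / self.curve.roi_area_um2

    @property
    def around_density_qp(self) -> float:
        """Average local density of Q around each P (A * <rho_Q>, um^-2)."""
        return self.amplitude * self.rho_q

    @property
    def around_density_pq(self) -> float:
        """Average local density of P around each Q (A * <rho_P>, um^-2)."""
        return self.amplitude * self.rho_p

    def predict(self, r=None) -> np.ndarray:
        r = self.curve.r if r is None else np.asarray(r, dtype=float)
        return crosscorr_model(r, self.amplitude, self.x_c, self.sigma)

    def summary(self) -> str:
        return "\n".join(
            [
                "Cross-correlation fit (symmetric Gaussian model)",
                f"  A (correlation amplitude)     : {self.amplitude:10.4f}",
                f"  x_c (center-to-center dist.)  : {self.x_c:10.3f} nm",
                f"  sigma (dispersion radius)     : {self.sigma:10.3f} nm",
                f"  A<rho_Q> (Q around each P)    : {self.around_density_qp:10.4f} um^-2",
                f"  A<rho_P> (P around each Q)    : {self.around_density_pq:10.4f} um^-2",
                f"  converged                     : {self.converged}",
            ]
        )


class CrossCorrelationModel:
    """Weighted least-squares fit of the symmetric displaced-Gaussian c(r)."""

    def __init__(self, curve: CorrelationCurve):
        self.curve = curve

    def fit(self, init: dict | None = None) -> CrossCorrResults:
        c = self.curve
        m = c.pairs > 0
        r, v, wgt = c.r[m], c.value[m], np.sqrt(c.pairs[m])
        init = init or {}
        a0 = init.get("A", max(float(np.max(v) - 1.0), 0.01))
        xc_grid = [init["x_c"]] if "x_c" in init else [0.0, float(r[np.argmax(v)]), 100.0]
        sig_grid = [init["sigma"]] if "sigma" in init else [10.0, 30.0, 100.0]

        def resid(theta):
            return wgt * (crosscorr_model(r, *theta) - v)

        best = None
        for xc0 in xc_grid:
            for s0 in sig_grid:
                try:
                    res = least_squares(
                        resid,
                        [a0, xc0, s0],
                        bounds=([0.0, 0.0, 1e-2], [np.inf, float(r[-1]), np.inf]),
                        max_nfev=2000,
                    )
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
        if best is None:
            raise RuntimeError("cross-correlation fit failed from every start")
        try:
            jtj = best.jac.T @ best.jac
            dof = max(len(r) - 3, 1)
            cov = np.linalg.inv(jtj) * 2 * best.cost / dof
        except np.linalg.LinAlgError:
            cov = None
        return CrossCorrResults(
            amplitude=float(best.x[0]),
            x_c=float(best.x[1]),
            sigma=float(best.x[2]),
            cov=cov,
            curve=c,
            converged=bool(best.success),
        )


def fit_crosscorr(curve: CorrelationCurve, **kwargs) -> CrossCorrResults:
    """Functional wrapper over :class:`CrossCorrelationModel`."""
    return CrossCorrelationModel(curve).fit(**kwargs)
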