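"""Rendering and quantitative assessment of super-resolution reconstructions.

Covers the bookkeeping and statistics used to judge predicted images against
ground truth: histogram rendering with an optional one-pixel Gaussian blur,
linking of localizations that persist over consecutive frames, emitter
density and acquisition-time accounting, localization-precision estimation
from nearest-neighbour distances in adjacent frames (NeNA), paired
cluster-area analysis of binarized images, and a plain intensity-normalized
Pearson correlation between images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .io_formats import LocalizationTable

logger = logging.getLogger("paintdense")

__all__ = [
    "RenderConfig",
    "ClusterRecord",
    "render_image",
    "link_localizations",
    "emitter_density",
    "acquisition_time",
    "nena_precision",
    "cluster_area_analysis",
    "normalized_pcc",
    "match_localizations",
]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters: oversampling factor and blur mode."""

    oversampling: int = 8
    blur: str = "one_pixel"  # "none" | "one_pixel"

    def __post_init__(self) -> None:
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.blur not in ("none", "one_pixel"):
            raise ValueError(f"unknown blur mode {self.blur!r}")


@dataclass
class ClusterRecord:
    """One connected component of a binarized image."""

    label: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y)
    source: str  # "gt" | "predicted"

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("cluster area must be > 0")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_image(locs: LocalizationTable, shape: tuple[int, int],
                 cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """2D histogram of localizations on an oversampled grid.

    ``shape`` is the camera frame shape (H, W); the output is
    (H * os, W * os). Camera pixel-centre coordinate x falls into rendered
    pixel floor((x + 0.5) * os). With ``blur="one_pixel"`` the histogram is
    convolved with a Gaussian of sigma 1 rendered pixel. Total intensity
    equals the localization count up to boundary truncation of the blur.
    """
    H, W = shape
    os_ = cfg.oversampling
    img = np.zeros((H * os_, W * os_), dtype=np.float64)
    if len(locs) == 0:
        logger.warning("render_image: empty localization table -> zero image")
        return img
    x = locs["x"]
    y = locs["y"]
    ix = np.floor((x + 0.5) * os_).astype(int)
    iy = np.floor((y + 0.5) * os_).astype(int)
    ok = (ix >= 0) & (ix < W * os_) & (iy >= 0) & (iy < H * os_)
    np.add.at(img, (iy[ok], ix[ok]), 1.0)
    if cfg.blur == "one_pixel":
        img = ndimage.gaussian_filter(img, sigma=1.0, mode="constant")
    return img


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


def link_localizations(locs: LocalizationTable, max_distance: float,
                       max_dark_frames: int = 0) -> LocalizationTable:
    """Merge localizations that persist across consecutive frames.

    Chains are grown greedily frame by frame: each localization in frame t is
    matched to the nearest open chain whose last member is within
    ``max_distance`` pixels and at most ``max_dark_frames`` frames in the
    past (nearest-first; ties to the chain started earlier). Each chain is
    emitted as one record at the photon-weighted mean position with summed
    photons, first frame index, and an extra ``len`` column.
    """
    df = locs.df
    if len(df) == 0:
        return locs
    chains = []  # dicts: x, y, w (photon sums), last_frame, first_frame, n, extras
    open_idx: list[int] = []

    for frame, grp in df.groupby("frame", sort=True):
        frame = int(frame)
        open_idx = [i for i in open_idx
                    if frame - chains[i]["last_frame"] <= max_dark_frames + 1]
        gx = grp["x"].to_numpy()
        gy = grp["y"].to_numpy()
        gp = grp["photons"].to_numpy()
        if open_idx and len(gx):
            last = np.array([[chains[i]["lx"], chains[i]["ly"]] for i in open_idx])
            d = np.hypot(last[:, 0:1] - gx[None, :], last[:, 1:2] - gy[None, :])
            d[d > max_distance] = np.inf
            pairs = []
            while np.isfinite(d).any():
                ci, li = np.unravel_index(np.argmin(d), d.shape)
                pairs.append((open_idx[ci], li))
                d[ci, :] = np.inf
                d[:, li] = np.inf
            matched_locs = {li for _, li in pairs}
        else:
            pairs = []
            matched_locs = set()
        for chain_i, li in pairs:
            ch = chains[chain_i]
            w = gp[li]
            ch["sx_w"] += gx[li] * w
            ch["sy_w"] += gy[li] * w
            ch["w"] += w
            ch["lx"], ch["ly"] = gx[li], gy[li]
            ch["last_frame"] = frame
            ch["n"] += 1
        for li in range(len(gx)):
            if li in matched_locs:
                continue
            chains.append({"sx_w": gx[li] * gp[li], "sy_w": gy[li] * gp[li],
                           "w": gp[li], "lx": gx[li], "ly": gy[li],
                           "first_frame": frame, "last_frame": frame, "n": 1})
            open_idx.append(len(chains) - 1)

    out = pd.DataFrame(
        {
            "frame": [c["first_frame"] for c in chains],
            "x": [c["sx_w"] / c["w"] for c in chains],
            "y": [c["sy_w"] / c["w"] for c in chains],
            "photons": [c["w"] for c in chains],
            "sx": 1.0,
            "sy": 1.0,
            "bg": 0.0,
            "lpx": 0.1,
            "lpy": 0.1,
            "len": [c["n"] for c in chains],
        }
    )
    return LocalizationTable(out)


# ---------------------------------------------------------------------------
# Density and time accounting
# ---------------------------------------------------------------------------


def emitter_density(locs: LocalizationTable, field_area_um2: float,
                    n_frames: int) -> float:
    """Mean localizations per µm² per frame."""
    if field_area_um2 <= 0 or n_frames < 1:
        raise ValueError("field_area_um2 must be > 0 and n_frames >= 1")
    return len(locs) / (field_area_um2 * n_frames)


def acquisition_time(n_frames: int, integration_time: float) -> float:
    """Total acquisition time in seconds, exact in decimal arithmetic.

    The integration time is interpreted as a decimal number (e.g. 0.15 s), so
    10,000 frames at 150 ms give exactly 1500 s = 25 min with no binary
    float residue.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    return float(Fraction(str(integration_time)) * n_frames)


# ---------------------------------------------------------------------------
# NeNA localization precision
# ---------------------------------------------------------------------------


def _adjacent_frame_distances(locs: LocalizationTable, pixel_size: float) -> np.ndarray:
    """Nearest-neighbour distance (nm) from each loc in frame t to frame t+1."""
    df = locs.df
    by_frame = {int(f): g[["x", "y"]].to_numpy() * pixel_size
                for f, g in df.groupby("frame")}
    dists = []
    for f, pts in by_frame.items():
        nxt = by_frame.get(f + 1)
        if nxt is None or len(nxt) == 0 or len(pts) == 0:
            continue
        d, _ = cKDTree(nxt).query(pts, k=1)
        dists.append(d)
    return np.concatenate(dists) if dists else np.empty(0)


def nena_precision(locs: LocalizationTable, pixel_size: float,
                   cutoff_nm: float = 100.0) -> tuple[float, dict]:
    """Localization precision from nearest neighbours in adjacent frames.

    Collects, for every localization in frame t, the distance to its nearest
    neighbour in frame t + 1; an emitter localized twice with per-axis
    precision sigma yields displacement distances following

        p(d) = d / (2 sigma^2) * exp(-d^2 / (4 sigma^2)),

    to which a uniform-in-area background term (linear in d) is added for
    unrelated neighbours. The mixture is fitted by maximum likelihood over
    d < ``cutoff_nm``; returns (sigma_nm, diagnostics).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if locs.n_frames_spanned < 2:
        raise ValueError("need localizations spanning >= 2 frames")
    d_all = _adjacent_frame_distances(locs, pixel_size)
    d = d_all[d_all < cutoff_nm]
    if len(d) < 100:
        raise ValueError(
            f"only {len(d)} nearest-neighbour distances below {cutoff_nm} nm; "
            "need >= 100 for a stable fit")

    dmax = cutoff_nm
    d = np.maximum(d, 1e-6)

    def nll(params):
        log_sigma, logit_w = params
        sigma = np.exp(log_sigma)
        w = 1.0 / (1.0 + np.exp(-logit_w))
        s2 = 2.0 * sigma**2
        norm = -np.expm1(-dmax**2 / (2.0 * s2))  # truncated-Rayleigh mass
        rayl = d / s2 * np.exp(-(d**2) / (2.0 * s2)) / max(norm, 1e-300)
        bg = 2.0 * d / dmax**2
        p = (1.0 - w) * rayl + w * bg
        return -np.log(np.maximum(p, 1e-300)).sum()

    best = None
    for sigma0 in (2.0, 5.0, 15.0, 40.0):
        res = optimize.minimize(nll, x0=[np.log(sigma0), -2.0], method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    sigma = float(np.exp(best.x[0]))
    w = float(1.0 / (1.0 + np.exp(-best.x[1])))
    diag = {"n_pairs": int(len(d)), "background_weight": w,
            "neg_log_likelihood": float(best.fun), "cutoff_nm": cutoff_nm,
            "converged": bool(best.success)}
    return sigma, diag


# ---------------------------------------------------------------------------
# Cluster-area analysis
# ---------------------------------------------------------------------------


def _clusters(img: np.ndarray, pixel_size_nm: float, min_area_px: int,
              source: str) -> list[ClusterRecord]:
    thr = threshold_otsu(img, nbins=256)
    lab = cc_label(img > thr, connectivity=2)
    px_um = pixel_size_nm / 1000.0
    out = []
    for rp in regionprops(lab):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid
        out.append(ClusterRecord(label=rp.label, area_um2=rp.area * px_um**2,
                                 centroid_um=(cx * px_um, cy * px_um), source=source))
    return out


def cluster_area_analysis(img_gt: np.ndarray, img_pred: np.ndarray,
                          pixel_size_out_nm: float, min_area_px: int = 4,
                          pairing_radius_nm: float = 250.0):
    """Paired cluster areas of two registered images, with slope and Pearson r.

    Each image is binarized with Otsu's threshold (256-bin histogram),
    8-connected components are labeled, components smaller than
    ``min_area_px`` rendered pixels are dropped, and clusters are paired by
    nearest centroid within ``pairing_radius_nm``. Paired areas are fitted by
    least squares through the origin (area_pred = slope * area_gt); Pearson r
    is computed over the pairs. Returns (pairs DataFrame, slope, r).
    """
    if img_gt.shape != img_pred.shape:
        raise ValueError("images must have the same shape (registered)")
    gt = _clusters(img_gt, pixel_size_out_nm, min_area_px, "gt")
    pr = _clusters(img_pred, pixel_size_out_nm, min_area_px, "predicted")
    if not gt or not pr:
        raise ValueError("no clusters found in at least one image")
    pr_cent = np.array([c.centroid_um for c in pr])
    tree = cKDTree(pr_cent)
    radius_um = pairing_radius_nm / 1000.0
    rows = []
    used = set()
    for g in gt:
        d, j = tree.query(g.centroid_um, k=1)
        if d <= radius_um and j not in used:
            used.add(j)
            rows.append({"gt_label": g.label, "pred_label": pr[j].label,
                         "area_gt_um2": g.area_um2, "area_pred_um2": pr[j].area_um2,
                         "centroid_dist_um": float(d)})
    if not rows:
        raise ValueError("no cluster pairs within the pairing radius")
    pairs = pd.DataFrame(rows)
    a = pairs["area_gt_um2"].to_numpy()
    b = pairs["area_pred_um2"].to_numpy()
    slope = float((a * b).sum() / (a * a).sum())
    r = float(np.corrcoef(a, b)[0, 1]) if len(pairs) > 1 else 1.0
    logger.info("cluster_area_analysis: %d pairs, slope=%.3f, r=%.3f",
                len(pairs), slope, r)
    return pairs, slope, r


def normalized_pcc(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Pearson correlation of intensity-normalized images, in [-1, 1]."""
    a = np.asarray(img_a, dtype=float).ravel()
    b = np.asarray(img_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Localization matching (recall / precision / RMSE vs ground truth)
# ---------------------------------------------------------------------------


def match_localizations(gt: LocalizationTable, pred: LocalizationTable,
                        max_dist_px: float = 1.0) -> dict:
    """Frame-by-frame greedy nearest matching of predicted to true emitters.

    Within each frame, candidate pairs closer than ``max_dist_px`` camera
    pixels are matched nearest-first (one-to-one). Returns recall, precision,
    RMSE over matched pairs (camera pixels), and the counts involved.
    """
    gt_by = {int(f): g[["x", "y"]].to_numpy() for f, g in gt.df.groupby("frame")}
    pr_by = {int(f): g[["x", "y"]].to_numpy() for f, g in pred.df.groupby("frame")}
    n_gt = len(gt)
    n_pred = len(pred)
    n_match = 0
    sq = 0.0
    for f, gpts in gt_by.items():
        ppts = pr_by.get(f)
        if ppts is None or len(ppts) == 0:
            continue
        d = np.hypot(gpts[:, 0:1] - ppts[None, :, 0].reshape(1, -1),
                     gpts[:, 1:2] - ppts[None, :, 1].reshape(1, -1))
        d[d > max_dist_px] = np.inf
        while np.isfinite(d).any():
            gi, pi = np.unravel_index(np.argmin(d), d.shape)
            sq += d[gi, pi] ** 2
            n_match += 1
            d[gi, :] = np.inf
            d[:, pi] = np.inf
    recall = n_match / n_gt if n_gt else 0.0
    precision = n_match / n_pred if n_pred else 0.0
    rmse = float(np.sqrt(sq / n_match)) if n_match else float("inf")
    return {"recall": recall, "precision": precision, "rmse_px": rmse,
            "n_gt": n_gt, "n_pred": n_pred, "n_matched": n_match}
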