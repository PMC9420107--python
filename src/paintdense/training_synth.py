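"""Training-patch synthesis: sparse emitter frames summed into dense patches.

Re-implements the image-summing procedure for building a high-density
training set from sparse DNA-PAINT data: crop a small patch around every
localization of a sparse movie, then sum k randomly chosen patches to obtain
a dense patch whose coordinate list is the exact concatenation of the k input
lists. Summing k raw patches accumulates the camera offset k times, so
(k - 1) * offset is subtracted from every output; the offset itself is
estimated from a dark (closed-shutter) movie. The same arithmetic applied to
whole frames (``sum_frame_groups``) turns a low-concentration movie into an
artificial high-density one: assuming emitters scale linearly with imager
concentration, summing groups of round(c_target / c_low) frames emulates an
acquisition at c_target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import LocalizationTable, Movie, PatchSet

logger = logging.getLogger("paintdense")

__all__ = [
    "SummingConfig",
    "extract_sparse_patches",
    "estimate_offset",
    "sum_patches",
    "choose_k_for_density",
    "sum_frame_groups",
    "concentration_group_factor",
]


@dataclass
class SummingConfig:
    """Parameters of the patch extraction + summing stage.

    ``patch_size`` (P) is the square crop side in camera pixels (16 and 17 are
    the two sizes in common use); ``min_emitters`` the minimum coordinates a
    sparse patch must contain; ``k_per_output`` the number of sparse patches
    summed per output (overridden when ``target_density`` is set, in which
    case k is derived so outputs land at that mean density in emitters/µm²);
    ``n_outputs`` the number of dense patches to produce.
    """

    patch_size: int = 16
    min_emitters: int = 1
    k_per_output: int = 1
    n_outputs: int = 1
    target_density: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.min_emitters < 1:
            raise ValueError("min_emitters must be >= 1")
        if self.k_per_output < 1 or self.n_outputs < 1:
            raise ValueError("k_per_output and n_outputs must be >= 1")


def extract_sparse_patches(movie: Movie, locs: LocalizationTable,
                           cfg: SummingConfig) -> PatchSet:
    """Crop one P x P patch per retained localization of a sparse movie.

    The crop is centred on the integer pixel containing the localization
    (column floor(x), row floor(y)); with half = floor(P/2) the crop spans
    columns [floor(x) - half, floor(x) - half + P). The patch's coordinate
    list holds ALL localizations of that frame falling inside the crop, in
    patch-local sub-pixel coordinates, so the centre localization maps to
    (x - floor(x) + half, y - floor(y) + half). Crops that would exceed the
    image bounds are discarded; patches with fewer than ``min_emitters``
    coordinates are dropped.
    """
    P = cfg.patch_size
    half = P // 2
    H, W = movie.frame_shape
    if len(locs) == 0:
        logger.warning("empty localization table: returning empty PatchSet")
        return PatchSet(patches=np.empty((0, P, P), dtype=movie.frames.dtype),
                        coords=[], provenance="sparse", camera=movie.camera)

    patches, coords = [], []
    n_border = 0
    df = locs.df
    for frame_idx, grp in df.groupby("frame", sort=True):
        frame_idx = int(frame_idx)
        if frame_idx >= movie.n_frames:
            continue
        frame = movie.frames[frame_idx]
        gx = grp["x"].to_numpy()
        gy = grp["y"].to_numpy()
        for x, y in zip(gx, gy):
            cx, cy = int(np.floor(x)), int(np.floor(y))
            x0, y0 = cx - half, cy - half
            if x0 < 0 or y0 < 0 or x0 + P > W or y0 + P > H:
                n_border += 1
                continue
            inside = (gx >= x0) & (gx < x0 + P) & (gy >= y0) & (gy < y0 + P)
            local = np.column_stack([gx[inside] - x0, gy[inside] - y0])
            if len(local) < cfg.min_emitters:
                continue
            patches.append(frame[y0:y0 + P, x0:x0 + P])
            coords.append(local)

    logger.info("extract_sparse_patches: kept %d patches, discarded %d at borders",
                len(patches), n_border)
    if not patches:
        logger.warning("no patches retained (all at borders?)")
        return PatchSet(patches=np.empty((0, P, P), dtype=movie.frames.dtype),
                        coords=[], provenance="sparse", camera=movie.camera)
    return PatchSet(patches=np.stack(patches), coords=coords,
                    provenance="sparse", camera=movie.camera)


def estimate_offset(dark_movie: Movie) -> float:
    """Camera offset = mean pixel intensity of closed-shutter frames."""
    if dark_movie.n_frames == 0 or dark_movie.frames.size == 0:
        raise ValueError("dark movie must contain at least one frame")
    return float(dark_movie.frames.mean())


def sum_patches(sparse: PatchSet, cfg: SummingConfig, offset: float) -> PatchSet:
    """Sum k randomly chosen sparse patches per output, correcting the offset.

    Each output = elementwise sum of k sparse patches minus (k - 1) * offset,
    clipped at 0 (counts are physically nonnegative; clipped pixels are
    counted in the log). Its coordinate list is the concatenation of the k
    input lists, so emitter counts are conserved exactly. The k inputs are
    drawn uniformly without replacement within one output and with
    replacement across outputs; deterministic per ``cfg.seed``.
    """
    k = cfg.k_per_output
    n_sparse = len(sparse)
    if k > n_sparse:
        raise ValueError(f"k_per_output={k} exceeds number of sparse patches {n_sparse}")
    rng = np.random.default_rng(cfg.seed)
    P = sparse.patch_size
    out = np.empty((cfg.n_outputs, P, P), dtype=np.float64)
    out_coords = []
    n_clipped = 0
    src = sparse.patches.astype(np.float64)
    for i in range(cfg.n_outputs):
        idx = rng.choice(n_sparse, size=k, replace=False)
        s = src[idx].sum(axis=0) - (k - 1) * offset
        n_clipped += int((s < 0).sum())
        out[i] = np.maximum(s, 0.0)
        out_coords.append(np.concatenate([sparse.coords[j] for j in idx])
                          if k else np.empty((0, 2)))
    if n_clipped:
        logger.info("sum_patches: clipped %d negative pixels to 0", n_clipped)
    ps = PatchSet(patches=out, coords=out_coords, provenance="summed",
                  camera=sparse.camera)
    logger.info("sum_patches: %d outputs at %.2f emitters/µm² mean density",
                len(ps), ps.density_per_um2())
    return ps


def choose_k_for_density(target_density: float, mean_emitters_per_patch: float,
                         patch_size: int, pixel_size: float) -> int:
    """Patches to sum so outputs hit ``target_density`` emitters/µm².

    k = max(1, round(target_density * (P * pixel_size / 1000)^2 / mean)),
    i.e. the number of mean-occupancy sparse patches whose emitters fill the
    patch area to the target.
    """
    if min(target_density, mean_emitters_per_patch, patch_size, pixel_size) <= 0:
        raise ValueError("all inputs must be positive")
    area_um2 = (patch_size * pixel_size / 1000.0) ** 2
    return max(1, round(target_density * area_um2 / mean_emitters_per_patch))


def sum_frame_groups(movie: Movie, group_size: int, offset: float,
                     seed: int = 0) -> Movie:
    """Sum randomized groups of frames into an artificial high-density movie.

    The (drift-corrected) input frames are randomly permuted (seeded),
    partitioned into consecutive groups of ``group_size`` (remainder frames
    dropped), and each group is summed and reduced by (group_size - 1) *
    offset, clipped at 0. The output has floor(N / group_size) frames.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = movie.n_frames
    if n < group_size:
        raise ValueError(f"movie has {n} frames, fewer than group_size={group_size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_out = n // group_size
    used = perm[: n_out * group_size].reshape(n_out, group_size)
    src = movie.frames.astype(np.float64)
    out = src[used].sum(axis=1) - (group_size - 1) * offset
    n_clipped = int((out < 0).sum())
    if n_clipped:
        logger.info("sum_frame_groups: clipped %d negative pixels to 0", n_clipped)
    out = np.maximum(out, 0.0)
    return Movie(frames=out, integration_time=movie.integration_time,
                 camera=movie.camera)


def concentration_group_factor(c_low: float, c_target: float) -> int:
    """Group size emulating c_target from c_low data: round(c_target / c_low).

    Assumes emitter density scales linearly with imager concentration (valid
    at low site occupancy), e.g. 0.5 nM -> 20 nM gives 40.
    """
    if c_low <= 0:
        raise ValueError("c_low must be > 0")
    if c_target < c_low:
        raise ValueError(f"c_target={c_target} below c_low={c_low}")
    return int(round(c_target / c_low))
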