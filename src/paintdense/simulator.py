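"""Synthetic DNA-PAINT movies with known ground truth.

The simulator emulates a DNA-PAINT acquisition: docking sites arranged into
biological morphologies (filaments, dense 2D patches, mitochondria-like
outlines), transient imager binding at each site following two-state
kinetics, and EMCCD image formation with a Gaussian PSF.

Kinetics model
--------------
Each docking site alternates independently between an unbound state with
association rate ``r = concentration * k_on`` (per second) and a bound
("bright") state with exponential dwell time of mean ``tau_bright``. The
stationary probability of being bound is

    p = r * tau_bright / (1 + r * tau_bright)

and the expected number of simultaneously bright emitters per frame is
``N_sites * p``. DNA-PAINT has no bleaching, so this density is stationary
over arbitrarily long movies; the imager concentration is the knob that moves
an acquisition between the sparse (~0.028 /µm², pM-range), ground-truth and
high-density (1.6-6 /µm², nM-range) regimes.

The kinetic constants default to typical DNA-PAINT literature values
(k_on = 1e6 /M/s, tau_bright = 0.5 s, 2000 detected photons per full frame);
the validated observable is the resulting emitter density, not the constants
themselves, which is why :func:`concentration_for_density` exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .io_formats import CameraModel, LocalizationTable, Movie

__all__ = [
    "EmitterField",
    "KineticsConfig",
    "StructureSpec",
    "place_structures",
    "simulate_binding",
    "render_frames",
    "expected_density",
    "measured_density",
    "concentration_for_density",
    "uniform_field",
    "simulate_movie",
]


# ---------------------------------------------------------------------------
# Ground-truth structures
# ---------------------------------------------------------------------------


@dataclass
class EmitterField:
    """Docking-site coordinates with structure labels.

    ``x_nm``/``y_nm`` are continuous positions in nm within a rectangular
    field of size ``field_size_nm`` (width, height); ``labels`` holds one of
    ``filament | patch | outline`` per site.
    """

    x_nm: np.ndarray
    y_nm: np.ndarray
    labels: np.ndarray
    field_size_nm: tuple[float, float]

    def __post_init__(self) -> None:
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.labels = np.asarray(self.labels)
        w, h = self.field_size_nm
        if len(self.x_nm) != len(self.y_nm) or len(self.x_nm) != len(self.labels):
            raise ValueError("site arrays must have equal length")
        if len(self.x_nm) and (
            self.x_nm.min() < 0 or self.x_nm.max() > w or self.y_nm.min() < 0 or self.y_nm.max() > h
        ):
            raise ValueError("sites must lie within the field")

    @property
    def n_sites(self) -> int:
        return len(self.x_nm)

    @property
    def area_um2(self) -> float:
        w, h = self.field_size_nm
        return (w / 1000.0) * (h / 1000.0)


@dataclass(frozen=True)
class KineticsConfig:
    """Imager binding and photon-budget parameters.

    k_on is the association rate in /M/s, tau_bright the mean bright (bound)
    time in s, concentration the molar imager concentration, photons_per_frame
    the mean number of *detected* photons for a binding spanning one full
    frame, psf_sigma_nm the Gaussian PSF sigma, and bg_photons the mean
    detected background photons per pixel per frame (unbound imagers).
    """

    k_on: float = 1.0e6
    tau_bright: float = 0.5
    concentration: float = 5.0e-9
    photons_per_frame: float = 2000.0
    psf_sigma_nm: float = 110.0
    bg_photons: float = 10.0

    def __post_init__(self) -> None:
        for name in ("k_on", "tau_bright", "photons_per_frame", "psf_sigma_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.concentration < 0 or self.bg_photons < 0:
            raise ValueError("concentration and bg_photons must be >= 0")

    @property
    def on_rate(self) -> float:
        """Per-site association rate r = c * k_on in /s."""
        return self.concentration * self.k_on

    @property
    def occupancy(self) -> float:
        """Stationary probability p that a site is bound."""
        rt = self.on_rate * self.tau_bright
        return rt / (1.0 + rt)


@dataclass
class StructureSpec:
    """Counts and geometry of the synthetic structures in a field.

    Filaments are random polylines carrying sites at a linear density
    (microtubule-like, "1D"); patches are uniformly filled disks (dense "2D"
    regions); outlines are ellipse perimeters (mitochondria-like "1D").
    """

    n_filaments: int = 0
    n_patches: int = 0
    n_outlines: int = 0
    filament_length_um: float = 2.0
    filament_site_density_per_um: float = 50.0
    filament_segments: int = 4
    patch_radius_um: float = 0.3
    patch_site_density_per_um2: float = 400.0
    outline_semi_axes_um: tuple[float, float] = (0.5, 0.25)
    outline_site_density_per_um: float = 50.0

    def __post_init__(self) -> None:
        if min(self.n_filaments, self.n_patches, self.n_outlines) < 0:
            raise ValueError("structure counts must be nonnegative")


def _random_polyline(rng, length_nm, n_segments, field_w, field_h):
    """Random polyline of total length length_nm, folded into the field."""
    seg = length_nm / n_segments
    start = rng.uniform([0.1 * field_w, 0.1 * field_h], [0.9 * field_w, 0.9 * field_h])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    for _ in range(n_segments):
        heading += rng.normal(0.0, 0.4)
        nxt = pts[-1] + seg * np.array([np.cos(heading), np.sin(heading)])
        # bounce off field borders to keep the polyline inside
        for k, lim in enumerate((field_w, field_h)):
            if nxt[k] < 0 or nxt[k] > lim:
                nxt[k] = np.clip(2 * np.clip(nxt[k], 0, lim) - nxt[k], 0, lim)
                heading = np.pi - heading if k == 0 else -heading
        pts.append(nxt)
    return np.asarray(pts)


def _sample_on_polyline(rng, pts, n):
    seg_vec = np.diff(pts, axis=0)
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = rng.uniform(0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return pts[idx] + frac[:, None] * seg_vec[idx]


def place_structures(spec: StructureSpec, field_size_nm, seed: int = 0) -> EmitterField:
    """Lay out docking sites for the requested structures; deterministic per seed."""
    w, h = float(field_size_nm[0]), float(field_size_nm[1])
    if w <= 0 or h <= 0:
        raise ValueError("field_size must be > 0")
    rng = np.random.default_rng(seed)
    xs, ys, labels = [], [], []

    for _ in range(spec.n_filaments):
        pts = _random_polyline(rng, spec.filament_length_um * 1000.0, spec.filament_segments, w, h)
        n = rng.poisson(spec.filament_length_um * spec.filament_site_density_per_um)
        if n:
            p = _sample_on_polyline(rng, pts, n)
            xs.append(p[:, 0])
            ys.append(p[:, 1])
            labels.append(np.full(n, "filament"))

    for _ in range(spec.n_patches):
        r_nm = spec.patch_radius_um * 1000.0
        cx = rng.uniform(r_nm, max(w - r_nm, r_nm))
        cy = rng.uniform(r_nm, max(h - r_nm, r_nm))
        area = np.pi * spec.patch_radius_um**2
        n = rng.poisson(spec.patch_site_density_per_um2 * area)
        if n:
            rad = r_nm * np.sqrt(rng.uniform(0, 1, n))
            ang = rng.uniform(0, 2 * np.pi, n)
            xs.append(np.clip(cx + rad * np.cos(ang), 0, w))
            ys.append(np.clip(cy + rad * np.sin(ang), 0, h))
            labels.append(np.full(n, "patch"))

    for _ in range(spec.n_outlines):
        a_nm = spec.outline_semi_axes_um[0] * 1000.0
        b_nm = spec.outline_semi_axes_um[1] * 1000.0
        cx = rng.uniform(a_nm, max(w - a_nm, a_nm))
        cy = rng.uniform(a_nm, max(h - a_nm, a_nm))
        tilt = rng.uniform(0, np.pi)
        # Ramanujan perimeter approximation
        per_um = np.pi * (3 * (a_nm + b_nm) - np.sqrt((3 * a_nm + b_nm) * (a_nm + 3 * b_nm))) / 1000.0
        n = rng.poisson(spec.outline_site_density_per_um * per_um)
        if n:
            t = rng.uniform(0, 2 * np.pi, n)
            ex = a_nm * np.cos(t)
            ey = b_nm * np.sin(t)
            rx = ex * np.cos(tilt) - ey * np.sin(tilt)
            ry = ex * np.sin(tilt) + ey * np.cos(tilt)
            xs.append(np.clip(cx + rx, 0, w))
            ys.append(np.clip(cy + ry, 0, h))
            labels.append(np.full(n, "outline"))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        lab = np.concatenate(labels)
    else:
        x = np.empty(0)
        y = np.empty(0)
        lab = np.empty(0, dtype="<U8")
    return EmitterField(x_nm=x, y_nm=y, labels=lab, field_size_nm=(w, h))


def uniform_field(n_sites: int, field_size_nm, seed: int = 0,
                  label: str = "patch") -> EmitterField:
    """Docking sites uniformly scattered over the field (structureless control)."""
    rng = np.random.default_rng(seed)
    w, h = float(field_size_nm[0]), float(field_size_nm[1])
    return EmitterField(
        x_nm=rng.uniform(0, w, n_sites),
        y_nm=rng.uniform(0, h, n_sites),
        labels=np.full(n_sites, label),
        field_size_nm=(w, h),
    )


# ---------------------------------------------------------------------------
# Binding kinetics
# ---------------------------------------------------------------------------


def simulate_binding(field: EmitterField, kinetics: KineticsConfig, n_frames: int,
                     integration_time: float, seed: int = 0) -> pd.DataFrame:
    """Simulate transient imager binding at every docking site.

    Each site is an independent stationary alternating-renewal process:
    exponential unbound waits with rate ``r = c * k_on`` and exponential bound
    dwells with mean ``tau_bright``; the initial state is drawn from the
    stationary occupancy so the emitter density has no transient. Returns a
    DataFrame with columns ``site``, ``start_frame`` and ``duration_frames``
    (both continuous, in frame units) for every event overlapping the movie.
    """
    if n_frames < 1 or integration_time <= 0:
        raise ValueError("need n_frames >= 1 and integration_time > 0")
    T = n_frames * integration_time
    r = kinetics.on_rate
    n_sites = field.n_sites
    rng = np.random.default_rng(seed)
    empty = pd.DataFrame({"site": np.empty(0, int), "start_frame": np.empty(0),
                          "duration_frames": np.empty(0)})
    if r == 0.0 or n_sites == 0:
        return empty

    tau = kinetics.tau_bright
    p = kinetics.occupancy
    # upper bound on cycles per site over T (mean cycle = 1/r + tau)
    m = T / (1.0 / r + tau)
    n_max = int(np.ceil(m + 6.0 * np.sqrt(m) + 10.0))

    waits = rng.exponential(1.0 / r, size=(n_sites, n_max))
    durs = rng.exponential(tau, size=(n_sites, n_max))
    # stationary start: with prob p the site is already bound at t=0 with a
    # memoryless residual dwell, i.e. its first unbound wait is zero
    bound0 = rng.random(n_sites) < p
    waits[bound0, 0] = 0.0

    # event k of a site starts at sum(waits[:k+1]) + sum(durs[:k])
    starts = np.cumsum(waits, axis=1) + np.concatenate(
        [np.zeros((n_sites, 1)), np.cumsum(durs[:, :-1], axis=1)], axis=1
    )
    keep = starts < T
    if not keep.any():
        return empty
    site_idx = np.broadcast_to(np.arange(n_sites)[:, None], starts.shape)[keep]
    t0 = starts[keep]
    dur = durs[keep]
    order = np.lexsort((t0, site_idx))
    return pd.DataFrame(
        {
            "site": site_idx[order],
            "start_frame": t0[order] / integration_time,
            "duration_frames": dur[order] / integration_time,
        }
    )


def expected_density(field: EmitterField, kinetics: KineticsConfig) -> float:
    """Expected simultaneously-bright emitters per µm² per frame: N*p/area."""
    area = field.area_um2
    if area <= 0:
        raise ValueError("field area must be > 0")
    return field.n_sites * kinetics.occupancy / area


def measured_density(truth: LocalizationTable, kinetics: KineticsConfig,
                     area_um2: float, n_frames: int) -> float:
    """Time-averaged bright emitters per µm² measured from a ground-truth table.

    Counting table rows overstates the instantaneous density by the factor
    (tau_bright + t_int) / tau_bright because an event crossing a frame
    boundary appears in both frames. Weighting each instance by its frame
    overlap (photons / photons_per_frame) removes that bias, giving an
    unbiased estimate of N_sites * occupancy / area.
    """
    if area_um2 <= 0 or n_frames < 1:
        raise ValueError("area_um2 must be > 0 and n_frames >= 1")
    return float(truth["photons"].sum() / kinetics.photons_per_frame
                 / (area_um2 * n_frames))


def concentration_for_density(field: EmitterField, kinetics: KineticsConfig,
                              target_density: float) -> float:
    """Imager concentration (molar) that yields ``target_density`` emitters/µm².

    Inverts p = r*tau/(1+r*tau) with r = c*k_on for the field's site count.
    """
    if field.n_sites == 0:
        raise ValueError("field has no sites")
    p = target_density * field.area_um2 / field.n_sites
    if not 0 <= p < 1:
        raise ValueError(
            f"target density {target_density}/µm² needs occupancy {p:.3f} outside [0, 1)"
        )
    if p == 0:
        return 0.0
    return p / ((1.0 - p) * kinetics.k_on * kinetics.tau_bright)


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------


def _stamp_gaussian(frame: np.ndarray, x_px: float, y_px: float, photons: float,
                    sigma_px: float) -> None:
    """Add an integrated 2D Gaussian (pixel-integrated via erf) in place."""
    H, W = frame.shape
    R = int(np.ceil(4.0 * sigma_px)) + 1
    x0 = max(int(np.floor(x_px)) - R, 0)
    x1 = min(int(np.floor(x_px)) + R + 1, W)
    y0 = max(int(np.floor(y_px)) - R, 0)
    y1 = min(int(np.floor(y_px)) + R + 1, H)
    if x0 >= x1 or y0 >= y1:
        return
    s = sigma_px * np.sqrt(2.0)
    xe = np.arange(x0, x1 + 1) - 0.5  # pixel edges (pixel-centre convention)
    ye = np.arange(y0, y1 + 1) - 0.5
    fx = 0.5 * (erf((xe[1:] - x_px) / s) - erf((xe[:-1] - x_px) / s))
    fy = 0.5 * (erf((ye[1:] - y_px) / s) - erf((ye[:-1] - y_px) / s))
    frame[y0:y1, x0:x1] += photons * np.outer(fy, fx)


def render_frames(events: pd.DataFrame, field: EmitterField, kinetics: KineticsConfig,
                  camera: CameraModel, shape: tuple[int, int], n_frames: int,
                  integration_time: float, seed: int = 0,
                  shot_noise: bool = True) -> tuple[Movie, LocalizationTable]:
    """Render binding events into camera frames; return movie + true positions.

    Every event contributes to each frame it overlaps, with its mean photon
    count scaled by the overlap fraction (pro-rata for partial frames). Counts
    are formed as Poisson(photons + background) * gain + offset + read noise,
    rounded and clipped to the camera's nonnegative integer range. The
    returned table holds the TRUE emitter positions per frame (ground truth,
    not fitted); ``photons`` is each instance's expected detected photons.
    """
    H, W = int(shape[0]), int(shape[1])
    px = camera.pixel_size
    if W * px < field.field_size_nm[0] - 1e-9 or H * px < field.field_size_nm[1] - 1e-9:
        raise ValueError(
            f"frame shape {shape} at {px} nm/px is smaller than the "
            f"{field.field_size_nm} nm field"
        )
    rng = np.random.default_rng(seed)
    sigma_px = kinetics.psf_sigma_nm / px

    # explode events into (frame, site, overlap fraction) instances
    if len(events):
        start = events["start_frame"].to_numpy()
        dur = events["duration_frames"].to_numpy()
        site = events["site"].to_numpy()
        end = start + dur
        f_lo = np.clip(np.floor(start).astype(int), 0, None)
        f_hi = np.clip(np.ceil(end).astype(int), None, n_frames)
        counts = np.clip(f_hi - f_lo, 0, None)
        inst_frame = np.concatenate(
            [np.arange(a, a + c) for a, c in zip(f_lo, counts)]
        ) if counts.sum() else np.empty(0, int)
        inst_site = np.repeat(site, counts)
        inst_start = np.repeat(start, counts)
        inst_end = np.repeat(end, counts)
        overlap = np.minimum(inst_end, inst_frame + 1) - np.maximum(inst_start, inst_frame)
        good = overlap > 1e-9
        inst_frame, inst_site, overlap = inst_frame[good], inst_site[good], overlap[good]
    else:
        inst_frame = np.empty(0, int)
        inst_site = np.empty(0, int)
        overlap = np.empty(0)

    x_px_all = field.x_nm / px
    y_px_all = field.y_nm / px
    photon_mean = kinetics.photons_per_frame * overlap

    order = np.argsort(inst_frame, kind="stable")
    inst_frame, inst_site, photon_mean = inst_frame[order], inst_site[order], photon_mean[order]
    bounds = np.searchsorted(inst_frame, np.arange(n_frames + 1))

    frames = np.empty((n_frames, H, W), dtype=np.uint16)
    photon_map = np.empty((H, W))
    for f in range(n_frames):
        photon_map.fill(kinetics.bg_photons)
        for j in range(bounds[f], bounds[f + 1]):
            s = inst_site[j]
            _stamp_gaussian(photon_map, x_px_all[s], y_px_all[s], photon_mean[j], sigma_px)
        if shot_noise:
            electrons = rng.poisson(photon_map * camera.qe)
        else:
            electrons = photon_map * camera.qe
        counts = electrons * camera.gain + camera.offset
        if shot_noise and camera.read_noise > 0:
            counts = counts + rng.normal(0.0, camera.read_noise, size=counts.shape)
        frames[f] = np.clip(np.rint(counts), 0, 2**16 - 1).astype(np.uint16)

    lp = np.where(photon_mean > 0, sigma_px / np.sqrt(np.maximum(photon_mean, 1.0)), 0.1)
    truth = LocalizationTable.from_arrays(
        frame=inst_frame,
        x=x_px_all[inst_site],
        y=y_px_all[inst_site],
        photons=np.maximum(photon_mean, 1e-6),
        sx=np.full(len(inst_frame), sigma_px),
        sy=np.full(len(inst_frame), sigma_px),
        bg=np.full(len(inst_frame), kinetics.bg_photons),
        lpx=lp,
        lpy=lp,
        site=inst_site,
    )
    movie = Movie(frames=frames, integration_time=integration_time, camera=camera)
    return movie, truth


def simulate_movie(field: EmitterField, kinetics: KineticsConfig, camera: CameraModel,
                   shape: tuple[int, int], n_frames: int, integration_time: float = 0.15,
                   seed: int = 0, shot_noise: bool = True) -> tuple[Movie, LocalizationTable]:
    """Convenience wrapper: binding simulation + rendering with one seed."""
    ss = np.random.SeedSequence(seed).spawn(2)
    events = simulate_binding(field, kinetics, n_frames, integration_time,
                              seed=ss[0].generate_state(1)[0] % 2**31)
    return render_frames(events, field, kinetics, camera, shape, n_frames,
                         integration_time, seed=ss[1].generate_state(1)[0] % 2**31,
                         shot_noise=shot_noise)
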