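"""Spot detection, sub-pixel localization and trajectory linking.

Recovers trajectories from fluorescence image stacks: candidate spots are
local maxima of a band-pass (difference-of-Gaussians) filtered frame above
a robust-SD threshold, refined to sub-pixel precision by least-squares 2-D
Gaussian fitting, then linked frame-to-frame by greedy global nearest
neighbour with optional gap bridging.  Tracks shorter than a minimum
duration (default 15 s) are discarded before any MSD analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .simulate import Trajectory

__all__ = [
    "Localization",
    "LinkingParams",
    "detect_spots",
    "detect_stack",
    "link_tracks",
    "filter_tracks",
]


@dataclass
class Localization:
    frame: int
    x: float  # µm, sub-pixel
    y: float  # µm
    intensity: float  # photons
    fit_sd: float  # µm


@dataclass
class LinkingParams:
    max_disp: float = 0.5  # µm per frame
    max_gap: int = 0  # frames bridged without interpolation
    min_duration: float = 15.0  # seconds, inclusive

    def validate(self) -> None:
        if not (self.max_disp > 0):
            raise ValueError("max_disp must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_duration < 0:
            raise ValueError("min_duration must be >= 0")


def _gauss2d_residual(p, yy, xx, img):
    amp, x0, y0, sd, bg = p
    model = amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sd**2)) + bg
    return (model - img).ravel()


def detect_spots(
    frame_image: np.ndarray,
    expected_psf_sd: float,
    pixel_size: float,
    snr_threshold: float = 4.0,
    frame: int = 0,
) -> list[Localization]:
    """Detect and sub-pixel-localize particles in one 2-D frame.

    Candidates are local maxima of the DoG-filtered image exceeding
    background + snr_threshold × robust background SD (1.4826·MAD); each is
    refined by least-squares 2-D Gaussian fitting in a ±3·PSF-SD window.
    Fits that diverge or drift out of the window are dropped.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"detect_spots expects a 2-D frame, got shape {img.shape}")
    psf_px = expected_psf_sd / pixel_size
    bp = difference_of_gaussians(img, psf_px * 0.8, psf_px * 2.0)
    med = np.median(bp)
    mad = np.median(np.abs(bp - med))
    thresh = med + snr_threshold * 1.4826 * max(mad, 1e-12)
    peaks = peak_local_max(bp, min_distance=max(1, int(2 * psf_px)), threshold_abs=thresh)

    win = max(2, int(np.ceil(3 * psf_px)))
    out: list[Localization] = []
    for r, c in peaks:
        y0, y1 = max(0, r - win), min(img.shape[0], r + win + 1)
        x0, x1 = max(0, c - win), min(img.shape[1], c + win + 1)
        sub = img[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float) + 0.5  # pixel centres
        bg0 = float(np.median(sub))
        p0 = [max(float(img[r, c]) - bg0, 1.0), c + 0.5, r + 0.5, psf_px, bg0]
        try:
            res = least_squares(_gauss2d_residual, p0, args=(yy, xx, sub), max_nfev=200)
        except Exception:
            continue
        amp, xc, yc, sd, bg = res.x
        if not res.success or amp <= 0 or not (0 < sd < 3 * win):
            continue
        if not (x0 <= xc <= x1 and y0 <= yc <= y1):
            continue  # fit left the window
        intensity = float(2 * np.pi * amp * sd**2)
        out.append(
            Localization(
                frame=frame,
                x=float(xc * pixel_size),
                y=float(yc * pixel_size),
                intensity=intensity,
                fit_sd=float(abs(sd) * pixel_size),
            )
        )
    return out


def detect_stack(
    stack: np.ndarray,
    expected_psf_sd: float,
    pixel_size: float,
    snr_threshold: float = 4.0,
) -> dict[int, list[Localization]]:
    """Run detect_spots on every frame of a stack, grouped by frame index."""
    return {
        f: detect_spots(stack[f], expected_psf_sd, pixel_size, snr_threshold, frame=f)
        for f in range(stack.shape[0])
    }


def link_tracks(
    locs_by_frame: Mapping[int, Sequence[Localization]],
    params: LinkingParams,
    frame_interval: float,
) -> list[Trajectory]:
    """Greedy global-nearest-neighbour frame-to-frame linking.

    Candidate pairs within ``max_disp`` are sorted by distance and accepted
    when both ends are unclaimed (ties break by distance, then lower track
    id).  An unmatched track end stays eligible for up to ``max_gap``
    missing frames; bridged gap frames are left absent, not interpolated.
    """
    params.validate()
    if not locs_by_frame:
        return []
    frames = sorted(locs_by_frame)
    # active track: list of (frame, Localization); keyed by creation order
    tracks: list[list[tuple[int, Localization]]] = []
    active: list[int] = []  # indices into tracks
    for loc in locs_by_frame[frames[0]]:
        tracks.append([(frames[0], loc)])
        active.append(len(tracks) - 1)

    for f in frames[1:]:
        locs = list(locs_by_frame.get(f, []))
        # candidate (distance, track_idx, loc_idx), track end within gap limit
        cands = []
        for ti in active:
            last_f, last = tracks[ti][-1]
            if f - last_f > params.max_gap + 1:
                continue
            for li, loc in enumerate(locs):
                d = np.hypot(loc.x - last.x, loc.y - last.y)
                if d <= params.max_disp * (f - last_f):
                    cands.append((d, ti, li))
        cands.sort(key=lambda c: (c[0], c[1]))
        used_t: set[int] = set()
        used_l: set[int] = set()
        for d, ti, li in cands:
            if ti in used_t or li in used_l:
                continue
            tracks[ti].append((f, locs[li]))
            used_t.add(ti)
            used_l.add(li)
        for li, loc in enumerate(locs):
            if li not in used_l:
                tracks.append([(f, loc)])
        # prune ends older than the gap limit, keep fresh ones
        active = [
            ti for ti in range(len(tracks)) if f - tracks[ti][-1][0] <= params.max_gap
        ]

    out = []
    for tid, points in enumerate(tracks):
        fr = np.array([f for f, _ in points], dtype=np.int64)
        out.append(
            Trajectory(
                track_id=tid,
                frames=fr,
                times=fr * frame_interval,
                x=np.array([p.x for _, p in points]),
                y=np.array([p.y for _, p in points]),
            )
        )
    return out


def filter_tracks(tracks: Sequence[Trajectory], params: LinkingParams) -> list[Trajectory]:
    """Keep tracks whose time span ≥ min_duration (inclusive); order preserved."""
    params.validate()
    return [tr for tr in tracks if tr.duration >= params.min_duration - 1e-12]
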