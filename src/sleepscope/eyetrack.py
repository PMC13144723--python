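"""Eye-angle extraction from egocentric head-ROI image frames.

Frames are oriented with the body axis along image rows (anterior at row 0).
Dark eyes on a lighter background are isolated with a difference-of-Gaussian
filter (after intensity inversion), located by projecting intensities onto
the body axis (shared row = projection peak) and onto the orthogonal axis
(two column positions from a bimodal 1-D Gaussian mixture), and their
orientations measured from the second central moments of a rectangular mask
around each center.

Angle convention: 0 aligns an eye's major axis with the body axis; positive
angles are counter-clockwise in the egocentric view, identically for both
eyes, so a conjugate saccade moves both angles in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.mixture import GaussianMixture

from sleepscope import presets


@dataclass
class EyeFit:
    """Per-frame two-eye fit: centers, central moments, angles, quality."""

    center_left: tuple
    center_right: tuple
    moments_left: tuple     # (mu20, mu02, mu11)
    moments_right: tuple
    angle_left_rad: float
    angle_right_rad: float
    quality: float


def dog_filter(
    frame: np.ndarray,
    sigma1_mm: float,
    sigma2_mm: float,
    px_per_mm: float,
    invert: bool = False,
) -> np.ndarray:
    """Difference-of-Gaussian band-pass: G(sigma1)*I - G(sigma2)*I.

    With sigma1 > sigma2, the wide-minus-narrow convention responds
    positively at *dark* eye-sized structures on a lighter background (the
    narrow blur preserves the intensity dip, the wide one averages it away),
    so NIR frames need no inversion; pass ``invert`` for bright-blob images.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("dog_filter expects a 2-D frame")
    if not sigma1_mm > sigma2_mm > 0:
        raise ValueError("need sigma1 > sigma2 > 0")
    img = -frame if invert else frame
    s1 = sigma1_mm * px_per_mm
    s2 = sigma2_mm * px_per_mm
    return gaussian_filter(img, s1) - gaussian_filter(img, s2)


def locate_eyes(filtered: np.ndarray, min_sep_px: float = 2.0):
    """Locate the two eye centers in a (sign-corrected) filtered frame.

    The shared row comes from the peak of the maximum projection onto the
    body axis; the two columns from a bimodal 1-D Gaussian mixture fitted to
    the non-negative column profile, initialized at the two largest local
    maxima.  Returns ((row, col_left), (row, col_right), quality); a
    collapsed mixture (means closer than ``min_sep_px``) yields quality 0.
    """
    resp = np.maximum(np.asarray(filtered, dtype=float), 0.0)
    if resp.sum() <= 0:
        return (0.0, 0.0), (0.0, 0.0), 0.0
    
    row_profile = resp.max(axis=1)
    y = float(np.argmax(row_profile))
    col_profile = resp.sum(axis=0)
    w = col_profile / col_profile.sum()
    xs = np.arange(col_profile.size, dtype=float)
    # weighted sample for the 1-D mixture
    counts = np.round(w * 4000).astype(int)
    sample = np.repeat(xs, counts).reshape(-1, 1)
    if sample.size < 10:
        return (y, 0.0), (y, 0.0), 0.0
    # initialize at the two largest local maxima of the column profile
    locmax = [i for i in range(1, col_profile.size - 1)
              if col_profile[i] >= col_profile[i - 1]
              and col_profile[i] >= col_profile[i + 1]]
    locmax.sort(key=lambda i: -col_profile[i])
    if len(locmax) >= 2:
        init = np.array([[float(locmax[0])], [float(locmax[1])]])
    else:
        init = np.array([[xs.size * 0.33], [xs.size * 0.67]])
    gm = GaussianMixture(
        n_components=2, covariance_type="tied", means_init=init,
        random_state=0, max_iter=200,
    ).fit(sample)
    m = np.sort(gm.means_.ravel())
    if m[1] - m[0] < min_sep_px:
        return (y, float(m[0])), (y, float(m[1])), 0.0
    # centroid refinement around each initial center
    centers = []
    half = max(2, int(round((m[1] - m[0]) / 3)))
    for cx in m:
        rs = slice(max(0, int(y) - half), min(resp.shape[0], int(y) + half + 1))
        cs = slice(max(0, int(cx) - half), min(resp.shape[1], int(cx) + half + 1))
        patch = resp[rs, cs]
        w2 = np.maximum(patch - 0.2 * patch.max(), 0.0)
        tot = w2.sum()
        if tot > 0:
            ii, jj = np.mgrid[rs, cs].astype(float)
            centers.append(((w2 * ii).sum() / tot, (w2 * jj).sum() / tot))
        else:
            centers.append((y, float(cx)))
    # quality: response peak relative to a robust scale of the signed DoG
    # map; pure noise gives a ratio of ~3-5, real eyes one of 15+
    filt = np.asarray(filtered, dtype=float)
    peak = row_profile[int(y)]
    scale = 1.4826 * np.median(np.abs(filt - np.median(filt))) + 1e-12
    quality = float(np.clip((peak / scale - 5.0) / 10.0, 0.0, 1.0))
    return centers[0], centers[1], quality


def _mask_moments(img: np.ndarray, center: tuple, half_px: int,
                  rel_threshold: float = 0.2):
    """Zeroth/second central moments of an intensity blob in a square mask.

    Mass below ``rel_threshold`` of the patch maximum is clipped so that
    rectified background noise does not dilute the second moments.
    """
    r0 = int(round(center[0]))
    c0 = int(round(center[1]))
    rs = slice(max(0, r0 - half_px), min(img.shape[0], r0 + half_px + 1))
    cs = slice(max(0, c0 - half_px), min(img.shape[1], c0 + half_px + 1))
    patch = img[rs, cs]
    patch = np.maximum(patch - rel_threshold * patch.max(), 0.0)
    m00 = patch.sum()
    if m00 <= 0:
        raise ValueError("zero-mass mask")
    ii, jj = np.mgrid[rs, cs].astype(float)
    cy = (patch * ii).sum() / m00
    cx = (patch * jj).sum() / m00
    mu20 = (patch * (jj - cx) ** 2).sum() / m00
    mu02 = (patch * (ii - cy) ** 2).sum() / m00
    mu11 = (patch * (jj - cx) * (ii - cy)).sum() / m00
    return (cy, cx), (mu20, mu02, mu11)


def _moments_to_angle(mu20: float, mu02: float, mu11: float) -> float:
    """Orientation of the major axis relative to the body axis (rows).

    The image-plane orientation (from the column axis) is
    0.5 * atan2(2 mu11, mu20 - mu02); the body-axis-relative angle is its
    complement, wrapped into (-pi/2, pi/2].  A circularly symmetric blob
    (mu11 ~ 0 and mu20 ~ mu02) gets angle 0 by convention.
    """
    if abs(mu11) < 1e-9 and abs(mu20 - mu02) < 1e-9:
        return 0.0
    phi = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    theta = np.pi / 2.0 - phi
    while theta > np.pi / 2.0:
        theta -= np.pi
    while theta <= -np.pi / 2.0:
        theta += np.pi
    return float(theta)


def eye_angles(
    frame: np.ndarray,
    centers: tuple,
    px_per_mm: float,
    mask_mm: float = presets.EYE_MASK_MM,
    quality: float = 1.0,
) -> EyeFit:
    """Measure both eye angles from central moments within masks.

    ``centers`` are (row, col) for the left and right eye (left = smaller
    column).  Moments are computed on the inverted, background-subtracted
    frame (dark eyes become positive mass); the DoG filter is used only for
    localization, since its ringing distorts second moments.
    """
    frame = np.asarray(frame, dtype=float)
    inv = -frame
    inv -= np.median(inv)
    half = max(2, int(round(mask_mm * px_per_mm / 2)))
    (cl, cr) = centers
    _, mom_l = _mask_moments(inv, cl, half)
    _, mom_r = _mask_moments(inv, cr, half)
    return EyeFit(
        center_left=cl, center_right=cr,
        moments_left=mom_l, moments_right=mom_r,
        angle_left_rad=_moments_to_angle(*mom_l),
        angle_right_rad=_moments_to_angle(*mom_r),
        quality=quality,
    )


def track_stack(
    frames: np.ndarray,
    px_per_mm: float,
    sigmas_mm: tuple = presets.DOG_SIGMAS_SINGLE_MM,
) -> list[EyeFit]:
    """Run the full eye-tracking chain on an image stack."""
    fits = []
    for frame in np.atleast_3d(frames).reshape(-1, *frames.shape[-2:]):
        filt = dog_filter(frame, *sigmas_mm, px_per_mm=px_per_mm)
        cl, cr, q = locate_eyes(filt)
        fits.append(eye_angles(frame, (cl, cr), px_per_mm, quality=q))
    return fits
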