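"""Expansion-quality metrics: expansion factor, deformation fields, error curves.

Expansion microscopy is only quantitative if the gel expands isotropically.
Two complementary measurements are implemented:

* the expansion factor — mean ratio of post- to pre-expansion distances
  between matched landmark pairs;
* the distortion of matched pre/post image fields — a similarity transform
  (rotation + isotropic scale + translation) is estimated first, and the
  smooth residual displacement field d(x) left after similarity alignment is
  recovered by local block matching. The field is summarized as an error
  curve: for random point pairs (p, q) at measurement length l = |p - q|
  (post-expansion microns), the measurement error is |d(p) - d(q)|, binned by
  l, with the RMS error per bin. The scalar figure of merit is the average
  percent error: the mean of rmse(l)/l over curve points up to a 40 micron
  cutoff, times 100.

The registration backend here is deliberately simple (log-polar FFT
similarity estimation followed by phase-correlation block matching with a
similarity re-fit); it is judged purely by its recovery of known synthetic
deformation fields, and can be swapped out behind the same contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.fft import fft2, fftshift
from scipy import interpolate, ndimage, stats
from skimage import exposure, filters, transform
from skimage.registration import phase_cross_correlation

__all__ = [
    "UnregistrableError",
    "ExpansionFactorEstimate",
    "SimilarityParams",
    "DeformationField",
    "ErrorCurve",
    "PlateComparison",
    "estimate_expansion_factor",
    "register_nonrigid",
    "error_curve",
    "compare_plates",
    "detect_landmarks",
    "match_landmarks",
    "plot_error_curve",
]


class UnregistrableError(RuntimeError):
    """Raised when the pre/post pair cannot be aligned with any confidence."""


@dataclass
class ExpansionFactorEstimate:
    factor: float
    per_pair_ratios: np.ndarray
    landmark_pairs: list


@dataclass
class SimilarityParams:
    """Similarity transform about the image center: rotation (radians, image
    row/col frame), isotropic scale, translation (d_row, d_col) in px."""

    scale: float
    rotation: float
    translation: tuple[float, float]


@dataclass
class DeformationField:
    """Residual displacement after similarity alignment, on the post grid.

    ``displacement[:, r, c]`` is (d_row, d_col) in post-image pixels; it is
    defined (trustworthy) only where ``feature_mask`` is True and has zero
    mean over the mask. ``pixel_size`` converts to post-expansion microns.
    """

    displacement: np.ndarray
    feature_mask: np.ndarray
    similarity: SimilarityParams
    pixel_size: float = 1.0

    @property
    def displacement_um(self) -> np.ndarray:
        return self.displacement * self.pixel_size


@dataclass
class ErrorCurve:
    lengths: np.ndarray  # mean measurement length per bin, post-expansion um
    rmse: np.ndarray  # RMS pair error per bin, um
    n_pairs: np.ndarray
    cutoff: float
    average_percent_error: float
    bin_width: float
    n_pairs_per_bin: int
    seed: int


@dataclass
class PlateComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame


def estimate_expansion_factor(landmark_pairs) -> ExpansionFactorEstimate:
    """Mean of per-pair post/pre distance ratios.

    ``landmark_pairs`` is a list of ((pre_a, pre_b), (post_a, post_b)) where
    each point is (row, col) in physical units. Distances are Euclidean;
    coincident pre-expansion landmarks are an error.
    """
    if not landmark_pairs:
        raise ValueError("at least one landmark pair is required")
    ratios = []
    for (pre_a, pre_b), (post_a, post_b) in landmark_pairs:
        d_pre = float(np.hypot(*(np.asarray(pre_a, float) - np.asarray(pre_b, float))))
        d_post = float(np.hypot(*(np.asarray(post_a, float) - np.asarray(post_b, float))))
        if d_pre == 0:
            raise ValueError("coincident pre-expansion landmarks")
        ratios.append(d_post / d_pre)
    ratios = np.asarray(ratios)
    return ExpansionFactorEstimate(
        factor=float(ratios.mean()), per_pair_ratios=ratios, landmark_pairs=list(landmark_pairs)
    )


def _center_similarity(shape, scale, rotation, translation_rc) -> transform.SimilarityTransform:
    """Similarity about the image center, in skimage (x=col, y=row) convention."""
    c_xy = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
    t_xy = np.array([translation_rc[1], translation_rc[0]])
    to_origin = transform.SimilarityTransform(translation=-c_xy)
    core = transform.SimilarityTransform(scale=scale, rotation=rotation)
    back = transform.SimilarityTransform(translation=c_xy + t_xy)
    return transform.SimilarityTransform(matrix=back.params @ core.params @ to_origin.params)


def _warp(image, tf, output_shape):
    return transform.warp(
        image, inverse_map=tf.inverse, output_shape=output_shape, order=1, mode="constant",
        cval=float(np.median(image)), preserve_range=True,
    )


def _masked_ncc(a, b, mask) -> float:
    av, bv = a[mask], b[mask]
    if av.std() == 0 or bv.std() == 0:
        return 0.0
    return float(np.corrcoef(av, bv)[0, 1])


def _estimate_scale_rotation(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Scale and rotation (mod pi) from the log-polar FFT magnitude spectra."""
    shape = post.shape
    win = filters.window("hann", shape)
    f_pre = fftshift(np.abs(fft2((pre - pre.mean()) * win)))
    f_post = fftshift(np.abs(fft2((post - post.mean()) * win)))
    radius = min(shape) // 2
    out_shape = (360, 300)
    wp_pre = transform.warp_polar(
        np.log1p(f_pre), radius=radius, output_shape=out_shape, scaling="log", order=1
    )
    wp_post = transform.warp_polar(
        np.log1p(f_post), radius=radius, output_shape=out_shape, scaling="log", order=1
    )
    # phase (whitened) normalization: the raw spectra are dominated by the
    # object form factor, which would pin the correlation at zero shift
    shifts, _, _ = phase_cross_correlation(wp_pre, wp_post, upsample_factor=20)
    klog = out_shape[1] / np.log(radius)
    # Post content magnified by s compresses its spectrum by s: the log-radial
    # coordinate of wp_post lags wp_pre by klog*ln(s).
    scale = float(np.exp(shifts[1] / klog))
    # row shift is the spectrum rotation in degrees; the image-frame warp
    # needs the opposite sign (and is only determined mod pi)
    rotation = float(-np.deg2rad(shifts[0] * (360.0 / out_shape[0])))
    return scale, rotation


def _estimate_similarity(
    pre: np.ndarray, post: np.ndarray, corr_floor: float
) -> tuple[SimilarityParams, np.ndarray]:
    scale, rotation = _estimate_scale_rotation(pre, post)
    best = None
    # The FFT magnitude is point-symmetric, so rotation is known only mod pi;
    # try both candidates and keep the one that correlates better.
    for rot in (rotation, rotation + np.pi):
        tf0 = _center_similarity(post.shape, scale, rot, (0.0, 0.0))
        pre_w0 = _warp(pre, tf0, post.shape)
        shift, _, _ = phase_cross_correlation(post, pre_w0, upsample_factor=10, normalization=None)
        tf = _center_similarity(post.shape, scale, rot, (float(shift[0]), float(shift[1])))
        pre_w = _warp(pre, tf, post.shape)
        ncc = _masked_ncc(pre_w, post, np.ones_like(post, bool))
        if best is None or ncc > best[0]:
            best = (ncc, rot, (float(shift[0]), float(shift[1])), pre_w)
    ncc, rot, shift_rc, pre_w = best
    if ncc < corr_floor:
        raise UnregistrableError(f"similarity alignment correlation {ncc:.3f} below floor")
    rot = (rot + np.pi) % (2 * np.pi) - np.pi  # report in (-pi, pi]
    return SimilarityParams(scale=scale, rotation=rot, translation=shift_rc), pre_w


def register_nonrigid(
    pre: np.ndarray,
    post: np.ndarray,
    grid_spacing: int = 24,
    blur_sigma: float = 8.0,
    feature_quantile: float = 0.6,
    pixel_size: float = 1.0,
    corr_floor: float = 0.1,
) -> DeformationField:
    """Estimate the residual deformation between a matched pre/post pair.

    Steps: (1) estimate a similarity transform (log-polar FFT for
    rotation/scale, phase correlation for translation); (2) histogram-match
    the aligned pre image to the post image; (3) build a feature mask by Gaussian
    blurring and thresholding both aligned images at ``feature_quantile``
    (regions featureless in either image are excluded); (4) block-match a
    coarse node grid by upsampled phase correlation, re-fit and remove any
    remaining similarity component (folding it into the reported transform),
    and interpolate the node displacements into a smooth full-resolution
    field with zero mean over the feature mask.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.ndim != 2 or post.ndim != 2:
        raise ValueError("pre and post must be 2-D rasters")
    similarity, pre_w = _estimate_similarity(pre, post, corr_floor)
    # histogram-normalize only after coarse alignment: before it, the two
    # fields contain very different foreground fractions and matching their
    # histograms would scramble the background
    pre_w = exposure.match_histograms(pre_w, post)

    blur_post = ndimage.gaussian_filter(post, blur_sigma)
    blur_pre = ndimage.gaussian_filter(pre_w, blur_sigma)
    mask = (blur_post >= np.quantile(blur_post, feature_quantile)) & (
        blur_pre >= np.quantile(blur_pre, feature_quantile)
    )
    if not mask.any():
        raise UnregistrableError("feature mask is empty")

    rows, cols = post.shape
    hw = grid_spacing
    node_r = np.arange(hw, rows - hw, grid_spacing)
    node_c = np.arange(hw, cols - hw, grid_spacing)
    disp = np.full((2, len(node_r), len(node_c)), np.nan)
    for i, r in enumerate(node_r):
        for j, c in enumerate(node_c):
            sl = (slice(r - hw, r + hw + 1), slice(c - hw, c + hw + 1))
            if mask[sl].mean() < 0.25:
                continue
            p_post, p_pre = post[sl], pre_w[sl]
            if p_post.std() < 1e-9 or p_pre.std() < 1e-9:
                continue
            shift, _, _ = phase_cross_correlation(
                p_post, p_pre, upsample_factor=20, normalization=None
            )
            if np.hypot(*shift) > 0.6 * hw:
                continue
            disp[:, i, j] = shift

    valid = ~np.isnan(disp[0])
    if valid.sum() < 3:
        raise UnregistrableError("too few valid block matches")

    # Remove any residual similarity component (d ~ t + a*delta + b*J delta)
    # from the node displacements and fold it into the reported transform.
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, ccg = np.meshgrid(node_r, node_c, indexing="ij")
    dr = (rr - cr)[valid].astype(float)
    dc = (ccg - cc)[valid].astype(float)
    vy, vx = disp[0][valid], disp[1][valid]
    n = len(dr)
    design = np.zeros((2 * n, 4))
    design[:n, 0] = 1.0  # t_row
    design[n:, 1] = 1.0  # t_col
    design[:n, 2] = dr
    design[n:, 2] = dc  # isotropic scale residual
    design[:n, 3] = dc
    design[n:, 3] = -dr  # in-plane rotation residual
    coef, *_ = np.linalg.lstsq(design, np.concatenate([vy, vx]), rcond=None)
    t_r, t_c, a_s, b_rot = coef
    rr_f = (rr - cr).astype(float)
    cc_f = (ccg - cc).astype(float)
    disp[0] -= t_r + a_s * rr_f + b_rot * cc_f
    disp[1] -= t_c + a_s * cc_f - b_rot * rr_f
    similarity = SimilarityParams(
        scale=similarity.scale * (1.0 + a_s),
        rotation=similarity.rotation - b_rot,
        translation=(similarity.translation[0] + t_r, similarity.translation[1] + t_c),
    )

    # Fill unmatched nodes from their valid neighbours, then interpolate the
    # node grid smoothly to full resolution.
    full = np.zeros((2, rows, cols))
    pts = np.column_stack([rr[valid], ccg[valid]])
    for comp in range(2):
        vals = disp[comp][valid]
        filled = interpolate.griddata(pts, vals, (rr, ccg), method="linear")
        nearest = interpolate.griddata(pts, vals, (rr, ccg), method="nearest")
        filled = np.where(np.isnan(filled), nearest, filled)
        spline = interpolate.RectBivariateSpline(
            node_r, node_c, filled, kx=min(3, len(node_r) - 1), ky=min(3, len(node_c) - 1)
        )
        full[comp] = spline(np.arange(rows), np.arange(cols))

    mean_d = full[:, mask].mean(axis=1)
    full -= mean_d[:, None, None]
    similarity = SimilarityParams(
        scale=similarity.scale,
        rotation=similarity.rotation,
        translation=(similarity.translation[0] + mean_d[0], similarity.translation[1] + mean_d[1]),
    )
    return DeformationField(
        displacement=full, feature_mask=mask, similarity=similarity, pixel_size=pixel_size
    )


def error_curve(
    field: DeformationField,
    n_pairs_per_bin: int = 2000,
    bin_width: float = 2.0,
    cutoff: float = 40.0,
    seed: int = 0,
) -> ErrorCurve:
    """Measurement error vs measurement length from random point pairs.

    Pairs are drawn uniformly from the feature mask; the pair error is the
    vector difference of the displacement at the two ends (a relative
    measure: any uniform translation drops out). ``n_pairs_per_bin`` sets the
    average sampling density per length bin.
    """
    mask = field.feature_mask
    pix = np.argwhere(mask)
    if len(pix) < 2:
        raise ValueError("feature mask too small to sample point pairs")
    rng = np.random.default_rng(seed)
    ps = field.pixel_size
    max_len = float(np.hypot(*(pix.max(axis=0) - pix.min(axis=0)))) * ps
    edges = np.arange(0.0, max_len + bin_width, bin_width)
    n_bins = len(edges) - 1
    n_total = int(n_pairs_per_bin * n_bins)

    idx_a = rng.integers(0, len(pix), size=n_total)
    idx_b = rng.integers(0, len(pix), size=n_total)
    keep = idx_a != idx_b
    a, b = pix[idx_a[keep]], pix[idx_b[keep]]
    lengths = np.hypot(*(a - b).T) * ps
    da = field.displacement[:, a[:, 0], a[:, 1]]
    db = field.displacement[:, b[:, 0], b[:, 1]]
    err = np.hypot(*(da - db)) * ps

    which = np.digitize(lengths, edges) - 1
    lengths_out, rmse_out, counts = [], [], []
    for bin_i in range(n_bins):
        sel = which == bin_i
        n = int(sel.sum())
        if n == 0:
            continue
        # quadratic-mean length pairs consistently with the RMS error: for a
        # linear field d = A x the curve then satisfies rmse(l) = |A| l exactly
        lengths_out.append(np.sqrt(np.mean(lengths[sel] ** 2)))
        rmse_out.append(np.sqrt(np.mean(err[sel] ** 2)))
        counts.append(n)
    lengths_out = np.asarray(lengths_out)
    rmse_out = np.asarray(rmse_out)
    below = lengths_out <= cutoff
    if not below.any():
        raise ValueError(f"no length bins at or below the {cutoff} um cutoff")
    ape = float(np.mean(rmse_out[below] / lengths_out[below]) * 100.0)
    return ErrorCurve(
        lengths=lengths_out,
        rmse=rmse_out,
        n_pairs=np.asarray(counts),
        cutoff=cutoff,
        average_percent_error=ape,
        bin_width=bin_width,
        n_pairs_per_bin=n_pairs_per_bin,
        seed=seed,
    )


def compare_plates(per_plate_values: dict, alpha: float = 0.05) -> PlateComparison:
    """One-way ANOVA across plates with post-hoc Tukey HSD pairwise tests."""
    labels = list(per_plate_values)
    groups = [np.asarray(per_plate_values[k], dtype=float) for k in labels]
    if len(groups) < 2:
        raise ValueError("need at least 2 plates")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every plate needs at least 2 values")
    f, p = stats.f_oneway(*groups)
    tk = stats.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        pv = float(tk.pvalue[i, j])
        rows.append(
            {
                "plate_a": labels[i],
                "plate_b": labels[j],
                "mean_difference": float(groups[i].mean() - groups[j].mean()),
                "p_value": pv,
                "significant": pv < alpha,
            }
        )
    return PlateComparison(f_statistic=float(f), p_value=float(p), pairwise=pd.DataFrame(rows))


def detect_landmarks(
    image: np.ndarray,
    threshold_method="otsu",
    min_area: int = 20,
    exclude_border: bool = True,
) -> np.ndarray:
    """Centroids (row, col) of all thresholded objects of at least ``min_area`` px.

    Objects touching the image border are dropped by default: a clipped
    object's centroid is biased inward, which would bias distance ratios.
    """
    from .nucmask import EIGHT, _resolve_threshold

    image = np.asarray(image, dtype=float)
    binary = image > _resolve_threshold(image, threshold_method)
    labels, n = ndimage.label(binary, structure=EIGHT)
    if n == 0:
        return np.empty((0, 2))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    keep = [
        lab
        for lab in range(1, n + 1)
        if sizes[lab - 1] >= min_area and not (exclude_border and lab in border)
    ]
    if not keep:
        return np.empty((0, 2))
    return np.asarray(ndimage.center_of_mass(binary, labels, keep), dtype=float)


def match_landmarks(pre_points: np.ndarray, post_points: np.ndarray):
    """Match landmarks across an (unknown) isotropic expansion about the centroid.

    A first-pass scale is taken from the ratio of RMS distances to the
    centroid; each pre point is then paired with the nearest post point to
    its predicted position (mutually exclusive, closest first). Returns the
    list of ((pre_a, pre_b), (post_a, post_b)) pairs over all matched-point
    combinations, ready for :func:`estimate_expansion_factor`.
    """
    pre_points = np.asarray(pre_points, float)
    post_points = np.asarray(post_points, float)
    if len(pre_points) < 2 or len(post_points) < 2:
        raise ValueError("need at least two landmarks in each image")
    c_pre = pre_points.mean(axis=0)
    c_post = post_points.mean(axis=0)
    rms_pre = np.sqrt(np.mean(np.sum((pre_points - c_pre) ** 2, axis=1)))
    rms_post = np.sqrt(np.mean(np.sum((post_points - c_post) ** 2, axis=1)))
    if rms_pre == 0:
        raise ValueError("degenerate pre-expansion landmarks")
    s0 = rms_post / rms_pre
    predicted = c_post + (pre_points - c_pre) * s0
    cost = np.linalg.norm(predicted[:, None, :] - post_points[None, :, :], axis=2)
    matches = []
    used_pre, used_post = set(), set()
    for flat in np.argsort(cost, axis=None):
        i, j = np.unravel_index(flat, cost.shape)
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        matches.append((pre_points[i], post_points[j]))
        if len(matches) == min(len(pre_points), len(post_points)):
            break
    pairs = []
    for (pa, qa), (pb, qb) in itertools.combinations(matches, 2):
        pairs.append(((pa, pb), (qa, qb)))
    return pairs


def plot_error_curve(curve: ErrorCurve, ax=None):
    """RMS error vs measurement length, with the cutoff marked."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(curve.lengths, curve.rmse, marker="o", ms=3)
    ax.axvline(curve.cutoff, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("measurement length (um, post-expansion)")
    ax.set_ylabel("RMS error (um)")
    ax.set_title(f"avg percent error <= {curve.cutoff:g} um: {curve.average_percent_error:.2f}%")
    return ax
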