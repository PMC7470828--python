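"""Movie preprocessing: z-projection, drift correction, background removal.

The processing chain mirrors a standard confocal calcium-imaging workflow:
z-stacks are averaged to a single plane per time point, translational drift
is corrected against a pre-stimulus reference image, a smooth fluorescence
background is estimated on temporally quiet ("non-responsive") pixels by
least-squares fitting of a bivariate polynomial surface and subtracted, and
fluorescence is finally expressed relative to the pre-stimulus baseline
(F/F0 and dF/F0).

Non-responsive pixels are found from the temporal coefficient of variation
(CV = SD over time / mean over time): active pixels fluctuate with calcium
transients and have high CV, background pixels do not. The CV map is split
by Otsu's threshold and the low-CV class is used for the background fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .core import Movie, ReferenceImage, save_json

__all__ = [
    "z_project",
    "make_reference",
    "register_translation",
    "temporal_cv_map",
    "nonresponsive_mask",
    "BackgroundModel",
    "fit_background",
    "subtract_background",
    "normalize",
    "preprocess_movie",
]


def z_project(movie: Movie, allow_projected: bool = True) -> Movie:
    """Average over the z axis, yielding a T x Y x X movie.

    A movie without a z axis is returned unchanged when ``allow_projected``
    is true (the default), otherwise it is rejected.
    """
    if not movie.has_z:
        if allow_projected:
            return movie
        raise ValueError("movie has no z axis to project")
    return movie.with_data(movie.data.mean(axis=1))


def make_reference(
    movie: Movie, n_frames: int = 10, first_onset: int | None = None
) -> ReferenceImage:
    """Temporal mean of the first ``n_frames`` pre-stimulus frames."""
    movie = z_project(movie)
    if n_frames < 1 or n_frames > movie.n_frames:
        raise ValueError(f"n_frames={n_frames} outside movie length")
    if first_onset is not None and n_frames > first_onset:
        raise ValueError(
            f"n_frames={n_frames} reaches past the first stimulus onset "
            f"({first_onset})"
        )
    return ReferenceImage(
        data=movie.data[:n_frames].mean(axis=0), n_frames_averaged=n_frames
    )


def register_translation(
    movie: Movie,
    reference: ReferenceImage,
    upsample_factor: int = 1,
) -> tuple[Movie, np.ndarray]:
    """Correct translational drift frame by frame against a reference image.

    Each frame's displacement relative to the reference is estimated by
    phase cross-correlation and undone. With ``upsample_factor=1`` shifts
    are integer pixels (the tested contract); larger values enable subpixel
    registration.

    Returns
    -------
    (registered_movie, shifts)
        ``shifts[t] = (dy, dx)`` is the measured drift of frame ``t``
        relative to the reference; the frame is translated by ``-shifts[t]``.
        Pixels shifted in from outside the field are filled with edge values.
    """
    movie = z_project(movie)
    ref = np.asarray(reference.data, dtype=float)
    if ref.shape != movie.frame_shape:
        raise ValueError("reference and movie frame shapes differ")
    T = movie.n_frames
    shifts = np.zeros((T, 2))
    out = np.empty_like(movie.data, dtype=float)
    for t in range(T):
        frame = np.asarray(movie.data[t], dtype=float)
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"degenerate (constant) frame {t}: zero shift assumed")
            out[t] = frame
            continue
        corr_shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift to apply to the frame to
        # align it with the reference, i.e. minus the drift.
        drift = -np.asarray(corr_shift, dtype=float)
        shifts[t] = drift
        if np.all(drift == np.round(drift)):
            out[t] = ndimage.shift(frame, -drift, order=0, mode="nearest")
        else:
            out[t] = ndimage.shift(frame, -drift, order=1, mode="nearest")
    registered = movie.with_data(out)
    registered.meta["registration_shifts"] = shifts
    return registered, shifts


def temporal_cv_map(
    movie: Movie, eps: float | None = None, return_low_mean_mask: bool = False
):
    """Per-pixel coefficient of variation over time (population SD / mean).

    Pixels whose temporal mean falls at or below ``eps`` (default
    ``1e-6 * max``) get CV 0 and are flagged.
    """
    movie = z_project(movie)
    data = np.asarray(movie.data, dtype=float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)  # population SD, ddof=0
    if eps is None:
        eps = 1e-6 * float(np.abs(data).max() or 1.0)
    low = mean <= eps
    cv = np.zeros_like(mean)
    np.divide(sd, mean, out=cv, where=~low)
    if return_low_mean_mask:
        return cv, low
    return cv


def nonresponsive_mask(
    cv_map: np.ndarray, nbins: int = 256
) -> tuple[np.ndarray, float]:
    """Split the CV map with Otsu's threshold; low-CV pixels are the
    non-responsive (background) class.

    Returns ``(mask, threshold)`` where ``mask`` is true on non-responsive
    pixels (CV strictly below the threshold). A constant CV map yields an
    all-true mask with a warning.
    """
    cv = np.asarray(cv_map, dtype=float)
    if not np.all(np.isfinite(cv)):
        raise ValueError("CV map contains non-finite values")
    if np.ptp(cv) == 0:
        warnings.warn("constant CV map: entire image classed non-responsive")
        return np.ones_like(cv, dtype=bool), float(cv.flat[0])
    thr = float(threshold_otsu(cv, nbins=nbins))
    return cv < thr, thr


# ---------------------------------------------------------------------------
# polynomial background surface


def poly_terms(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (i, j) of all monomials x^i y^j with i + j <= degree."""
    return [(i, j) for d in range(degree + 1) for i in range(d + 1) for j in [d - i]]


def poly_design_matrix(
    yy: np.ndarray, xx: np.ndarray, degree: int, shape: tuple[int, int]
) -> np.ndarray:
    """Design matrix of the bivariate polynomial basis at pixel coordinates.

    Coordinates are mapped to [-1, 1] over the full image extent so the fit
    is well conditioned and coefficients are shape-portable.
    """
    ny, nx = shape
    yn = 2.0 * yy / max(ny - 1, 1) - 1.0
    xn = 2.0 * xx / max(nx - 1, 1) - 1.0
    cols = [(xn**i) * (yn**j) for i, j in poly_terms(degree)]
    return np.stack(cols, axis=-1)


@dataclass
class BackgroundModel:
    """Least-squares bivariate polynomial background surface.

    ``coefficients`` follow the ``poly_terms(degree)`` ordering on [-1, 1]
    normalised coordinates of ``shape``.
    """

    coefficients: np.ndarray
    degree: int
    shape: tuple[int, int]
    mask: np.ndarray | None = None
    cv_threshold: float | None = None
    residual_rms: float = field(default=float("nan"))

    def surface(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or self.shape
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        A = poly_design_matrix(yy, xx, self.degree, shape)
        return A @ self.coefficients

    def to_json(self, path: str | Path) -> None:
        save_json(
            {
                "degree": self.degree,
                "shape": list(self.shape),
                "coefficients": self.coefficients,
                "cv_threshold": self.cv_threshold,
                "residual_rms": self.residual_rms,
            },
            path,
        )


def fit_background(
    image: np.ndarray, mask: np.ndarray, degree: int = 4
) -> BackgroundModel:
    """Fit a polynomial surface of total degree <= ``degree`` to the masked
    (non-responsive) pixels of a single image.

    The image is typically the temporal mean of the registered movie: the
    mask is defined by temporal statistics, so the background model is
    temporal by construction and is fitted once, not per frame.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    n_terms = len(poly_terms(degree))
    yy, xx = np.nonzero(mask)
    if yy.size < n_terms:
        raise ValueError(
            f"only {yy.size} mask pixels for {n_terms} polynomial terms"
        )
    A = poly_design_matrix(yy, xx, degree, image.shape)
    coef, _, rank, _ = np.linalg.lstsq(A, image[mask], rcond=None)
    if rank < n_terms:
        raise ValueError(
            "rank-deficient background fit: mask geometry does not constrain "
            "all polynomial terms (e.g. mask confined to a line)"
        )
    resid = A @ coef - image[mask]
    return BackgroundModel(
        coefficients=coef,
        degree=degree,
        shape=image.shape,
        mask=mask,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def subtract_background(movie: Movie, model: BackgroundModel) -> Movie:
    """Subtract the fitted surface from every frame, clamping at zero."""
    movie = z_project(movie)
    surf = model.surface(movie.frame_shape)
    out = np.clip(np.asarray(movie.data, dtype=float) - surf, 0.0, None)
    return movie.with_data(out)


def normalize(
    movie: Movie,
    f0: np.ndarray | float,
    kind: str = "dff",
    eps: float | None = None,
):
    """Normalise fluorescence to baseline: F/F0 or dF/F0 = (F - F0) / F0.

    ``f0`` is a per-pixel baseline image (typically the reference image) or
    a scalar. Pixels with F0 <= eps are excluded (set to 0) and returned in
    the flag mask.

    Returns ``(normalized_movie, invalid_mask)``.
    """
    if kind not in ("dff", "f"):
        raise ValueError("kind must be 'dff' or 'f'")
    movie = z_project(movie)
    data = np.asarray(movie.data, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if eps is None:
        eps = 1e-6 * float(np.abs(data).max() or 1.0)
    if np.all(f0 <= eps):
        raise ValueError("baseline F0 is zero (or below eps) everywhere")
    invalid = np.broadcast_to(f0 <= eps, movie.frame_shape).copy()
    safe_f0 = np.where(invalid, 1.0, f0)
    out = data / safe_f0
    if kind == "dff":
        out = out - 1.0
    out[:, invalid] = 0.0
    normed = movie.with_data(out)
    normed.meta["normalization"] = kind
    return normed, invalid


def preprocess_movie(
    movie: Movie,
    n_ref_frames: int = 10,
    first_onset: int | None = None,
    register: bool = True,
    degree: int = 4,
    subtract: bool = True,
) -> dict:
    """Full chain: z-project, register, CV/Otsu mask, background, dF/F0.

    Returns a dict with the intermediate products: ``movie`` (dF/F0),
    ``f_movie`` (background-corrected F), ``reference``, ``shifts``,
    ``cv_map``, ``mask``, ``background`` and ``invalid``.
    """
    proj = z_project(movie)
    ref = make_reference(proj, n_ref_frames, first_onset=first_onset)
    shifts = np.zeros((proj.n_frames, 2))
    if register:
        proj, shifts = register_translation(proj, ref)
        ref = make_reference(proj, n_ref_frames, first_onset=first_onset)
    cv = temporal_cv_map(proj)
    mask, cv_thr = nonresponsive_mask(cv)
    model = None
    corrected = proj
    if subtract:
        model = fit_background(proj.data.mean(axis=0), mask, degree=degree)
        model.cv_threshold = cv_thr
        corrected = subtract_background(proj, model)
        ref = make_reference(corrected, n_ref_frames, first_onset=first_onset)
    # After background subtraction, pixels outside fluorescent structures
    # have F0 near zero; guard the division with a scale-free 5% of the
    # bright-pixel baseline rather than the generic 1e-6 epsilon.
    f0_eps = 0.05 * float(np.percentile(ref.data, 99))
    dff, invalid = normalize(corrected, ref.data, kind="dff", eps=max(f0_eps, 1e-12))
    return {
        "movie": dff,
        "f_movie": corrected,
        "reference": ref,
        "shifts": shifts,
        "cv_map": cv,
        "mask": mask,
        "cv_threshold": cv_thr,
        "background": model,
        "invalid": invalid,
    }
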