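"""Synthetic calcium-imaging movies and RNAscope slides with ground truth.

Every downstream stage of the pipeline (registration, background fitting,
ROI segmentation, responder calling, dot counting, group statistics) is
validated against data produced here, where the generative truth — response
amplitudes in units of baseline noise SD, drift paths, polynomial
background coefficients, per-cell transcript-dot counts — is known exactly.

The movie model is deliberately simple and analytically checkable:

    frame(t) = background(x, y) + sum_cells mask_c * (baseline + transient_c(t))
               + Gaussian noise

with an instant-rise / single-exponential-decay transient locked to each
stimulus onset. The model omits optics (PSF, z-attenuation), bleaching and
non-rigid tissue motion on purpose; a green test on these data establishes
algorithmic correctness, not robustness to those effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import Movie, StimulusProtocol, save_json
from .preprocess import poly_design_matrix, poly_terms

__all__ = [
    "CalciumTruth",
    "SkinTruth",
    "RnascopeTruth",
    "make_soma_truth",
    "make_skin_truth",
    "make_rnascope_truth",
    "gen_traces",
    "gen_soma_movie",
    "gen_skin_movie",
    "gen_rnascope_image",
    "soma_label_image",
    "grid_cell_masks",
]

#: default transient decay constant, frames (8 frames = 32 s at 0.25 Hz)
DEFAULT_TAU_FRAMES = 8.0
#: WGA channel: labelled-cell contrast in units of WGA background SD
WGA_CONTRAST_SD = 10.0


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class CalciumTruth:
    """Ground truth for a DRG-soma movie.

    ``amplitudes[label][c]`` is cell ``c``'s response amplitude to stimulus
    ``label`` as a multiple of the per-pixel baseline noise SD (0 = no
    response). ``background_coeffs`` follow :func:`~trpscope.preprocess.poly_terms`
    ordering on [-1, 1]-normalised image coordinates.
    """

    cell_positions: np.ndarray  # (n, 2) float, (y, x)
    cell_radius_px: float
    amplitudes: dict[str, np.ndarray]
    expressed: list[frozenset]
    k_responsive: np.ndarray  # (n,) bool
    wga_labeled: np.ndarray  # (n,) bool
    noise_sd: float = 5.0
    baseline_level: float = 100.0
    background_coeffs: np.ndarray | None = None
    background_degree: int = 4
    drift_path: np.ndarray | None = None  # (T, 2)
    tau_frames: float = DEFAULT_TAU_FRAMES

    @property
    def n_cells(self) -> int:
        return len(self.cell_positions)

    def validate(self, shape: tuple[int, int]) -> None:
        pos = np.asarray(self.cell_positions, dtype=float)
        r = float(self.cell_radius_px)
        if r <= 0:
            raise ValueError("cell radius must be positive")
        if self.n_cells > 1:
            d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() <= 2 * r:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"overlapping cells {i} and {j}: centre distance "
                    f"{d.min():.1f} px <= 2 x radius {r} px"
                )
        for lab, amp in self.amplitudes.items():
            if np.any(np.asarray(amp) < 0):
                raise ValueError(f"negative amplitude for stimulus {lab!r}")
        if self.drift_path is not None:
            drift = np.asarray(self.drift_path, dtype=float)
            margin = r + 1
            lo = pos.min(axis=0) - np.abs(drift).max(axis=0) - margin
            hi = pos.max(axis=0) + np.abs(drift).max(axis=0) + margin
            if (lo < 0).any() or (hi >= np.asarray(shape)).any():
                raise ValueError("drift carries a cell outside the field")
        if self.background_coeffs is not None:
            surf = background_surface(
                self.background_coeffs, shape, self.background_degree
            )
            if surf.min() <= 0:
                raise ValueError("background field must be strictly positive")


@dataclass
class SkinTruth:
    """Ground truth for a skin-nerve movie: branches instead of somata.

    Each branch is a thin rasterised polyline whose member pixels share one
    temporal trace (perfectly correlated within the branch).
    """

    branch_labels: np.ndarray  # (Y, X) int, 0 = background
    amplitudes: dict[str, np.ndarray]
    expressed: list[frozenset]
    k_responsive: np.ndarray
    noise_sd: float = 5.0
    baseline_level: float = 100.0
    background_coeffs: np.ndarray | None = None
    background_degree: int = 4
    drift_path: np.ndarray | None = None
    tau_frames: float = DEFAULT_TAU_FRAMES

    @property
    def n_branches(self) -> int:
        return int(self.branch_labels.max())


@dataclass
class RnascopeTruth:
    """Ground truth for a synthetic RNAscope slide.

    ``dots_per_cell[c]`` transcripts are placed inside cell ``c``'s mask; a
    ``cluster_fraction`` of them are emitted as spatially merged clusters
    whose integrated intensity is the exact sum of their members (the
    generative counterpart of the cluster/single intensity-ratio correction).
    """

    cell_masks: np.ndarray  # (Y, X) int label image
    dots_per_cell: np.ndarray  # (n,) int
    wga_labeled: np.ndarray  # (n,) bool
    cluster_fraction: float = 0.2
    single_dot_intensity: float = 1000.0  # integrated grey-level units
    single_dot_diameter_um: float = 0.8
    noise_sd: float = 0.0  # grey levels; set from SNR by the generator helper
    cluster_sizes: list[list[int]] = field(default_factory=list)  # realised

    @property
    def n_cells(self) -> int:
        return int(self.cell_masks.max())


# ---------------------------------------------------------------------------
# helpers


def background_surface(
    coeffs: np.ndarray, shape: tuple[int, int], degree: int = 4
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return poly_design_matrix(yy, xx, degree, shape) @ np.asarray(coeffs, float)


def random_background_coeffs(
    rng: np.random.Generator,
    degree: int = 4,
    offset: float = 300.0,
    amplitude: float = 20.0,
) -> np.ndarray:
    """Random smooth, strictly positive polynomial background field.

    The default offset is bright relative to the noise SD, emulating tissue
    autofluorescence: the temporal-CV criterion for non-responsive pixels
    relies on background fluorescence being substantial, so that CV is
    dominated by temporal variance (transients), not by a near-zero mean.
    """
    coeffs = rng.uniform(-1, 1, size=len(poly_terms(degree)))
    coeffs *= amplitude / max(np.abs(coeffs[1:]).sum(), 1e-12)
    coeffs[0] = offset
    return coeffs


def transient_kernel(
    n_frames: int, onset: int, tau_frames: float
) -> np.ndarray:
    """Instant rise at ``onset``, exponential decay with constant ``tau``."""
    t = np.arange(n_frames, dtype=float)
    k = np.zeros(n_frames)
    sel = t >= onset
    k[sel] = np.exp(-(t[sel] - onset) / tau_frames)
    return k


def _cell_traces(
    truth, protocol: StimulusProtocol, n_frames: int, n_sources: int
) -> np.ndarray:
    """Per-source fluorescence excess over the resting baseline, (n, T)."""
    traces = np.zeros((n_sources, n_frames))
    for w in protocol.windows:
        amp = np.asarray(truth.amplitudes.get(w.label, np.zeros(n_sources)), float)
        kern = transient_kernel(n_frames, w.start_frame, truth.tau_frames)
        traces += amp[:, None] * truth.noise_sd * kern[None, :]
    return traces


def soma_label_image(truth: CalciumTruth, shape: tuple[int, int]) -> np.ndarray:
    """Render the true cell discs as a label image (1-based labels)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    for c, (cy, cx) in enumerate(np.asarray(truth.cell_positions, float)):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= truth.cell_radius_px**2
        labels[disc] = c + 1
    return labels


def _apply_drift(frame: np.ndarray, d: np.ndarray) -> np.ndarray:
    if np.all(d == np.round(d)):
        return ndimage.shift(frame, d, order=0, mode="nearest")
    return ndimage.shift(frame, d, order=1, mode="nearest")


def _render_movie(
    source_labels: np.ndarray,
    traces: np.ndarray,
    truth,
    shape_txy: tuple,
    rng: np.random.Generator,
    noise: str = "gaussian",
) -> np.ndarray:
    """Compose background + per-source baseline/transients + drift + noise."""
    n_frames = shape_txy[0]
    zdim = shape_txy[1] if len(shape_txy) == 4 else None
    frame_shape = shape_txy[-2:]
    bg = np.zeros(frame_shape)
    if truth.background_coeffs is not None:
        bg = background_surface(
            truth.background_coeffs, frame_shape, truth.background_degree
        )
    static = bg + (source_labels > 0) * truth.baseline_level
    drift = (
        np.zeros((n_frames, 2))
        if truth.drift_path is None
        else np.asarray(truth.drift_path, float)
    )
    out = np.empty(shape_txy, dtype=float)
    for t in range(n_frames):
        frame = static.copy()
        for s in range(traces.shape[0]):
            if traces[s, t] != 0:
                frame[source_labels == s + 1] += traces[s, t]
        frame = _apply_drift(frame, drift[t])
        if zdim is None:
            out[t] = frame
        else:
            out[t] = frame[None, :, :]
    if noise == "gaussian":
        if truth.noise_sd > 0:
            out += rng.normal(0.0, truth.noise_sd, size=out.shape)
    elif noise == "poisson":
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return np.clip(out, 0.0, None)


def _wga_image(
    source_labels: np.ndarray,
    wga_labeled: np.ndarray,
    rng: np.random.Generator,
    bg_mean: float = 100.0,
    bg_sd: float = 10.0,
    contrast_sd: float = WGA_CONTRAST_SD,
) -> np.ndarray:
    img = rng.normal(bg_mean, bg_sd, size=source_labels.shape)
    for s, labeled in enumerate(np.asarray(wga_labeled, bool)):
        if labeled:
            img[source_labels == s + 1] += contrast_sd * bg_sd
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# truth factories


def make_soma_truth(
    shape: tuple[int, int],
    n_cells: int = 10,
    cell_radius_px: float = 4.0,
    p_expressed: dict[str, float] | None = None,
    amplitude_sd: float = 10.0,
    k_amplitude_sd: float = 10.0,
    p_k_responsive: float = 1.0,
    p_wga: float = 0.5,
    noise_sd: float = 5.0,
    baseline_level: float = 100.0,
    background: bool = True,
    seed: int = 0,
) -> CalciumTruth:
    """Random non-overlapping somata with a programmed expression mixture.

    ``p_expressed`` maps agonist label to the probability that a cell
    functionally expresses that channel (independent draws); an expressed
    cell responds with ``amplitude_sd`` x noise SD.
    """
    rng = np.random.default_rng(seed)
    p_expressed = p_expressed or {"M3": 0.4, "A1": 0.3, "V1": 0.5}
    margin = cell_radius_px + 6
    positions = []
    tries = 0
    while len(positions) < n_cells:
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place non-overlapping cells")
        cand = rng.uniform(
            [margin, margin], [shape[0] - margin, shape[1] - margin]
        )
        if all(
            np.hypot(*(cand - p)) > 2 * cell_radius_px + 2 for p in positions
        ):
            positions.append(cand)
    expressed = []
    for _ in range(n_cells):
        expressed.append(
            frozenset(
                lab for lab, p in p_expressed.items() if rng.random() < p
            )
        )
    k_resp = rng.random(n_cells) < p_k_responsive
    amplitudes = {
        lab: np.array(
            [amplitude_sd if lab in e else 0.0 for e in expressed]
        )
        for lab in p_expressed
    }
    amplitudes["K"] = np.where(k_resp, k_amplitude_sd, 0.0)
    coeffs = random_background_coeffs(rng) if background else None
    return CalciumTruth(
        cell_positions=np.array(positions),
        cell_radius_px=cell_radius_px,
        amplitudes=amplitudes,
        expressed=expressed,
        k_responsive=k_resp,
        wga_labeled=rng.random(n_cells) < p_wga,
        noise_sd=noise_sd,
        baseline_level=baseline_level,
        background_coeffs=coeffs,
    )


def _rasterize_polyline(
    labels: np.ndarray, points: np.ndarray, width_px: int, label: int
) -> np.ndarray:
    """Draw a polyline of the given width; returns the branch's pixel mask."""
    mask = np.zeros(labels.shape, dtype=bool)
    for (y0, x0), (y1, x1) in zip(points[:-1], points[1:]):
        n = int(max(abs(y1 - y0), abs(x1 - x0), 1)) * 2
        ys = np.round(np.linspace(y0, y1, n)).astype(int)
        xs = np.round(np.linspace(x0, x1, n)).astype(int)
        ok = (ys >= 0) & (ys < labels.shape[0]) & (xs >= 0) & (xs < labels.shape[1])
        mask[ys[ok], xs[ok]] = True
    if width_px > 1:
        mask = ndimage.binary_dilation(
            mask, structure=ndimage.generate_binary_structure(2, 2),
            iterations=width_px // 2,
        )
    return mask


def make_skin_truth(
    shape: tuple[int, int],
    n_branches: int = 5,
    branch_length_px: int = 60,
    width_px: int = 3,
    expressed: list[frozenset] | None = None,
    amplitude_sd: float = 10.0,
    noise_sd: float = 5.0,
    baseline_level: float = 100.0,
    background: bool = True,
    seed: int = 0,
) -> SkinTruth:
    """Random-walk nerve-ending branches, pairwise disjoint after dilation.

    Skin endings do not always respond robustly to high K+, so K amplitudes
    mirror the agonist truth rather than gating it.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    placed = 0
    tries = 0
    while placed < n_branches:
        tries += 1
        if tries > 2000:
            raise RuntimeError("could not place disjoint branches")
        start = rng.uniform([10, 10], [shape[0] - 10, shape[1] - 10])
        angle = rng.uniform(0, 2 * np.pi)
        pts = [start]
        for _ in range(branch_length_px // 4):
            angle += rng.normal(0, 0.45)
            step = np.array([np.sin(angle), np.cos(angle)]) * 4
            nxt = np.clip(pts[-1] + step, 4, np.asarray(shape) - 5)
            pts.append(nxt)
        mask = _rasterize_polyline(labels, np.asarray(pts), width_px, placed + 1)
        # keep branches separated by >= 3 px so segmented ROIs stay disjoint
        grown = ndimage.binary_dilation(mask, iterations=3)
        if (grown & occupied).any():
            continue
        labels[mask] = placed + 1
        occupied |= grown
        placed += 1
    if expressed is None:
        expressed = [
            frozenset(rng.choice(["M3", "A1", "V1"], size=rng.integers(1, 3),
                                 replace=False).tolist())
            for _ in range(n_branches)
        ]
    amplitudes = {
        lab: np.array([amplitude_sd if lab in e else 0.0 for e in expressed])
        for lab in ("M3", "A1", "V1")
    }
    amplitudes["K"] = np.array(
        [amplitude_sd if e else 0.0 for e in expressed]
    )
    coeffs = random_background_coeffs(rng) if background else None
    return SkinTruth(
        branch_labels=labels,
        amplitudes=amplitudes,
        expressed=list(expressed),
        k_responsive=np.array([bool(e) for e in expressed]),
        noise_sd=noise_sd,
        baseline_level=baseline_level,
        background_coeffs=coeffs,
    )


# ---------------------------------------------------------------------------
# generators


def gen_traces(
    n: int,
    amplitude_sd: float,
    onset: int,
    n_frames: int,
    noise_sd: float = 1.0,
    baseline: float = 0.0,
    tau_frames: float = DEFAULT_TAU_FRAMES,
    seed: int = 0,
) -> np.ndarray:
    """(n, T) array of single-ROI traces: baseline + transient + noise.

    ``amplitude_sd`` is the step height in units of the trace noise SD;
    0 gives pure-null traces for false-positive-rate measurements.
    """
    rng = np.random.default_rng(seed)
    kern = transient_kernel(n_frames, onset, tau_frames)
    clean = baseline + amplitude_sd * noise_sd * kern
    return clean[None, :] + rng.normal(0, noise_sd, size=(n, n_frames))


def gen_soma_movie(
    truth: CalciumTruth,
    protocol: StimulusProtocol,
    shape: tuple,
    seed: int,
    noise: str = "gaussian",
    frame_period_s: float = 4.0,
    pixel_size_um: float = 1.0,
) -> tuple[Movie, np.ndarray, CalciumTruth]:
    """Render a DRG-soma movie plus its WGA retrograde-label channel.

    ``shape`` is (T, Y, X) or (T, Z, Y, X); z planes are identical up to
    noise. Returns ``(movie, wga_image, truth)``.
    """
    frame_shape = shape[-2:]
    n_frames = shape[0]
    if protocol.last_end > n_frames:
        raise ValueError("stimulus protocol does not fit within the movie")
    truth.validate(frame_shape)
    rng = np.random.default_rng(seed)
    labels = soma_label_image(truth, frame_shape)
    traces = _cell_traces(truth, protocol, n_frames, truth.n_cells)
    data = _render_movie(labels, traces, truth, tuple(shape), rng, noise)
    movie = Movie(
        data=data,
        frame_period_s=frame_period_s,
        pixel_size_um=pixel_size_um,
        channel="GCaMP3",
    )
    wga = _wga_image(labels, truth.wga_labeled, rng)
    return movie, wga, truth


def gen_skin_movie(
    truth: SkinTruth,
    protocol: StimulusProtocol,
    shape: tuple,
    seed: int,
    noise: str = "gaussian",
    frame_period_s: float = 4.0,
    pixel_size_um: float = 1.0,
) -> tuple[Movie, SkinTruth]:
    """Render a skin-nerve movie: branches share one trace per branch."""
    frame_shape = shape[-2:]
    if truth.branch_labels.shape != tuple(frame_shape):
        raise ValueError("branch label image does not match movie shape")
    if protocol.last_end > shape[0]:
        raise ValueError("stimulus protocol does not fit within the movie")
    for lab, amp in truth.amplitudes.items():
        if np.any(np.asarray(amp) < 0):
            raise ValueError(f"negative amplitude for stimulus {lab!r}")
    rng = np.random.default_rng(seed)
    traces = _cell_traces(truth, protocol, shape[0], truth.n_branches)
    data = _render_movie(truth.branch_labels, traces, truth, tuple(shape), rng, noise)
    movie = Movie(
        data=data,
        frame_period_s=frame_period_s,
        pixel_size_um=pixel_size_um,
        channel="GCaMP3",
    )
    return movie, truth


# ---------------------------------------------------------------------------
# RNAscope


def grid_cell_masks(
    shape: tuple[int, int], n_cells: int, cell_radius_px: int
) -> np.ndarray:
    """Circular cell masks on a regular grid (stand-in for the manual
    Pgp9.5-based segmentation, which is an input to the real pipeline)."""
    side = int(np.ceil(np.sqrt(n_cells)))
    pitch_y = shape[0] // side
    pitch_x = shape[1] // side
    if min(pitch_y, pitch_x) < 2 * cell_radius_px + 4:
        raise ValueError("image too small for requested cells")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    c = 0
    for gy in range(side):
        for gx in range(side):
            if c >= n_cells:
                break
            cy = gy * pitch_y + pitch_y // 2
            cx = gx * pitch_x + pitch_x // 2
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px**2] = c + 1
            c += 1
    return labels


def make_rnascope_truth(
    shape: tuple[int, int] = (700, 700),
    n_cells: int = 100,
    cell_radius_px: int = 28,
    mean_dots: float = 8.0,
    cluster_fraction: float = 0.2,
    p_wga: float = 0.5,
    snr: float = 10.0,
    single_dot_intensity: float = 1000.0,
    single_dot_diameter_um: float = 0.8,
    pixel_size_um: float = 0.325,
    seed: int = 0,
) -> RnascopeTruth:
    """Poisson dots-per-cell truth on a grid of circular cells.

    Defaults follow the stated quantification conditions: ~100 cells,
    Poisson-distributed counts (mean 8), 20% of dots emitted inside
    clusters, spot SNR 10 (peak amplitude / noise SD).
    """
    rng = np.random.default_rng(seed)
    masks = grid_cell_masks(shape, n_cells, cell_radius_px)
    dots = rng.poisson(mean_dots, size=n_cells)
    sigma_px = (single_dot_diameter_um / pixel_size_um) / (2 * np.sqrt(2))
    peak_amp = single_dot_intensity / (2 * np.pi * sigma_px**2)
    noise_sd = peak_amp / snr if snr > 0 else 0.0
    return RnascopeTruth(
        cell_masks=masks,
        dots_per_cell=dots,
        wga_labeled=rng.random(n_cells) < p_wga,
        cluster_fraction=cluster_fraction,
        single_dot_intensity=single_dot_intensity,
        single_dot_diameter_um=single_dot_diameter_um,
        noise_sd=noise_sd,
    )


def _add_gaussian_spot(
    img: np.ndarray, y: float, x: float, sigma: float, integrated: float
) -> None:
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(img.shape[0], int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(img.shape[1], int(x) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    amp = integrated / (2 * np.pi * sigma**2)
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def gen_rnascope_image(
    truth: RnascopeTruth,
    shape: tuple[int, int],
    pixel_size_um: float,
    seed: int,
) -> tuple[dict[str, np.ndarray], RnascopeTruth]:
    """Render probe / WGA / DAPI channels for an RNAscope truth.

    A ``cluster_fraction`` of each cell's dots are merged into clusters of
    2-4 members laid out as short chains (spacing ~0.9 dot diameters), so a
    cluster appears as one contiguous object whose integrated intensity is
    exactly the sum of its members. A smooth background gradient and
    Gaussian noise are added on top.

    Returns ``(channels, truth)`` with keys ``probe``, ``wga``, ``dapi``;
    the realised cluster memberships are recorded in ``truth.cluster_sizes``.
    """
    d_px = truth.single_dot_diameter_um / pixel_size_um
    if d_px < 2:
        raise ValueError(
            f"dot diameter {d_px:.2f} px < 2 px: pixel size too coarse"
        )
    if truth.cell_masks.shape != tuple(shape):
        raise ValueError("cell mask shape does not match requested shape")
    if truth.dots_per_cell.sum() > 0 and truth.cell_masks.max() == 0:
        raise ValueError("dots requested but no cell masks present")
    rng = np.random.default_rng(seed)
    sigma = d_px / (2 * np.sqrt(2))
    probe = np.zeros(shape, dtype=float)
    # gentle smooth gradient, small relative to spot amplitude
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    amp = truth.single_dot_intensity / (2 * np.pi * sigma**2)
    probe += 0.05 * amp * (xx / shape[1] + 0.5 * yy / shape[0]) + 0.02 * amp

    slices = ndimage.find_objects(truth.cell_masks)
    truth.cluster_sizes = []
    for c in range(truth.n_cells):
        n = int(truth.dots_per_cell[c])
        sizes: list[int] = []
        if n == 0 or slices[c] is None:
            truth.cluster_sizes.append(sizes)
            continue
        ys, xs = np.nonzero(truth.cell_masks == c + 1)
        n_clustered = int(round(truth.cluster_fraction * n))
        # group clustered dots into chains of 2-4; leftovers become singles
        pool = n_clustered
        while pool >= 2:
            size = int(min(rng.integers(2, 5), pool))
            sizes.append(size)
            pool -= size
        n_singles = n - sum(sizes)
        # random positions strictly inside the mask
        def draw_pos():
            i = rng.integers(len(ys))
            return float(ys[i]), float(xs[i])

        for _ in range(n_singles):
            y, x = draw_pos()
            _add_gaussian_spot(probe, y, x, sigma, truth.single_dot_intensity)
        for size in sizes:
            y, x = draw_pos()
            ang = rng.uniform(0, 2 * np.pi)
            for m in range(size):
                ang += rng.normal(0, 0.5)
                my = y + 0.9 * d_px * m * np.sin(ang)
                mx = x + 0.9 * d_px * m * np.cos(ang)
                my = float(np.clip(my, 0, shape[0] - 1))
                mx = float(np.clip(mx, 0, shape[1] - 1))
                _add_gaussian_spot(
                    probe, my, mx, sigma, truth.single_dot_intensity
                )
        truth.cluster_sizes.append(sizes)
    if truth.noise_sd > 0:
        probe += rng.normal(0, truth.noise_sd, size=shape)
    probe = np.clip(probe, 0, None)
    wga = _wga_image(truth.cell_masks, truth.wga_labeled, rng)
    dapi = np.where(truth.cell_masks > 0, 200.0, 20.0)
    if truth.noise_sd > 0:
        dapi = np.clip(dapi + rng.normal(0, 5.0, size=shape), 0, None)
    return {"probe": probe, "wga": wga, "dapi": dapi}, truth


def save_truth_json(truth, path: str | Path) -> None:
    """Ground-truth JSON sidecar for a generated dataset."""
    doc = {}
    for k, v in vars(truth).items():
        if isinstance(v, np.ndarray) and v.ndim > 1 and k.endswith(("masks", "labels")):
            doc[k] = {"shape": list(v.shape), "n_labels": int(v.max())}
        elif isinstance(v, list) and v and isinstance(v[0], frozenset):
            doc[k] = [sorted(s) for s in v]
        else:
            doc[k] = v
    save_json(doc, path)
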