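"""End-to-end analysis drivers and the synthetic cohort experiment.

``analyze_drg_movie`` / ``analyze_skin_movie`` chain preprocessing, ROI
extraction, responder calling and the mode-appropriate summaries.
``simulate_cohort`` builds a full synthetic "inflamed vs control side"
experiment — several virtual animals per side with a programmed enrichment
of TRPM3 responders ipsilaterally — and pushes every movie through the
pipeline, ending in the bootstrap ratio-of-means comparison. It is the
package's parameter-recovery testbed: the programmed enrichment is known,
so the estimated ratio and its CI can be validated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Movie, StimulusProtocol, default_protocol
from .preprocess import preprocess_movie
from .respond import (
    ResponseTable,
    apply_k_exclusion,
    classify_responses,
    coexpression_classes,
    normalize_to_k,
    responder_fraction,
    responsive_area,
)
from .roi import RoiSet, classify_wga, detect_correlated_rois, detect_soma_rois
from .stats import bootstrap_ratio_ci
from .synthgen import gen_soma_movie, make_soma_truth, soma_label_image

__all__ = ["analyze_drg_movie", "analyze_skin_movie", "simulate_cohort"]


def analyze_drg_movie(
    movie: Movie,
    protocol: StimulusProtocol,
    wga_image: np.ndarray | None = None,
    cell_masks: np.ndarray | None = None,
    register: bool = True,
    peak_mult: float = 5.0,
    k_exclude: bool = True,
) -> dict:
    """DRG-soma pipeline: preprocess, segment somata, call responses,
    apply the K+ excitability gate and K+ normalisation.

    ``cell_masks`` imports a label mask (the manual-identification
    workflow); omit it for automatic blob detection on the reference image.
    Returns a dict with ``roiset``, ``table``, ``fractions`` and the
    preprocessing products under ``pre``.
    """
    pre = preprocess_movie(
        movie, first_onset=protocol.first_onset, register=register
    )
    dff = pre["movie"]
    roiset = detect_soma_rois(
        dff, reference=pre["reference"].data, import_mask=cell_masks
    )
    if wga_image is not None and roiset.n_rois:
        classify_wga(roiset, wga_image)
    table = classify_responses(
        roiset, protocol, frame_period_s=movie.frame_period_s, peak_mult=peak_mult
    )
    if k_exclude and protocol.has_k:
        apply_k_exclusion(table)
        normalize_to_k(table)
    coexpression_classes(table)
    fractions = (
        responder_fraction(table) if table.included_ids() else pd.DataFrame()
    )
    return {"roiset": roiset, "table": table, "fractions": fractions, "pre": pre}


def analyze_skin_movie(
    movie: Movie,
    protocol: StimulusProtocol,
    min_corr: float = 0.8,
    min_size_px: int = 10,
    peak_mult: float = 5.0,
) -> dict:
    """Skin-nerve pipeline: preprocess, correlated-activity segmentation,
    responder calling and responsive-area fractions (no K+ exclusion)."""
    pre = preprocess_movie(movie, first_onset=protocol.first_onset)
    roiset = detect_correlated_rois(
        pre["movie"], min_corr=min_corr, min_size_px=min_size_px
    )
    table = classify_responses(
        roiset, protocol, frame_period_s=movie.frame_period_s, peak_mult=peak_mult
    )
    coexpression_classes(table)
    areas = responsive_area(roiset, table, imaged_area_px=movie.data[0].size)
    return {"roiset": roiset, "table": table, "areas": areas, "pre": pre}


def simulate_cohort(
    n_animals: int = 6,
    cells_per_animal: int = 30,
    p_m3_ipsi: float = 0.4,
    p_m3_contra: float = 0.2,
    amplitude_sd: float = 10.0,
    p_k_responsive: float = 0.9,
    shape: tuple = (48, 96, 96),
    n_boot: int = 10_000,
    seed: int = 0,
    register: bool = False,
) -> dict:
    """Synthetic ipsi-vs-contra cohort with a programmed M3 enrichment.

    Each virtual animal contributes one DRG movie per side; the ipsilateral
    ("inflamed") side carries a ``p_m3_ipsi / p_m3_contra``-fold enrichment
    of TRPM3-responsive cells. Movies run through the full DRG pipeline
    (truth label masks imported, mirroring the manual identification step),
    and the pooled non-excluded cells feed the cell-level bootstrap
    ratio-of-means comparison of M3 responder fractions.

    Returns ``per_animal`` (side/animal fractions), ``comparison``
    (``GroupComparison``, true value 100 * p_m3_ipsi / p_m3_contra), the
    pooled per-cell indicators, and an exclusion audit trail.
    """
    ss = np.random.SeedSequence(seed)
    protocol = default_protocol(pre=12, stim_len=6, wash=12, labels=("M3", "K"))
    rows = []
    indicators: dict[str, list[int]] = {"ipsi": [], "contra": []}
    audit_violations = 0
    for a in range(n_animals):
        for side, p_m3 in (("ipsi", p_m3_ipsi), ("contra", p_m3_contra)):
            child = ss.spawn(1)[0]
            s_truth, s_movie = child.generate_state(2) % (2**31)
            truth = make_soma_truth(
                shape[-2:],
                n_cells=cells_per_animal,
                cell_radius_px=4.0,
                p_expressed={"M3": p_m3},
                amplitude_sd=amplitude_sd,
                p_k_responsive=p_k_responsive,
                seed=int(s_truth),
            )
            movie, wga, _ = gen_soma_movie(
                truth, protocol, shape, seed=int(s_movie)
            )
            res = analyze_drg_movie(
                movie,
                protocol,
                wga_image=wga,
                cell_masks=soma_label_image(truth, shape[-2:]),
                register=register,
            )
            table: ResponseTable = res["table"]
            included = set(table.included_ids())
            m3 = set(table.responders("M3"))
            # exclusion audit: no K+-excluded ROI may surface downstream
            excluded_ids = set(
                table.rois.loc[table.rois["excluded"], "roi_id"].tolist()
            )
            for lab in protocol.labels:
                audit_violations += len(set(table.responders(lab)) & excluded_ids)
            for rid in sorted(included):
                indicators[side].append(int(rid in m3))
            rows.append(
                {
                    "animal": a,
                    "side": side,
                    "n_cells": len(included),
                    "n_excluded": table.rois["excluded"].sum(),
                    "n_m3": len(m3),
                    "fraction": len(m3) / len(included) if included else np.nan,
                }
            )
    per_animal = pd.DataFrame(rows)
    boot_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    comparison = bootstrap_ratio_ci(
        np.array(indicators["ipsi"], dtype=float),
        np.array(indicators["contra"], dtype=float),
        n_boot=n_boot,
        seed=boot_seed,
    )
    return {
        "per_animal": per_animal,
        "comparison": comparison,
        "indicators": indicators,
        "true_ratio_pct": 100.0 * p_m3_ipsi / p_m3_contra,
        "audit_violations": int(audit_violations),
    }
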