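"""Per-ROI response classification and population summaries.

A region counts as a responder to a stimulus only if two independent
criteria both hold on its dF/F0 trace:

1. **Peak criterion** — the peak during stimulation, measured above the
   pre-stimulus baseline mean, strictly exceeds 5 x the SD of the trace over
   the pre-stimulus window.
2. **Derivative criterion** — the peak of the first derivative (dF/dt)
   during stimulation strictly exceeds the SD of dF/dt over the
   pre-stimulus window.

The dual criterion rejects slow baseline drift (which can satisfy the peak
criterion alone) while the 5-SD peak gate controls noise-driven false
positives. Regions that fail the criterion on the terminal depolarising
high-K+ window are considered non-excitable and excluded from every
downstream summary (DRG mode); amplitudes are reported normalised to the
K+ response. Skin mode skips K+ exclusion/normalisation, since nerve
endings do not reliably depolarise-respond, and reports responsive area
fractions instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AGONISTS, K_LABEL, StimulusProtocol
from .roi import RoiSet

__all__ = [
    "ResponseCall",
    "ResponseTable",
    "call_response",
    "classify_responses",
    "apply_k_exclusion",
    "normalize_to_k",
    "coexpression_classes",
    "coexpression_frequencies",
    "responder_fraction",
    "responsive_area",
]


@dataclass
class ResponseCall:
    """Outcome of the dual responder criterion for one trace/stimulus."""

    is_responder: bool
    peak_dff: float
    peak_margin: float  # peak - mult * SD(pre); > 0 passes criterion 1
    deriv_margin: float  # peak dF/dt - mult * SD(dF/dt pre); > 0 passes 2
    degenerate: bool = False


def call_response(
    trace: np.ndarray,
    stim_window: tuple[int, int],
    pre_window: tuple[int, int],
    frame_period_s: float = 4.0,
    peak_mult: float = 5.0,
    deriv_mult: float = 1.0,
    baseline_subtract: bool = True,
    eps: float = 1e-12,
) -> ResponseCall:
    """Dual-criterion responder call on a single dF/F0 trace.

    ``stim_window`` and ``pre_window`` are (start, stop) frame ranges,
    stop-exclusive; both must span >= 3 frames and the baseline must precede
    the stimulation. SDs are sample SDs (ddof=1). A zero pre-stimulus SD is
    replaced by ``eps`` and the call flagged degenerate.

    With ``baseline_subtract`` (default) the peak is measured above the
    pre-window mean; otherwise the raw trace maximum is compared against
    baseline mean + ``peak_mult`` x SD all the same (the margin is identical;
    ``peak_dff`` is then reported unsubtracted).
    """
    trace = np.asarray(trace, dtype=float)
    s0, s1 = stim_window
    p0, p1 = pre_window
    if p1 - p0 < 3 or s1 - s0 < 3:
        raise ValueError("stimulus and baseline windows must span >= 3 frames")
    if p1 > s0:
        raise ValueError("baseline window must precede the stimulus window")
    if s1 > len(trace):
        raise ValueError("stimulus window beyond end of trace")
    pre = trace[p0:p1]
    base = pre.mean()
    sd = pre.std(ddof=1)
    degenerate = sd <= eps
    if degenerate:
        sd = eps
    peak_raw = trace[s0:s1].max()
    peak_above = peak_raw - base
    peak_margin = peak_above - peak_mult * sd

    dtrace = np.diff(trace) / frame_period_s
    # dtrace[i] spans frames i -> i+1; the onset step lives at index s0-1
    d_stim = dtrace[max(s0 - 1, 0) : s1 - 1]
    d_pre = dtrace[p0 : p1 - 1]
    d_sd = d_pre.std(ddof=1)
    if d_sd <= eps:
        d_sd = eps
        degenerate = True
    deriv_margin = d_stim.max() - deriv_mult * d_sd

    return ResponseCall(
        is_responder=bool(peak_margin > 0 and deriv_margin > 0),
        peak_dff=float(peak_above if baseline_subtract else peak_raw),
        peak_margin=float(peak_margin),
        deriv_margin=float(deriv_margin),
        degenerate=bool(degenerate),
    )


@dataclass
class ResponseTable:
    """Per-ROI x per-stimulus calls plus per-ROI summary flags.

    ``calls`` has one row per (roi_id, stimulus) with the responder flag and
    amplitudes; ``rois`` one row per ROI with the K+ responder/excluded
    flags, WGA status and co-expression class (filled by
    :func:`coexpression_classes`).
    """

    calls: pd.DataFrame
    rois: pd.DataFrame
    protocol: StimulusProtocol
    k_excluded: bool = False

    def included_ids(self) -> list[int]:
        return self.rois.loc[~self.rois["excluded"], "roi_id"].tolist()

    def responders(self, label: str, include_excluded: bool = False) -> list[int]:
        sub = self.calls[(self.calls["stimulus"] == label) & self.calls["is_responder"]]
        ids = sub["roi_id"].tolist()
        if include_excluded:
            return ids
        keep = set(self.included_ids())
        return [i for i in ids if i in keep]

    def to_csv(self, calls_path, rois_path) -> None:
        self.calls.to_csv(calls_path, index=False)
        self.rois.to_csv(rois_path, index=False)


def classify_responses(
    roiset: RoiSet,
    protocol: StimulusProtocol,
    frame_period_s: float = 4.0,
    peak_mult: float = 5.0,
    deriv_mult: float = 1.0,
    recovery_gap: int = 0,
) -> ResponseTable:
    """Run the dual criterion on every ROI trace for every stimulus window.

    The per-stimulus baseline is the span between the previous stimulus'
    end (plus ``recovery_gap`` frames) and the current onset, capped at the
    protocol's ``pre_frames``.
    """
    call_rows = []
    roi_rows = []
    for roi_id in roiset.roi_ids:
        trace = roiset.traces[roi_id]
        k_resp = False
        for w in protocol.windows:
            pre = protocol.pre_window(w.label, gap=recovery_gap)
            call = call_response(
                trace,
                (w.start_frame, w.end_frame),
                pre,
                frame_period_s=frame_period_s,
                peak_mult=peak_mult,
                deriv_mult=deriv_mult,
            )
            call_rows.append(
                {
                    "roi_id": roi_id,
                    "stimulus": w.label,
                    "is_responder": call.is_responder,
                    "peak_dff": call.peak_dff,
                    "peak_margin": call.peak_margin,
                    "deriv_margin": call.deriv_margin,
                    "degenerate": call.degenerate,
                }
            )
            if w.label == K_LABEL:
                k_resp = call.is_responder
        roi_rows.append(
            {
                "roi_id": roi_id,
                "k_responder": k_resp,
                "excluded": False,
                "wga_status": roiset.wga_status.get(roi_id, "n/a"),
                "coexpression_class": "",
                "area_px": roiset.area_px(roi_id),
                "area_um2": roiset.area_um2(roi_id),
            }
        )
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "roi_id", "stimulus", "is_responder", "peak_dff",
            "peak_margin", "deriv_margin", "degenerate",
        ],
    )
    rois = pd.DataFrame(
        roi_rows,
        columns=[
            "roi_id", "k_responder", "excluded", "wga_status",
            "coexpression_class", "area_px", "area_um2",
        ],
    )
    return ResponseTable(calls=calls, rois=rois, protocol=protocol)


def apply_k_exclusion(table: ResponseTable) -> ResponseTable:
    """Flag ROIs failing the high-K+ criterion as excluded from all
    downstream summaries (the excitability gate)."""
    if not table.protocol.has_k:
        raise ValueError("protocol has no high-K+ stimulus to gate on")
    table.rois["excluded"] = ~table.rois["k_responder"]
    table.k_excluded = True
    return table


def normalize_to_k(table: ResponseTable) -> ResponseTable:
    """Add K+-normalised amplitudes: peak_dff / peak_dff(K) per ROI.

    Only defined for non-excluded ROIs; a non-excluded ROI with a
    non-positive K+ peak indicates an inconsistent table and is rejected.
    """
    if not table.k_excluded:
        raise ValueError("apply_k_exclusion must run before K-normalisation")
    k_peak = (
        table.calls[table.calls["stimulus"] == K_LABEL]
        .set_index("roi_id")["peak_dff"]
    )
    excluded = table.rois.set_index("roi_id")["excluded"]
    bad = [
        rid
        for rid in k_peak.index
        if not excluded.get(rid, True) and k_peak[rid] <= 0
    ]
    if bad:
        raise ValueError(
            f"non-excluded ROI(s) {bad} have non-positive K+ peak: "
            "inconsistent table"
        )
    norm = []
    for _, row in table.calls.iterrows():
        rid = row["roi_id"]
        if excluded.get(rid, True):
            norm.append(np.nan)
        else:
            norm.append(row["peak_dff"] / k_peak[rid])
    table.calls["peak_dff_norm"] = norm
    return table


def _class_string(labels: set[str]) -> str:
    ordered = [lab for lab in AGONISTS if lab in labels]
    return "+".join(ordered) if ordered else "none"


def coexpression_classes(table: ResponseTable) -> ResponseTable:
    """Assign each ROI its functional co-expression class: the set of
    agonists (M3/A1/V1) it responded to, one of 8 possible classes."""
    resp = {
        lab: set(table.responders(lab, include_excluded=True))
        for lab in AGONISTS
        if lab in table.protocol.labels
    }
    classes = []
    for rid in table.rois["roi_id"]:
        classes.append(_class_string({lab for lab, s in resp.items() if rid in s}))
    table.rois["coexpression_class"] = classes
    return table


def coexpression_frequencies(
    table: ResponseTable, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Relative frequency of each co-expression class among non-excluded
    ROIs, optionally per group (e.g. ipsi/contra x WGA+/-).

    The 8 class frequencies sum to 1 within each group.
    """
    rois = table.rois[~table.rois["excluded"]].copy()
    if rois.empty:
        raise ValueError("no non-excluded ROIs")
    if grouping is not None:
        rois["group"] = rois["roi_id"].map(grouping)
    else:
        rois["group"] = "all"
    freqs = (
        rois.groupby("group")["coexpression_class"]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )
    return freqs


def responder_fraction(
    table: ResponseTable,
    grouping: pd.Series | None = None,
) -> pd.DataFrame:
    """Fraction of non-excluded ROIs responding to each stimulus, per group.

    ``grouping`` maps roi_id to a group key (e.g. animal id); per-group rows
    are retained so the per-animal values can feed the ANOVA stage. Empty
    groups are reported with NaN fraction and flagged.
    """
    included = set(table.included_ids())
    rows = []
    groups: dict = {}
    for rid in table.rois["roi_id"]:
        if rid not in included:
            continue
        g = grouping.get(rid, "all") if grouping is not None else "all"
        groups.setdefault(g, []).append(rid)
    if not groups:
        raise ValueError("no non-excluded ROIs in any group")
    for lab in table.protocol.labels:
        resp = set(table.responders(lab))
        for g, ids in sorted(groups.items(), key=lambda kv: str(kv[0])):
            n = len(ids)
            k = len(resp.intersection(ids))
            rows.append(
                {
                    "group": g,
                    "stimulus": lab,
                    "n_rois": n,
                    "n_responders": k,
                    "fraction": k / n if n else np.nan,
                    "empty_group": n == 0,
                }
            )
    return pd.DataFrame(rows)


def responsive_area(
    roiset: RoiSet,
    table: ResponseTable,
    imaged_area_px: int | None = None,
    per_class: bool = True,
) -> pd.DataFrame:
    """Skin-nerve readout: summed area of responding ROIs / imaged area.

    K+ exclusion is deliberately NOT applied here — nerve endings do not
    reliably respond to depolarisation, so all segmented ROIs count. Rows
    cover each stimulus ("any responder") and, with ``per_class``, each
    exact co-expression class; exact-class fractions sum to the
    any-agonist fraction.
    """
    total = imaged_area_px or roiset.labels.size
    areas = {i: roiset.area_px(i) for i in roiset.roi_ids}
    rows = []
    for lab in table.protocol.labels:
        ids = table.responders(lab, include_excluded=True)
        rows.append(
            {
                "kind": "stimulus",
                "key": lab,
                "area_px": sum(areas[i] for i in ids),
                "fraction": sum(areas[i] for i in ids) / total,
            }
        )
    if per_class:
        if (table.rois["coexpression_class"] == "").all() and len(table.rois):
            coexpression_classes(table)
        for cls, sub in table.rois.groupby("coexpression_class"):
            ids = sub["roi_id"].tolist()
            rows.append(
                {
                    "kind": "class",
                    "key": cls,
                    "area_px": sum(areas[i] for i in ids),
                    "fraction": sum(areas[i] for i in ids) / total,
                }
            )
    return pd.DataFrame(rows)
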