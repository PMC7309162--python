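"""Pathologic-finding criteria applied to delineated recordings.

Thresholds are the standard printed criteria: wide QRS at ≥120 ms; ST
elevation/depression at ≥0.1 mV measured 80 ms after the J point against the
PR-segment isoelectric baseline; pathologic Q at ≥25% of the R amplitude
with ≥40 ms duration; T inversion as a negative T peak in any of V4–V6;
left ventricular hypertrophy by the Sokolow–Lyon voltage S(V1) +
max(R(V5), R(V6)) ≥ 3.5 mV.  All thresholds are inclusive and overridable.

A recording-level label requires the criterion to hold in at least half of
the beats where it could be evaluated (majority vote).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import DiagnosticParams, FiducialSet
from .records import MultiLeadRecord

FINDINGS = ("wide_qrs", "st_elevation", "st_depression", "pathologic_q",
            "t_inversion_v4_6", "lvh")


@dataclass
class CriteriaThresholds:
    """Printed diagnostic thresholds, kept overridable in one place."""

    wide_qrs_ms: float = 120.0
    st_mv: float = 0.1
    st_delay_after_j_s: float = 0.080
    q_fraction_of_r: float = 0.25
    q_duration_ms: float = 40.0
    lvh_mv: float = 3.5
    #: minimum |T| (μV) for a T-inversion call, below which polarity is noise
    t_floor_uv: float = 30.0


@dataclass
class PathologyLabelSet:
    """Per-recording booleans plus the measurements behind them."""

    wide_qrs: bool
    st_elevation: bool
    st_depression: bool
    pathologic_q: bool
    t_inversion_v4_6: bool
    lvh: bool
    qrs_ms: float
    st_dev_max_mv: float
    st_dev_min_mv: float
    q_r_ratio_max: float
    sokolow_mv: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FINDINGS}


def _vote(flags) -> bool:
    flags = [bool(f) for f in flags]
    return bool(flags and sum(flags) * 2 >= len(flags))


def classify_pathologies(params: DiagnosticParams, fiducials: FiducialSet,
                         record: MultiLeadRecord,
                         thresholds: CriteriaThresholds = None
                         ) -> PathologyLabelSet:
    """Evaluate every finding criterion on one delineated recording."""
    thr = thresholds or CriteriaThresholds()
    for required in ("V1", "V5", "V6", "V4"):
        if required not in record.lead_names:
            raise ValueError(f"criteria need lead {required}, absent from record")
    fs = fiducials.fs
    ms = 1000.0 / fs
    st_at = int(round(thr.st_delay_after_j_s * fs))

    wide, elev, depr, path_q, t_inv, lvh = [], [], [], [], [], []
    st_max_all, st_min_all, qr_all, sok_all = [], [], [], []
    for b in fiducials.beats:
        if not b.valid["QRS"]:
            continue
        c = b.consensus
        wide.append((c["qrs_off"] - c["qrs_on"]) * ms >= thr.wide_qrs_ms)

        # ST deviation per lead at J + delay, vs the lead's own baseline;
        # aVR is excluded as in standard practice (it mirrors the other
        # leads, so true elevation elsewhere shows as reciprocal depression)
        j = c["qrs_off"]
        devs = []
        for name in record.lead_names:
            if name == "aVR":
                continue
            m = b.per_lead[name]
            idx = j + st_at
            if idx < record.n_samples:
                devs.append((record.lead(name)[idx] - m["baseline"]) / 1000.0)
        if devs:
            st_max_all.append(max(devs))
            st_min_all.append(min(devs))
            elev.append(max(devs) >= thr.st_mv)
            depr.append(min(devs) <= -thr.st_mv)

        # pathologic Q: any lead with deep and wide enough Q
        beat_q = False
        best_ratio = 0.0
        for name in record.lead_names:
            m = b.per_lead[name]
            if m.get("q") is None or m.get("r_amp") in (None, 0):
                continue
            ratio = abs(m["q_amp"]) / abs(m["r_amp"])
            best_ratio = max(best_ratio, ratio)
            if m.get("qrs_on") is not None:
                q_dur_ms = 2.0 * (m["q"] - m["qrs_on"]) * ms
                if ratio >= thr.q_fraction_of_r and q_dur_ms >= thr.q_duration_ms:
                    beat_q = True
        path_q.append(beat_q)
        qr_all.append(best_ratio)

        # T inversion in V4–V6
        inv = False
        for name in ("V4", "V5", "V6"):
            amp = b.per_lead[name].get("t_amp")
            if amp is not None and amp <= -thr.t_floor_uv:
                inv = True
        t_inv.append(inv)

        # Sokolow–Lyon voltage
        s_v1 = abs(b.per_lead["V1"].get("s_amp") or 0.0)
        r_v56 = max(abs(b.per_lead["V5"].get("r_amp") or 0.0),
                    abs(b.per_lead["V6"].get("r_amp") or 0.0))
        sok = (s_v1 + r_v56) / 1000.0
        sok_all.append(sok)
        lvh.append(sok >= thr.lvh_mv)

    return PathologyLabelSet(
        wide_qrs=_vote(wide),
        st_elevation=_vote(elev),
        st_depression=_vote(depr),
        pathologic_q=_vote(path_q),
        t_inversion_v4_6=_vote(t_inv),
        lvh=_vote(lvh),
        qrs_ms=params.qrs_ms,
        st_dev_max_mv=float(np.median(st_max_all)) if st_max_all else float("nan"),
        st_dev_min_mv=float(np.median(st_min_all)) if st_min_all else float("nan"),
        q_r_ratio_max=float(np.median(qr_all)) if qr_all else float("nan"),
        sokolow_mv=float(np.median(sok_all)) if sok_all else float("nan"),
    )


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def add(self, truth: bool, predicted: bool):
        if truth and predicted:
            self.tp += 1
        elif truth and not predicted:
            self.fn += 1
        elif not truth and predicted:
            self.fp += 1
        else:
            self.tn += 1


def compare_labels(truth, predicted) -> dict:
    """Tally per-finding confusion counts across recordings.

    ``truth`` is a list of dicts (finding → bool); ``predicted`` a list of
    :class:`PathologyLabelSet` or dicts of the same shape.
    """
    if len(truth) != len(predicted):
        raise ValueError(f"label list lengths differ: {len(truth)} vs "
                         f"{len(predicted)}")
    counts = {f: ConfusionCounts() for f in FINDINGS}
    for t, p in zip(truth, predicted):
        p_dict = p.as_dict() if isinstance(p, PathologyLabelSet) else p
        for f in FINDINGS:
            if f in t:
                counts[f].add(bool(t[f]), bool(p_dict.get(f, False)))
    return counts
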