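"""Waveform-identicalness metrics (CC, RMSE) and report assembly.

CC is the Pearson correlation between the target and reconstructed lead
over the full held-out segment; RMSE is in μV.  The per-finding diagnostic
performance is summarized as sensitivity = TP/(TP+FN) and specificity =
TN/(TN+FP), displayed as whole percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import MultiLeadRecord


def lead_cc(y, yhat) -> float:
    """Pearson correlation of two equal-length sample vectors."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("signals must share a length of at least 3")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("correlation undefined for a constant signal")
    yc = y - y.mean()
    hc = yhat - yhat.mean()
    return float(yc @ hc / math.sqrt((yc @ yc) * (hc @ hc)))


def lead_rmse(y, yhat) -> float:
    """Root-mean-square error in μV."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("signals must have equal length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def record_metrics(target: MultiLeadRecord, recon: MultiLeadRecord):
    """Per-lead CC and RMSE between a target record and a reconstruction."""
    cc = {}
    rmse = {}
    for name in target.lead_names:
        cc[name] = lead_cc(target.lead(name), recon.lead(name))
        rmse[name] = lead_rmse(target.lead(name), recon.lead(name))
    return cc, rmse


def sens_spec(tp: int, fp: int, tn: int, fn: int):
    """(sensitivity %, specificity %) with full precision; NaN when a term
    is undefined (no positives / no negatives)."""
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return sens, spec


@dataclass
class EvalReport:
    """Assembled evaluation: waveform metrics per method, the diagnostic
    parameter comparison, and per-finding sensitivity/specificity."""

    waveform: pd.DataFrame          # rows: lead + mean; cols: (method, metric)
    parameters: pd.DataFrame        # rows: parameter; cols: method
    diagnostics: pd.DataFrame       # rows: finding; cols: (method, sens/spec)
    notes: list = field(default_factory=list)

    def to_text(self) -> str:
        parts = ["== Waveform identicalness (CC / RMSE μV) ==",
                 self.waveform.round(4).to_string(),
                 "", "== Diagnostic parameters ==",
                 self.parameters.round(3).to_string()]
        if len(self.diagnostics):
            parts += ["", "== Pathology detection (%) ==",
                      self.diagnostics.round(0).to_string()]
        for n in self.notes:
            parts.append(f"note: {n}")
        return "\n".join(parts) + "\n"


def build_report(target: MultiLeadRecord, reconstructions: dict,
                 params: dict = None, confusions: dict = None) -> EvalReport:
    """Assemble an :class:`EvalReport`.

    ``reconstructions`` maps method name ('lr', 'lstm', ...) to a
    reconstructed 12-lead record; ``params`` maps column name (including
    'standard') to a DiagnosticParams; ``confusions`` maps method name to
    per-finding ConfusionCounts.
    """
    notes = []
    leads = list(target.lead_names)
    cols = {}
    for method, rec in reconstructions.items():
        if rec is None:
            notes.append(f"method {method!r} missing; partial report")
            continue
        cc, rmse = record_metrics(target, rec)
        cols[(method, "CC")] = [cc[n] for n in leads] + \
            [float(np.mean(list(cc.values())))]
        cols[(method, "RMSE_uV")] = [rmse[n] for n in leads] + \
            [float(np.mean(list(rmse.values())))]
    waveform = pd.DataFrame(cols, index=leads + ["mean"])

    if params:
        rows = ["axis_deg", "p_amp_ii_mv", "pr_ms", "qrs_ms",
                "qrs_voltage_mv", "qt_ms", "t_amp_v4_mv", "t_amp_v5_mv",
                "t_amp_v6_mv"]
        parameters = pd.DataFrame(
            {name: [getattr(p, r) for r in rows]
             for name, p in params.items()}, index=rows)
    else:
        parameters = pd.DataFrame()

    if confusions:
        rows = {}
        for method, counts in confusions.items():
            sens_col, spec_col = [], []
            findings = list(counts.keys())
            for f in findings:
                c = counts[f]
                s, p = sens_spec(c.tp, c.fp, c.tn, c.fn)
                sens_col.append(s)
                spec_col.append(p)
            rows[(method, "sensitivity")] = pd.Series(sens_col, index=findings)
            rows[(method, "specificity")] = pd.Series(spec_col, index=findings)
        diagnostics = pd.DataFrame(rows)
    else:
        diagnostics = pd.DataFrame()

    return EvalReport(waveform=waveform, parameters=parameters,
                      diagnostics=diagnostics, notes=notes)
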