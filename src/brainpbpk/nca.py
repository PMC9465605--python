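"""Non-compartmental analysis: AUC(0-tlast), Cmax, Tmax and exposure ratios.

Each animal is one subject; group summaries are mean and sample SD, and
the cross-matrix AUC ratios (CSF/serum, ISF/serum, ISF/CSF, in percent)
are formed from group-mean AUCs.  Pre-dose and below-LLOQ samples are
excluded, and dialysate concentrations are corrected to ISF scale with
the in-vitro probe recovery before any exposure metric is computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .microdialysis import apply_recovery

__all__ = ["auc_trapezoid", "cmax_tmax", "nca_per_subject", "nca_summarize"]


def _validate_series(t, c):
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("t and c must be 1-D arrays of equal length")
    if t.size < 1:
        raise ValueError("empty concentration series")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing without duplicates")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("concentrations must be finite and non-negative")
    return t, c


def auc_trapezoid(t, c) -> float:
    """Linear-trapezoid AUC (nM*h) over the sampled span."""
    t, c = _validate_series(t, c)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(c, t))


def cmax_tmax(t, c) -> tuple[float, float]:
    """Maximum observed concentration and its time (earliest on ties)."""
    t, c = _validate_series(t, c)
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def nca_per_subject(data: pd.DataFrame, recovery: float = 1.0) -> pd.DataFrame:
    """Per-subject, per-matrix NCA table.

    ``data`` uses the observation schema (subject, group, route,
    dose_mgkg, matrix, time_h, conc_nM, bloq).  ``recovery`` corrects
    ``isf_dialysate`` rows to ISF concentrations.
    """
    keep = (data["time_h"] > 0) & ~data["bloq"].astype(bool)
    d = data.loc[keep].copy()
    isf = d["matrix"] == "isf_dialysate"
    d.loc[isf, "conc_nM"] = apply_recovery(d.loc[isf, "conc_nM"].to_numpy(), recovery)
    rows = []
    for (subj, grp, route, mgkg, mat), sub in d.groupby(
        ["subject", "group", "route", "dose_mgkg", "matrix"], sort=False
    ):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(float)
        c = sub["conc_nM"].to_numpy(float)
        cmax, tmax = cmax_tmax(t, c)
        rows.append(
            {
                "subject": subj,
                "group": grp,
                "route": route,
                "dose_mgkg": mgkg,
                "matrix": mat,
                "n_samples": len(sub),
                "auc_0_tlast": auc_trapezoid(t, c) if len(sub) >= 2 else np.nan,
                "cmax": cmax,
                "tmax": tmax,
            }
        )
    return pd.DataFrame(rows)


def nca_summarize(data: pd.DataFrame, recovery: float = 1.0) -> dict[str, pd.DataFrame]:
    """Group-level NCA summary and cross-matrix AUC ratios.

    Returns ``{"subjects": ..., "summary": ..., "ratios": ...}``.  SD is
    the sample standard deviation and is absent (NaN) for n = 1.  Ratios
    are percentages of group-mean AUCs; ISF here means the
    recovery-corrected dialysate matrix.
    """
    per = nca_per_subject(data, recovery=recovery)
    if per.empty:
        raise ValueError("no quantifiable post-dose observations")
    summary = (
        per.groupby(["group", "route", "dose_mgkg", "matrix"])
        .agg(
            n=("subject", "nunique"),
            auc_mean=("auc_0_tlast", "mean"),
            auc_sd=("auc_0_tlast", lambda s: s.std(ddof=1)),
            cmax_mean=("cmax", "mean"),
            cmax_sd=("cmax", lambda s: s.std(ddof=1)),
            tmax_min=("tmax", "min"),
            tmax_max=("tmax", "max"),
        )
        .reset_index()
    )
    ratio_rows = []
    for (grp, route, mgkg), sub in summary.groupby(["group", "route", "dose_mgkg"]):
        mean_auc = dict(zip(sub["matrix"], sub["auc_mean"]))

        def pct(a, b):
            if a in mean_auc and b in mean_auc and mean_auc[b] > 0:
                return 100.0 * mean_auc[a] / mean_auc[b]
            return np.nan

        ratio_rows.append(
            {
                "group": grp,
                "route": route,
                "dose_mgkg": mgkg,
                "csf_serum_pct": pct("csf", "serum"),
                "isf_serum_pct": pct("isf_dialysate", "serum"),
                "isf_csf_pct": pct("isf_dialysate", "csf"),
            }
        )
    return {
        "subjects": per,
        "summary": summary,
        "ratios": pd.DataFrame(ratio_rows),
    }
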