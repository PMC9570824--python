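"""AHI estimation, OSA severity grading, and agreement statistics.

The apnea-hypopnea index (AHI) is the number of apnea-hypopnea events per
hour of total sleep time; severity bins are normal (AHI < 5), mild
(5 <= AHI < 15), moderate (15 <= AHI < 30) and severe (AHI >= 30).  Both
the estimated and the reference AHI divide by the hypnogram's total sleep
time, so detector and scorer are compared on the same denominator.

Agreement between estimated and reference AHI over a cohort is summarized
with the Pearson correlation, the two-way random-effects absolute-agreement
single-measurement ICC(2,1), Bland-Altman bias (t-based CI) with 95% limits
of agreement, and — on the four ordinal severity classes — the linearly
weighted kappa with its confusion matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .io_formats import AgreementReport

SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")
_SEVERITY_EDGES = (5.0, 15.0, 30.0)


class AhiError(ValueError):
    pass


def compute_ahi(event_count: int, total_sleep_time_s: float) -> float:
    """Events per hour of sleep."""
    if total_sleep_time_s <= 0:
        raise AhiError("total sleep time must be positive")
    return event_count / (total_sleep_time_s / 3600.0)


def severity(ahi: float) -> str:
    """Severity class from AHI with half-open bins (left-closed above 5)."""
    if ahi < 0:
        raise AhiError(f"negative AHI {ahi}")
    for edge, label in zip(_SEVERITY_EDGES, SEVERITY_CLASSES[:3]):
        if ahi < edge:
            return label
    return "severe"


def icc_2_1(true: np.ndarray, est: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed with pingouin on the long-format rating table.
    """
    import pingouin as pg

    n = len(true)
    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["true", "est"], n),
            "ratings": np.concatenate([true, est]),
        }
    )
    res = pg.intraclass_corr(
        data=df, targets="targets", raters="raters", ratings="ratings"
    )
    # two-way random, absolute agreement, single measurement: labeled
    # "ICC2" (Shrout-Fleiss) or "ICC(A,1)" (McGraw-Wong) depending on version
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[sel, "ICC"].iloc[0])


def bland_altman(
    true: np.ndarray, est: np.ndarray, alpha: float = 0.05
) -> dict:
    """Bias (est - true) with a t-based CI and 1.96-SD limits of agreement."""
    diff = np.asarray(est, dtype=float) - np.asarray(true, dtype=float)
    n = diff.size
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    t = stats.t.ppf(1 - alpha / 2, n - 1)
    half = t * sd / np.sqrt(n)
    return {
        "bias": bias,
        "bias_ci": [bias - half, bias + half],
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


def weighted_kappa_linear(true_classes: list[str], est_classes: list[str]) -> float:
    """Linearly weighted kappa over the four ordinal severity classes."""
    order = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    y1 = [order[c] for c in true_classes]
    y2 = [order[c] for c in est_classes]
    return float(
        cohen_kappa_score(y1, y2, weights="linear", labels=list(range(4)))
    )


def severity_confusion(
    true_classes: list[str], est_classes: list[str]
) -> np.ndarray:
    """4x4 confusion matrix, rows = reference severity, cols = estimated."""
    order = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    mat = np.zeros((4, 4), dtype=int)
    for t, e in zip(true_classes, est_classes):
        mat[order[t], order[e]] += 1
    return mat


def agreement(
    ahi_true: np.ndarray,
    ahi_est: np.ndarray,
    ahi_est_corrected: np.ndarray | None = None,
    participants: list[str] | None = None,
) -> AgreementReport:
    """Cohort agreement report between reference and estimated AHI.

    The headline statistics (r, ICC, Bland-Altman, kappa, confusion) are
    computed on the uncorrected estimate; the corrected (in-sleep) AHI is
    carried per participant for side-by-side reporting.
    """
    true = np.asarray(ahi_true, dtype=float)
    est = np.asarray(ahi_est, dtype=float)
    if true.shape != est.shape:
        raise AhiError("ahi_true and ahi_est must have equal length")
    n = true.size
    if n < 3:
        raise AhiError(f"need at least 3 participants, got {n}")
    if true.std() == 0 or est.std() == 0:
        raise AhiError("zero variance: Pearson correlation undefined")
    corrected = (
        np.asarray(ahi_est_corrected, dtype=float)
        if ahi_est_corrected is not None
        else est.copy()
    )
    ids = participants if participants is not None else [f"p{i}" for i in range(n)]
    sev_true = [severity(a) for a in true]
    sev_est = [severity(a) for a in est]
    sev_corr = [severity(a) for a in corrected]
    r = float(stats.pearsonr(true, est)[0])
    return AgreementReport(
        participants=list(ids),
        ahi_true=true.tolist(),
        ahi_est=est.tolist(),
        ahi_est_corrected=corrected.tolist(),
        severity_true=sev_true,
        severity_est=sev_est,
        severity_est_corrected=sev_corr,
        pearson_r=r,
        icc=icc_2_1(true, est),
        bland_altman=bland_altman(true, est),
        kappa_linear=weighted_kappa_linear(sev_true, sev_est),
        confusion=severity_confusion(sev_true, sev_est).tolist(),
    )


def agreement_figures(report: AgreementReport, out_dir) -> list:
    """Scatter + Bland-Altman + row-normalized severity confusion figures."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    true = np.asarray(report.ahi_true)
    est = np.asarray(report.ahi_est)
    paths = []

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(true, est, s=25)
    lim = max(true.max(), est.max()) * 1.05 + 1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("reference AHI (events/h)")
    ax.set_ylabel("estimated AHI (events/h)")
    ax.set_title(f"r = {report.pearson_r:.3f}, ICC = {report.icc:.3f}")
    paths.append(out_dir / "ahi_scatter.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    mean = (true + est) / 2
    diff = est - true
    ba = report.bland_altman
    ax.scatter(mean, diff, s=25)
    for y, style in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, color="gray", ls=style, lw=0.9)
    ax.set_xlabel("mean of estimates (events/h)")
    ax.set_ylabel("estimated - reference (events/h)")
    paths.append(out_dir / "bland_altman.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    conf = np.asarray(report.confusion, dtype=float)
    row_pct = np.divide(
        conf, conf.sum(axis=1, keepdims=True),
        out=np.zeros_like(conf), where=conf.sum(axis=1, keepdims=True) > 0,
    )
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(row_pct, cmap="Blues", vmin=0, vmax=1)
    for i in range(4):
        for j in range(4):
            ax.text(
                j, i, f"{int(conf[i, j])}\n({row_pct[i, j]:.0%})",
                ha="center", va="center", fontsize=8,
            )
    ax.set_xticks(range(4), SEVERITY_CLASSES)
    ax.set_yticks(range(4), SEVERITY_CLASSES)
    ax.set_xlabel("estimated severity")
    ax.set_ylabel("reference severity")
    paths.append(out_dir / "severity_confusion.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths
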