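"""Volume-vs-date plots with detected growth onsets marked."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .monitoring import DetectionRecord, VolumeSeries

__all__ = ["plot_patient"]


def plot_patient(
    series: VolumeSeries,
    record: DetectionRecord | None = None,
    path: str | Path | None = None,
):
    """Plot one patient's volume trajectory in mL.

    Marks the post-operative baseline and, when growth was detected, the
    change-point onset (red star) and the scan at which the online detector
    fired.  Returns the matplotlib figure; saves to ``path`` if given.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    vols_ml = series.volumes / 1000.0
    ax.plot(series.dates, vols_ml, "o-", color="steelblue", label=f"{series.source} volume")
    if record is not None:
        b = record.baseline.index - 1
        ax.plot(series.dates[b], vols_ml[b], "s", color="black", ms=9, fillstyle="none",
                label="post-op baseline")
        if record.growth_detected:
            o, t = record.onset_index - 1, record.trigger_index - 1
            ax.plot(series.dates[o], vols_ml[o], "*", color="red", ms=16, label="detected onset")
            ax.axvline(series.dates[t], color="gray", ls="--", lw=1, label="online trigger scan")
    ax.set_xlabel("scan date")
    ax.set_ylabel("tumor volume (mL)")
    ax.set_title(f"patient {series.patient_id}")
    ax.legend(loc="best", fontsize=8)
    fig.autofmt_xdate()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
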