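"""Summary figures for a simulated (or re-supplied) study dataset."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .protocol import StudyDataset, session_summary


def render_figures(dataset: StudyDataset, out_dir) -> list[Path]:
    """Write the three study-summary panels as PNGs; returns the paths.

    Panels: phase-by-phase mean time-compression thresholds ±1 SE per
    talker; pre/post thresholds only; pre/post AzBio-in-noise scores.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summ = session_summary(dataset)
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for talker, marker in (("trained", "o"), ("novel", "s")):
        sub = summ[summ["talker"] == talker]
        ax.errorbar(sub["phase"].astype(str), sub["mean"], yerr=sub["se"],
                    marker=marker, capsize=3, label=f"{talker} talker",
                    mfc="white" if talker == "trained" else None)
    ax.set_xlabel("phase")
    ax.set_ylabel("time-compression threshold (%)")
    ax.legend()
    fig.tight_layout()
    paths.append(out / "fig_sessions.png")
    fig.savefig(paths[-1], dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    pp = summ[summ["phase"].isin(["pre", "post"])]
    for talker, marker in (("trained", "o"), ("novel", "s")):
        sub = pp[pp["talker"] == talker]
        ax.errorbar(sub["phase"].astype(str), sub["mean"], yerr=sub["se"],
                    marker=marker, capsize=3, label=f"{talker} talker")
    ax.set_ylabel("time-compression threshold (%)")
    ax.legend()
    fig.tight_layout()
    paths.append(out / "fig_prepost_thresholds.png")
    fig.savefig(paths[-1], dpi=150)
    plt.close(fig)

    az = dataset.azbio_scores.groupby("phase")["score"].agg(["mean", "std", "count"])
    az = az.reindex(["pre", "post"])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(az.index, az["mean"], yerr=(az["std"] / az["count"] ** 0.5).fillna(0.0),
           capsize=4, color=["#7f7f7f", "#2c7fb8"])
    ax.set_ylabel("AzBio in noise (% correct)")
    fig.tight_layout()
    paths.append(out / "fig_azbio.png")
    fig.savefig(paths[-1], dpi=150)
    plt.close(fig)

    return paths
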