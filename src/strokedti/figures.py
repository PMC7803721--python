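"""Headless-safe summary figures for a completed pipeline run."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def save_summary_figures(out_dir: str | Path) -> list[Path]:
    """Plot lesion volume curves and the incidence heat map from the
    stage tables under ``out_dir/tables``; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written = []

    profiles = pd.read_csv(out_dir / "tables" / "lesion_profiles.csv")
    t2 = profiles[profiles["modality"] == "T2WI"]
    vols = t2.groupby(["group", "day", "subject_id"])["total_volume_mm3"].first()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, color in (("small", "tab:blue"), ("large", "tab:red")):
        m = vols.loc[group].groupby("day").mean()
        s = vols.loc[group].groupby("day").sem()
        ax.errorbar(m.index, m, yerr=s, color=color, marker="o", label=group)
    ax.set_xlabel("day post stroke")
    ax.set_ylabel("lesion volume (mm$^3$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = fig_dir / "lesion_volumes.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    inc = pd.read_csv(out_dir / "tables" / "incidence.csv")
    piv = inc.pivot_table(index="region", columns=["group", "day"],
                          values="fraction")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_yticks(range(len(piv.index)), piv.index)
    ax.set_xticks(range(piv.shape[1]),
                  [f"{g} d{d}" for g, d in piv.columns], rotation=45)
    fig.colorbar(im, label="fraction of subjects affected")
    fig.tight_layout()
    path = fig_dir / "incidence_heatmap.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written
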