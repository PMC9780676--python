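"""Optional figures: influence posteriors, participant sub-traits, loadings."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def render_report(summary_path, posterior_path=None, out_dir=".") -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = json.loads(Path(summary_path).read_text())
    written: list[Path] = []

    if posterior_path:
        draws = pd.read_csv(posterior_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        names = ["rho_fm", "rho_sis", "rho_m1lat"]
        ax.violinplot([draws[n] for n in names], showmedians=True)
        ax.set_xticks(range(1, len(names) + 1), ["FM-12", "SIS-Hand", "M1-LAT"])
        ax.set_ylabel("correlation with latent UE-IF")
        ax.axhline(0.0, color="0.6", lw=0.8)
        fig.tight_layout()
        p = out / "influence_posteriors.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    parts = summary["participants"]
    fig, ax = plt.subplots(figsize=(5, 4))
    fm = parts["fm_trait"]
    m1 = parts["m1_trait"]
    for pid in fm:
        ax.errorbar(
            fm[pid]["p50"], m1[pid]["p50"],
            xerr=[[fm[pid]["p50"] - fm[pid]["p25"]], [fm[pid]["p75"] - fm[pid]["p50"]]],
            yerr=[[m1[pid]["p50"] - m1[pid]["p25"]], [m1[pid]["p75"] - m1[pid]["p50"]]],
            fmt="o", ms=3, color="tab:blue", ecolor="0.7",
        )
    ax.set_xlabel("latent FM-12 sub-trait (median, IQR)")
    ax.set_ylabel("latent M1-LAT sub-trait (median, IQR)")
    fig.tight_layout()
    p = out / "participant_subtraits.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    med = summary["location_loadings"]["median_medial_to_lateral"]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(range(1, 9), med, color="tab:red")
    ax.set_xlabel("homotopic pair (1 = medial, 8 = lateral)")
    ax.set_ylabel("median loading on latent M1-LAT")
    fig.tight_layout()
    p = out / "loading_topology.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
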