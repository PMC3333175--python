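"""PNG exports mirroring the standard figure layouts.

Thin matplotlib helpers over the report tables: grouped bars of AS
proportion and mean isoform count per size stratum, precomputed-quartile
boxplots for protein length and Ka/Ks per group, and log-frequency domain
spectra.  Everything here is presentation only; no statistics are computed.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = [
    "bar_by_stratum",
    "boxplot_from_quartiles",
    "domain_spectrum",
    "export_all",
]


def bar_by_stratum(strata: pd.DataFrame, value: str, path: str | Path) -> None:
    """Grouped bars of a per-(criterion, stratum) column, one group per stratum."""
    pivot = strata.pivot(index="stratum", columns="criterion", values=value)
    ax = pivot.plot.bar(figsize=(8, 4), width=0.8)
    ax.set_ylabel(value.replace("_", " "))
    ax.set_xlabel("family-size stratum")
    ax.legend(title="identity criterion >", fontsize=8)
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()


def boxplot_from_quartiles(df: pd.DataFrame, prefix: str, path: str | Path) -> None:
    """Boxplots from precomputed five-number summaries (one box per row)."""
    stats = []
    for _, row in df.iterrows():
        if pd.isna(row[f"{prefix}_median"]):
            continue
        stats.append(
            {
                "label": f"{row['group']} (>{row['criterion']:g})",
                "whislo": row[f"{prefix}_min"],
                "q1": row[f"{prefix}_q1"],
                "med": row[f"{prefix}_median"],
                "q3": row[f"{prefix}_q3"],
                "whishi": row[f"{prefix}_max"],
                "fliers": [],
            }
        )
    if not stats:
        return
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(stats)), 4))
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel(prefix.replace("_", " "))
    ax.tick_params(axis="x", rotation=75, labelsize=7)
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()


def domain_spectrum(domains: pd.DataFrame, criterion: float, path: str | Path) -> None:
    """Log10-frequency of domain counts per group at one criterion."""
    sub = domains[domains["criterion"] == criterion]
    if not len(sub):
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    for group, gdf in sub.groupby("group"):
        ax.plot(gdf["domain_count"], gdf["log10_frequency"], marker="|",
                linestyle="none", label=group)
    ax.set_xlabel("number of domains")
    ax.set_ylabel("log10 frequency")
    ax.legend()
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()


def export_all(report, outdir: str | Path) -> None:
    """Write every figure the report's tables support."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report.tables
    bar_by_stratum(tables["proportions"], "as_proportion", outdir / "as_proportion.png")
    bar_by_stratum(
        tables["proportions"], "mean_isoform_count", outdir / "isoform_count.png"
    )
    boxplot_from_quartiles(tables["lengths"], "length", outdir / "protein_length.png")
    if "kaks" in tables:
        boxplot_from_quartiles(tables["kaks"], "kaks", outdir / "ka_ks.png")
    if "domains" in tables:
        crit = min(tables["domains"]["criterion"].unique(), default=None)
        if crit is not None:
            domain_spectrum(tables["domains"], crit, outdir / "domain_spectrum.png")
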