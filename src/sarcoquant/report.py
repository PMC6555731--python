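"""Markdown summary report over a pipeline run's output directory.

Collects whatever stage outputs are present — shift panels and ECDFs,
period/series tables, band quantification tables — renders one plot per
section with matplotlib, and writes ``report.md`` plus PNG figures.
Regeneration over the same outputs is idempotent.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ValidationError  # noqa: E402


def _shift_section(outdir: Path, lines: list[str]) -> None:
    panel_path = outdir / "shift" / "shift_panel.tsv"
    if not panel_path.exists():
        return
    panel = pd.read_csv(panel_path, sep="\t")
    lines.append("## Gene-set LFC shifts\n")
    lines.append("```\n" + panel.to_string(index=False) + "\n```")
    lines.append("")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ok = panel[panel["status"] == "ok"]
    labels = ok["comparison"] + "\n" + ok["set"]
    ax.bar(range(len(ok)), ok["statistic"], color="#4878a8")
    ax.set_xticks(range(len(ok)), labels, fontsize=6, rotation=30, ha="right")
    ax.set_ylabel("median-shift statistic (log2)")
    fig.tight_layout()
    fig.savefig(outdir / "shift_panel.png", dpi=120)
    plt.close(fig)
    lines.append("![shift panel](shift_panel.png)\n")

    ecdfs = sorted((outdir / "shift").glob("*.ecdf.csv"))
    if ecdfs:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for p in ecdfs:
            df = pd.read_csv(p)
            ax.step(df["lfc"], df["fraction"], where="post",
                    label=p.name.removesuffix(".ecdf.csv"), lw=1)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("cumulative fraction")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(outdir / "ecdf.png", dpi=120)
        plt.close(fig)
        lines.append("![ECDFs](ecdf.png)\n")


def _morpho_section(outdir: Path, lines: list[str]) -> None:
    periods_path = outdir / "morpho" / "periods.csv"
    if not periods_path.exists():
        return
    df = pd.read_csv(periods_path)
    lines.append("## Sarcomere morphometry\n")
    lines.append("```\n" + df.to_string(index=False) + "\n```")
    lines.append("")
    vals = df["period_um"].dropna()
    if len(vals):
        fig, ax = plt.subplots(figsize=(4.5, 3))
        ax.hist(vals, bins=15, color="#6aa06a")
        ax.set_xlabel("estimated sarcomere period (um)")
        ax.set_ylabel("profiles")
        fig.tight_layout()
        fig.savefig(outdir / "periods.png", dpi=120)
        plt.close(fig)
        lines.append("![period histogram](periods.png)\n")


def _densitometry_section(outdir: Path, lines: list[str]) -> None:
    quants_path = outdir / "densitometry" / "band_quants.csv"
    if not quants_path.exists():
        return
    df = pd.read_csv(quants_path)
    lines.append("## Gel densitometry\n")
    lines.append("```\n" + df.to_string(index=False) + "\n```")
    lines.append("")


def make_report(outdir: str | Path) -> Path:
    """Render ``report.md`` summarising every stage output found in outdir."""
    outdir = Path(outdir)
    lines: list[str] = ["# sarcoquant run report\n"]
    n_before = len(lines)
    _shift_section(outdir, lines)
    _morpho_section(outdir, lines)
    _densitometry_section(outdir, lines)
    if len(lines) == n_before:
        raise ValidationError(f"no stage outputs found under {outdir}")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
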