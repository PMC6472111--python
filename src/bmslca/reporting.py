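"""Rendering of result bundles: CSV tables, text tables and figure files.

Reported values are rounded to two significant figures (matching the
source tables' style) in the human-readable output; CSV files keep full
precision so that round-tripping recovers the computed numbers exactly.
Figures are drawn from the emitted data files, never from in-memory
state, so every plot is reproducible from the CSVs alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import round_sig

__all__ = ["render_tables", "figure_series", "write_manifest"]

TABLE_KEYS = ("production", "consumption", "breastfeeding", "comparison")


def _fmt(value, sd=None) -> str:
    if pd.isna(value):
        return ""
    text = f"{round_sig(float(value)):g}"
    if sd is not None and not pd.isna(sd) and sd > 0:
        text += f" ± {round_sig(float(sd)):g}"
    return text


def _text_table(df: pd.DataFrame) -> str:
    out = pd.DataFrame()
    sd_cols = {c for c in df.columns if c.endswith("_sd")}
    for col in df.columns:
        if col in sd_cols:
            continue
        sd_col = f"{col}_sd"
        if pd.api.types.is_numeric_dtype(df[col]):
            if sd_col in df.columns:
                out[col] = [_fmt(v, s) for v, s in zip(df[col], df[sd_col])]
            else:
                out[col] = [_fmt(v) for v in df[col]]
        else:
            out[col] = df[col]
    return out.to_string(index=False)


def render_tables(bundle: dict, out_dir: str | Path, style: str = "both") -> list[Path]:
    """Write the bundle's tables as CSV and/or fixed-width text files."""
    missing = [k for k in TABLE_KEYS if k not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {', '.join(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key in TABLE_KEYS:
        df: pd.DataFrame = bundle[key]
        if style in ("csv", "both"):
            path = out_dir / f"{key}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        if style in ("text", "both"):
            path = out_dir / f"{key}.txt"
            path.write_text((_text_table(df) if not df.empty else "(empty)") + "\n")
            written.append(path)
    return written


def figure_series(bundle: dict, out_dir: str | Path, plot: bool = True) -> list[Path]:
    """Emit the comparison figure series as CSV data files and plots.

    The difference chart shows CFP_Cons - CFP_BF per country and variant
    with 95% intervals; the waste-sweep chart shows the CFP_BF/CFP_Cons
    ratio against the consumer-stage BMS waste fraction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key in ("fig4", "fig5"):
        if key not in bundle or bundle[key].empty:
            continue
        path = out_dir / f"{key}.csv"
        bundle[key].to_csv(path, index=False)
        written.append(path)
    if not plot:
        return written

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig4_path = out_dir / "fig4.csv"
    if fig4_path.exists():
        df = pd.read_csv(fig4_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        variants = list(dict.fromkeys(df["variant"]))
        countries = list(dict.fromkeys(df["country"]))
        markers = dict(zip(variants, "oDsd"))
        for j, variant in enumerate(variants):
            sub = df[df["variant"] == variant]
            x = [countries.index(c) + (j - 1.5) * 0.15 for c in sub["country"]]
            ax.errorbar(
                x, sub["difference"],
                yerr=[sub["difference"] - sub["ci95_low"],
                      sub["ci95_high"] - sub["difference"]],
                fmt=markers.get(variant, "o"), label=variant, capsize=3, linestyle="",
            )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xticks(range(len(countries)))
        ax.set_xticklabels(countries, rotation=20)
        ax.set_ylabel("CFP$_{Cons}$ $-$ CFP$_{BF}$ (kg CO$_2$e per kg BMS)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        png = out_dir / "fig4.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)

    fig5_path = out_dir / "fig5.csv"
    if fig5_path.exists():
        df = pd.read_csv(fig5_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        for (country, basis), sub in df.groupby(["country", "basis"]):
            ax.plot(
                sub["bms_waste_fraction"], sub["ratio"],
                linestyle="-" if basis == "dry_mass" else "--",
                label=f"{country} ({basis})",
            )
        ax.axhline(1.0, color="k", lw=0.8)
        ax.set_xlabel("BMS waste fraction at the consumer stage")
        ax.set_ylabel("CFP$_{BF}$ / CFP$_{Cons}$")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        png = out_dir / "fig5.png"
        fig.savefig(png, dpi=150)
        plt.close(fig)
        written.append(png)
    return written


def write_manifest(bundle: dict, out_dir: str | Path) -> Path:
    """Record the run manifest plus a configuration hash for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = bundle["manifest"]
    doc = manifest.to_dict()
    doc["config_hash"] = manifest.config_hash(bundle["scenarios"])
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
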