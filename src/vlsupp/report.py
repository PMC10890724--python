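"""Descriptive and estimate reports (tables always, figures when asked).

``report_descriptives`` produces a baseline-characteristics table in the
classic cohort layout: per-regimen counts (percentages) for sex, age and CD4
groups, medians with IQRs, per-week counts of persons contributing a VL
observation, and end-of-follow-up status. ``report_estimates`` persists the
estimate tables and draws simple point-and-interval figures by week and
regimen (crude proportions, adjusted odds ratios, predicted proportions).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REGIMEN_ORDER = ("EFV", "ATVr", "DTG")


def _fmt_count(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f}%)" if n else "0"


def _median_iqr(x: pd.Series) -> str:
    if len(x) == 0:
        return "-"
    med = x.median()
    q1, q3 = x.quantile([0.25, 0.75])
    return f"{med:g} ({q1:g}-{q3:g})"


def report_descriptives(cohort: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by regimen plus per-week VL availability."""
    from vlsupp.prep import WEEKS, bin_age, bin_cd4

    cohort = cohort.copy()
    cohort["age_group"] = bin_age(cohort["age_years"].to_numpy())
    cohort["cd4_group"] = bin_cd4(cohort["cd4_cells"].to_numpy())
    groups = {reg: cohort.loc[cohort["regimen"] == reg] for reg in REGIMEN_ORDER}
    groups["Overall"] = cohort

    rows: dict[str, dict[str, str]] = {}

    def add(label, fn):
        rows[label] = {name: fn(df) for name, df in groups.items()}

    add("Total", lambda d: str(len(d)))
    for sex in ("female", "male"):
        add(f"Sex: {sex}", lambda d, s=sex: _fmt_count(int((d["sex"] == s).sum()), len(d)))
    add("Age, median (IQR)", lambda d: _median_iqr(d["age_years"]))
    for ag in ("12-19", "20-29", "30-39", "40+"):
        add(f"Age {ag}", lambda d, a=ag: _fmt_count(int((d["age_group"] == a).sum()), len(d)))
    add("CD4, median (IQR)", lambda d: _median_iqr(d["cd4_cells"]))
    for cg in ("<200", "200-349", ">=350"):
        add(f"CD4 {cg}", lambda d, c=cg: _fmt_count(int((d["cd4_group"] == c).sum()), len(d)))
    for w in WEEKS:
        with_vl = set(table.loc[table["week"] == w, "person_id"])
        add(
            f"With VL at week {w}",
            lambda d, s=with_vl: _fmt_count(
                int(d["person_id"].isin(s).sum()), len(d)
            ),
        )
    for status in ("in_care", "ltfu", "dead"):
        add(
            f"Status: {status}",
            lambda d, s=status: _fmt_count(int((d["end_status"] == s).sum()), len(d)),
        )
    out = pd.DataFrame(rows).T
    out.index.name = "characteristic"
    return out[list(groups)]


def _interval_plot(ax, df: pd.DataFrame, value_col: str, title: str, log_scale=False):
    colors = {"EFV": "#1b9e77", "ATVr": "#d95f02", "DTG": "#7570b3"}
    for i, reg in enumerate(REGIMEN_ORDER):
        sub = df.loc[df["regimen"] == reg]
        if len(sub) == 0:
            continue
        x = sub["week"].astype(float) + (i - 1) * 1.5
        ax.errorbar(
            x,
            sub[value_col],
            yerr=[sub[value_col] - sub["lower"], sub["upper"] - sub[value_col]],
            fmt="o",
            capsize=3,
            label=reg,
            color=colors.get(reg),
        )
    if log_scale:
        ax.set_yscale("log")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("week since start/switch")
    ax.set_title(title)
    ax.legend()


def report_estimates(
    estimates: pd.DataFrame, outdir, figures: bool = True
) -> dict[str, Path]:
    """Write per-kind estimate tables (and figures) from an estimates frame.

    The tables are a pure function of the input frame, so re-rendering from
    a persisted estimates.csv reproduces them byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    est = estimates.copy()
    aor = est.loc[est["kind"] == "aOR"]
    props = est.loc[est["kind"] == "proportion"]
    std = props.loc[props["standardized"].astype(str) == "True"]
    nonstd = props.loc[props["standardized"].astype(str) == "False"]
    crude = props.loc[~props.index.isin(std.index) & ~props.index.isin(nonstd.index)]

    for name, df in [
        ("aor_table", aor),
        ("standardized_proportions", std),
        ("nonstandardized_proportions", nonstd),
        ("crude_proportions", crude),
    ]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        outputs[name] = path

    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if len(crude):
            fig, ax = plt.subplots(figsize=(6, 4))
            _interval_plot(ax, crude, "point", "Crude suppression by regimen")
            ax.set_ylabel("proportion suppressed")
            fig.tight_layout()
            fig.savefig(outdir / "crude_proportions.png", dpi=120)
            plt.close(fig)
            outputs["crude_figure"] = outdir / "crude_proportions.png"
        regimen_aor = aor.loc[aor["week"].astype(str) != ""]
        if len(regimen_aor):
            fig, ax = plt.subplots(figsize=(6, 4))
            df = regimen_aor.copy()
            df["regimen"] = df["contrast"].str.extract(r"regimen: (\w+)")[0]
            _interval_plot(ax, df, "point", "Regimen aORs by week", log_scale=True)
            ax.set_ylabel("adjusted odds ratio")
            fig.tight_layout()
            fig.savefig(outdir / "aor_by_week.png", dpi=120)
            plt.close(fig)
            outputs["aor_figure"] = outdir / "aor_by_week.png"
        if len(std) or len(nonstd):
            fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
            _interval_plot(axes[0], nonstd, "point", "Non-standardized")
            _interval_plot(axes[1], std, "point", "Standardized")
            axes[0].set_ylabel("predicted proportion suppressed")
            fig.tight_layout()
            fig.savefig(outdir / "predicted_proportions.png", dpi=120)
            plt.close(fig)
            outputs["predictions_figure"] = outdir / "predicted_proportions.png"
    return outputs
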