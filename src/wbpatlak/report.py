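"""Human-readable summary of a completed study run directory.

Produces a markdown report with three tables — per-organ metric summaries
(mean ± sd across subjects for both protocol arms), and the agreement
battery for normal organs and lesions — plus Passing–Bablok scatter and
Bland–Altman difference plots per metric.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .study import METRICS

__all__ = ["report"]

REQUIRED = ("paired_values.csv", "agreement.csv", "config.yaml", "manifest.json")


def _organ_table(paired: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of each metric per organ, standard and two-short arms."""
    organs = paired[paired.region_type == "organ"]
    rows = []
    for metric in METRICS:
        for arm in ("std", "tsd"):
            row = {"metric": metric, "arm": arm}
            for organ, sub in organs[organs.metric == metric].groupby("region"):
                row[organ] = f"{sub[arm].mean():.3g} ± {sub[arm].std(ddof=1):.2g}"
            rows.append(row)
    return pd.DataFrame(rows)


def _figures(paired: pd.DataFrame, out: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    for metric in METRICS:
        sub = paired[paired.metric == metric].dropna(subset=["std", "tsd"])
        if len(sub) < 3:
            continue
        x = sub["std"].to_numpy()
        y = sub["tsd"].to_numpy()
        d = y - x
        bias, sd = d.mean(), d.std(ddof=1)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(x, y, s=12, alpha=0.6)
        lim = [0, max(x.max(), y.max()) * 1.05]
        ax1.plot(lim, lim, "k--", lw=1, label="identity")
        ax1.set_xlabel(f"{metric} (standard)")
        ax1.set_ylabel(f"{metric} (two-short)")
        ax1.legend(frameon=False)
        ax2.scatter((x + y) / 2, d, s=12, alpha=0.6)
        for val, style in ((bias, "-"), (bias - 1.96 * sd, ":"),
                           (bias + 1.96 * sd, ":")):
            ax2.axhline(val, color="k", ls=style, lw=1)
        ax2.set_xlabel(f"{metric} mean of methods")
        ax2.set_ylabel("two-short − standard")
        fig.suptitle(metric)
        fig.tight_layout()
        name = f"agreement_{metric.replace('-', '_')}.png"
        fig.savefig(out / name, dpi=110)
        plt.close(fig)
        made.append(name)
    return made


def report(run_dir) -> Path:
    """Write ``report.md`` (+ figures) into a completed run directory."""
    run = Path(run_dir)
    missing = [name for name in REQUIRED if not (run / name).exists()]
    if missing:
        raise FileNotFoundError(
            f"run directory {run} is missing artifacts: {', '.join(missing)}")

    paired = pd.read_csv(run / "paired_values.csv")
    agreement = pd.read_csv(run / "agreement.csv")

    lines = ["# Two-short vs standard Patlak parametric imaging — study report", ""]
    n_sub = paired.subject.nunique()
    lines += [f"Subjects: {n_sub}; paired region-metric samples: "
              f"{len(paired) // len(METRICS)}", ""]

    lines += ["## Normal-organ values (mean ± sd across subjects)", ""]
    lines += [_organ_table(paired).to_markdown(index=False), ""]

    for group, title in (("organs", "Normal organs"), ("lesions", "Lesions")):
        sub = agreement[agreement.group == group].copy()
        if sub.empty:
            continue
        lines += [f"## Agreement battery — {title}", ""]
        disp = pd.DataFrame({
            "Metric": sub.metric,
            "Intercept A (CI)": [f"{a:.3f} ({lo:.3f}–{hi:.3f})" for a, lo, hi in
                                 zip(sub.intercept_A, sub.intercept_A_ci_lo,
                                     sub.intercept_A_ci_hi)],
            "Slope B (CI)": [f"{b:.3f} ({lo:.3f}–{hi:.3f})" for b, lo, hi in
                             zip(sub.slope_B, sub.slope_B_ci_lo, sub.slope_B_ci_hi)],
            "Cusum p": [f"{p:.2f}" for p in sub.cusum_p],
            "BA bias (LoA)": [f"{b:.3g} ({lo:.3g}–{hi:.3g})" for b, lo, hi in
                              zip(sub.ba_bias, sub.ba_loa_lo, sub.ba_loa_hi)],
            "Spearman rho (CI); p": [
                f"{r:.3f} ({lo:.3f}–{hi:.3f}); p={p:.2g}" for r, lo, hi, p in
                zip(sub.spearman_rho, sub.spearman_ci_lo, sub.spearman_ci_hi,
                    sub.spearman_p)],
        })
        lines += [disp.to_markdown(index=False), ""]

    figures = _figures(paired, run)
    if figures:
        lines += ["## Figures", ""]
        lines += [f"![{name}]({name})" for name in figures] + [""]

    out = run / "report.md"
    out.write_text("\n".join(lines))
    return out
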