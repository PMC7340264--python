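"""Report bundle: CSV tables and a single-page HTML summary.

CSV output is the contract (byte-identical across reruns at a fixed seed);
the HTML page carries the same numbers plus bar charts of the per-step
R-value differences, the Rgap-vs-cutoff curve and the per-shell CC/CC*
comparison, rendered with matplotlib as inline SVG.
"""

from __future__ import annotations

import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .protocol import CrossValResult, LadderResult
from .stats import RANDOM_DATA_R

__all__ = ["summarize"]

_CSV_FLOAT = "%.10g"


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _delta_chart(steps: pd.DataFrame) -> str:
    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(steps))
    ax.bar(x - 0.2, steps["d_rwork"], width=0.4, label="dRwork")
    ax.bar(x + 0.2, steps["d_rfree"], width=0.4, label="dRfree")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(
        [f"{a:.2f}→{b:.2f}" for a, b in zip(steps["cutoff_from"], steps["cutoff_to"])],
        rotation=45,
        fontsize=7,
    )
    ax.set_ylabel("R difference at step start")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _rgap_chart(steps: pd.DataFrame) -> str:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(steps["cutoff_to"], steps["r_gap_at_start"], "o-")
    ax.invert_xaxis()
    ax.set_xlabel("high-resolution cutoff (Å)")
    ax.set_ylabel("Rgap at starting resolution")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _cc_chart(shells: pd.DataFrame) -> str:
    fig, ax = plt.subplots(figsize=(6, 3))
    mid = 0.5 * (shells["d_high"] + shells["d_low"])
    ax.plot(mid, shells["cc_work"], "o-", label="CCwork")
    if "cc_free" in shells and shells["cc_free"].notna().any():
        ax.plot(mid, shells["cc_free"], "s-", label="CCfree")
    if "cc_star" in shells and shells["cc_star"].notna().any():
        ax.plot(mid, shells["cc_star"], "k--", label="CC*")
    ax.invert_xaxis()
    ax.set_xlabel("shell centre d (Å)")
    ax.set_ylabel("correlation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _fig_to_svg(fig)


def summarize(
    result: LadderResult | CrossValResult,
    out_dir,
    write_models: bool = False,
) -> dict[str, Path]:
    """Write steps.csv, shells.csv, merging.csv (if available), report.html.

    Returns a name -> path mapping of everything written.  CSV files are
    byte-identical across reruns with the same inputs and seed.
    """
    from .model import write_pdb  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if isinstance(result, CrossValResult):
        ladder = result.ladders[0]
        steps_df = result.summary
        title = f"Complete cross-validation over {result.k} free sets"
    else:
        ladder = result
        steps_df = ladder.steps_frame()
        title = f"Paired-refinement ladder (free set {ladder.free_set})"

    p = out / "steps.csv"
    steps_df.to_csv(p, index=False, float_format=_CSV_FLOAT)
    written["steps"] = p

    if ladder.steps:
        last = ladder.steps[-1]
        p = out / "shells.csv"
        last.shells.to_csv(p, float_format=_CSV_FLOAT)
        written["shells"] = p

    if ladder.merging is not None:
        p = out / "merging.csv"
        ladder.merging.to_csv(p, float_format=_CSV_FLOAT)
        written["merging"] = p

    if write_models:
        for res in ladder.results:
            p = out / f"model_{res.d_cutoff:.2f}A.pdb"
            write_pdb(res.model, p)
            written[f"model_{res.d_cutoff:.2f}"] = p

    # ---- HTML ------------------------------------------------------------
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{title}</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 8px;font-size:12px}</style>",
        "</head><body>",
        f"<h1>{title}</h1>",
        f"<p>Starting resolution A = {ladder.start_resolution:.2f} &Aring;; "
        f"ladder cutoffs: {', '.join(f'{c:.2f}' for c in ladder.cutoffs)} &Aring;. "
        f"Shells with Rwork &gt; {RANDOM_DATA_R} are flagged: a perfect model "
        "scores about that against pure noise, so higher means the shell is "
        "worse than noise for this model.</p>",
        "<h2>Per-step R-value differences (each computed at the step's "
        "lower-resolution cutoff X)</h2>",
    ]
    if isinstance(result, CrossValResult):
        plot_steps = pd.DataFrame(
            {
                "cutoff_from": steps_df["cutoff_from"],
                "cutoff_to": steps_df["cutoff_to"],
                "d_rwork": steps_df["d_rwork_mean"],
                "d_rfree": steps_df["d_rfree_mean"],
                "r_gap_at_start": steps_df["r_gap_mean"],
            }
        )
    else:
        plot_steps = steps_df.rename(columns={})
    if len(plot_steps):
        parts.append(_delta_chart(plot_steps))
        parts.append("<h2>Rgap at the starting resolution vs cutoff</h2>")
        parts.append(_rgap_chart(plot_steps))
    parts.append("<h2>Steps</h2>")
    parts.append(steps_df.to_html(float_format=lambda v: f"{v:.5g}"))
    if ladder.steps:
        parts.append("<h2>Per-shell correlations (final model)</h2>")
        parts.append(_cc_chart(ladder.steps[-1].shells))
        parts.append(ladder.steps[-1].shells.to_html(float_format=lambda v: f"{v:.5g}"))
    if ladder.merging is not None:
        parts.append("<h2>Merging statistics</h2>")
        parts.append(ladder.merging.to_html(float_format=lambda v: f"{v:.5g}"))
    parts.append("</body></html>")
    p = out / "report.html"
    p.write_text("\n".join(parts))
    written["report"] = p
    return written
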