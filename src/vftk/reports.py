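"""Rendering of evaluation and explanation reports.

Every figure has a CSV twin carrying exactly the plotted numbers, and
rendering is deterministic (stable ordering, no timestamps in the SVG
metadata).  Local explanation plots follow the clinical convention:
red bars push the log-odds toward the schizophrenia class, blue bars
toward the healthy-control class.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluate import EvalReport

__all__ = ["render_reports"]

_RED, _BLUE = "#c0392b", "#2d6fa3"
_SAVEFIG = {"format": "svg", "metadata": {"Date": None}}


def _save_barh(labels: Sequence[str], values: Sequence[float], colors, title: str,
               xlabel: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ypos = range(len(labels))[::-1]
    ax.barh(list(ypos), list(values), color=colors)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(labels)
    ax.set_xlabel(xlabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def render_reports(
    eval_report: EvalReport | None,
    global_table: pd.DataFrame | None,
    local_explanations: Mapping[str, dict] | None,
    out_dir: str | Path,
    top_k: int = 10,
    model: str = "ebm",
    featureset: str = "VN",
) -> dict[str, Path]:
    """Write metric, importance and local-explanation CSVs and figures.

    ``global_table`` is the output of :func:`vftk.ebm.global_importance`;
    ``local_explanations`` maps subject id to the output of
    :func:`vftk.ebm.local_explanation`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if eval_report is not None:
        path = out_dir / "metrics.csv"
        row = {"model": model, "featureset": featureset,
               **{k: round(v, 4) for k, v in eval_report.as_dict().items()}}
        pd.DataFrame([row]).to_csv(path, index=False)
        written["metrics"] = path
        probs = eval_report.probabilities.round(6)
        probs.to_csv(out_dir / "holdout_probabilities.csv")
        written["probabilities"] = out_dir / "holdout_probabilities.csv"

    if global_table is not None:
        top = global_table.head(top_k).copy()
        top["importance"] = top["importance"].round(6)
        path = out_dir / "global_importance.csv"
        top.to_csv(path, index=False)
        written["global_csv"] = path
        fig_path = out_dir / "global_importance.svg"
        _save_barh(
            list(top["feature"]), list(top["importance"]),
            _BLUE, f"Top {len(top)} features by mean |contribution|",
            "mean |contribution| (log-odds)", fig_path,
        )
        written["global_fig"] = fig_path

    if local_explanations:
        local_dir = out_dir / "local"
        local_dir.mkdir(exist_ok=True)
        for subject_id in sorted(local_explanations):
            exp = local_explanations[subject_id]
            ranked = exp["ranked"][:top_k]
            df = pd.DataFrame(ranked, columns=["feature", "contribution"])
            df["contribution"] = df["contribution"].round(6)
            df.to_csv(local_dir / f"{subject_id}.csv", index=False)
            colors = [_RED if v > 0 else _BLUE for _, v in ranked]
            _save_barh(
                [f for f, _ in ranked], [v for _, v in ranked], colors,
                f"{subject_id}: P(SH) = {exp['probability']:.2f}",
                "contribution to log-odds (red: toward SH)",
                local_dir / f"{subject_id}.svg",
            )
        written["local_dir"] = local_dir
    return written
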