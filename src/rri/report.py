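"""Human-readable markdown summary of a pipeline run.

Every number in the report is read back from the CSV/JSON files the run
wrote, so the rendered text can never drift from the result bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import PipelineRun


def _fmt(df: pd.DataFrame, ndigits: int = 3) -> str:
    return df.round(ndigits).to_markdown(index=False)


def plot_trajectories(trajectories: pd.DataFrame, path) -> str:
    """Facet plot of predicted EF trajectories: sex rows, brain-level
    columns, one line per reserve level.  Optional output; requires
    matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sexes = sorted(trajectories.female.unique())
    mbs = sorted(trajectories.memb_level.unique())
    mrs = sorted(trajectories.memr_level.unique())
    fig, axes = plt.subplots(len(sexes), len(mbs), sharex=True, sharey=True,
                             figsize=(3 * len(mbs), 2.6 * len(sexes)))
    axes = np.atleast_2d(axes)
    for i, f in enumerate(sexes):
        for j, mb in enumerate(mbs):
            ax = axes[i, j]
            for mr in mrs:
                sub = trajectories[
                    (trajectories.female == f)
                    & (trajectories.memb_level == mb)
                    & (trajectories.memr_level == mr)].sort_values("T")
                ax.plot(sub["T"], sub.predicted_ef,
                        label=f"reserve {mr:+.0f} SD")
            if i == 0:
                ax.set_title(f"brain {mb:+.0f} SD")
            if j == 0:
                ax.set_ylabel(("female" if f else "male") + "\npredicted EF")
            if i == len(sexes) - 1:
                ax.set_xlabel("visit offset T")
    axes[0, -1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def render_report(run: PipelineRun, *, path=None) -> str:
    """Render the run's tables as markdown; omitted stages get a notice."""
    out = Path(run.out_dir)
    lines = [
        "# Residual reserve index - pipeline report",
        "",
        f"- config hash: `{run.config_hash}`",
        f"- seed: {run.seed}",
        f"- stages: " + ", ".join(f"{k}={v}" for k, v in run.stages.items()),
        "",
    ]

    def section(title, key, renderer):
        lines.append(f"## {title}")
        p = run.outputs.get(key)
        if p is None or not Path(p).exists():
            lines.append("_stage not run; section omitted_")
        else:
            lines.append(renderer(p))
        lines.append("")

    section("Cohort descriptives (sex-stratified)", "descriptives",
            lambda p: _fmt(pd.read_csv(p)))
    section("Memory decomposition", "decomposition_variance", lambda p:
            "```json\n" + json.dumps(json.load(open(p)), indent=2) + "\n```")
    section("Growth-form comparison", "growth_comparison",
            lambda p: _fmt(pd.read_csv(p)))
    section("Structural coefficients (intercept and slope blocks)",
            "analytical_coefficients", lambda p: _fmt(pd.read_csv(p)))
    section("Interaction tests", "interaction_tests",
            lambda p: _fmt(pd.read_csv(p)))
    section("Simple slopes of MEMR by MEMB level and sex", "simple_slopes",
            lambda p: _fmt(pd.read_csv(p)))
    if "planted_truth" in run.outputs and "recovery" in run.outputs:
        section("Planted vs recovered structural effects", "recovery",
                lambda p: _fmt(pd.read_csv(p)))
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
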