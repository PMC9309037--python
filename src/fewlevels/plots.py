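"""Panel figures: rejection-rate curves, variance-estimate histograms,
and design-sweep partial-effect curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sweep import COVARIATES, fit_quantile_spline


def plot_rates(metrics: pd.DataFrame, coefficient: str = "slope"):
    """Type I error / power vs number of levels, one panel per
    (variance, policy), one line per model."""
    df = metrics[(metrics["coefficient"] == coefficient)
                 & (metrics["policy"].isin(["nonsingular_only", "all"]))]
    variances = sorted(df["variance"].unique())
    policies = ["nonsingular_only", "all"]
    fig, axes = plt.subplots(len(variances), 2, figsize=(9, 4 * len(variances)),
                             squeeze=False, sharey="row")
    for i, v in enumerate(variances):
        for j, pol in enumerate(policies):
            ax = axes[i][j]
            sub = df[(df["variance"] == v) & (df["policy"] == pol)]
            fixed = metrics[(metrics["coefficient"] == coefficient)
                            & (metrics["variance"] == v)
                            & (metrics["policy"] == "all")
                            & (~metrics["model_id"].isin(sub["model_id"].unique()))]
            for model, grp in pd.concat([sub, fixed]).groupby("model_id"):
                grp = grp.sort_values("m")
                ax.errorbar(grp["m"], grp["rejection_rate"], yerr=grp["mc_se"],
                            label=model, marker="o", capsize=2)
            ax.axhline(0.05, ls=":", color="gray")
            ax.set_title(f"variance={v}, {pol}")
            ax.set_xlabel("number of mountains")
            ax.set_ylabel("rejection rate")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_varcomp(varcomp: pd.DataFrame):
    """Zero mass and mean/median of variance estimates vs number of levels."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col in zip(axes, ("zero_mass", "mean")):
        for (term, subset), grp in varcomp.groupby(["term", "subset"]):
            grp = grp.sort_values("m")
            ax.plot(grp["m"], grp[col], marker="o", label=f"{term}/{subset}")
        if col == "mean" and "true_value" in varcomp:
            ax.axhline(varcomp["true_value"].iloc[0], ls=":", color="blue")
        ax.set_xlabel("number of mountains")
        ax.set_ylabel(col)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_sweep(sweep: pd.DataFrame, response: str = "type_I_mixed", n_grid: int = 50):
    """Partial-effect curves of each design factor on a sweep response."""
    df = sweep[sweep["valid"]].dropna(subset=[response])
    fit = fit_quantile_spline(df[COVARIATES], df[response])
    fig, axes = plt.subplots(1, len(COVARIATES), figsize=(12, 3))
    for ax, cov in zip(axes, COVARIATES):
        grid = np.linspace(df[cov].min(), df[cov].max(), n_grid)
        ax.plot(grid, fit.intercept + fit.partial_effect(cov, grid))
        ax.set_xlabel(cov)
        ax.set_ylabel(response)
    fig.tight_layout()
    return fig


def render_report(results_dir: Path, out_dir: Path) -> list[Path]:
    """Render whatever tables a results directory holds into PNG figures."""
    results_dir, out_dir = Path(results_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    metrics_path = results_dir / "metrics.csv"
    if metrics_path.exists():
        fig = plot_rates(pd.read_csv(metrics_path))
        path = out_dir / "rates.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    varcomp_path = results_dir / "varcomp.csv"
    if varcomp_path.exists():
        fig = plot_varcomp(pd.read_csv(varcomp_path))
        path = out_dir / "varcomp.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    sweep_path = results_dir / "sweep.csv"
    if sweep_path.exists():
        df = pd.read_csv(sweep_path)
        for response in ("type_I_mixed", "type_I_fixed", "power_mixed", "power_fixed"):
            fig = plot_sweep(df, response)
            path = out_dir / f"sweep_{response}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
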