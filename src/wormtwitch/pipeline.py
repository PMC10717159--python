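"""End-to-end runs: simulate (or load) a cohort, analyse, report.

A pipeline run produces a self-contained output directory: the cohort table,
per-endpoint summary/ANOVA/Tukey CSVs, bar plots, and a provenance manifest
(seed, parameters, and a content hash for every output file).

Blinding mirrors a double-blinded design as a software correctness check:
with ``blinded=True`` the measurement and statistics stages see opaque
condition codes only, and the code-to-label key is applied at reporting.
Blinded and unblinded runs of the same seed are numerically identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .io import sha256_file
from .stats import one_way_anova, summarize, tukey_hsd

__all__ = ["RunConfig", "run_pipeline", "PRESETS", "PipelineError"]

PRESETS = {
    "contractility": synthetic.contractility_preset,
    "two_group_contractility": synthetic.two_group_contractility_preset,
    "null": synthetic.null_cohort_preset,
    "mobility": synthetic.mobility_preset,
    "aging_mobility": synthetic.aging_mobility_preset,
    "muscle_integrity": synthetic.muscle_integrity_preset,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    #: name of a synthetic cohort preset (ignored when cohort_csv is given)
    preset: str = "contractility"
    #: optional path to an existing long-format cohort CSV
    cohort_csv: str | None = None
    endpoints: list[str] | None = None
    group_col: str = "condition"
    n_animals: int = 30
    blinded: bool = True
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(
                f"cohort CSV not found: {self.cohort_csv}"
            )
        if self.cohort_csv is None and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )


def _plot_endpoint(summary: pd.DataFrame, endpoint: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(summary)), 3.2))
    x = range(len(summary))
    ax.bar(x, summary["mean"], yerr=summary["sem"], capsize=3, color="#7fb3d5")
    ax.set_xticks(list(x))
    ax.set_xticklabels(summary["condition"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel(endpoint)
    ax.set_title(f"{endpoint}: mean ± SEM")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> analyse -> report; returns a run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    # --- stage: acquire -------------------------------------------------
    stage = "acquire"
    try:
        if config.cohort_csv is not None:
            table = pd.read_csv(config.cohort_csv)
            truth = None
        else:
            spec = PRESETS[config.preset](
                n_animals=config.n_animals, seed=config.seed
            )
            table, truth = synthetic.gen_cohort(spec)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # condition codes: analysis always runs on opaque codes so that results
    # cannot depend on labels; blinding only controls what is written out.
    labels = list(dict.fromkeys(table[config.group_col]))
    code_of = {lab: f"grp{i:02d}" for i, lab in enumerate(labels)}
    label_of = {v: k for k, v in code_of.items()}
    coded = table.copy()
    coded[config.group_col] = coded[config.group_col].map(code_of)

    cohort_path = out / "cohort.csv"
    (coded if config.blinded else table).to_csv(cohort_path, index=False)
    files.append(cohort_path)
    key_path = out / "condition_key.json"
    with open(key_path, "w") as fh:
        json.dump(code_of, fh, indent=2, sort_keys=True)
    files.append(key_path)

    # --- stage: statistics ----------------------------------------------
    stage = "statistics"
    endpoints = config.endpoints or sorted(coded["endpoint"].unique())
    summaries, anovas, tukeys = [], [], []
    try:
        for ep in endpoints:
            summ = summarize(coded, group_col=config.group_col, endpoint=ep)
            an = one_way_anova(coded, group_col=config.group_col, endpoint=ep)
            tk = tukey_hsd(coded, group_col=config.group_col, endpoint=ep)
            summ.insert(0, "endpoint", ep)
            summaries.append(summ)
            anovas.append(
                {
                    "endpoint": ep,
                    "F": an.f_statistic,
                    "df_between": an.df_between,
                    "df_within": an.df_within,
                    "p_value": an.p_value,
                    "variance_warning": an.variance_warning,
                }
            )
            t = tk.table.copy()
            t.insert(0, "endpoint", ep)
            tukeys.append(t)
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed on endpoint {ep!r}: {exc}"
        ) from exc

    summary_df = pd.concat(summaries, ignore_index=True)
    tukey_df = pd.concat(tukeys, ignore_index=True)
    anova_df = pd.DataFrame(anovas)
    # unblind for reporting (row order fixed by the coded analysis)
    summary_df["condition"] = summary_df["condition"].map(label_of)
    tukey_df["condition_a"] = tukey_df["condition_a"].map(label_of)
    tukey_df["condition_b"] = tukey_df["condition_b"].map(label_of)

    for name, df in (
        ("summary.csv", summary_df),
        ("anova.csv", anova_df),
        ("tukey.csv", tukey_df),
    ):
        path = out / name
        df.to_csv(path, index=False)
        files.append(path)

    # --- stage: plots ----------------------------------------------------
    stage = "plots"
    if config.make_plots:
        try:
            for ep in endpoints:
                sub = summary_df[summary_df["endpoint"] == ep]
                path = out / f"plot_{ep}.png"
                _plot_endpoint(sub, ep, path)
                files.append(path)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- manifest ---------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "preset": None if config.cohort_csv else config.preset,
        "cohort_csv": config.cohort_csv,
        "blinded": config.blinded,
        "group_col": config.group_col,
        "n_animals": config.n_animals,
        "endpoints": endpoints,
        "outputs": {
            str(p.relative_to(out)): sha256_file(p) for p in files
        },
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "out_dir": str(out),
        "endpoints": endpoints,
        "anova": anova_df,
        "tukey": tukey_df,
        "summary": summary_df,
        "manifest": manifest,
    }
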