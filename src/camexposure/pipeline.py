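"""End-to-end pipeline: validate -> segment -> summarise -> rates -> models.

`run_pipeline` takes a coded-image table and a child roster (either in
memory or as CSV paths) and produces the publication-shaped outputs: a
cohort description, per-margin rates with design-based CIs and shares,
weighted median/IQR summaries, adjusted rate-ratio models with the
interaction test, and within-decile ethnicity rate ratios — plus a run log
of row counts, exclusions and convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as dz
from .rates import margin_shares, rate_per_day, weighted_median_iqr
from .segmentation import segment, summarise_children
from .vocab import load_vocabulary, validate_and_filter

__all__ = ["PipelineConfig", "run_pipeline", "describe_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Analysis constants and rules (all config-exposed, defaults standard)."""

    seconds_per_photo: float = 7.0
    timeout: float = 30.0
    day_seconds: float = 36_000.0
    boundary: str = "continue"  # gap == timeout continues the episode
    df_rule: str = "clusters_minus_strata"
    strict: bool = True
    vocabulary: str | None = None  # path; None -> packaged default

    def __post_init__(self) -> None:
        if min(self.seconds_per_photo, self.day_seconds) <= 0 or self.timeout < 0:
            raise PipelineError("constants must be positive (timeout >= 0)")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def describe_cohort(children: pd.DataFrame) -> pd.DataFrame:
    """Frequency table of the cohort: N and % by demographic variable."""
    rows = []
    for var in ("ethnicity", "decile_group", "age", "gender"):
        if var not in children.columns or len(children) == 0:
            continue
        counts = children[var].value_counts(dropna=True)
        for level, n in counts.items():
            rows.append((var, level, int(n), round(100 * n / counts.sum(), 1)))
    return pd.DataFrame(rows, columns=["variable", "level", "n", "percent"])


def _rate_table(margin_rates: pd.DataFrame, prefix: str) -> pd.DataFrame:
    """Assemble one core/non-core column of the rates table with shares."""
    out = margin_rates.copy()
    for family in ("setting", "medium", "product"):
        fam_rows = [m for m in out.index if f"{prefix}_{family}_" in m]
        if not fam_rows:
            continue
        vals = out.loc[fam_rows, "rate"].to_numpy()
        if vals.sum() > 0:
            out.loc[fam_rows, "share"] = margin_shares(vals)
    out.loc[f"{prefix}_total", "share"] = 100.0 if out.loc[f"{prefix}_total", "rate"] > 0 else np.nan
    return out


def run_pipeline(
    coded: pd.DataFrame | str,
    children: pd.DataFrame | str,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis; returns a results bundle (dict of tables).

    Keys: ``cohort`` (frequency table), ``validation`` (exclusion report),
    ``episodes``, ``summary`` (per child), ``rates_core`` / ``rates_noncore``
    (rate, CI, share per margin), ``median_iqr`` (weighted, by stratum),
    ``models_core`` / ``models_noncore`` (rate-ratio tables for models 1-3),
    ``interaction_core`` / ``interaction_noncore`` (Wald F), ``stratified_rr``
    (non-core ethnicity RRs within decile groups), and ``log``.
    """
    config = config or PipelineConfig()
    vocab = load_vocabulary(config.vocabulary)
    if isinstance(coded, (str, Path)):
        coded = pd.read_csv(coded, keep_default_na=False, na_values=[])
    if isinstance(children, (str, Path)):
        children = pd.read_csv(children)

    try:
        retained, report = validate_and_filter(coded, vocab, strict=config.strict)
    except Exception as err:
        raise PipelineError(f"stage validate: {err}") from err

    try:
        episodes = segment(
            retained, timeout=config.timeout, boundary=config.boundary, permissive=True
        )
        # denominator photos: distinct images retained, or roster counts if given
        if "n_photos" not in children.columns:
            children = children.copy()
            photo_counts = retained.drop_duplicates(["child_id", "timestamp"])[
                "child_id"
            ].value_counts()
            children["n_photos"] = (
                children["child_id"].map(photo_counts).fillna(0).astype(int)
            )
        summary = summarise_children(
            episodes, children, vocab, seconds_per_photo=config.seconds_per_photo
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage segment: {err}") from err

    active = children.loc[children["n_photos"] > 0].reset_index(drop=True)
    summary = summary.loc[summary["n_photos"] > 0].reset_index(drop=True)
    svy = dz.SurveyDesign.from_children(active, df_rule=config.df_rule)

    try:
        margin_rates = dz.estimate_margin_rates(
            summary, svy, day_seconds=config.day_seconds
        )
        rates_core = _rate_table(
            margin_rates.loc[[m for m in margin_rates.index if m.startswith("core_")]],
            "core",
        )
        rates_noncore = _rate_table(
            margin_rates.loc[[m for m in margin_rates.index if m.startswith("noncore_")]],
            "noncore",
        )
        per_child = active[
            ["child_id", "ethnicity", "decile_group", "sampling_weight"]
        ].merge(
            summary[["child_id", "core_total", "noncore_total", "exposure_time"]],
            on="child_id",
        )
        for col in ("core_total", "noncore_total"):
            per_child[f"{col}_rate"] = rate_per_day(
                per_child[col], per_child["exposure_time"], config.day_seconds
            )
        med = {
            col: weighted_median_iqr(
                per_child, f"{col}_rate", by=["ethnicity", "decile_group"]
            )
            for col in ("core_total", "noncore_total")
        }
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage rates: {err}") from err

    results: dict = {
        "cohort": describe_cohort(children),
        "validation": report,
        "episodes": episodes,
        "summary": summary,
        "rates_core": rates_core,
        "rates_noncore": rates_noncore,
        "median_iqr": med,
        "log": {
            "n_children": len(children),
            "n_children_with_photos": len(active),
            "n_coded_rows": report["input"],
            "n_episodes": len(episodes),
        },
    }

    try:
        for status, outcome in (("core", "core_total"), ("noncore", "noncore_total")):
            fits = dz.fit_models(summary, active, svy, outcome=outcome)
            results[f"models_{status}"] = {
                m: fit.rate_ratios() for m, fit in fits.items()
            }
            results[f"fits_{status}"] = fits
            wald = dz.wald_interaction_test(fits[3])
            results[f"interaction_{status}"] = wald
            results["log"][f"converged_{status}"] = all(
                f.converged for f in fits.values()
            )
        results["stratified_rr"] = dz.stratified_rate_ratios(results["fits_noncore"][3])
    except Exception as err:
        raise PipelineError(f"stage model: {err}") from err

    return results


def save_results(results: dict, outdir: str) -> None:
    """Persist the bundle: CSV per table plus a machine-readable JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["cohort"].to_csv(out / "cohort.csv", index=False)
    results["episodes"].to_csv(out / "episodes.csv", index=False)
    results["summary"].to_csv(out / "child_summary.csv", index=False)
    results["rates_core"].to_csv(out / "rates_core.csv")
    results["rates_noncore"].to_csv(out / "rates_noncore.csv")
    results["stratified_rr"].to_csv(out / "stratified_rr.csv", index=False)
    model_rows = []
    for status in ("core", "noncore"):
        for m, tab in results[f"models_{status}"].items():
            for name, row in tab.iterrows():
                model_rows.append(
                    (status, m, name, row["rr"], row["ci_low"], row["ci_high"])
                )
    pd.DataFrame(
        model_rows, columns=["outcome", "model", "term", "rr", "ci_low", "ci_high"]
    ).to_csv(out / "models.csv", index=False)

    blob = {
        "log": results["log"],
        "validation": results["validation"],
        "rates": {
            k: results[k].reset_index().to_dict(orient="records")
            for k in ("rates_core", "rates_noncore")
        },
        "interaction": {
            k: asdict(results[f"interaction_{k}"]) for k in ("core", "noncore")
        },
    }
    with open(out / "results.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True, default=float)
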