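"""Group-comparison layer and cohort reports.

Per-animal summary metrics (mean velocity, fraction of time at rest, bout
statistics, per-velocity-bin event rates, per-distance-bin normalized
co-activity, onset SCI peaks) are compared between conditions with
non-parametric tests on single values per animal (Mann-Whitney U for
unpaired, Wilcoxon signed-rank for paired designs), and with a linear
mixed-effects model when multiple correlated strata are measured per animal
(condition as fixed effect, animal as grouping factor).  All tests are
two-sided at alpha = 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

COHORT_COLUMNS = ["animal", "session", "condition", "metric", "stratum", "value"]


def make_cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a cohort table; one row per (animal, session, metric, stratum)."""
    df = pd.DataFrame(rows)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort rows missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["animal", "session", "condition", "metric", "stratum"])
    if dup.any():
        raise ValueError("duplicate (animal, session, condition, metric, stratum) rows")
    return df[COHORT_COLUMNS]


def _per_animal_means(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = table[table["metric"] == metric]
    if not len(sub):
        raise ValueError(f"no rows for metric {metric!r}")
    return (
        sub.groupby(["animal", "condition"], as_index=False)["value"].mean()
    )


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    conditions: tuple[str, str],
    test: str = "mann_whitney",
) -> dict:
    """Two-sided test on per-animal means for one metric.

    ``mann_whitney`` compares two independent groups of animals;
    ``wilcoxon_signed_rank`` compares paired per-animal values (the same
    animals measured under both conditions).
    """
    means = _per_animal_means(table, metric)
    a = means.loc[means["condition"] == conditions[0]]
    b = means.loc[means["condition"] == conditions[1]]
    if test == "mann_whitney":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 animals per group")
        res = stats.mannwhitneyu(a["value"], b["value"], alternative="two-sided")
        return {
            "test": "mann_whitney",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "n": (int(len(a)), int(len(b))),
        }
    if test == "wilcoxon_signed_rank":
        paired = a.merge(b, on="animal", suffixes=("_a", "_b"))
        if len(paired) < 2:
            raise ValueError("need at least 2 paired animals")
        diff = paired["value_a"] - paired["value_b"]
        if np.allclose(diff, 0):
            return {
                "test": "wilcoxon_signed_rank",
                "statistic": 0.0,
                "p": 1.0,
                "n": int(len(paired)),
                "degenerate": True,
            }
        res = stats.wilcoxon(paired["value_a"], paired["value_b"])
        return {
            "test": "wilcoxon_signed_rank",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "n": int(len(paired)),
        }
    raise ValueError(f"unknown test {test!r}")


@dataclass
class ContrastResult:
    beta: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool
    n_animals: int


def grouped_slope_contrast(
    table: pd.DataFrame, metric: str, condition_ref: str | None = None
) -> ContrastResult:
    """Condition effect on per-stratum means with per-animal grouping.

    Fits ``value ~ condition`` with a random intercept per animal on the
    per-(animal, stratum) means, via statsmodels MixedLM (the standard
    mixed-model facility; this module owns only the design and reporting).
    Each stratum (e.g. a distance or velocity bin) carries equal weight.
    """
    import statsmodels.formula.api as smf

    sub = table[table["metric"] == metric]
    if not len(sub):
        raise ValueError(f"no rows for metric {metric!r}")
    df = (
        sub.groupby(["animal", "condition", "stratum"], as_index=False)["value"].mean()
    )
    conditions = sorted(df["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("grouped_slope_contrast requires exactly 2 conditions")
    if df["animal"].nunique() < 2:
        raise ValueError("grouping undefined with a single animal")
    for cond in conditions:
        if df.loc[df["condition"] == cond, "animal"].nunique() < 2:
            raise ValueError(f"need at least 2 animals in condition {cond!r}")
    if condition_ref is None:
        condition_ref = conditions[0]
    df = df.copy()
    df["condition"] = pd.Categorical(
        df["condition"], categories=[condition_ref] + [c for c in conditions if c != condition_ref]
    )
    model = smf.mixedlm("value ~ condition", df, groups=df["animal"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    term = [p for p in fit.params.index if p.startswith("condition")][0]
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    if not np.isfinite(se) or se == 0:
        raise RuntimeError("singular mixed-model fit: standard error undefined")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ContrastResult(
        beta=beta,
        se=se,
        z=float(z),
        p=float(p),
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        converged=bool(getattr(fit, "converged", True)),
        n_animals=int(df["animal"].nunique()),
    )


REQUIRED_STAGES = {
    "raster": "preprocess",
    "events": "events",
    "epochs": "behavior",
    "coactivity": "coactivity",
    "sci": "sci",
}


def build_report(
    inputs: dict[str, str | Path],
    cohort: pd.DataFrame | None = None,
    group_tests: list[dict] | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble a session/cohort report from pipeline output files.

    ``inputs`` maps stage output names (``raster``, ``events``, ``epochs``,
    ``coactivity``, ``sci``) to file paths; a missing file raises an error
    naming the pipeline stage that should have produced it.  The report embeds
    the config and any group-test results; regeneration from identical inputs
    is byte-identical.
    """
    report: dict = {"config": config or {}, "stages": {}}
    for key, stage in REQUIRED_STAGES.items():
        if key not in inputs:
            continue
        path = Path(inputs[key])
        if not path.exists():
            raise FileNotFoundError(
                f"missing output {path.name!r} from the {stage} stage"
            )
        if path.suffix == ".json":
            report["stages"][key] = json.loads(path.read_text())
        else:
            df = pd.read_csv(path)
            report["stages"][key] = {
                "rows": int(len(df)),
                "columns": list(df.columns),
            }
    if cohort is not None:
        report["cohort"] = {
            "n_rows": int(len(cohort)),
            "metrics": sorted(cohort["metric"].unique()),
            "animals": sorted(cohort["animal"].unique()),
        }
    if group_tests:
        report["group_tests"] = group_tests
    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, sort_keys=True, indent=2, default=str))
    return path
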