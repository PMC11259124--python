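"""Case-control gene-burden statistics on collapsed carrier manifests.

The burden contrast is a 2x2 table of carrier status by cohort.  The
odds ratio is the cross-product (a*d)/(b*c) and its confidence interval
is Woolf's log-normal interval,

    exp( ln(OR) +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),

without continuity correction.  ``z`` defaults to the conventional
two-decimal normal quantile for the level (1.96 at 95%), which is what
epidemiological reports customarily use; the full-precision quantile is
available via ``exact_z=True``.  All computation is at full precision;
rounding happens only at report serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: carriers/non-carriers among cases (a/b) and controls (c/d)."""

    a: int
    b: int
    c: int
    d: int
    case_label: str = "cases"
    control_label: str = "controls"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def with_correction(self) -> "ContingencyTable":
        """Haldane-Anscombe: add 0.5 to every cell (returned as floats in OR/CI)."""
        raise NotImplementedError("use odds_ratio/woolf_ci with correction=True")


def normal_quantile(level: float, exact: bool = False) -> float:
    """Two-sided normal quantile for a confidence level.

    By convention reports use the two-decimal value (1.96 for 95%);
    ``exact=True`` returns the full-precision quantile.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return z if exact else round(z, 2)


def odds_ratio(t: ContingencyTable, correction: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    With ``correction=True`` the Haldane-Anscombe 0.5 is added to every
    cell (off by default; the headline values need no correction).  A
    zero in b or c without correction yields ``inf``; a zero in a or d
    yields 0; a zero in both numerator and denominator yields ``nan``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    num, den = a * d, b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def woolf_ci(
    t: ContingencyTable,
    level: float = 0.95,
    correction: bool = False,
    exact_z: bool = False,
) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the odds ratio.

    Requires all four cells positive unless ``correction`` is enabled.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "Woolf CI undefined with a zero cell; enable the Haldane-Anscombe correction"
        )
    z = normal_quantile(level, exact=exact_z)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def carrier_frequency(carriers: int, n: int) -> float:
    """Carrier frequency as a percentage."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= carriers <= n:
        raise ValueError("carriers must be between 0 and n")
    return 100.0 * carriers / n


@dataclass(frozen=True)
class BurdenResult:
    """Odds-ratio estimate with Woolf interval for one comparison."""

    table: ContingencyTable
    or_estimate: float
    ci_low: float
    ci_high: float
    level: float
    z: float
    carrier_freq_case: float
    carrier_freq_control: float


def burden_test(
    t: ContingencyTable,
    level: float = 0.95,
    correction: bool = False,
    exact_z: bool = False,
) -> BurdenResult:
    """Full burden result (OR, Woolf CI, carrier frequencies) for one table."""
    return BurdenResult(
        table=t,
        or_estimate=odds_ratio(t, correction=correction),
        ci_low=woolf_ci(t, level, correction, exact_z)[0],
        ci_high=woolf_ci(t, level, correction, exact_z)[1],
        level=level,
        z=normal_quantile(level, exact=exact_z),
        carrier_freq_case=carrier_frequency(t.a, t.n_cases),
        carrier_freq_control=carrier_frequency(t.c, t.n_controls),
    )


# -- building tables from manifests -----------------------------------------


def build_2x2(
    case_manifest: pd.DataFrame,
    control_manifest: pd.DataFrame,
    case_label: str = "cases",
    control_label: str = "controls",
    carrier_column: str = "carrier",
) -> ContingencyTable:
    """Derive the 2x2 table from collapsed carrier manifests.

    Non-carrier cells are always derived as N minus carriers, never
    taken as input.  Case and control sample ids must be disjoint.
    """
    if len(case_manifest) == 0 or len(control_manifest) == 0:
        raise ValueError("empty case or control panel")
    shared = set(case_manifest.index) & set(control_manifest.index)
    if shared:
        raise ValueError(f"sample ids present in both panels: {sorted(shared)[:5]}")
    a = int(case_manifest[carrier_column].astype(bool).sum())
    c = int(control_manifest[carrier_column].astype(bool).sum())
    return ContingencyTable(
        a=a,
        b=len(case_manifest) - a,
        c=c,
        d=len(control_manifest) - c,
        case_label=case_label,
        control_label=control_label,
    )


def table_from_counts(
    case_n: int,
    case_carriers: int,
    control_n: int,
    control_carriers: int,
    case_label: str = "cases",
    control_label: str = "controls",
) -> ContingencyTable:
    """Count-only mode: build the table from cohort sizes and carrier counts."""
    return ContingencyTable(
        a=case_carriers,
        b=case_n - case_carriers,
        c=control_carriers,
        d=control_n - control_carriers,
        case_label=case_label,
        control_label=control_label,
    )


def pool_controls(panels: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Pool control panels assuming no overlap between them.

    ``panels`` is a sequence of (n, carriers) pairs; returns the summed
    (n, carriers).
    """
    if not panels:
        raise ValueError("need at least one panel")
    n = sum(p[0] for p in panels)
    carriers = sum(p[1] for p in panels)
    return n, carriers


def subgroup_reanalysis(
    case_manifest: pd.DataFrame,
    control_manifest: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], pd.Series],
    level: float = 0.95,
    **labels: str,
) -> BurdenResult:
    """Re-run the burden test on the subsets satisfying ``predicate``.

    ``predicate`` maps a manifest to a boolean mask (e.g.
    ``lambda m: m["age"] >= 17``).  Both panels are filtered; an emptied
    panel is an error.
    """
    case_sub = case_manifest.loc[predicate(case_manifest).astype(bool)]
    control_sub = control_manifest.loc[predicate(control_manifest).astype(bool)]
    if len(case_sub) == 0 or len(control_sub) == 0:
        raise ValueError("subgroup predicate emptied a panel")
    table = build_2x2(case_sub, control_sub, **labels)
    return burden_test(table, level=level)


# -- descriptive statistics --------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive summary of a cohort manifest."""

    n: int
    median_age: Optional[float]
    mean_age: Optional[float]
    sd_age: Optional[float]
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    n_missing: dict[str, int] = field(default_factory=dict)


def describe_cohort(
    manifest: pd.DataFrame,
    age_column: str = "age",
    categorical_columns: Sequence[str] = (),
) -> CohortSummary:
    """Median / mean / sample SD of age plus categorical proportions.

    Missing values are excluded per field with counts recorded; the SD
    uses the n-1 denominator and is ``None`` when fewer than two ages
    are present.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    n_missing: dict[str, int] = {}
    median = mean = sd = None
    if age_column in manifest.columns:
        ages = pd.to_numeric(manifest[age_column], errors="coerce").dropna()
        n_missing[age_column] = len(manifest) - len(ages)
        if len(ages):
            median = float(ages.median())
            mean = float(ages.mean())
            sd = float(ages.std(ddof=1)) if len(ages) > 1 else None
    proportions: dict[str, dict[str, float]] = {}
    for col in categorical_columns:
        vals = manifest[col].dropna()
        n_missing[col] = len(manifest) - len(vals)
        if len(vals):
            proportions[col] = (vals.value_counts() / len(vals)).to_dict()
    return CohortSummary(
        n=len(manifest),
        median_age=median,
        mean_age=mean,
        sd_age=sd,
        proportions=proportions,
        n_missing=n_missing,
    )


def describe_numeric(values: Iterable[float]) -> dict[str, Optional[float]]:
    """Median/mean/sample-SD for any continuous clinical field."""
    arr = pd.to_numeric(pd.Series(list(values)), errors="coerce").dropna()
    if len(arr) == 0:
        raise ValueError("no non-missing values")
    return {
        "n": int(len(arr)),
        "median": float(arr.median()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
    }


def diagnostic_yield(
    manifest: pd.DataFrame,
    genes_column: str = "reported_genes",
    sep: str = ";",
) -> dict:
    """Per-gene diagnostic counts and shares over a cohort manifest.

    An individual with a non-empty ``reported_genes`` field counts once
    in the diagnosed numerator; individuals with multiple reported genes
    count once per gene in the per-gene shares (shares are over the
    diagnosed N, so they may sum past 100%).
    """
    total = len(manifest)
    if total == 0:
        raise ValueError("empty manifest")
    genes = manifest[genes_column].fillna("").astype(str)
    diagnosed_mask = genes.str.strip() != ""
    n_diag = int(diagnosed_mask.sum())
    per_gene: dict[str, int] = {}
    for entry in genes[diagnosed_mask]:
        for gene in {g.strip() for g in entry.split(sep) if g.strip()}:
            per_gene[gene] = per_gene.get(gene, 0) + 1
    shares = {g: 100.0 * k / n_diag for g, k in per_gene.items()} if n_diag else {}
    return {
        "n_total": total,
        "n_diagnosed": n_diag,
        "yield_percent": 100.0 * n_diag / total,
        "gene_counts": dict(sorted(per_gene.items(), key=lambda kv: -kv[1])),
        "gene_shares_percent": shares,
    }


# -- forest output -----------------------------------------------------------


def forest_table(results: Sequence[BurdenResult], labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Plot-ready table of OR/CI rows, one per comparison, in input order."""
    if not results:
        raise ValueError("need at least one result")
    if labels is None:
        labels = [r.table.control_label for r in results]
    df = pd.DataFrame(
        {
            "label": list(labels),
            "or": [r.or_estimate for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
        }
    )
    df.attrs["axis_scale"] = "log"
    return df


def plot_forest(results: Sequence[BurdenResult], path: str,
                labels: Optional[Sequence[str]] = None) -> None:
    """Write a simple forest plot (log-scaled OR axis) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = forest_table(results, labels)
    fig, ax = plt.subplots(figsize=(6, 0.8 * len(df) + 1.2))
    y = np.arange(len(df))[::-1]
    ax.errorbar(
        df["or"], y,
        xerr=[df["or"] - df["ci_low"], df["ci_high"] - df["or"]],
        fmt="s", color="black", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(df["label"])
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
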