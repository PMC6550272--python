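"""Outcome-measure analytics for paired intake/conclusion cohorts.

Implements the study's statistical pipeline:

* the 40-item emotion-guessing protocol (8 emotions x 5, fixed random
  order) and its correct-count scoring;
* SRS-2 severity banding of total T-scores;
* two-timepoint repeated-measures ANOVA, which for two levels is exactly
  the squared paired t-test (F = t², df = (1, n-1));
* item-level Wilcoxon tests with Benjamini–Hochberg FDR correction
  (signed-rank default for paired data; a rank-sum variant is provided);
* Pearson correlations of covariates against improvement scores;
* change summaries (mean / SD with n-1 denominator / SEM = SD/sqrt(n)) and
  severity-transition counts;
* study-level compliance and usage arithmetic.

T-scores are taken as input columns and never computed from raw items (the
item-to-T conversion tables are proprietary), so item-level and T-score
analyses are deliberately decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .labels import EMOTIONS, canonical

__all__ = [
    "make_egg_protocol",
    "score_egg",
    "srs2_severity_class",
    "AnovaResult",
    "rm_anova_two_timepoints",
    "wilcoxon_item_tests",
    "bh_adjust",
    "pearson_assoc",
    "summarize_change",
    "yes_fraction",
    "study_compliance",
    "analyze_cohort",
    "write_report",
    "SchemaError",
    "EGG_N_ITEMS",
]

EGG_N_ITEMS = 40
_EGG_PER_EMOTION = 5


class SchemaError(ValueError):
    """Cohort table is missing required columns."""


# ---------------------------------------------------------------------------
# emotion-guessing game


def make_egg_protocol(seed: int = 0) -> list[str]:
    """Fixed random order of the 40-item protocol: each emotion 5 times."""
    rng = np.random.default_rng(seed)
    items = [e for e in EMOTIONS for _ in range(_EGG_PER_EMOTION)]
    return [items[i] for i in rng.permutation(EGG_N_ITEMS)]


def score_egg(responses: Sequence[str], protocol: Sequence[str]) -> int:
    """Number of position-wise correct labels (aliases canonicalized); no
    partial credit."""
    if len(responses) != len(protocol):
        raise ValueError(f"{len(responses)} responses for a {len(protocol)}-item protocol")
    return int(sum(canonical(r) == canonical(p) for r, p in zip(responses, protocol)))


# ---------------------------------------------------------------------------
# SRS-2 severity bands

_SEVERITY_ORDER = ("normal", "mild", "moderate", "severe")


def srs2_severity_class(total_tscore: float) -> str:
    """Severity band of a total T-score.

    The published band edges overlap at 60, 65 and 75; the fixed convention
    here is normal < 60, mild in [60, 65], moderate in (65, 75],
    severe > 75.
    """
    t = float(total_tscore)
    if not np.isfinite(t):
        raise ValueError("T-score must be finite")
    if t < 60:
        return "normal"
    if t <= 65:
        return "mild"
    if t <= 75:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# paired two-timepoint repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    n: int
    mean_intake: float
    mean_conclusion: float
    sd_intake: float
    sd_conclusion: float
    sem_intake: float
    sem_conclusion: float

    @property
    def mean_change(self) -> float:
        return self.mean_conclusion - self.mean_intake


def rm_anova_two_timepoints(intake, conclusion) -> AnovaResult:
    """Within-subject one-way ANOVA with two levels.

    Equivalent to the squared paired t: F = t², df = (1, n−1), two-sided p
    from the F distribution. Degenerate pairings (n < 2, or zero variance of
    the differences) raise with the offending condition named.
    """
    x = np.asarray(intake, dtype=float)
    y = np.asarray(conclusion, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("intake and conclusion must be paired 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError(f"need n >= 2 paired observations, got n={n}")
    d = y - x
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise ValueError("zero variance of paired differences (degenerate pairing)")
    t = d.mean() / (sd_d / np.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    return AnovaResult(
        F=float(F),
        df1=1,
        df2=n - 1,
        p=p,
        n=n,
        mean_intake=float(x.mean()),
        mean_conclusion=float(y.mean()),
        sd_intake=float(x.std(ddof=1)),
        sd_conclusion=float(y.std(ddof=1)),
        sem_intake=float(x.std(ddof=1) / np.sqrt(n)),
        sem_conclusion=float(y.std(ddof=1) / np.sqrt(n)),
    )


# ---------------------------------------------------------------------------
# item-level nonparametric tests


def _wilcoxon_signed_rank(d: np.ndarray) -> tuple[float, bool]:
    """Two-sided signed-rank p with mid-rank ties; exact when the effective
    n is <= 25 and there are no ties among nonzero |d|, else normal
    approximation with continuity correction. All-zero differences are
    degenerate: p = 1."""
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0, True
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue), False


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0, True
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), False


def wilcoxon_item_tests(
    intake_items, conclusion_items, variant: str = "signed_rank"
) -> pd.DataFrame:
    """Per-item change tests over an n x m ordinal item matrix pair.

    Returns a table with item_id, mean_intake, mean_conclusion, mean_change
    (= conclusion − intake), p_raw, p_adjusted (Benjamini–Hochberg over the
    m items) and a degenerate flag for all-tied items (p = 1, no exception).
    """
    X = np.asarray(intake_items, dtype=float)
    Y = np.asarray(conclusion_items, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("item matrices must be paired and 2-D")
    if variant not in ("signed_rank", "rank_sum"):
        raise ValueError(f"unknown variant {variant!r}")
    rows = []
    for j in range(X.shape[1]):
        if variant == "signed_rank":
            p, degen = _wilcoxon_signed_rank(Y[:, j] - X[:, j])
        else:
            p, degen = _rank_sum(X[:, j], Y[:, j])
        rows.append(
            {
                "item_id": j + 1,
                "mean_intake": X[:, j].mean(),
                "mean_conclusion": Y[:, j].mean(),
                "mean_change": Y[:, j].mean() - X[:, j].mean(),
                "p_raw": p,
                "degenerate": degen,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# correlations and summaries


def pearson_assoc(x, y) -> tuple[float, float]:
    """Product-moment r with two-sided p via t = r·sqrt((n−2)/(1−r²)).

    Perfect correlation reports the p → 0 limit. Constant input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D arrays of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-15:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def summarize_change(intake, conclusion) -> dict:
    """Per-timepoint mean / SD (n−1) / SEM, the mean change, and the number
    of participants whose severity class improved."""
    x = np.asarray(intake, dtype=float)
    y = np.asarray(conclusion, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired arrays with n >= 2")
    n = len(x)
    movers = sum(
        _SEVERITY_ORDER.index(srs2_severity_class(b)) < _SEVERITY_ORDER.index(srs2_severity_class(a))
        for a, b in zip(x, y)
    )
    return {
        "n": n,
        "mean_intake": float(x.mean()),
        "mean_conclusion": float(y.mean()),
        "sd_intake": float(x.std(ddof=1)),
        "sd_conclusion": float(y.std(ddof=1)),
        "sem_intake": float(x.std(ddof=1) / np.sqrt(n)),
        "sem_conclusion": float(y.std(ddof=1) / np.sqrt(n)),
        "mean_change": float(y.mean() - x.mean()),
        "n_class_improved": int(movers),
    }


def yes_fraction(n_yes: int, n_total: int) -> float:
    """Interview tally as a percentage (e.g. 12 of 14 -> 85.7)."""
    if n_total <= 0 or n_yes < 0 or n_yes > n_total:
        raise ValueError("need 0 <= n_yes <= n_total with n_total > 0")
    return 100.0 * n_yes / n_total


def study_compliance(statuses: Sequence[str]) -> dict:
    """Study-level compliance arithmetic from per-family statuses.

    Families who withdrew before home use are excluded from the eligible
    denominator; the rate is compliant / (consented − withdrew) in percent.
    """
    statuses = [str(s) for s in statuses]
    allowed = {"compliant", "completed", "noncompliant", "withdrew"}
    unknown = set(statuses) - allowed
    if unknown:
        raise ValueError(f"unknown statuses: {sorted(unknown)}")
    n = len(statuses)
    n_withdrew = statuses.count("withdrew")
    n_compliant = sum(s in ("compliant", "completed") for s in statuses)
    eligible = n - n_withdrew
    if eligible == 0:
        raise ValueError("no eligible families")
    return {
        "n_consented": n,
        "n_withdrew": n_withdrew,
        "n_eligible": eligible,
        "n_compliant": n_compliant,
        "compliance_rate_percent": 100.0 * n_compliant / eligible,
    }


# ---------------------------------------------------------------------------
# cohort-level orchestration


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    wilcoxon_variant: str = "signed_rank"


_REQUIRED_COLUMNS = (
    ["participant_id", "srs2_total_intake", "srs2_total_conclusion", "egg_intake", "egg_conclusion"]
    + [f"item_{j:02d}_{t}" for j in range(1, 66) for t in ("intake", "conclusion")]
)


def analyze_cohort(cohort, config: AnalysisConfig | None = None) -> dict:
    """Full machine-readable report over a cohort table (path or DataFrame).

    Sections: total and subscale ANOVA, item-level table with the BH column,
    emotion-guessing ANOVA (pairwise-complete rows only), Pearson tests of
    covariates vs improvements, usage summary, and severity transitions.
    """
    from .synthetic import SRS2_SUBSCALES  # column naming shared with the generator

    config = config or AnalysisConfig()
    df = pd.read_csv(cohort) if isinstance(cohort, (str, Path)) else cohort.copy()
    if df.empty:
        raise SchemaError("cohort table is empty")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing[:8]}{'...' if len(missing) > 8 else ''}")
    if "status" in df.columns:
        df = df[df["status"].isin(["completed", "compliant"])].reset_index(drop=True)

    report: dict = {"n_participants": int(len(df)), "alpha": config.alpha}

    anova_rows = {}
    res = rm_anova_two_timepoints(df["srs2_total_intake"], df["srs2_total_conclusion"])
    anova_rows["total"] = res.__dict__ | {"mean_change": res.mean_change}
    for name in SRS2_SUBSCALES:
        ci, cc = f"srs2_{name}_intake", f"srs2_{name}_conclusion"
        if ci in df.columns and cc in df.columns:
            r = rm_anova_two_timepoints(df[ci], df[cc])
            anova_rows[name] = r.__dict__ | {"mean_change": r.mean_change}
    report["srs2_anova"] = anova_rows

    X = df[[f"item_{j:02d}_intake" for j in range(1, 66)]].to_numpy()
    Y = df[[f"item_{j:02d}_conclusion" for j in range(1, 66)]].to_numpy()
    items = wilcoxon_item_tests(X, Y, variant=config.wilcoxon_variant)
    report["item_tests"] = items.to_dict(orient="records")
    report["n_items_significant_raw"] = int((items["p_raw"] < config.alpha).sum())
    report["n_items_significant_adjusted"] = int((items["p_adjusted"] < config.alpha).sum())

    egg = df[["egg_intake", "egg_conclusion"]].dropna()
    if len(egg) >= 2 and (egg["egg_conclusion"] - egg["egg_intake"]).std(ddof=1) > 0:
        r = rm_anova_two_timepoints(egg["egg_intake"], egg["egg_conclusion"])
        report["egg_anova"] = r.__dict__ | {"mean_change": r.mean_change}
    else:
        report["egg_anova"] = None

    srs_improvement = (df["srs2_total_intake"] - df["srs2_total_conclusion"]).to_numpy()
    correlations = {}
    for cov in ("abiq", "n_therapies", "days_at_home"):
        if cov not in df.columns:
            continue
        entry = {}
        try:
            r, p = pearson_assoc(df[cov].to_numpy(dtype=float), srs_improvement)
            entry["srs2"] = {"r": r, "p": p}
        except ValueError as exc:
            entry["srs2"] = {"error": str(exc)}
        sub = df[[cov, "egg_intake", "egg_conclusion"]].dropna()
        if len(sub) >= 3:
            try:
                r, p = pearson_assoc(
                    sub[cov].to_numpy(dtype=float),
                    (sub["egg_conclusion"] - sub["egg_intake"]).to_numpy(),
                )
                entry["egg"] = {"r": r, "p": p}
            except ValueError as exc:
                entry["egg"] = {"error": str(exc)}
        correlations[cov] = entry
    report["correlations"] = correlations

    report["srs2_summary"] = summarize_change(
        df["srs2_total_intake"], df["srs2_total_conclusion"]
    )
    transitions: dict[str, int] = {}
    for a, b in zip(df["srs2_total_intake"], df["srs2_total_conclusion"]):
        key = f"{srs2_severity_class(a)}->{srs2_severity_class(b)}"
        transitions[key] = transitions.get(key, 0) + 1
    report["severity_transitions"] = transitions

    if "usage_min" in df.columns:
        totals = df["usage_min"].to_numpy(dtype=float)
        report["usage"] = {
            "total_min": float(totals.sum()),
            "mean_min": float(totals.mean()),
            "sd_min": float(totals.std(ddof=1)) if len(totals) > 1 else 0.0,
            "max_min": float(totals.max()),
            "min_min": float(totals.min()),
        }
    return report


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "p < .001"
    if p < 0.01:
        return f"p = {p:.3f}"
    return f"p = {p:.3f}"


def write_report(report: dict, outdir) -> None:
    """Persist report.json plus a human-readable report.md."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))

    lines = [
        "# Cohort outcome report",
        "",
        f"Participants analyzed: {report['n_participants']}",
        "",
        "## SRS-2 repeated-measures ANOVA (intake vs conclusion)",
        "",
        "| scale | intake mean (SD) | conclusion mean (SD) | F(df1,df2) | sig. |",
        "|---|---|---|---|---|",
    ]
    for name, r in report["srs2_anova"].items():
        lines.append(
            f"| {name} | {r['mean_intake']:.2f} ({r['sd_intake']:.2f}) "
            f"| {r['mean_conclusion']:.2f} ({r['sd_conclusion']:.2f}) "
            f"| F({r['df1']},{r['df2']}) = {r['F']:.2f} | {_fmt_p(r['p'])} |"
        )
    if report.get("egg_anova"):
        r = report["egg_anova"]
        lines += [
            "",
            "## Emotion-guessing game",
            "",
            f"n = {r['n']}: {r['mean_intake']:.2f} ({r['sd_intake']:.2f}) -> "
            f"{r['mean_conclusion']:.2f} ({r['sd_conclusion']:.2f}), "
            f"F({r['df1']},{r['df2']}) = {r['F']:.3f}, {_fmt_p(r['p'])}",
        ]
    lines += [
        "",
        "## Item-level tests",
        "",
        f"{report['n_items_significant_raw']} of 65 items nominally significant; "
        f"{report['n_items_significant_adjusted']} after Benjamini-Hochberg correction.",
    ]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
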