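"""Coefficient-of-variation reproducibility analysis.

The reproducibility metric is the coefficient of variation (COV): the sample
standard deviation normalized to the mean.  A feature with COV <= 10% is
rated *stable*.  Two study designs are supported:

* clinical — each subject imaged once at an individually chosen FOV; one COV
  per feature across all subjects;
* experimental — every subject imaged at each FOV; one COV per (subject,
  feature) across that subject's FOVs, and a feature counts as reproducible
  only when it is stable for every subject.

Undefined feature values (degenerate regions/tiles) are excluded from the
COV and the used sample size is reported; a COV whose mean is numerically
zero is flagged missing rather than reported as an arbitrarily large number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ALL_FEATURES

__all__ = [
    "STABILITY_THRESHOLD",
    "cov",
    "classify_stable",
    "make_feature_table",
    "clinical_design_covs",
    "experimental_design_covs",
    "compare_methods",
    "relative_increase_pct",
    "ReproducibilityReport",
    "ComparisonSummary",
]

#: "COVs up to 10% rated stable": threshold inclusive.
STABILITY_THRESHOLD = 0.10

_MEAN_TOL = 1e-12


def cov(values) -> float:
    """Sample (n-1) standard deviation divided by |mean|.

    Returns NaN (undefined) when the mean is numerically zero relative to the
    data scale; raises on fewer than two finite values.
    """
    v = np.asarray(list(values), dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("cov requires at least 2 finite values")
    scale = np.abs(v).max()
    if scale == 0.0:
        return 0.0
    mean = v.mean()
    if abs(mean) < _MEAN_TOL * scale:
        return float("nan")
    return float(v.std(ddof=1) / abs(mean))


def classify_stable(cov_value: float, threshold: float = STABILITY_THRESHOLD) -> bool:
    """Stable iff cov <= threshold; an undefined COV is never stable."""
    if not np.isfinite(cov_value):
        return False
    return bool(cov_value <= threshold)


def make_feature_table(rows) -> pd.DataFrame:
    """Assemble extraction rows into a tidy feature table.

    Each row is a mapping with ``subject_id``, ``fov_label``, ``method``
    (``conventional`` or ``map``) plus the 93 feature values (NaN encodes an
    undefined value).  Duplicate (subject, fov, method) rows are rejected.
    """
    df = pd.DataFrame(list(rows))
    key = ["subject_id", "fov_label", "method"]
    missing_cols = [c for c in key + list(ALL_FEATURES) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"feature table is missing columns: {missing_cols[:5]} ...")
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (subject_id, fov_label, method) rows")
    return df[key + list(ALL_FEATURES)]


@dataclass(frozen=True)
class ReproducibilityReport:
    """Per-feature COVs and stability verdicts for one method and design.

    ``cov_table`` is tidy: one row per COV (per feature, and per subject in
    the experimental design) with columns ``feature``, ``subject_id`` (NaN
    for the clinical design), ``cov``, ``stable``, ``missing``, ``n_used``.
    ``per_feature`` carries one verdict row per catalog feature.
    """

    design: str
    method: str
    threshold: float
    cov_table: pd.DataFrame
    per_feature: pd.DataFrame

    @property
    def stable_count(self) -> int:
        return int(self.per_feature["stable"].sum())

    @property
    def missing_count(self) -> int:
        return int(self.per_feature["missing"].sum())

    @property
    def n_covs(self) -> int:
        return len(self.cov_table)

    def counts_are_exhaustive(self) -> bool:
        """stable + unstable + missing partitions the catalog."""
        pf = self.per_feature
        n_unstable = int((~pf["stable"] & ~pf["missing"]).sum())
        return self.stable_count + n_unstable + self.missing_count == len(pf)


def _cov_row(series: pd.Series, threshold: float) -> dict:
    vals = series.to_numpy(dtype=np.float64)
    finite = vals[np.isfinite(vals)]
    n_used = int(finite.size)
    if n_used < 2:
        return {"cov": float("nan"), "stable": False, "missing": True, "n_used": n_used}
    c = cov(finite)
    missing = not np.isfinite(c)
    return {
        "cov": c,
        "stable": classify_stable(c, threshold),
        "missing": missing,
        "n_used": n_used,
    }


def clinical_design_covs(
    table: pd.DataFrame, method: str, threshold: float = STABILITY_THRESHOLD
) -> ReproducibilityReport:
    """One COV per feature across all subjects (one FOV per subject)."""
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValueError(f"no rows for method {method!r}")
    if sub.groupby("subject_id").size().max() > 1:
        raise ValueError("clinical design expects exactly one image per subject")
    if len(sub) < 2:
        raise ValueError("clinical design COVs require at least 2 subjects")

    rows = []
    for feat in ALL_FEATURES:
        r = _cov_row(sub[feat], threshold)
        r.update({"feature": feat, "subject_id": float("nan")})
        rows.append(r)
    cov_table = pd.DataFrame(rows)[
        ["feature", "subject_id", "cov", "stable", "missing", "n_used"]
    ]
    per_feature = cov_table.set_index("feature")[["cov", "stable", "missing"]].copy()
    return ReproducibilityReport(
        design="clinical",
        method=method,
        threshold=threshold,
        cov_table=cov_table,
        per_feature=per_feature,
    )


def experimental_design_covs(
    table: pd.DataFrame, method: str, threshold: float = STABILITY_THRESHOLD
) -> ReproducibilityReport:
    """One COV per (subject, feature) across FOVs; a feature is reproducible
    only when stable for every subject."""
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValueError(f"no rows for method {method!r}")
    fovs_per_subject = sub.groupby("subject_id")["fov_label"].nunique()
    if (fovs_per_subject < 2).any():
        raise ValueError("experimental design requires >= 2 FOVs per subject")

    rows = []
    for sid, grp in sub.groupby("subject_id", sort=True):
        for feat in ALL_FEATURES:
            r = _cov_row(grp[feat], threshold)
            r.update({"feature": feat, "subject_id": sid})
            rows.append(r)
    cov_table = pd.DataFrame(rows)[
        ["feature", "subject_id", "cov", "stable", "missing", "n_used"]
    ]

    per = cov_table.groupby("feature", sort=False)
    per_feature = pd.DataFrame(
        {
            "cov": per["cov"].max(),  # worst subject, for reporting
            "stable": per.apply(
                lambda g: bool((g["stable"] & ~g["missing"]).all()),
                include_groups=False,
            ),
            "missing": per["missing"].all(),
        }
    ).reindex(ALL_FEATURES)
    return ReproducibilityReport(
        design="experimental",
        method=method,
        threshold=threshold,
        cov_table=cov_table,
        per_feature=per_feature,
    )


def relative_increase_pct(count_before: int, count_after: int) -> float:
    """Relative increase of a stable-feature count, as a percentage."""
    if count_before <= 0:
        raise ValueError("count_before must be positive")
    return 100.0 * (count_after - count_before) / count_before


@dataclass(frozen=True)
class ComparisonSummary:
    """Conventional-vs-map comparison for one design and cohort."""

    design: str
    threshold: float
    stable_conventional: int
    stable_map: int
    improved: int  # features whose matched COVs decreased on average
    crossed_to_stable: int  # unstable conventionally, stable from maps
    relative_increase_pct: float
    n_covs_per_method: int
    frac_covs_stable_conventional: float
    frac_covs_stable_map: float

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "threshold": self.threshold,
            "stable_conventional": self.stable_conventional,
            "stable_map": self.stable_map,
            "improved": self.improved,
            "crossed_to_stable": self.crossed_to_stable,
            "relative_increase_pct": self.relative_increase_pct,
            "n_covs_per_method": self.n_covs_per_method,
            "frac_covs_stable_conventional": self.frac_covs_stable_conventional,
            "frac_covs_stable_map": self.frac_covs_stable_map,
        }


def compare_methods(
    report_conv: ReproducibilityReport, report_map: ReproducibilityReport
) -> ComparisonSummary:
    """Count stability gains of parametric-map over conventional extraction."""
    if report_conv.design != report_map.design:
        raise ValueError("reports come from different study designs")
    if report_conv.threshold != report_map.threshold:
        raise ValueError("reports use different stability thresholds")

    key = ["feature", "subject_id"]
    merged = report_conv.cov_table.merge(
        report_map.cov_table, on=key, suffixes=("_conv", "_map"), how="inner"
    )
    if len(merged) != len(report_conv.cov_table):
        raise ValueError("reports cover different cohorts")

    both = merged.dropna(subset=["cov_conv", "cov_map"])
    # Feature-level improvement: mean matched COV decreased.
    by_feat = both.groupby("feature")[["cov_conv", "cov_map"]].mean()
    improved = int((by_feat["cov_map"] < by_feat["cov_conv"]).sum())

    pf_conv = report_conv.per_feature["stable"]
    pf_map = report_map.per_feature["stable"]
    crossed = int((~pf_conv & pf_map).sum())

    stable_conv = report_conv.stable_count
    stable_map = report_map.stable_count
    rel = relative_increase_pct(stable_conv, stable_map) if stable_conv > 0 else float("nan")

    defined_conv = report_conv.cov_table["cov"].notna()
    defined_map = report_map.cov_table["cov"].notna()
    frac_conv = float(
        report_conv.cov_table["stable"].sum() / max(int(defined_conv.count()), 1)
    )
    frac_map = float(
        report_map.cov_table["stable"].sum() / max(int(defined_map.count()), 1)
    )

    return ComparisonSummary(
        design=report_conv.design,
        threshold=report_conv.threshold,
        stable_conventional=stable_conv,
        stable_map=stable_map,
        improved=improved,
        crossed_to_stable=crossed,
        relative_increase_pct=rel,
        n_covs_per_method=len(report_conv.cov_table),
        frac_covs_stable_conventional=frac_conv,
        frac_covs_stable_map=frac_map,
    )


def plot_paired_covs(
    report_conv: ReproducibilityReport,
    report_map: ReproducibilityReport,
    out_path: str,
    features=None,
) -> None:
    """Line plot of paired per-feature COVs (conventional vs map)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pf_c = report_conv.per_feature["cov"]
    pf_m = report_map.per_feature["cov"]
    feats = list(features) if features is not None else list(pf_c.index)
    x = np.arange(len(feats))
    fig, ax = plt.subplots(figsize=(max(6, len(feats) * 0.25), 4))
    ax.plot(x, pf_c.loc[feats].to_numpy(), color="0.3", marker="o", label="conventional")
    ax.plot(x, pf_m.loc[feats].to_numpy(), color="0.7", marker="o", label="parametric map")
    ax.axhline(report_conv.threshold, ls=":", color="k", lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels(feats, rotation=90, fontsize=6)
    ax.set_ylabel("COV")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
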