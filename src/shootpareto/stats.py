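"""Genotype-level statistics over per-replicate feature records.

Variability is measured by the coefficient of variation (sample SD over
mean); genotype-vs-wildtype comparisons use the two-sample Kolmogorov–
Smirnov test with a Bonferroni-corrected threshold; plant-vs-baseline
front-distance comparisons use a one-sided binomial test where a "success"
is a baseline draw landing closer to the front than the plant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .skeleton import FeatureRecord

__all__ = [
    "FEATURE_COLUMNS",
    "GenotypeEnsemble",
    "ComparisonResult",
    "coefficient_of_variation",
    "ks_vs_wildtype",
    "binomial_front_test",
    "ensemble_summary",
    "cov_comparison",
]

#: Table column order: trade-off first, then the raw traits.
FEATURE_COLUMNS = [
    "tradeoff",
    "epsilon",
    "alpha_closest",
    "total_length",
    "travel_distance",
    "n_rosette",
    "n_branch_points",
    "hull_volume",
]


@dataclass
class GenotypeEnsemble:
    """All replicate feature records for one genotype."""

    genotype: str
    records: list[FeatureRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("an ensemble needs at least one record")

    @property
    def n_replicates(self) -> int:
        return len(self.records)

    def feature(self, name: str) -> np.ndarray:
        return np.asarray([r.as_dict()[name] for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.records])
        df.insert(0, "genotype", self.genotype)
        return df


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one hypothesis test on one feature."""

    feature: str
    statistic: float
    p_value: float
    adjusted_threshold: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted_threshold": self.adjusted_threshold,
            "significant": self.significant,
        }


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n−1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CoV needs at least two values")
    mean = x.mean()
    if mean == 0.0:
        raise ValueError("CoV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def ks_vs_wildtype(
    wt, mutant, n_comparisons: int, feature: str = ""
) -> ComparisonResult:
    """Two-sample two-sided KS test with a Bonferroni-adjusted threshold.

    ``n_comparisons`` is the number of mutants tested against the wildtype
    (the adjusted threshold is 0.05 / n_comparisons); it is an explicit
    argument, never inferred.
    """
    wt = np.asarray(wt, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if wt.size < 2 or mutant.size < 2:
        raise ValueError("both samples need at least two values")
    res = sps.ks_2samp(wt, mutant, alternative="two-sided", method="auto")
    threshold = 0.05 / n_comparisons
    return ComparisonResult(
        feature=feature,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        adjusted_threshold=threshold,
        significant=bool(res.pvalue < threshold),
    )


def binomial_front_test(
    plant_eps, baseline_eps, feature: str = "epsilon"
) -> ComparisonResult:
    """One-sided binomial test that the plant out-scores its baseline.

    A success is a paired baseline draw with a strictly smaller front
    distance than the plant (ties count against the plant, i.e. as
    non-successes); under the null each pair is a fair coin, and the
    alternative is that successes are rare (the plant is closer to the
    front).
    """
    plant_eps = np.asarray(plant_eps, dtype=float)
    baseline_eps = np.asarray(baseline_eps, dtype=float)
    if plant_eps.shape != baseline_eps.shape:
        raise ValueError("paired samples must have equal length")
    k = int(np.sum(baseline_eps < plant_eps))
    n = plant_eps.size
    res = sps.binomtest(k, n, p=0.5, alternative="less")
    return ComparisonResult(
        feature=feature,
        statistic=float(k),
        p_value=float(res.pvalue),
        adjusted_threshold=0.05,
        significant=bool(res.pvalue < 0.05),
    )


def ensemble_summary(ensemble: GenotypeEnsemble) -> pd.Series:
    """Mean ± sample SD per feature, one formatted table row.

    Single-replicate ensembles report SD = 0 by convention.
    """
    row: dict[str, object] = {
        "genotype": f"{ensemble.genotype} ({ensemble.n_replicates})"
    }
    for col in FEATURE_COLUMNS:
        x = ensemble.feature(col)
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        row[col] = f"{x.mean():.3f} ± {sd:.3f}"
        row[f"{col}_mean"] = float(x.mean())
        row[f"{col}_sd"] = sd
    return pd.Series(row)


def cov_comparison(
    ensembles: list[GenotypeEnsemble],
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Coefficient of variation per (genotype × feature).

    Works equally for replicate ensembles (variability across plants of one
    genotype) and for time-series "ensembles" whose records are the same
    plant at successive time points (variability through growth).
    """
    features = features or FEATURE_COLUMNS
    rows = {}
    for ens in ensembles:
        if ens.n_replicates < 2:
            raise ValueError(
                f"ensemble {ens.genotype!r} needs >= 2 records for CoV"
            )
        rows[ens.genotype] = {
            f: coefficient_of_variation(ens.feature(f)) for f in features
        }
    return pd.DataFrame.from_dict(rows, orient="index")[features]
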