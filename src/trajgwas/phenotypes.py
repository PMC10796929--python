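"""Cognitive-score preparation and the piecewise-linear trajectory design.

Raw test scores are z-standardised against the baseline (day-0) mean and
sample SD of each test; domain scores average the z-scores of their
component tests and the global composite averages the five domain scores.
The trajectory design encodes a two-slope linear spline with a single knot
(default day 365): an intercept, baseline age centred at a reference
(years), time from baseline to the knot (``s1``) and time past the knot
(``s2``), both expressed in years so slope coefficients read as change in
z-units per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeStandardizer",
    "fit_standardizer",
    "apply_standardizer",
    "domain_score",
    "composite_score",
    "build_trajectory_basis",
    "load_domain_map",
    "DEFAULT_DOMAIN_MAP",
]


def load_domain_map(path) -> dict:
    """Read a {domain: [test_id, ...]} map from YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not all(isinstance(v, list) for v in raw.values()):
        raise ValueError("domain map must be a mapping of domain -> list of test ids")
    return {str(k): [str(t) for t in v] for k, v in raw.items()}

#: Five cognitive domains with synthetic component tests (two per domain).
#: Real batteries supply their own map, e.g. from a YAML file.
DEFAULT_DOMAIN_MAP = {
    "attention": ["attention_1", "attention_2"],
    "executive": ["executive_1", "executive_2"],
    "memory": ["memory_1", "memory_2"],
    "learning": ["learning_1", "learning_2"],
    "language": ["language_1", "language_2"],
}


@dataclass
class PhenotypeStandardizer:
    """Per-test baseline mean and SD, fitted on day-0 rows only."""

    params: pd.DataFrame  # index test_id, columns baseline_mean, baseline_sd
    n_baseline: pd.Series = field(default=None)

    def scale_factor(self, tests=None) -> float:
        """Mean of 1/SD over tests: converts a raw-unit effect shared by all
        component tests into its size on the averaged z-score scale."""
        sd = self.params["baseline_sd"]
        if tests is not None:
            sd = sd.loc[list(tests)]
        return float((1.0 / sd).mean())


def fit_standardizer(phenotypes: pd.DataFrame) -> PhenotypeStandardizer:
    """Fit baseline mean/SD per test from ``time_days == 0`` rows.

    Uses the sample (n-1) SD. A test whose baseline scores are constant
    (SD 0) cannot be standardised; the error names every offending test.
    """
    base = phenotypes.loc[phenotypes["time_days"] == 0]
    if base.empty:
        raise ValueError("no baseline (time_days == 0) rows to standardise against")
    grp = base.groupby("test_id")["score"]
    params = pd.DataFrame({"baseline_mean": grp.mean(), "baseline_sd": grp.std(ddof=1)})
    counts = grp.count()
    bad = params.index[(counts < 2) | ~(params["baseline_sd"] > 0)].tolist()
    if bad:
        raise ValueError(
            "cannot standardise tests with constant or single-value baseline: "
            + ", ".join(map(str, bad))
        )
    return PhenotypeStandardizer(params=params, n_baseline=counts)


def apply_standardizer(
    standardizer: PhenotypeStandardizer, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Return a copy with a ``z`` column; all visits use baseline parameters."""
    out = phenotypes.copy()
    mean = out["test_id"].map(standardizer.params["baseline_mean"])
    sd = out["test_id"].map(standardizer.params["baseline_sd"])
    if mean.isna().any():
        missing = sorted(out.loc[mean.isna(), "test_id"].unique())
        raise KeyError(f"tests not seen at baseline: {missing}")
    out["z"] = (out["score"] - mean) / sd
    return out


def _mean_over(df: pd.DataFrame, value_col: str, label_col: str, label: str) -> pd.DataFrame:
    kept = df.dropna(subset=[value_col])
    out = (
        kept.groupby(["subject_id", "time_days"], as_index=False)[value_col]
        .mean()
        .rename(columns={value_col: "z"})
    )
    out[label_col] = label
    return out


def domain_score(z_rows: pd.DataFrame, domain_map: dict | None = None) -> pd.DataFrame:
    """Average available component z-scores within each domain.

    Missing components are simply left out of the mean (available-case
    averaging); a (subject, time, domain) cell with no non-missing
    component is omitted and logged.
    """
    domain_map = DEFAULT_DOMAIN_MAP if domain_map is None else domain_map
    pieces = []
    for domain, tests in domain_map.items():
        sub = z_rows.loc[z_rows["test_id"].isin(tests)]
        n_cells = sub.groupby(["subject_id", "time_days"]).size().shape[0]
        scored = _mean_over(sub, "z", "domain", domain)
        if len(scored) < n_cells:
            logger.info(
                "domain %s: %d subject-time cells dropped (all components missing)",
                domain,
                n_cells - len(scored),
            )
        pieces.append(scored)
    return pd.concat(pieces, ignore_index=True)


def composite_score(domain_rows: pd.DataFrame) -> pd.DataFrame:
    """Global composite: unweighted mean of the available domain scores."""
    out = _mean_over(domain_rows, "z", "domain", "global")
    return out


def build_trajectory_basis(
    time_days,
    baseline_age,
    knot_days: float = 365.0,
    age_ref: float | None = None,
) -> pd.DataFrame:
    """Design columns of the two-slope spline model.

    Returns a DataFrame with ``intercept``, ``age_c`` (baseline age minus
    ``age_ref``, years), ``s1 = min(t, knot)/365`` and
    ``s2 = max(t - knot, 0)/365`` (years), so that
    ``365*(s1 + s2) == t`` for every non-negative t.
    """
    t = np.asarray(time_days, dtype=float)
    age = np.asarray(baseline_age, dtype=float)
    if np.any(t < 0):
        raise ValueError("time_days must be non-negative")
    if knot_days <= 0:
        raise ValueError("knot_days must be positive")
    if age_ref is None:
        age_ref = float(np.mean(age))
    return pd.DataFrame(
        {
            "intercept": np.ones_like(t),
            "age_c": age - age_ref,
            "s1": np.minimum(t, knot_days) / 365.0,
            "s2": np.maximum(t - knot_days, 0.0) / 365.0,
        }
    )
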