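"""Two-sample statistics on score distributions between patient groups.

Provides the Kolmogorov-Smirnov two-sample test, a bootstrap
difference-in-means test whose p-value is floored at 1/n_boot and reported
as "< 1/n_boot" when no resample crosses zero, and the ER/PR
concordance-discordance accounting with per-cell classifier confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoSampleResult",
    "ConcordanceTable",
    "ks_two_sample",
    "bootstrap_mean_diff",
    "permutation_mean_diff",
    "concordance_report",
    "compare_groups_table",
]


@dataclass
class TwoSampleResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    n_boot: int | None = None
    seed: int | None = None
    p_label: str = ""

    def __post_init__(self) -> None:
        if not self.p_label:
            self.p_label = f"{self.p_value:.3g}"


@dataclass
class ConcordanceTable:
    """ER x PR status cross-tabulation with per-cell mean confidence."""

    counts: pd.DataFrame
    concordant_fraction: float
    mean_confidence: pd.DataFrame
    ks_p_by_status: dict = field(default_factory=dict)
    n_dropped: int = 0


def _as_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    return x


def ks_two_sample(sample_a, sample_b) -> TwoSampleResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|.

    Uses the exact null distribution for small samples (n_a * n_b <= 100)
    and the asymptotic one otherwise.
    """
    a, b = _as_sample(sample_a), _as_sample(sample_b)
    method = "exact" if a.size * b.size <= 100 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return TwoSampleResult(
        statistic_name="ks_D",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
    )


def bootstrap_mean_diff(
    sample_a, sample_b, n_boot: int = 100_000, seed: int = 0
) -> TwoSampleResult:
    """Bootstrap test of the difference in group means.

    Each group is resampled with replacement independently ``n_boot``
    times; the two-sided p-value is twice the smaller tail fraction of the
    resampled mean difference crossing zero, clamped to [1/n_boot, 1].
    When no resample crosses zero the p-value is reported as "< 1/n_boot".
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    a, b = _as_sample(sample_a), _as_sample(sample_b)
    rng = np.random.default_rng(seed)
    # vectorized resampling in blocks to bound memory
    block = max(1, int(5e6 / (a.size + b.size)))
    deltas = np.empty(n_boot)
    for start in range(0, n_boot, block):
        m = min(block, n_boot - start)
        ma = a[rng.integers(0, a.size, size=(m, a.size))].mean(axis=1)
        mb = b[rng.integers(0, b.size, size=(m, b.size))].mean(axis=1)
        deltas[start : start + m] = ma - mb
    frac_le = float((deltas <= 0).mean())
    frac_ge = float((deltas >= 0).mean())
    raw = 2.0 * min(frac_le, frac_ge)
    p = min(max(raw, 1.0 / n_boot), 1.0)
    label = f"< {1.0 / n_boot:g}" if raw < 1.0 / n_boot else f"{p:.3g}"
    return TwoSampleResult(
        statistic_name="delta_mean",
        statistic=float(a.mean() - b.mean()),
        p_value=p,
        n_a=a.size,
        n_b=b.size,
        n_boot=n_boot,
        seed=seed,
        p_label=label,
    )


def permutation_mean_diff(
    sample_a, sample_b, n_perm: int = 100_000, seed: int = 0
) -> TwoSampleResult:
    """Permutation-test alternative to :func:`bootstrap_mean_diff`."""
    a, b = _as_sample(sample_a), _as_sample(sample_b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    count = 0
    block = max(1, int(5e6 / pooled.size))
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        idx = np.argsort(rng.random((m, pooled.size)), axis=1)
        perm = pooled[idx]
        deltas = perm[:, : a.size].mean(axis=1) - perm[:, a.size :].mean(axis=1)
        count += int((np.abs(deltas) >= abs(observed) - 1e-12).sum())
        done += m
    p = max((count + 1) / (n_perm + 1), 1.0 / n_perm)
    return TwoSampleResult(
        statistic_name="delta_mean",
        statistic=float(observed),
        p_value=min(p, 1.0),
        n_a=a.size,
        n_b=b.size,
        n_boot=n_perm,
        seed=seed,
    )


def concordance_report(
    er_labels, pr_labels, confidences=None
) -> ConcordanceTable:
    """Cross-tabulate paired ER/PR status and classifier confidence.

    Concordant patients carry the same sign for both receptors (both
    positive or both negative).  When per-patient classifier confidences
    are supplied, the mean confidence is reported per (status, concordance)
    cell and a KS test compares concordant vs discordant confidences
    within each status column; degenerate columns are flagged NaN.
    """
    er = pd.Series(er_labels).reset_index(drop=True)
    pr = pd.Series(pr_labels).reset_index(drop=True)
    if len(er) != len(pr):
        raise ValueError("ER and PR label vectors must be paired")
    valid = er.notna() & pr.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} patients with unpaired labels",
                      stacklevel=2)
    er, pr = er[valid], pr[valid]
    conf = None
    if confidences is not None:
        conf = pd.Series(confidences).reset_index(drop=True)[valid]

    counts = pd.crosstab(er, pr).reindex(
        index=sorted(er.unique()), columns=sorted(pr.unique()), fill_value=0
    )
    counts.index.name, counts.columns.name = "ER", "PR"
    concordant = (er == pr).to_numpy()
    frac = float(concordant.mean()) if len(er) else float("nan")

    mean_conf = pd.DataFrame(
        index=["concordant", "discordant"], columns=sorted(er.unique()),
        dtype=float,
    )
    ks_p: dict = {}
    if conf is not None:
        for status in mean_conf.columns:
            in_status = (er == status).to_numpy()
            c = conf[in_status & concordant]
            d = conf[in_status & ~concordant]
            mean_conf.loc["concordant", status] = c.mean() if len(c) else np.nan
            mean_conf.loc["discordant", status] = d.mean() if len(d) else np.nan
            if len(c) and len(d):
                ks_p[status] = ks_two_sample(c, d).p_value
            else:
                ks_p[status] = float("nan")
    return ConcordanceTable(
        counts=counts,
        concordant_fraction=frac,
        mean_confidence=mean_conf,
        ks_p_by_status=ks_p,
        n_dropped=n_dropped,
    )


def compare_groups_table(
    scores: pd.DataFrame,
    score_columns: list,
    group_column: str,
    n_boot: int = 100_000,
    seed: int = 0,
    ordinal_level_limit: int = 5,
) -> pd.DataFrame:
    """KS and bootstrap Δmean p-values for each score across two groups.

    Discontinuous ordinal scores (at most ``ordinal_level_limit`` distinct
    values, e.g. pathologic stage) are refused by the KS test (reported
    n/a); the bootstrap mean-difference test still runs.
    """
    groups = sorted(scores[group_column].dropna().unique())
    if len(groups) != 2:
        raise ValueError("group column must have exactly two levels")
    rows = []
    for i, col in enumerate(score_columns):
        a = scores.loc[scores[group_column] == groups[0], col].dropna()
        b = scores.loc[scores[group_column] == groups[1], col].dropna()
        n_levels = pd.concat([a, b]).nunique()
        if n_levels <= ordinal_level_limit:
            ks_label = "n/a"
        else:
            ks_label = ks_two_sample(a, b).p_label
        boot = bootstrap_mean_diff(a, b, n_boot=n_boot, seed=seed + i)
        rows.append({
            "score": col,
            "ks_p": ks_label,
            "bootstrap_delta_mean_p": boot.p_label,
            "delta_mean": boot.statistic,
        })
    return pd.DataFrame(rows)
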