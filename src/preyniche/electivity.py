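"""Prey selection: Vanderploeg-Scavia electivity and Neu-style chi-square tests.

The electivity index E* compares a taxon's proportion in the diet (r) with its
proportion in the environment (p):

    E* = (r - p) / (r + p - 2 r p)

ranging from -1 (total avoidance) through 0 (use proportional to availability)
to +1 (exclusive preference). Following common stomach-content practice, E* is
not computed for taxa whose total dietary count at a site falls below a
minimum (default 10 items summed over both predator species).

Statistical significance of selection uses the classical resource-selection
recipe: a chi-square goodness-of-fit test of observed diet counts against
expected counts proportional to availability, followed by 95% simultaneous
Bonferroni confidence intervals on the usage proportions; availability falling
below/above a taxon's interval indicates significant preference/avoidance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AbundanceTable, ValidationError
from .prey_metrics import UtilizationProfile, make_profile, profile_from_counts

NOT_COMPUTED = float("nan")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed report tables."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def electivity_index(r: float, p: float) -> float:
    """Vanderploeg-Scavia E* for one food category.

    ``r`` and ``p`` are the diet and availability proportions. Returns NaN
    when both are zero (electivity undefined); +1 when the taxon is eaten but
    absent from the environment; -1 when available but never eaten.
    """
    if not (0 <= r <= 1 and 0 <= p <= 1):
        raise ValidationError(f"proportions must lie in [0, 1]; got r={r}, p={p}")
    if r == 0 and p == 0:
        return NOT_COMPUTED
    num = r - p
    if num == 0:
        return 0.0
    # clamp against float round-off at the +/-1 endpoints
    return float(np.clip(num / (r + p - 2 * r * p), -1.0, 1.0))


def inclusion_mask(
    table: AbundanceTable, min_total: float = 10, basis: str = "count"
) -> pd.Series:
    """Which taxa clear the minimum total dietary frequency for E*.

    Sums N (``basis='count'``) or Freq (``basis='freq'``) over every stomach
    group in the table — i.e. over both predator species at the site — and
    flags taxa whose total is at least ``min_total``.
    """
    if basis not in ("count", "freq"):
        raise ValidationError(f"basis must be 'count' or 'freq', got {basis!r}")
    groups = table.stomach_groups()
    total = pd.Series(0.0, index=table.taxa)
    for g in groups:
        total = total + (table.counts(g) if basis == "count" else table.freqs(g))
    return total >= min_total


@dataclass(frozen=True)
class ChiSquareSelection:
    """Goodness-of-fit of diet counts against availability-proportional use."""

    statistic: float
    df: int
    pvalue: float
    taxa: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    residuals: np.ndarray
    dropped: tuple[str, ...] = ()


def chisq_selection_test(
    observed_counts: Sequence[float] | pd.Series,
    availability: UtilizationProfile | Sequence[float],
    taxa: Sequence[str] | None = None,
) -> ChiSquareSelection:
    """Chi-square test of observed diet counts vs expected from availability.

    Expected counts are ``n * p_i`` with the availability proportions
    renormalized over the tested taxa so that expectations sum to n. Taxa with
    zero availability cannot contribute an expected count and are dropped
    (their selection is instead read from E* = +1).
    """
    if isinstance(observed_counts, pd.Series):
        taxa = list(observed_counts.index) if taxa is None else list(taxa)
        observed = observed_counts.to_numpy(dtype=float)
    else:
        observed = np.asarray(observed_counts, dtype=float)
        taxa = [str(i) for i in range(observed.size)] if taxa is None else list(taxa)
    if isinstance(availability, UtilizationProfile):
        avail = np.asarray([availability[t] for t in taxa], dtype=float)
    else:
        avail = np.asarray(availability, dtype=float)
    if observed.shape != avail.shape:
        raise ValidationError("observed and availability have different lengths")
    if observed.sum() <= 0:
        raise ValidationError("no observed items to test")

    keep = avail > 0
    dropped = tuple(t for t, k in zip(taxa, keep) if not k)
    observed_k = observed[keep]
    avail_k = avail[keep] / avail[keep].sum()
    n = observed_k.sum()
    expected = n * avail_k
    residuals = (observed_k - expected) / np.sqrt(expected)
    statistic = float(np.sum(residuals**2))
    df = int(observed_k.size - 1)
    pvalue = float(stats.chi2.sf(statistic, df)) if df > 0 else float("nan")
    return ChiSquareSelection(
        statistic,
        df,
        pvalue,
        tuple(t for t, k in zip(taxa, keep) if k),
        observed_k,
        expected,
        residuals,
        dropped,
    )


def bonferroni_intervals(
    observed_counts: Sequence[float] | pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Simultaneous (1 - alpha) Bonferroni confidence intervals on usage.

    For k tested taxa each interval is
    ``p_hat_i +/- z_{1 - alpha/(2k)} * sqrt(p_hat_i (1 - p_hat_i) / n)``,
    clipped to [0, 1]. A taxon never observed gets the degenerate interval
    [0, 0].
    """
    if isinstance(observed_counts, pd.Series):
        taxa = list(observed_counts.index)
        observed = observed_counts.to_numpy(dtype=float)
    else:
        observed = np.asarray(observed_counts, dtype=float)
        taxa = [str(i) for i in range(observed.size)]
    k = observed.size
    if k == 0:
        raise ValidationError("no taxa to build intervals for")
    n = observed.sum()
    if n <= 0:
        raise ValidationError("no observed items")
    z = stats.norm.ppf(1 - alpha / (2 * k))
    phat = observed / n
    half = z * np.sqrt(phat * (1 - phat) / n)
    return pd.DataFrame(
        {
            "p_hat": phat,
            "ci_low": np.clip(phat - half, 0.0, 1.0),
            "ci_high": np.clip(phat + half, 0.0, 1.0),
        },
        index=taxa,
    )


@dataclass
class ElectivityResult:
    """Per-taxon electivity and selection inference for one diet group.

    ``per_taxon`` columns: r (diet proportion), p (availability), estar,
    included (cleared the minimum dietary total), reason (why excluded),
    residual (Pearson, NaN for untested taxa), ci_low/ci_high (Bonferroni on
    usage), verdict (preferred | avoided | proportional | not_testable).
    """

    group: str
    environment_group: str
    per_taxon: pd.DataFrame
    chi2: ChiSquareSelection | None
    alpha: float
    min_total: float
    basis: str

    def report(self, ndigits: int = 2) -> pd.DataFrame:
        """Report-table view with half-up rounding, as in printed diet tables."""
        out = self.per_taxon.copy()
        for col in ("r", "p", "estar", "residual", "ci_low", "ci_high"):
            out[col] = out[col].map(lambda x: round_half_up(x, ndigits))
        return out


def selection_analysis(
    table: AbundanceTable,
    group: str,
    environment_group: str | None = None,
    min_total: float = 10,
    basis: str = "count",
    alpha: float = 0.05,
    include_unidentified: bool = False,
) -> ElectivityResult:
    """Full prey-selection analysis of one diet group against availability.

    Computes diet and availability proportions over identified prey, E* for
    every taxon clearing the dietary-total threshold (summed across all
    stomach groups in the table), the chi-square goodness-of-fit test over the
    included taxa present in the environment, and Bonferroni intervals with
    selection verdicts.
    """
    if environment_group is None:
        envs = table.environment_groups()
        if len(envs) != 1:
            raise ValidationError(
                "environment_group must be given when the table has "
                f"{len(envs)} environment groups"
            )
        environment_group = envs[0]
    diet = make_profile(table, group, "count", include_unidentified)
    avail = make_profile(table, environment_group, "count", include_unidentified)
    mask = inclusion_mask(table, min_total, basis)

    taxa = list(diet.taxa)
    r = diet.proportions
    p = np.asarray([avail[t] for t in taxa])
    included = np.asarray([bool(mask[t]) for t in taxa])

    estar = np.full(len(taxa), NOT_COMPUTED)
    for i, t in enumerate(taxa):
        if included[i] and not (r[i] == 0 and p[i] == 0):
            estar[i] = electivity_index(r[i], p[i])

    counts = np.asarray([diet.denominator * ri for ri in r])
    test_sel = included & (p > 0)
    chi2 = None
    residual = np.full(len(taxa), NOT_COMPUTED)
    if test_sel.sum() >= 2:
        chi2 = chisq_selection_test(
            counts[test_sel], p[test_sel] / p[test_sel].sum(),
            [t for t, s in zip(taxa, test_sel) if s],
        )
        for t, res in zip(chi2.taxa, chi2.residuals):
            residual[taxa.index(t)] = res

    verdict = np.full(len(taxa), "not_testable", dtype=object)
    ci_low = np.full(len(taxa), NOT_COMPUTED)
    ci_high = np.full(len(taxa), NOT_COMPUTED)
    if test_sel.any():
        sub_counts = counts[test_sel]
        ci = bonferroni_intervals(
            pd.Series(sub_counts, index=[t for t, s in zip(taxa, test_sel) if s]),
            alpha,
        )
        p_avail = p[test_sel] / p[test_sel].sum()
        for (t, row), pa in zip(ci.iterrows(), p_avail):
            i = taxa.index(t)
            ci_low[i], ci_high[i] = row["ci_low"], row["ci_high"]
            if pa < row["ci_low"]:
                verdict[i] = "preferred"
            elif pa > row["ci_high"]:
                verdict[i] = "avoided"
            else:
                verdict[i] = "proportional"

    reason = np.where(
        included, "", f"total dietary {basis} below {min_total}"
    ).astype(object)
    per_taxon = pd.DataFrame(
        {
            "r": r,
            "p": p,
            "estar": estar,
            "included": included,
            "reason": reason,
            "residual": residual,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "verdict": verdict,
        },
        index=taxa,
    )
    return ElectivityResult(
        group, environment_group, per_taxon, chi2, alpha, min_total, basis
    )
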