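"""Carrier aggregation and exact association statistics.

Exact tests use the "probability method" for two-sided p-values: the sum
of the probabilities of all tables with the observed margins that are no
more probable than the observed table (with a small relative tolerance
for floating-point ties). The 2×2 test is computed in exact integer
arithmetic; the 2×K generalization (Freeman–Halton) enumerates
compositions of the smaller row margin in log space.

The "median test" is the classical nonparametric two-sample median test:
counts above vs. not-above the pooled median form a 2×2 table tested by
Pearson's chi-square with Yates continuity correction (values equal to
the pooled median count as "not above").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .models import PatientRecord
from .triage import Klass, severity_rank

TIE_RTOL = 1e-7


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero; the test is undefined."""


class EnumerationBudgetError(RuntimeError):
    """The exact enumeration would exceed the configured budget."""


@dataclass(frozen=True)
class ContingencyTable:
    """A 2×K table of non-negative counts with labelled rows/columns."""

    counts: tuple  # ((r1c1, ..., r1cK), (r2c1, ..., r2cK))
    row_labels: tuple = ("a", "b")
    col_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        counts = tuple(tuple(int(x) for x in row) for row in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) != 2:
            raise ValueError("table must have exactly 2 rows")
        if len(counts[0]) != len(counts[1]) or len(counts[0]) < 2:
            raise ValueError("table must have K >= 2 equal-length columns")
        if any(x < 0 for row in counts for x in row):
            raise ValueError("counts must be non-negative")
        if self.col_labels is None:
            object.__setattr__(
                self, "col_labels", tuple(f"c{i+1}" for i in range(len(counts[0])))
            )

    @property
    def k(self) -> int:
        return len(self.counts[0])

    @property
    def df(self) -> int:
        return self.k - 1

    @property
    def row_margins(self) -> Tuple[int, int]:
        return (sum(self.counts[0]), sum(self.counts[1]))

    @property
    def col_margins(self) -> Tuple[int, ...]:
        return tuple(a + b for a, b in zip(*self.counts))

    @property
    def total(self) -> int:
        return sum(self.row_margins)


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    correction_applied: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("CI must contain the point estimate")
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p must be in [0,1]")


# ---------------------------------------------------------------------------
# Exact tests

def fisher_exact_2x2(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2×2 table, exact integer arithmetic."""
    if table.k != 2:
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    (a, b), (c, d) = table.counts
    r1, r2 = table.row_margins
    c1, _ = table.col_margins
    n = table.total
    if 0 in (r1, r2) or 0 in table.col_margins:
        raise DegenerateTableError("zero margin: exact test undefined")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    numer = sum(w for w in weights if w <= obs)
    return min(1.0, numer / sum(weights))


def _compositions(total: int, caps: Sequence[int]):
    """Yield tuples x with sum(x) == total and 0 <= x[j] <= caps[j]."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    tail_cap = sum(caps[1:])
    for x0 in range(max(0, total - tail_cap), min(caps[0], total) + 1):
        for rest in _compositions(total - x0, caps[1:]):
            yield (x0,) + rest


def _n_compositions(total: int, caps: Sequence[int]) -> int:
    # dynamic program over bounded compositions
    dp = {0: 1}
    for cap in caps:
        nxt: Dict[int, int] = {}
        for s, cnt in dp.items():
            for x in range(0, cap + 1):
                if s + x > total:
                    break
                nxt[s + x] = nxt.get(s + x, 0) + cnt
        dp = nxt
    return dp.get(total, 0)


def fisher_exact_2xk(
    table: ContingencyTable, max_tables: int = 5_000_000
) -> float:
    """Freeman–Halton exact test: two-sided p over all 2×K tables with the
    observed margins, summing multivariate hypergeometric probabilities of
    tables at most as probable as the observed one.

    Raises :class:`EnumerationBudgetError` when the enumeration would
    exceed ``max_tables`` (never silently approximates).
    """
    cols = [j for j in range(table.k) if table.col_margins[j] > 0]
    if len(cols) < 2:
        raise DegenerateTableError("fewer than two non-empty columns")
    counts = tuple(tuple(row[j] for j in cols) for row in table.counts)
    col_m = [a + b for a, b in zip(*counts)]
    r1, r2 = sum(counts[0]), sum(counts[1])
    if r1 == 0 or r2 == 0:
        raise DegenerateTableError("zero row margin: exact test undefined")
    n = r1 + r2
    # enumerate over the smaller row for efficiency
    row = counts[0] if r1 <= r2 else counts[1]
    r = min(r1, r2)
    caps = [min(c, r) for c in col_m]
    if _n_compositions(r, caps) > max_tables:
        raise EnumerationBudgetError(
            f"exact enumeration exceeds budget of {max_tables} tables"
        )
    lg_col = [gammaln(c + 1) for c in col_m]
    base = gammaln(r1 + 1) + gammaln(r2 + 1) - gammaln(n + 1) + sum(lg_col)

    def log_prob(x: Tuple[int, ...]) -> float:
        s = base
        for xj, cj in zip(x, col_m):
            s -= gammaln(xj + 1) + gammaln(cj - xj + 1)
        return s

    lp_obs = log_prob(row)
    cutoff = lp_obs + math.log1p(TIE_RTOL)
    lps = [lp for lp in map(log_prob, _compositions(r, caps)) if lp <= cutoff]
    m = max(lps)
    p = math.exp(m) * sum(math.exp(lp - m) for lp in lps)
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Odds ratios

def odds_ratio(
    carriers_a: int, total_a: int, carriers_b: int, total_b: int
) -> OddsRatioResult:
    """Odds ratio for carrier status in group a vs. group b.

    95% CI on the log scale (Woolf); when any cell is zero the
    Haldane–Anscombe +0.5 correction is applied to all four cells for
    the estimate and CI. The two-sided p comes from the exact 2×2 test
    on the uncorrected counts.
    """
    if not (0 < total_a and 0 < total_b):
        raise ValueError("totals must be positive")
    a, b = carriers_a, carriers_b
    na, nb = total_a - a, total_b - b
    if a == 0 and b == 0:
        raise DegenerateTableError("no carriers in either group: OR undefined")
    cells = [a, na, b, nb]
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a_, na_, b_, nb_ = cells
    or_est = (a_ * nb_) / (b_ * na_)
    se = math.sqrt(1 / a_ + 1 / na_ + 1 / b_ + 1 / nb_)
    z = sps.norm.ppf(0.975)
    lo = math.exp(math.log(or_est) - z * se)
    hi = math.exp(math.log(or_est) + z * se)
    try:
        p = fisher_exact_2x2(ContingencyTable(((a, na), (b, nb))))
    except DegenerateTableError:
        p = 1.0
    return OddsRatioResult(or_est, lo, hi, p, corrected)


# ---------------------------------------------------------------------------
# Median test and mean CI

def median_test(ages_a: Sequence[float], ages_b: Sequence[float]) -> float:
    """Two-sample median test with Yates continuity correction.

    Pools both groups, counts values above vs. not-above the pooled
    median per group (ties with the median count as "not above"), and
    tests the 2×2 table with Pearson's chi-square, 1 df, continuity
    corrected. Degenerate splits return p = 1.
    """
    if len(ages_a) == 0 or len(ages_b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([np.asarray(ages_a, float), np.asarray(ages_b, float)])
    med = float(np.median(pooled))
    above = np.array([np.sum(np.asarray(g, float) > med) for g in (ages_a, ages_b)])
    notab = np.array([len(ages_a), len(ages_b)]) - above
    if above.sum() == 0 or notab.sum() == 0:
        return 1.0
    table = np.array([above, notab]).T  # groups x (above, not above)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    chi2 = float(np.sum((np.abs(table - expected) - 0.5).clip(0) ** 2 / expected))
    return float(sps.chi2.sf(chi2, df=1))


def group_mean_ci(values: Sequence[float]) -> Tuple[float, float, float]:
    """Mean with 95% t-interval: mean ± t(0.975, n−1)·sd/√n."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two values for a t-interval")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# Carrier aggregation

class VariantResolutionError(KeyError):
    """A patient references a variant id missing from the classified table."""


def aggregate_carriers(
    patients: Iterable[PatientRecord],
    classifications: Dict[str, dict],
    gene_set: Optional[Iterable[str]] = None,
    severity_floor: Klass = Klass.LIKELY_PATHOGENIC,
    kinds: Optional[Iterable[str]] = None,
) -> Dict[str, bool]:
    """Per-patient carrier flags.

    ``classifications`` maps variant id → ``{"gene", "classification",
    "consequence", "in_last_exon"}``. A patient is a carrier iff at
    least one carried variant lies in ``gene_set`` (all genes when
    None), has class at or above ``severity_floor``, and — when
    ``kinds`` is given — has a consequence kind in ``kinds`` (truncating
    kinds additionally require the last-exon exemption not to apply).
    Each patient counts once regardless of how many qualifying variants
    they carry.
    """
    genes = None if gene_set is None else set(gene_set)
    kindset = None if kinds is None else {str(k) for k in kinds}
    floor = severity_rank(severity_floor)
    flags: Dict[str, bool] = {}
    for p in patients:
        carrier = False
        for vid in p.variants:
            if vid not in classifications:
                raise VariantResolutionError(
                    f"patient {p.patient_id}: unknown variant id {vid!r}"
                )
            rec = classifications[vid]
            if genes is not None and rec["gene"] not in genes:
                continue
            if severity_rank(Klass(rec["classification"])) < floor:
                continue
            if kindset is not None:
                if str(rec.get("consequence")) not in kindset:
                    continue
                if rec.get("in_last_exon") in (True, "True", "true"):
                    continue
            carrier = True
            break
        flags[p.patient_id] = carrier
    return flags


def carrier_count(flags: Dict[str, bool]) -> int:
    return sum(flags.values())
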