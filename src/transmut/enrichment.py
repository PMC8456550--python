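"""Statistical contrasts between trans-regulatory and non-regulatory
mutation sets: categorical G-tests, amino-acid-change permutation tests, a
Poisson-dispersion resampling test for per-strain mutation counts, and
overlap enrichment against genomic interval sets (eQTL regions).

Resampling p-values are reported as raw fractions of the null resamples
(the proportion of permuted statistics at least as extreme as the observed
one), not with the (k+1)/(n+1) convention; a p of exactly 0 is therefore
possible at finite resample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bsa import GTestResult, g_statistic
from .errors import ConfigurationError, DataError, UndefinedTestError
from .variants import Mutation

#: One-letter amino acid codes plus the stop symbol.
AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)

# ---------------------------------------------------------------------------
# r x c G-test
# ---------------------------------------------------------------------------


def g_test_rxc(table: np.ndarray | pd.DataFrame) -> GTestResult:
    """Likelihood-ratio test of independence on an r x c count table with
    (r-1)(c-1) degrees of freedom."""
    values = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    G = g_statistic(values)
    df = (values.shape[0] - 1) * (values.shape[1] - 1)
    return GTestResult(G=G, df=df, p=float(stats.chi2.sf(G, df)))


def compare_mutation_property(
    trans_set: Sequence[Mutation],
    nonreg_set: Sequence[Mutation],
    property_extractor: Callable[[Mutation], object],
) -> tuple[pd.DataFrame, GTestResult]:
    """Build the 2 x k table of set membership against a categorical mutation
    property and G-test it.  Rows are the two sets, columns the categories in
    first-appearance order."""
    cats: list[object] = []
    counts = {"trans_regulatory": {}, "non_regulatory": {}}
    for label, mutations in (
        ("trans_regulatory", trans_set),
        ("non_regulatory", nonreg_set),
    ):
        for m in mutations:
            cat = property_extractor(m)
            if cat not in cats:
                cats.append(cat)
            counts[label][cat] = counts[label].get(cat, 0) + 1
    table = pd.DataFrame(
        [[counts[row].get(c, 0) for c in cats] for row in counts],
        index=list(counts),
        columns=[str(c) for c in cats],
    )
    return table, g_test_rxc(table)


# ---------------------------------------------------------------------------
# Amino-acid change matrices and permutation tests
# ---------------------------------------------------------------------------


@dataclass
class AAChangeMatrix:
    """Percent frequency of each amino-acid change in a mutation set.

    Rows are the original amino acid, columns the new one; entries sum to
    100 over the observed changes.
    """

    percent: pd.DataFrame
    total: int


def aa_change_matrix(mutations: Sequence[Mutation]) -> AAChangeMatrix:
    counts = pd.DataFrame(0.0, index=list(AA_ALPHABET), columns=list(AA_ALPHABET))
    total = 0
    for m in mutations:
        if m.aa_from is None or m.aa_to is None:
            raise DataError(f"mutation {m.id} lacks amino-acid annotation")
        counts.loc[m.aa_from, m.aa_to] += 1
        total += 1
    if total == 0:
        raise DataError("empty mutation set")
    return AAChangeMatrix(percent=counts / total * 100.0, total=total)


def aa_change_difference(
    trans_matrix: AAChangeMatrix, nonreg_matrix: AAChangeMatrix
) -> pd.DataFrame:
    """Difference matrix (trans % - nonreg %); cells observed in neither set
    are reported as absent (NaN)."""
    diff = trans_matrix.percent - nonreg_matrix.percent
    observed = (trans_matrix.percent > 0) | (nonreg_matrix.percent > 0)
    return diff.where(observed)


def _in_category(m: Mutation, target) -> bool:
    if callable(target):
        return bool(target(m))
    if isinstance(target, tuple):
        return (m.aa_from, m.aa_to) == target
    return m.aa_from == target  # aggregate: any change from this amino acid


def aa_permutation_test(
    trans_set: Sequence[Mutation],
    nonreg_set: Sequence[Mutation],
    target_category,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Label-permutation test of one amino-acid change category.

    ``target_category`` is either an (aa_from, aa_to) pair, a single source
    amino acid (aggregating all changes from it), or a predicate.  The
    statistic is the absolute difference of category proportions between the
    sets; the null permutes set labels with set sizes fixed; p is the raw
    fraction of permuted statistics >= the observed one.
    """
    n_t, n_n = len(trans_set), len(nonreg_set)
    if n_t == 0 or n_n == 0:
        raise DataError("both mutation sets must be non-empty")
    flags = np.array(
        [_in_category(m, target_category) for m in trans_set]
        + [_in_category(m, target_category) for m in nonreg_set]
    )
    k_total = int(flags.sum())
    obs = abs(flags[:n_t].mean() - flags[n_t:].mean())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # permuting labels == drawing the trans-set category count hypergeometrically
    k_trans = rng.hypergeometric(k_total, n_t + n_n - k_total, n_t, n_perm)
    perm = np.abs(k_trans / n_t - (k_total - k_trans) / n_n)
    return float(np.mean(perm >= obs - 1e-12))


# ---------------------------------------------------------------------------
# Poisson dispersion resampling test
# ---------------------------------------------------------------------------


def poisson_dispersion_test(
    counts: Sequence[int],
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Test whether per-strain mutation counts are overdispersed relative to
    a Poisson process.

    The statistic is the dispersion index (sample variance / sample mean);
    the null redraws same-size count vectors from Poisson(sample mean); p is
    the raw fraction of null statistics >= the observed one.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 5:
        raise DataError("need counts for at least 5 strains")
    mean = counts.mean()
    if mean == 0:
        raise DataError("mean count is zero; dispersion undefined")
    obs = counts.var(ddof=1) / mean
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null = rng.poisson(mean, size=(n_resamples, len(counts)))
    null_stat = null.var(axis=1, ddof=1) / null.mean(axis=1)
    return float(np.mean(null_stat >= obs))


# ---------------------------------------------------------------------------
# Interval overlap enrichment
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Genomic intervals, 1-based inclusive; overlaps allowed (union used)."""

    intervals: list[tuple[str, int, int]]
    genome_size: float = 12_070_000.0

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start > end:
                raise ConfigurationError(f"interval start > end on {chrom}: {start}-{end}")

    def union_length(self) -> int:
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for spans in by_chrom.values():
            spans.sort()
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            total += cur_e - cur_s + 1
        return total

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            c == chrom and s <= pos <= e for c, s, e in self.intervals
        )


@dataclass
class OverlapEnrichment:
    trans_proportion: float
    nonreg_proportion: float
    genome_fraction: float
    test: GTestResult
    table: pd.DataFrame = field(repr=False, default=None)


def interval_overlap_enrichment(
    trans_set: Sequence[Mutation],
    nonreg_set: Sequence[Mutation],
    intervals: IntervalSet,
    known_chroms: Iterable[str] | None = None,
) -> OverlapEnrichment:
    """Enrichment of mutations inside an interval set (e.g. eQTL regions).

    Membership uses inclusive interval ends.  Returns the per-set overlap
    proportions, the 2x2 G-test of set x membership, and the fraction of the
    genome covered by the union of the intervals.
    """
    if known_chroms is not None:
        known = set(known_chroms)
        for chrom, _, _ in intervals.intervals:
            if chrom not in known:
                raise DataError(f"interval chromosome {chrom!r} absent from genome table")

    def overlap_counts(mutations: Sequence[Mutation]) -> tuple[int, int]:
        inside = sum(intervals.contains(m.chrom, m.pos) for m in mutations)
        return inside, len(mutations) - inside

    t_in, t_out = overlap_counts(trans_set)
    n_in, n_out = overlap_counts(nonreg_set)
    table = pd.DataFrame(
        [[t_in, t_out], [n_in, n_out]],
        index=["trans_regulatory", "non_regulatory"],
        columns=["inside", "outside"],
    )
    try:
        test = g_test_rxc(table)
    except UndefinedTestError:
        test = GTestResult(G=0.0, df=1, p=1.0)
    return OverlapEnrichment(
        trans_proportion=t_in / max(len(trans_set), 1),
        nonreg_proportion=n_in / max(len(nonreg_set), 1),
        genome_fraction=intervals.union_length() / intervals.genome_size,
        test=test,
        table=table,
    )
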