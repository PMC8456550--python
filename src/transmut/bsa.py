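"""Bulk-segregant association: per-variant G-tests, aneuploidy detection,
linkage grouping and disambiguation of linked candidate mutations.

A mutation that changes fluorescence is enriched in one phenotypic bulk and
depleted in the other; the likelihood-ratio (G) test on the 2x2 table of
ref/alt read counts in the two bulks measures that allele-frequency
difference.  G = 2 * sum O ln(O/E) with expected counts from the table
margins; under the null it is chi-square with one degree of freedom, so the
p < 0.001 call threshold corresponds to G > 10.828.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedTestError

#: G value at which a 1-df chi-square upper tail equals 0.001.
G_CALL_THRESHOLD = 10.828

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BulkCounts:
    """Ref/alt read counts for one variant in the low and high bulks."""

    variant_id: str
    low_ref: int
    low_alt: int
    high_ref: int
    high_alt: int

    def as_table(self) -> np.ndarray:
        return np.array(
            [[self.low_ref, self.low_alt], [self.high_ref, self.high_alt]],
            dtype=float,
        )


@dataclass
class GTestResult:
    G: float
    df: int
    p: float
    sign: int = 0


@dataclass
class LinkageGroup:
    """Variants joined by a chain of pairwise distances under the threshold."""

    members: list[str]
    distances: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# G statistics
# ---------------------------------------------------------------------------


def g_statistic(observed: np.ndarray) -> float:
    """G = 2 * sum O ln(O/E) over an r x c table; 0*ln(0/E) contributes 0."""
    O = np.asarray(observed, dtype=float)
    if (O < 0).any():
        raise UndefinedTestError("negative counts")
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    total = O.sum()
    if (rows == 0).any() or (cols == 0).any() or total == 0:
        raise UndefinedTestError("table has a zero margin")
    E = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    return float(2.0 * terms.sum())


def g_test_2x2(a: int, b: int, c: int, d: int) -> GTestResult:
    """Likelihood-ratio test of independence on the table [[a, b], [c, d]]."""
    G = g_statistic([[a, b], [c, d]])
    return GTestResult(G=G, df=1, p=float(stats.chi2.sf(G, 1)))


def signed_association(counts: BulkCounts) -> GTestResult:
    """2x2 G-test with a sign: +1 when the alt allele is more frequent in
    the high-fluorescence bulk, -1 when in the low bulk, 0 when equal."""
    res = g_test_2x2(counts.low_ref, counts.low_alt, counts.high_ref, counts.high_alt)
    f_low = counts.low_alt / (counts.low_ref + counts.low_alt)
    f_high = counts.high_alt / (counts.high_ref + counts.high_alt)
    res.sign = int(np.sign(f_high - f_low))
    return res


@dataclass
class AssociationCalls:
    """Per-variant association calls plus the expected type-I count."""

    table: pd.DataFrame
    alpha: float

    @property
    def expected_false_positives(self) -> float:
        return len(self.table) * self.alpha


def call_associations(counts: list[BulkCounts], alpha: float = 0.001) -> AssociationCalls:
    """Signed G-test per variant; call = associated iff p < alpha."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    rows = []
    for bc in counts:
        res = signed_association(bc)
        rows.append(
            {
                "variant_id": bc.variant_id,
                "G": res.G,
                "p": res.p,
                "sign": res.sign,
                "associated": res.p < alpha,
            }
        )
    table = pd.DataFrame(
        rows, columns=["variant_id", "G", "p", "sign", "associated"]
    )
    return AssociationCalls(table=table, alpha=alpha)


def aneuploidy_g_test(
    chrom_reads_low: int,
    rest_reads_low: int,
    chrom_reads_high: int,
    rest_reads_high: int,
) -> GTestResult:
    """G-test on reads mapping to a chromosome vs the rest of the genome in
    each bulk; G > 10.828 flags the aneuploidy as associated."""
    return g_test_2x2(chrom_reads_low, rest_reads_low, chrom_reads_high, rest_reads_high)


# ---------------------------------------------------------------------------
# Aneuploidy from coverage
# ---------------------------------------------------------------------------


def detect_aneuploidy(
    coverage: pd.DataFrame | dict[str, float],
    ratio_threshold: float = 1.4,
) -> list[str]:
    """Flag chromosomes whose mean coverage is >= ratio_threshold times the
    median coverage of all other chromosomes (~1.5-fold for a disome)."""
    if isinstance(coverage, pd.DataFrame):
        cov = dict(zip(coverage["chrom"], coverage["mean_coverage"]))
    else:
        cov = dict(coverage)
    if len(cov) < 2:
        raise ConfigurationError("need coverage for at least two chromosomes")
    flagged = []
    for chrom, value in cov.items():
        others = [v for c, v in cov.items() if c != chrom]
        if value / np.median(others) >= ratio_threshold:
            flagged.append(chrom)
    return flagged


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------


def physical_to_genetic(pos_bp: float, cm_per_kb: float = 0.4) -> float:
    """Convert a physical coordinate to a genetic-map coordinate using a
    constant genome-wide recombination rate (S. cerevisiae average)."""
    return pos_bp / 1000.0 * cm_per_kb


def group_linked(
    positions: pd.DataFrame,
    threshold_cm: float = 25.0,
) -> list[LinkageGroup]:
    """Single-linkage clustering of variants within chromosomes.

    ``positions`` needs columns variant_id, chrom, cm.  Two variants join a
    group when a chain of pairs each closer than ``threshold_cm`` connects
    them; variants on different chromosomes are never linked.
    """
    for col in ("variant_id", "chrom", "cm"):
        if col not in positions.columns:
            raise ConfigurationError(f"positions table lacks column {col!r}")
    if positions["cm"].isna().any():
        raise ConfigurationError("missing genetic-map coordinate")
    groups: list[LinkageGroup] = []
    for _, sub in positions.groupby("chrom", sort=False):
        sub = sub.sort_values("cm")
        ids = sub["variant_id"].tolist()
        cms = sub["cm"].to_numpy(dtype=float)
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or cms[i] - cms[i - 1] >= threshold_cm:
                members = ids[start:i]
                dists = {
                    (a, b): abs(cms[start + k] - cms[start + j])
                    for j, a in enumerate(members)
                    for k, b in enumerate(members)
                    if j < k
                }
                groups.append(LinkageGroup(members=members, distances=dists))
                start = i
    return groups


# ---------------------------------------------------------------------------
# Disambiguation of linked candidates
# ---------------------------------------------------------------------------


def _g_vectorized(low_alt, low_dp, high_alt, high_dp) -> np.ndarray:
    O = np.stack(
        [low_dp - low_alt, low_alt, high_dp - high_alt, high_alt], axis=-1
    ).astype(float)
    O = O.reshape(-1, 2, 2)
    rows = O.sum(axis=2, keepdims=True)
    cols = O.sum(axis=1, keepdims=True)
    total = O.sum(axis=(1, 2), keepdims=True)
    E = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / np.where(E > 0, E, 1.0)), 0.0)
    return 2.0 * terms.sum(axis=(1, 2))


def compare_linked_g(
    counts_a: BulkCounts,
    counts_b: BulkCounts,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Parametric bootstrap comparing two linked candidates' G values.

    Variant ``a`` must carry the larger observed G.  Each resample redraws
    the alt count of each variant in each bulk as Binomial(depth, observed
    alt frequency) at the observed depths and recomputes both G statistics;
    the p-value is the fraction of resamples in which G_a <= G_b.  p < 0.05
    declares ``a`` the significantly stronger candidate.
    """
    if n_resamples < 100:
        raise ConfigurationError("n_resamples < 100 gives an unstable p-value")
    g_obs_a = g_statistic(counts_a.as_table())
    g_obs_b = g_statistic(counts_b.as_table())
    if g_obs_a < g_obs_b:
        raise ConfigurationError(
            "counts_a must be the variant with the larger observed G"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def resample(bc: BulkCounts) -> np.ndarray:
        dp_low = bc.low_ref + bc.low_alt
        dp_high = bc.high_ref + bc.high_alt
        la = rng.binomial(dp_low, bc.low_alt / dp_low, n_resamples)
        ha = rng.binomial(dp_high, bc.high_alt / dp_high, n_resamples)
        return _g_vectorized(la, np.full(n_resamples, dp_low), ha, np.full(n_resamples, dp_high))

    g_a = resample(counts_a)
    g_b = resample(counts_b)
    return float(np.mean(g_a <= g_b))
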