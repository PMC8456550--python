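"""Synthetic cohorts, crosses, plates and competitions.

Generates every input the pipeline consumes with the statistical structure
the analyses assume: overdispersed per-strain mutation counts with an
EMS-like spectrum (mostly G:C->A:T transitions), bulk allele counts at
mutation sites under truncation selection of the 2.5% fluorescence tails,
96-well plate expression data with control wells, positional gradients and
a replicated reference panel whose between-position variance exceeds its
within-position variance, and two-fluorophore competition counts.

Two cross models are provided.  ``population`` mode simulates a finite
population of ``n_spores`` meiotic products per chromosome as a Markov chain
with Haldane recombination fractions and takes the phenotypic tails of that
population as the bulks, so bulk allele frequencies carry the sampling noise
of the tail size.  ``sorted`` mode (the default) emulates FACS sorting of
``bulk_size`` cells (1.5e5 by default) from an effectively unbounded spore
population: tail thresholds are the exact phenotype-mixture quantiles and
each bulk's cells are independent draws from the tail-conditional genotype
distribution, computed from the causal-locus mixture and the Haldane map.
The sorted mode reproduces the regime in which read sampling, not bulk
composition, dominates the noise in bulk allele frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError
from .variants import classify_snv

# S. cerevisiae R64 nuclear chromosome lengths (sum ~12.07 Mb).
DEFAULT_GENOME: tuple[tuple[str, int], ...] = (
    ("chrI", 230_218), ("chrII", 813_184), ("chrIII", 316_620),
    ("chrIV", 1_531_933), ("chrV", 576_874), ("chrVI", 270_161),
    ("chrVII", 1_090_940), ("chrVIII", 562_643), ("chrIX", 439_888),
    ("chrX", 745_751), ("chrXI", 666_816), ("chrXII", 1_078_177),
    ("chrXIII", 924_431), ("chrXIV", 784_333), ("chrXV", 1_091_291),
    ("chrXVI", 948_066),
)


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


@dataclass
class SimConfig:
    """All parameters of the synthetic generators.

    Defaults are the study conditions: 16 chromosomes summing to 12.07 Mb,
    76 strains averaging 23.9 mutations with overdispersion, 96.3% G:C->A:T
    among SNVs, 69.4% coding, 2.5% phenotype tails sorted into bulks of
    1.5e5 cells sequenced to ~105x, 8x12 plates with 20 control wells, a
    146-position x 4-replicate reference panel, and 17:3 competition mixes.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_strains: int = 76

    # per-strain mutation counts: two-component Poisson mixture (rate
    # heterogeneity), mean 0.5*16.0 + 0.5*31.8 = 23.9
    count_weights: tuple[float, ...] = (0.5, 0.5)
    count_lambdas: tuple[float, ...] = (16.0, 31.8)

    # spectrum
    indel_fraction: float = 48 / 1819
    snv_gc_at: float = 0.963
    snv_other_transition: float = 0.012
    coding_fraction: float = 0.694
    intron_fraction_of_noncoding: float = 6 / 506

    # causal model
    n_causal: int = 1
    causal_effect_sd: float = 3.0

    # cross / bulks
    cm_per_kb: float = 0.4
    bulk_fraction: float = 0.025
    bulk_size: int = 150_000
    n_spores: int = 20_000
    cross_mode: str = "sorted"  # sorted | population
    coverage: float = 105.0

    # plates
    plate_rows: int = 8
    plate_cols: int = 12
    n_controls: int = 20
    n_replicates: int = 4
    panel_positions: int = 146
    panel_replicates: int = 4
    position_effect_sd: float = math.sqrt(2) * 0.01
    replicate_cv: float = 0.01
    row_gradient: float = 0.002
    col_gradient: float = 0.002
    autofluorescence: float = 0.02

    # competition
    competition_initial_ratio: float = 17 / 3
    competition_events: int = 5_000
    competition_generations: tuple[float, ...] = (0.0, 7.0)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.count_weights), 1.0):
            raise ConfigurationError("count_weights must sum to 1")
        if not 0 < self.bulk_fraction < 0.5:
            raise ConfigurationError("bulk_fraction must be in (0, 0.5)")
        snv_rest = self.snv_gc_at + self.snv_other_transition
        if snv_rest > 1 or min(
            self.snv_gc_at, self.snv_other_transition, self.indel_fraction
        ) < 0:
            raise ConfigurationError("spectrum probabilities must be in [0,1]")
        if self.cross_mode not in ("sorted", "population"):
            raise ConfigurationError(f"unknown cross_mode {self.cross_mode!r}")

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.genome)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# EMS cohort
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    return {
        "".join(c): str(Seq("".join(c)).translate())
        for c in itertools.product(_BASES, repeat=3)
    }


_CODONS = _codon_table()
_SENSE_CODONS = [c for c, aa in _CODONS.items() if aa != "*"]


def _sample_coding_change(ref: str, alt: str, rng: np.random.Generator):
    """Draw a codon context for a base substitution and translate it.

    The gene may lie on either genomic strand, so the codon-strand change is
    the substitution itself or its complement with equal probability; the
    source codon is uniform over sense codons carrying the required base.
    """
    if rng.random() < 0.5:
        c_ref, c_alt = ref, alt
    else:
        c_ref, c_alt = _COMP[ref], _COMP[alt]
    candidates = [
        (codon, i)
        for codon in _SENSE_CODONS
        for i in range(3)
        if codon[i] == c_ref
    ]
    codon, i = candidates[rng.integers(len(candidates))]
    new_codon = codon[:i] + c_alt + codon[i + 1 :]
    aa_from, aa_to = _CODONS[codon], _CODONS[new_codon]
    if aa_to == "*":
        effect = "nonsense"
    elif aa_from == aa_to:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return aa_from, aa_to, effect


_TRANSVERSIONS = [
    (a, b) for a in _BASES for b in _BASES if b != a and {a, b} not in ({"A", "G"}, {"C", "T"})
]


def _draw_substitution(cls: str, rng: np.random.Generator) -> tuple[str, str]:
    if cls == "GC_to_AT_transition":
        return ("G", "A") if rng.random() < 0.5 else ("C", "T")
    if cls == "other_transition":
        return ("A", "G") if rng.random() < 0.5 else ("T", "C")
    return _TRANSVERSIONS[rng.integers(len(_TRANSVERSIONS))]


def simulate_ems_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-strain mutation tables with truth labels.

    Each strain's mutation count comes from the configured Poisson mixture;
    positions are uniform over the genome; classes follow the EMS spectrum;
    coding SNVs get amino-acid changes sampled through real codon contexts;
    ``n_causal`` SNVs per strain are tagged with the causal effect size (in
    phenotypic standard deviations).
    """
    rng = config.rng() if rng is None else rng
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    rows = []
    for strain in range(config.n_strains):
        comp = rng.choice(len(config.count_weights), p=config.count_weights)
        n_mut = int(rng.poisson(config.count_lambdas[comp]))
        chroms = rng.choice(len(chrom_names), size=n_mut, p=chrom_p)
        snv_idx = [i for i in range(n_mut) if rng.random() >= config.indel_fraction]
        causal = set()
        if config.n_causal > 0 and snv_idx:
            causal = set(
                rng.choice(snv_idx, size=min(config.n_causal, len(snv_idx)), replace=False)
            )
        for i in range(n_mut):
            ci = chroms[i]
            pos = int(rng.integers(1, chrom_lengths[ci] + 1))
            is_indel = i not in snv_idx
            if is_indel:
                ref, alt, mtype = "A", "AT", "indel"
                aa_from = aa_to = None
                effect = "NA"
                region = "coding" if rng.random() < config.coding_fraction else (
                    "intron"
                    if rng.random() < config.intron_fraction_of_noncoding
                    else "intergenic"
                )
            else:
                u = rng.random()
                if u < config.snv_gc_at:
                    cls = "GC_to_AT_transition"
                elif u < config.snv_gc_at + config.snv_other_transition:
                    cls = "other_transition"
                else:
                    cls = "transversion"
                ref, alt = _draw_substitution(cls, rng)
                mtype = "SNV"
                if rng.random() < config.coding_fraction:
                    region = "coding"
                    aa_from, aa_to, effect = _sample_coding_change(ref, alt, rng)
                else:
                    region = (
                        "intron"
                        if rng.random() < config.intron_fraction_of_noncoding
                        else "intergenic"
                    )
                    aa_from = aa_to = None
                    effect = "NA"
            rows.append(
                {
                    "strain": f"strain{strain:03d}",
                    "id": f"strain{strain:03d}_m{i:03d}",
                    "chrom": chrom_names[ci],
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "mtype": mtype,
                    "region": region,
                    "effect": effect,
                    "aa_from": aa_from,
                    "aa_to": aa_to,
                    "is_causal": i in causal,
                    "effect_size": config.causal_effect_sd if i in causal else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross and bulks
# ---------------------------------------------------------------------------


def _order_loci(muts: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    out = muts.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    out["cm"] = out["pos"] / 1000.0 * config.cm_per_kb
    return out


def _simulate_spores(
    loci: pd.DataFrame, n_spores: int, rng: np.random.Generator
) -> np.ndarray:
    """Genotype matrix (n_spores, n_loci) from per-chromosome Markov chains
    with Haldane recombination between adjacent loci."""
    geno = np.empty((n_spores, len(loci)), dtype=bool)
    for chrom, sub in loci.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        g = rng.random(n_spores) < 0.5
        geno[:, idx[0]] = g
        d = np.diff(sub["cm"].to_numpy())
        for j, gap in enumerate(d):
            flip = rng.random(n_spores) < haldane_r(gap)
            g = g ^ flip
            geno[:, idx[j + 1]] = g
    return geno


def _reads_from_freq(
    freq: np.ndarray, coverage: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    depth = np.maximum(rng.poisson(coverage, size=len(freq)), 1)
    alt = rng.binomial(depth, freq)
    return depth, alt


def _causal_combo_distribution(loci: pd.DataFrame, causal_idx: np.ndarray):
    """Joint genotype distribution over causal loci, chromosome by
    chromosome along the Haldane chain (no interference, so recombination
    fractions compose additively in map distance)."""
    combos = list(itertools.product((0, 1), repeat=len(causal_idx)))
    probs = np.ones(len(combos))
    causal = loci.loc[causal_idx]
    for chrom, sub in causal.groupby("chrom", sort=False):
        pos_in_vec = [list(causal_idx).index(i) for i in sub.index]
        cms = sub["cm"].to_numpy()
        for k, combo in enumerate(combos):
            p = 0.5
            for j in range(1, len(pos_in_vec)):
                r = haldane_r(cms[j] - cms[j - 1])
                same = combo[pos_in_vec[j]] == combo[pos_in_vec[j - 1]]
                p *= (1 - r) if same else r
            probs[k] *= p
    probs = probs / probs.sum()
    return combos, probs


def _conditional_allele_prob(
    loci: pd.DataFrame, causal_idx: np.ndarray, combos
) -> np.ndarray:
    """P(g_j = 1 | causal combo) for every locus j, via the flanking causal
    loci on the same chromosome (Markov property of the chain)."""
    n_loci = len(loci)
    p = np.full((len(combos), n_loci), 0.5)
    causal_list = list(causal_idx)
    for chrom, sub in loci.groupby("chrom", sort=False):
        chrom_causal = [i for i in sub.index if i in causal_list]
        if not chrom_causal:
            continue
        c_cms = loci.loc[chrom_causal, "cm"].to_numpy()
        for j in sub.index:
            cm_j = loci.at[j, "cm"]
            if j in chrom_causal:
                vj = causal_list.index(j)
                for k, combo in enumerate(combos):
                    p[k, j] = float(combo[vj])
                continue
            left = [(c, cm) for c, cm in zip(chrom_causal, c_cms) if cm <= cm_j]
            right = [(c, cm) for c, cm in zip(chrom_causal, c_cms) if cm > cm_j]
            a = max(left, key=lambda t: t[1]) if left else None
            b = min(right, key=lambda t: t[1]) if right else None
            for k, combo in enumerate(combos):
                if a is not None and b is not None:
                    ga = combo[causal_list.index(a[0])]
                    gb = combo[causal_list.index(b[0])]
                    r_aj = haldane_r(cm_j - a[1])
                    r_jb = haldane_r(b[1] - cm_j)
                    r_ab = haldane_r(b[1] - a[1])
                    pj1 = (1 - r_aj) if ga == 1 else r_aj
                    like1 = (1 - r_jb) if gb == 1 else r_jb
                    pj0 = r_aj if ga == 1 else (1 - r_aj)
                    like0 = r_jb if gb == 1 else (1 - r_jb)
                    denom = (1 - r_ab) if ga == gb else r_ab
                    p[k, j] = pj1 * like1 / denom if denom > 0 else 0.5
                else:
                    anchor = a if a is not None else b
                    g_anchor = combo[causal_list.index(anchor[0])]
                    r = haldane_r(abs(cm_j - anchor[1]))
                    p[k, j] = (1 - r) if g_anchor == 1 else r
    return p


def simulate_cross_and_bulks(
    strain_mutations: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bulk ref/alt read counts for every mutation of one strain.

    Spore phenotype = sum of inherited causal effects + standard normal
    noise; the bottom and top ``bulk_fraction`` phenotype tails form the low
    and high bulks.  Read counts are Binomial at a per-site Poisson depth
    around the configured mean coverage.  Columns include the true per-bulk
    allele frequencies for downstream verification.
    """
    rng = config.rng() if rng is None else rng
    loci = _order_loci(strain_mutations, config)
    effects = loci["effect_size"].to_numpy(dtype=float)
    n_loci = len(loci)
    if n_loci == 0:
        return pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "low_ref", "low_alt",
                     "high_ref", "high_alt", "low_freq", "high_freq"]
        )

    if config.cross_mode == "population":
        geno = _simulate_spores(loci, config.n_spores, rng)
        pheno = geno @ effects + rng.normal(size=config.n_spores)
        k = max(int(round(config.bulk_fraction * config.n_spores)), 1)
        order = np.argsort(pheno)
        low_f = geno[order[:k]].mean(axis=0)
        high_f = geno[order[-k:]].mean(axis=0)
        # sorted cells counted at the sequencing stage are a large sample of
        # the tail; the binomial layer at bulk_size is negligible but kept
        low_freq = rng.binomial(config.bulk_size, low_f) / config.bulk_size
        high_freq = rng.binomial(config.bulk_size, high_f) / config.bulk_size
    else:  # sorted mode
        causal_idx = loci.index[effects != 0].to_numpy()
        if len(causal_idx) > 16:
            raise ConfigurationError("sorted mode supports at most 16 causal loci")
        if len(causal_idx) == 0:
            low_freq = rng.binomial(config.bulk_size, 0.5, n_loci) / config.bulk_size
            high_freq = rng.binomial(config.bulk_size, 0.5, n_loci) / config.bulk_size
        else:
            combos, probs = _causal_combo_distribution(loci, causal_idx)
            means = np.array([
                sum(effects[i] * combo[v] for v, i in enumerate(causal_idx))
                for combo in combos
            ])

            def cdf(t):
                return float(np.sum(probs * stats.norm.cdf(t - means)))

            lo_bound = means.min() - 10
            hi_bound = means.max() + 10
            t_low = optimize.brentq(lambda t: cdf(t) - config.bulk_fraction, lo_bound, hi_bound)
            t_high = optimize.brentq(
                lambda t: cdf(t) - (1 - config.bulk_fraction), lo_bound, hi_bound
            )
            p_cond = _conditional_allele_prob(loci, causal_idx, combos)
            w_low = probs * stats.norm.cdf(t_low - means)
            w_high = probs * stats.norm.sf(t_high - means)
            freqs = []
            for w in (w_low, w_high):
                cells = rng.multinomial(config.bulk_size, w / w.sum())
                alt_cells = np.zeros(n_loci)
                for k_c, n_c in enumerate(cells):
                    if n_c:
                        alt_cells += rng.binomial(n_c, p_cond[k_c])
                freqs.append(alt_cells / config.bulk_size)
            low_freq, high_freq = freqs

    low_dp, low_alt = _reads_from_freq(low_freq, config.coverage, rng)
    high_dp, high_alt = _reads_from_freq(high_freq, config.coverage, rng)
    return pd.DataFrame(
        {
            "variant_id": loci["id"],
            "chrom": loci["chrom"],
            "pos": loci["pos"],
            "is_causal": loci["is_causal"],
            "low_ref": low_dp - low_alt,
            "low_alt": low_alt,
            "high_ref": high_dp - high_alt,
            "high_alt": high_alt,
            "low_freq": low_freq,
            "high_freq": high_freq,
        }
    )


def simulate_coverage_table(
    config: SimConfig,
    aneuploid_chroms: tuple[str, ...] = (),
    fold: float = 1.5,
    noise_cv: float = 0.02,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-chromosome mean-coverage table, with listed chromosomes at
    ``fold`` times the baseline (a disome segregating 2:2 after a cross to a
    euploid shows ~1.5x bulk coverage)."""
    rng = config.rng() if rng is None else rng
    rows = []
    for chrom, _ in config.genome:
        base = config.coverage * (fold if chrom in aneuploid_chroms else 1.0)
        rows.append({"chrom": chrom, "mean_coverage": base * (1 + rng.normal(0, noise_cv))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plates
# ---------------------------------------------------------------------------


def simulate_reference_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """(panel_positions, panel_replicates) reference-strain measurements
    with between-position variance exceeding within-position variance."""
    rng = config.rng() if rng is None else rng
    pos_effect = rng.normal(0.0, config.position_effect_sd, (config.panel_positions, 1))
    noise = rng.lognormal(0.0, config.replicate_cv, (config.panel_positions, config.panel_replicates))
    return (1.0 + pos_effect) * noise


def simulate_test_strain_wells(
    true_expression: float, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Replicate measurements of one strain grown at one (random) position,
    on the same scale as the reference panel."""
    rng = config.rng() if rng is None else rng
    pos_effect = rng.normal(0.0, config.position_effect_sd)
    noise = rng.lognormal(0.0, config.replicate_cv, config.n_replicates)
    return true_expression * (1.0 + pos_effect) * noise


def simulate_plate_experiment(
    strain_effects: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Well table for all strains plus a reference panel.

    Well value = strain true expression x (1 + row/col gradient) x lognormal
    replicate noise + autofluorescence baseline.  Each plate carries
    ``n_controls`` reference wells at fixed positions and one
    non-fluorescent (autofluorescence) well; each strain is measured in
    ``n_replicates`` replicate plates.
    """
    rng = config.rng() if rng is None else rng
    n_wells = config.plate_rows * config.plate_cols
    coords = [
        (r + 1, c + 1) for r in range(config.plate_rows) for c in range(config.plate_cols)
    ]
    step = max(n_wells // config.n_controls, 1)
    control_pos = set(range(0, step * config.n_controls, step))
    autofl_pos = next(i for i in range(n_wells) if i not in control_pos)
    test_pos = [i for i in range(n_wells) if i not in control_pos and i != autofl_pos]

    strains = list(strain_effects)
    rows = []
    row_mid = (config.plate_rows + 1) / 2
    col_mid = (config.plate_cols + 1) / 2
    for rep in range(config.n_replicates):
        for plate_i in range(0, len(strains), len(test_pos)):
            plate_id = f"rep{rep + 1}_plate{plate_i // len(test_pos) + 1}"
            plate_strains = strains[plate_i : plate_i + len(test_pos)]
            layout = {}
            for i in control_pos:
                layout[i] = ("reference", 1.0, True, False)
            layout[autofl_pos] = ("autofl", 0.0, False, True)
            for s, i in zip(plate_strains, test_pos):
                layout[i] = (s, strain_effects[s], False, False)
            for i, (strain, true_val, is_ctrl, is_autofl) in layout.items():
                r, c = coords[i]
                gradient = (
                    1.0
                    + config.row_gradient * (r - row_mid)
                    + config.col_gradient * (c - col_mid)
                )
                value = (
                    true_val * gradient * rng.lognormal(0.0, config.replicate_cv)
                    + config.autofluorescence
                )
                rows.append(
                    {
                        "plate_id": plate_id,
                        "row": r,
                        "col": c,
                        "strain_id": strain,
                        "replicate": rep + 1,
                        "value": value,
                        "is_control": is_ctrl,
                        "is_autofluorescence": is_autofl,
                    }
                )
    panel = simulate_reference_panel(config, rng)
    return pd.DataFrame(rows), panel


# ---------------------------------------------------------------------------
# Competition
# ---------------------------------------------------------------------------


def simulate_competition_assay(
    true_fitness: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Two-fluorophore competition counts under deterministic ratio dynamics
    ln(Y/G)_g = ln(Y/G)_0 + g ln(w), with multinomial counting noise at the
    configured event count (exact expected counts when ``noise`` is off)."""
    if true_fitness <= 0:
        raise ConfigurationError("true_fitness must be positive")
    rng = config.rng() if rng is None else rng
    rows = []
    for g in config.competition_generations:
        ratio = config.competition_initial_ratio * true_fitness**g
        f = ratio / (1.0 + ratio)
        if noise:
            yfp = int(rng.binomial(config.competition_events, f))
            yfp = min(max(yfp, 1), config.competition_events - 1)
            gfp = config.competition_events - yfp
        else:
            yfp = f * config.competition_events
            gfp = (1.0 - f) * config.competition_events
        rows.append({"generations": g, "yfp_count": yfp, "gfp_count": gfp})
    return pd.DataFrame(rows)


def null_strain_config(config: SimConfig) -> SimConfig:
    """The same cohort conditions with no causal mutations (for specificity
    and calibration runs)."""
    return replace(config, n_causal=0)
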