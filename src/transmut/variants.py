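"""Reading, filtering and annotation of mutation calls.

Variant calls enter as freebayes-dialect VCF (one pooled sample per
fluorescence bulk) or as tabular records.  Filtering applies the stringent
per-field thresholds used to remove false positive calls from pooled
sequencing data; annotation places each point mutation in a coding, intronic
or intergenic context and, for coding SNVs, rewrites the affected codon on
the coding strand to classify the change as synonymous, nonsynonymous or
nonsense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import ConfigurationError, DataError, VcfParseError

logger = logging.getLogger(__name__)

#: INFO fields consumed from freebayes output.  AO and the quality metrics
#: with Number=A are taken per ALT allele after decomposition.
INFO_FIELDS = (
    "MQM", "DP", "AO", "RO", "PAIRED", "PAIREDR", "SAP", "EPP", "RPP",
    "FREQ.REF",
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One ALT allele of a variant call with its freebayes annotations.

    ``bulk_counts`` holds ((low_ref, low_alt), (high_ref, high_alt)) read
    counts from the two pooled bulk samples when present.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    info: dict[str, float] = field(default_factory=dict)
    bulk_counts: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")


@dataclass
class GeneModel:
    """A gene as an ordered set of CDS intervals on one strand.

    ``cds_segments`` are 1-based inclusive (start, end) pairs in genomic
    coordinates, ordered 5'->3' on the coding strand (i.e. descending start
    for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be + or -, got {self.strand!r}")
        if sum(e - s + 1 for s, e in self.cds_segments) % 3 != 0:
            raise ConfigurationError(
                f"CDS length of {self.gene_id} not divisible by 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.cds_segments]
        ends = [e for _, e in self.cds_segments]
        return min(starts), max(ends)

    def contains_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)


@dataclass
class Mutation:
    """A single genomic change with its regional and coding annotation."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mtype: str = "SNV"  # SNV | indel | aneuploidy
    region: str = "NA"  # coding | intron | intergenic | NA
    effect: str = "NA"  # synonymous | nonsynonymous | nonsense | NA
    aa_from: str | None = None
    aa_to: str | None = None
    gene: str | tuple[str, str] | None = None
    status: str = "ambiguous"  # trans_regulatory | non_regulatory | ambiguous


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def _per_alt(value, i: int):
    """Pick the i-th entry of a per-ALT (Number=A) INFO value."""
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else None
    return value


def read_freebayes_vcf(
    path: str,
    low_sample: str | None = None,
    high_sample: str | None = None,
) -> list[VariantRecord]:
    """Read a freebayes VCF into per-ALT :class:`VariantRecord` objects.

    Multi-allelic records are decomposed into one record per ALT allele.
    Missing INFO fields are simply absent from ``info`` (they are not
    zero-filled), which makes the corresponding filter rule a pass.
    FREQ.REF, which freebayes does not emit, is derived as RO/(RO+AO) when
    both counts are present.  Per-bulk allele counts are taken from the
    per-sample RO/AO FORMAT fields of the two pooled samples.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(path)
    samples = list(vcf.samples)
    li = samples.index(low_sample) if low_sample else 0
    hi = samples.index(high_sample) if high_sample else (1 if len(samples) > 1 else None)

    records: list[VariantRecord] = []
    n = 0
    try:
        for v in vcf:
            n += 1
            for i, alt in enumerate(v.ALT):
                info: dict[str, float] = {}
                for key in ("MQM", "AO", "PAIRED", "SAP", "EPP", "RPP"):
                    val = _per_alt(v.INFO.get(key), i)
                    if val is not None:
                        info[key] = float(val)
                for key in ("DP", "RO", "PAIREDR"):
                    val = v.INFO.get(key)
                    if val is not None:
                        info[key] = float(val)
                fr = v.INFO.get("FREQ.REF")
                if fr is not None:
                    info["FREQ.REF"] = float(fr)
                elif "RO" in info and "AO" in info and info["RO"] + info["AO"] > 0:
                    info["FREQ.REF"] = info["RO"] / (info["RO"] + info["AO"])
                for key, _ in v.INFO:
                    if key not in INFO_FIELDS:
                        logger.debug("ignoring INFO field %s", key)

                bulk = None
                if len(samples) >= 2 and hi is not None:
                    try:
                        ro = v.format("RO")
                        ao = v.format("AO")
                    except KeyError:
                        ro = ao = None
                    if ro is not None and ao is not None:
                        ro = ro.reshape(len(samples), -1)[:, 0]
                        ao_i = ao.reshape(len(samples), -1)[:, i]
                        bulk = (
                            (int(ro[li]), int(ao_i[li])),
                            (int(ro[hi]), int(ao_i[hi])),
                        )
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        qual=v.QUAL,
                        info=info,
                        bulk_counts=bulk,
                    )
                )
    except Exception as exc:  # cyvcf2 raises on malformed records
        if isinstance(exc, (DataError,)):
            raise
        raise VcfParseError(f"malformed VCF record near data line {n + 1} of {path}") from exc
    return records


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

#: (field, operator, threshold); ``gt`` keeps values strictly above the
#: threshold, ``lt`` strictly below.  QUAL is read from the record's own
#: quality, the rest from INFO.
DEFAULT_THRESHOLDS: dict[str, tuple[str, float]] = {
    "QUAL": ("gt", 200),
    "MQM": ("gt", 27),
    "DP": ("gt", 20),
    "AO": ("gt", 3),
    "RO": ("gt", 3),
    "FREQ.REF": ("gt", 0.1),
    "PAIRED": ("gt", 0.8),
    "PAIREDR": ("gt", 0.8),
    "SAP": ("lt", 100),
    "EPP": ("lt", 50),
    "RPP": ("lt", 50),
}


def filter_variants(
    records: Iterable[VariantRecord],
    thresholds: Mapping[str, tuple[str, float]] | None = None,
) -> list[VariantRecord]:
    """Retain records whose present fields all satisfy their inequality.

    Inequalities are strict, so a value exactly at its threshold is removed.
    A field absent from a record's INFO passes its rule (absence of an
    annotation is not treated as evidence against the call).  Order is
    preserved and per-rule removal counts are logged.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    for name, (op, cut) in thresholds.items():
        if op not in ("gt", "lt"):
            raise ConfigurationError(f"unknown operator {op!r} for {name}")
        if not isinstance(cut, (int, float)):
            raise ConfigurationError(f"non-numeric threshold for {name}: {cut!r}")

    removed_per_rule: dict[str, int] = {name: 0 for name in thresholds}
    kept: list[VariantRecord] = []
    for rec in records:
        ok = True
        for name, (op, cut) in thresholds.items():
            value = rec.qual if name == "QUAL" else rec.info.get(name)
            if value is None:
                continue
            if (op == "gt" and not value > cut) or (op == "lt" and not value < cut):
                removed_per_rule[name] += 1
                ok = False
        if ok:
            kept.append(rec)
    for name, count in removed_per_rule.items():
        if count:
            logger.info("filter rule %s removed %d record(s)", name, count)
    return kept


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _cds_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    chrom_seq = genome[gene.chrom]
    parts = [chrom_seq[s - 1 : e] for s, e in sorted(gene.cds_segments)]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds.upper()


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the coding sequence."""
    segments = sorted(gene.cds_segments)
    offset = 0
    if gene.strand == "+":
        for s, e in segments:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
    else:
        for s, e in reversed(segments):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
    raise DataError(f"position {pos} not in CDS of {gene.gene_id}")


def annotate_mutation(
    mutation: Mutation,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> Mutation:
    """Assign region, flanking/host gene and coding effect to a mutation.

    Coding SNVs have their codon rewritten on the annotated coding strand and
    translated with the standard genetic code; a new stop codon is a nonsense
    change.  Intergenic mutations record the flanking gene pair.  Aneuploidy
    records keep NA region/effect.
    """
    if mutation.mtype == "aneuploidy":
        return replace(mutation, region="NA", effect="NA")

    chrom_genes = [g for g in gene_models if g.chrom == mutation.chrom]
    host = next((g for g in chrom_genes if g.contains_cds(mutation.pos)), None)

    if host is None:
        intron_host = next(
            (g for g in chrom_genes if g.span[0] <= mutation.pos <= g.span[1]),
            None,
        )
        if intron_host is not None:
            return replace(mutation, region="intron", effect="NA", gene=intron_host.gene_id)
        # intergenic: nearest gene on each side
        left = [g for g in chrom_genes if g.span[1] < mutation.pos]
        right = [g for g in chrom_genes if g.span[0] > mutation.pos]
        lg = max(left, key=lambda g: g.span[1]).gene_id if left else ""
        rg = min(right, key=lambda g: g.span[0]).gene_id if right else ""
        return replace(mutation, region="intergenic", effect="NA", gene=(lg, rg))

    if mutation.mtype != "SNV":
        return replace(mutation, region="coding", effect="NA", gene=host.gene_id)

    chrom_seq = genome[mutation.chrom]
    ref_base = chrom_seq[mutation.pos - 1].upper()
    if ref_base != mutation.ref.upper():
        raise DataError(
            f"ref allele {mutation.ref} at {mutation.chrom}:{mutation.pos} "
            f"disagrees with genome sequence {ref_base}"
        )

    cds = _cds_sequence(host, genome)
    offset = _cds_offset(host, mutation.pos)
    alt_base = mutation.alt.upper()
    if host.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    codon_i = offset // 3
    within = offset % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_from = str(Seq(codon).translate())
    aa_to = str(Seq(new_codon).translate())
    if aa_to == "*" and aa_from != "*":
        effect = "nonsense"
    elif aa_from == aa_to:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return replace(
        mutation,
        region="coding",
        effect=effect,
        aa_from=aa_from,
        aa_to=aa_to,
        gene=host.gene_id,
    )


# ---------------------------------------------------------------------------
# Mutation spectrum
# ---------------------------------------------------------------------------

SPECTRUM_CLASSES = (
    "GC_to_AT_transition",
    "other_transition",
    "transversion",
    "indel",
    "aneuploidy",
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def classify_snv(ref: str, alt: str) -> str:
    """Spectrum class of a single-base substitution, complement-collapsed."""
    pair = (ref.upper(), alt.upper())
    if pair in (("G", "A"), ("C", "T")):
        return "GC_to_AT_transition"
    if pair in _TRANSITIONS:
        return "other_transition"
    return "transversion"


def classify_spectrum(mutations: Iterable[Mutation]) -> dict[str, int]:
    """Count mutations by spectrum class; counts sum to the input size."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for m in mutations:
        if m.mtype == "aneuploidy":
            counts["aneuploidy"] += 1
        elif m.mtype == "indel" or len(m.ref) != len(m.alt):
            counts["indel"] += 1
        else:
            counts[classify_snv(m.ref, m.alt)] += 1
    return counts
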