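"""Variant- and genotype-level filters and per-sample carrier collapsing.

The pipeline keeps high-quality genotypes (alt allele depth >= 20 and,
for heterozygotes, variant allele fraction >= 0.25), restricts to rare
variants (population MAF < 0.1%, absent = 0), applies a deliberately
minimal ACMG-style P/LP rule (PVS1-type truncation evidence plus
novelty/prior-report evidence), and collapses qualifying genotypes to a
single carrier flag per individual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .transcripts import ConsequenceCall, TranscriptModel
from .variants import GenotypeCall, VariantRecord, Zygosity

logger = logging.getLogger(__name__)

#: default thresholds
MIN_ALLELE_DEPTH = 20
MIN_HET_VAF = 0.25
MAX_MAF = 0.001
CNV_MIN_EXONS = 3


class AcmgClass(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    vus = "vus"
    likely_benign = "likely_benign"
    benign = "benign"
    unclassified = "unclassified"


#: classes reported as P/LP
PLP_CLASSES = frozenset({AcmgClass.pathogenic, AcmgClass.likely_pathogenic})


@dataclass(frozen=True)
class VariantAnnotation:
    """Population-frequency and knowledge annotations for one variant."""

    variant: VariantRecord
    population_maf: Optional[float] = None
    clinvar_id: Optional[str] = None
    previously_reported: bool = False
    acmg_class: AcmgClass = AcmgClass.unclassified

    def __post_init__(self) -> None:
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise ValueError(f"population_maf must be in [0,1], got {self.population_maf}")


@dataclass(frozen=True)
class CnvCall:
    """An already-called copy-number variant interval for one sample."""

    sample_id: str
    contig: str
    start: int
    end: int
    copy_state: str  # "del" or "dup"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNV start > end")


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def genotype_qc(
    g: GenotypeCall,
    min_allele_depth: int = MIN_ALLELE_DEPTH,
    min_het_vaf: float = MIN_HET_VAF,
) -> QcResult:
    """High-quality genotype filter.

    Passes iff alt allele depth >= ``min_allele_depth`` and, for
    heterozygous calls only, VAF >= ``min_het_vaf``.  Both thresholds are
    inclusive.
    """
    if g.total_depth == 0:
        return QcResult(False, "no coverage")
    if g.allele_depth < min_allele_depth:
        return QcResult(False, f"allele depth {g.allele_depth} < {min_allele_depth}")
    if g.zygosity == Zygosity.het and g.vaf < min_het_vaf:
        return QcResult(False, f"het VAF {g.vaf:.3f} < {min_het_vaf}")
    return QcResult(True)


def rarity_filter(a: VariantAnnotation, max_maf: float = MAX_MAF) -> bool:
    """Rare iff population MAF strictly below ``max_maf``.

    A variant absent from the reference panel (``population_maf`` None)
    is treated as MAF 0 and passes: novel variants must survive.
    """
    maf = a.population_maf if a.population_maf is not None else 0.0
    return maf < max_maf


def cnv_exon_span_filter(
    c: CnvCall, t: TranscriptModel, min_exons: int = CNV_MIN_EXONS
) -> bool:
    """Flag a CNV that overlaps at least ``min_exons`` *consecutive* exons."""
    if c.contig != t.contig:
        return False
    overlapped = [not (c.end < s or c.start > e) for s, e in t.exons]
    run = best = 0
    for hit in overlapped:
        run = run + 1 if hit else 0
        best = max(best, run)
    return best >= min_exons


def classify_acmg_lite(call: ConsequenceCall, a: VariantAnnotation) -> AcmgClass:
    """Minimal PVS1+PM2-style surrogate classification.

    Assumes the rarity filter already passed.  A PTV with a prior report
    or ClinVar entry is pathogenic; a novel PTV is likely pathogenic;
    anything else is not reportable here (returned as ``vus``).
    """
    if not call.is_ptv:
        return AcmgClass.vus
    if a.previously_reported or a.clinvar_id:
        return AcmgClass.pathogenic
    return AcmgClass.likely_pathogenic


@dataclass(frozen=True)
class CarrierStatus:
    sample_id: str
    is_carrier: bool
    qualifying_variants: tuple[str, ...] = ()
    classifications: tuple[str, ...] = ()
    has_homozygous: bool = False


def collapse_carriers(
    genotypes: Iterable[GenotypeCall],
    classifications: Mapping[str, tuple[bool, AcmgClass]],
    all_samples: Optional[Sequence[str]] = None,
    min_allele_depth: int = MIN_ALLELE_DEPTH,
    min_het_vaf: float = MIN_HET_VAF,
) -> pd.DataFrame:
    """Collapse QC-passing P/LP PTV genotypes to one carrier flag per sample.

    ``classifications`` maps a variant key (``VariantRecord.token`` or
    the record ``id``) to ``(is_ptv, acmg_class)``.  A sample is a
    carrier iff it holds at least one qualifying genotype; multiple
    qualifying variants still count once.  Homozygous qualifying
    genotypes are counted as carriers with a warning (the burden
    contrast is carrier vs non-carrier, but the analysis concerns
    monoallelic carriers).

    Returns a DataFrame indexed by sample with columns ``carrier``,
    ``qualifying_variants``, ``classifications``.
    """
    per_sample: dict[str, list[tuple[str, AcmgClass, Zygosity]]] = {}
    seen_samples: list[str] = []
    for g in genotypes:
        sid = g.sample_id
        if sid not in per_sample:
            per_sample[sid] = []
            seen_samples.append(sid)
        if not genotype_qc(g, min_allele_depth, min_het_vaf):
            continue
        key = g.variant.token
        cls = classifications.get(key)
        if cls is None and g.variant.id is not None:
            cls = classifications.get(g.variant.id)
        if cls is None:
            continue
        is_ptv, acmg = cls
        if is_ptv and acmg in PLP_CLASSES:
            per_sample[sid].append((key, acmg, g.zygosity))

    samples = list(all_samples) if all_samples is not None else seen_samples
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in manifest")
    rows = []
    for sid in samples:
        hits = per_sample.get(sid, [])
        hom = [h for h in hits if h[2] != Zygosity.het]
        if hom:
            warnings.warn(
                f"sample {sid}: homozygous/hemizygous qualifying PTV counted as carrier",
                stacklevel=2,
            )
        rows.append(
            {
                "sample_id": sid,
                "carrier": bool(hits),
                "qualifying_variants": ";".join(sorted({h[0] for h in hits})),
                "classifications": ";".join(sorted({h[1].value for h in hits})),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def qualifying_variant_classifications(
    calls: Iterable[ConsequenceCall],
    annotations: Mapping[str, VariantAnnotation],
    max_maf: float = MAX_MAF,
) -> dict[str, tuple[bool, AcmgClass]]:
    """Build the variant -> (is_ptv, acmg) map used by ``collapse_carriers``.

    Variants failing the rarity filter are dropped here, so filter order
    relative to genotype QC cannot affect the carrier set.
    """
    out: dict[str, tuple[bool, AcmgClass]] = {}
    for call in calls:
        key = call.variant.token
        ann = annotations.get(key, VariantAnnotation(variant=call.variant))
        if not rarity_filter(ann, max_maf):
            continue
        out[key] = (call.is_ptv, classify_acmg_lite(call, ann))
    return out


def drop_related(manifest: pd.DataFrame, column: str = "exclude_related") -> pd.DataFrame:
    """Drop individuals flagged as related in the manifest, logging the count."""
    if column not in manifest.columns:
        return manifest
    flagged = manifest[column].fillna(False).astype(bool)
    if flagged.any():
        logger.info("dropping %d related individuals", int(flagged.sum()))
    return manifest.loc[~flagged].drop(columns=[column])
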