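"""End-to-end pipeline: genotype table -> consequences -> filters ->
carrier collapsing -> burden statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from . import burden as bd
from .filtering import (
    MAX_MAF,
    MIN_ALLELE_DEPTH,
    MIN_HET_VAF,
    VariantAnnotation,
    collapse_carriers,
    qualifying_variant_classifications,
)
from .transcripts import TranscriptModel, classify_consequence
from .variants import GenotypeCall, VariantRecord, Zygosity


@dataclass
class BurdenAnalysis:
    """Carrier manifests and the burden result for one case-control contrast."""

    case_carriers: pd.DataFrame
    control_carriers: pd.DataFrame
    table: bd.ContingencyTable
    result: bd.BurdenResult


def carrier_manifest(
    genotypes: pd.DataFrame,
    transcript: TranscriptModel,
    annotations: Mapping[str, VariantAnnotation],
    all_samples: Optional[list[str]] = None,
    min_allele_depth: int = MIN_ALLELE_DEPTH,
    min_het_vaf: float = MIN_HET_VAF,
    max_maf: float = MAX_MAF,
) -> pd.DataFrame:
    """Annotate, filter, and collapse a genotype table to per-sample carrier flags."""
    uniq = genotypes[["contig", "pos", "ref", "alt"]].drop_duplicates()
    calls = [
        classify_consequence(
            transcript,
            VariantRecord(contig=r.contig, pos=int(r.pos), ref=r.ref, alt=r.alt),
        )
        for r in uniq.itertuples(index=False)
    ]
    classifications = qualifying_variant_classifications(calls, annotations, max_maf)
    gcalls = [
        GenotypeCall(
            sample_id=r.sample_id,
            variant=VariantRecord(contig=r.contig, pos=int(r.pos), ref=r.ref, alt=r.alt),
            zygosity=Zygosity(r.zygosity),
            allele_depth=int(r.allele_depth),
            total_depth=int(r.total_depth),
        )
        for r in genotypes.itertuples(index=False)
    ]
    return collapse_carriers(
        gcalls, classifications, all_samples, min_allele_depth, min_het_vaf
    )


def analyze_cohort(
    genotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    transcript: TranscriptModel,
    annotations: Mapping[str, VariantAnnotation],
    level: float = 0.95,
    **thresholds,
) -> BurdenAnalysis:
    """Run the full burden analysis on one cohort with a ``panel`` column."""
    if "panel" not in manifest.columns:
        raise ValueError("manifest requires a 'panel' column with case/control")
    carriers = carrier_manifest(
        genotypes, transcript, annotations, all_samples=list(manifest.index), **thresholds
    )
    case_ids = manifest.index[manifest["panel"] == "case"]
    control_ids = manifest.index[manifest["panel"] == "control"]
    case_c = carriers.loc[case_ids]
    control_c = carriers.loc[control_ids]
    table = bd.build_2x2(case_c, control_c)
    return BurdenAnalysis(
        case_carriers=case_c,
        control_carriers=control_c,
        table=table,
        result=bd.burden_test(table, level=level),
    )
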