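"""Packaged study fixtures: carrier roster, variant catalogue, clinical
features, control-cohort variant counts, and the published 2x2 counts.

The tables are transcribed verbatim from the source report.  They carry
one internal inconsistency (a carrier listed with c.4199del that is
absent from the variant catalogue, and a recurrence count of 6 for
c.4234C>T where the roster lists 5); ``validate_tables`` surfaces this
as a warning rather than silently resolving it.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from typing import Optional

import pandas as pd

from .burden import ContingencyTable, pool_controls, table_from_counts
from .filtering import AcmgClass, collapse_carriers
from .transcripts import Consequence
from .variants import GenotypeCall, VariantRecord, Zygosity

_CONSEQUENCE_LABELS = {
    "Stop gain": Consequence.stop_gain,
    "Frameshift": Consequence.frameshift,
    "Canonical splice site": Consequence.canonical_splice,
}

_ACMG_LABELS = {
    "Pathogenic": AcmgClass.pathogenic,
    "Likely pathogenic": AcmgClass.likely_pathogenic,
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("ptvburden.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_carrier_table() -> pd.DataFrame:
    """Per-patient carrier roster (id, variant names, age, sex, phenotypes)."""
    return _read("table1_carriers.tsv")


def load_variant_table() -> pd.DataFrame:
    """Unique case variants with genomic tokens, consequences, and evidence."""
    df = _read("table2_variants.tsv", dtype={"clinvar_id": str})
    df["consequence"] = df["consequence"].map(_CONSEQUENCE_LABELS)
    df["acmg"] = df["acmg"].map(_ACMG_LABELS)
    return df


def load_clinical_table() -> pd.DataFrame:
    """Echocardiographic features of the carriers with clinical follow-up."""
    return _read("table3_clinical.tsv")


def load_control_variant_table() -> pd.DataFrame:
    """Variant-by-panel carrier counts across the control cohorts."""
    df = _read("table4_control_variants.tsv")
    count_cols = [c for c in df.columns if c.endswith("_n")]
    df[count_cols] = df[count_cols].fillna(0).astype(int)
    return df


def validate_tables() -> list[str]:
    """Cross-check the carrier roster against the variant catalogue.

    Returns human-readable warnings for variants present in one table
    but not the other and for recurrence-count mismatches; also emits
    them via ``warnings.warn``.
    """
    roster = load_carrier_table()
    catalogue = load_variant_table()
    roster_counts = roster["hgvs_c"].value_counts()
    cat_counts = catalogue.set_index("hgvs_c")["n_patients"]
    msgs: list[str] = []
    for name in roster_counts.index.difference(cat_counts.index):
        msgs.append(
            f"{name}: listed for {roster_counts[name]} carrier(s) in the roster "
            "but absent from the variant catalogue"
        )
    for name in cat_counts.index.intersection(roster_counts.index):
        if int(cat_counts[name]) != int(roster_counts[name]):
            msgs.append(
                f"{name}: catalogue counts {int(cat_counts[name])} patients, "
                f"roster lists {int(roster_counts[name])}"
            )
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return msgs


def carrier_roster_genotypes() -> tuple[list[GenotypeCall], dict]:
    """Build collapsible genotypes and classifications from the fixtures.

    Each roster row becomes one heterozygous, QC-passing genotype.
    Variants present in the catalogue use their genomic token; a roster
    variant missing from the catalogue gets a placeholder record keyed
    by its coding name and is classified from that name (a frameshift
    here), with a warning.
    """
    roster = load_carrier_table()
    catalogue = load_variant_table().set_index("hgvs_c")
    classifications: dict[str, tuple[bool, AcmgClass]] = {}
    records: dict[str, VariantRecord] = {}
    for name, row in catalogue.iterrows():
        v = VariantRecord.from_token(row["variant"])
        records[name] = v
        classifications[v.token] = (True, row["acmg"])
    next_placeholder = 1
    genotypes = []
    for r in roster.itertuples(index=False):
        name = r.hgvs_c
        if name not in records:
            warnings.warn(
                f"{name} not in the variant catalogue; classifying from its coding name",
                stacklevel=2,
            )
            v = VariantRecord(contig="15", pos=next_placeholder, ref="N", alt="A", id=name)
            next_placeholder += 1
            records[name] = v
            is_ptv = any(tag in name for tag in ("del", "dup", "ins", "+", "-")) or "Ter" in str(
                getattr(r, "hgvs_p", "")
            )
            classifications[name] = (is_ptv, AcmgClass.likely_pathogenic)
        genotypes.append(
            GenotypeCall(
                sample_id=r.patient_id,
                variant=records[name],
                zygosity=Zygosity.het,
                allele_depth=30,
                total_depth=60,
            )
        )
    return genotypes, classifications


def carrier_roster_manifest() -> pd.DataFrame:
    """Collapse the roster fixture to per-sample carrier flags."""
    genotypes, classifications = carrier_roster_genotypes()
    return collapse_carriers(genotypes, classifications)


def published_counts() -> dict:
    """The published case/control cohort sizes and carrier counts."""
    with resources.files("ptvburden.data").joinpath("figure2_counts.json").open() as fh:
        return json.load(fh)


def published_tables() -> list[tuple[str, ContingencyTable]]:
    """The four published 2x2 comparisons (three panels plus pooled)."""
    counts = published_counts()
    case_n, case_a = counts["case_n"], counts["case_carriers"]
    out = []
    panels = []
    for ctrl in counts["controls"]:
        panels.append((ctrl["n"], ctrl["carriers"]))
        out.append(
            (
                ctrl["label"],
                table_from_counts(
                    case_n, case_a, ctrl["n"], ctrl["carriers"],
                    case_label=counts["case_label"], control_label=ctrl["label"],
                ),
            )
        )
    pooled_n, pooled_c = pool_controls(panels)
    out.append(
        (
            counts["combined_label"],
            table_from_counts(
                case_n, case_a, pooled_n, pooled_c,
                case_label=counts["case_label"], control_label=counts["combined_label"],
            ),
        )
    )
    return out


def diagnostic_manifest(
    n_total: int = 2366,
    gene_counts: Optional[dict[str, int]] = None,
    n_diagnosed: int = 482,
    n_multi_gene: int = 18,
) -> pd.DataFrame:
    """Synthetic per-sample diagnostic manifest consistent with the
    published aggregate gene tallies.

    No per-sample diagnostic table is published, so this constructs one
    with the stated totals: ``n_diagnosed`` of ``n_total`` samples carry
    a reported gene, the first ``n_multi_gene`` of them carry a second
    reported gene, and primary genes are allocated per ``gene_counts``
    (remainder pooled under OTHER).
    """
    if gene_counts is None:
        gene_counts = {"MYBPC3": 196, "MYH7": 120, "TNNI3": 59}
    allocated = sum(gene_counts.values())
    if allocated > n_diagnosed:
        raise ValueError("gene counts exceed diagnosed total")
    genes: list[str] = []
    for gene, k in gene_counts.items():
        genes.extend([gene] * k)
    genes.extend(["OTHER"] * (n_diagnosed - allocated))
    rows = []
    for i in range(n_total):
        if i < n_diagnosed:
            entry = genes[i]
            if i < n_multi_gene:
                entry += ";SECONDARY"
        else:
            entry = ""
        rows.append({"sample_id": f"S{i + 1:05d}", "reported_genes": entry})
    return pd.DataFrame(rows).set_index("sample_id")
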