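"""Genus-level classifier consensus and recruitment-database selection.

Several independent genus-level classifiers (alignment- and k-mer-based) are
run on the same samples; their reports decide which genera enter the
recruitment database: a genus qualifies when any method reports it in any
sample at a relative abundance of at least ``min_abundance`` percent
(default 0.1). The database holds one representative genome per species of
the qualifying genera where a genome is available, and is extended with a
curated list of fermentation-relevant species (lactic and acetic acid
bacteria), recorded with a distinct ``source`` value.

The same reports feed composition summaries: genera below the minority
threshold (default 0.9%) in *every* method are folded into a reserved
"Minorities" category alongside the reserved "Higher than genus",
"Unassigned" and "No hits" categories.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

DEFAULT_MIN_ABUNDANCE = 0.1
DEFAULT_MINORITY_THRESHOLD = 0.9

#: reserved non-genus categories, in display order.
RESERVED_CATEGORIES = ("Minorities", "Higher than genus", "Unassigned", "No hits")

REPORT_COLUMNS = ["method", "sample_id", "genus", "relative_abundance"]


def validate_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format classifier report table (method, sample, genus, %)."""
    missing = set(REPORT_COLUMNS) - set(reports.columns)
    if missing:
        raise ValueError(f"classifier report missing columns: {sorted(missing)}")
    if (reports["relative_abundance"] < 0).any():
        bad = reports[reports["relative_abundance"] < 0].iloc[0]
        raise ValueError(
            f"negative abundance for genus {bad['genus']!r} "
            f"({bad['method']}, {bad['sample_id']})"
        )
    if reports.duplicated(["method", "sample_id", "genus"]).any():
        raise ValueError("duplicate (method, sample, genus) rows in report")
    return reports


def select_genera(
    reports: pd.DataFrame, min_abundance: float = DEFAULT_MIN_ABUNDANCE
) -> set[str]:
    """Genera reported at >= min_abundance % by any method in any sample."""
    reports = validate_reports(reports)
    keep = reports[reports["relative_abundance"] >= min_abundance]
    return set(keep["genus"])


def build_manifest(
    genus_set: Iterable[str],
    representatives: pd.DataFrame,
    extension_species: Iterable[str] = (),
) -> pd.DataFrame:
    """Assemble the recruitment-database manifest.

    ``representatives`` maps available genomes, one row per species:
    columns (species, genus, genome_id, taxon_class, group_label,
    total_length). Species of selected genera enter with source="selected";
    extension species enter regardless of genus with
    source="LAB_AAB_extension". Species named in the extension list but
    lacking a representative genome are silently skipped ("if available").
    """
    genus_set = set(genus_set)
    ext = set(extension_species)
    rows = []
    for _, rep in representatives.iterrows():
        in_genus = rep["genus"] in genus_set
        in_ext = rep["species"] in ext
        if not (in_genus or in_ext):
            continue
        rows.append({
            "genome_id": rep["genome_id"],
            "species": rep["species"],
            "genus": rep["genus"],
            "taxon_class": rep["taxon_class"],
            "group_label": rep["group_label"],
            "total_length": int(rep["total_length"]),
            "source": "selected" if in_genus else "LAB_AAB_extension",
        })
    manifest = pd.DataFrame(
        rows,
        columns=[
            "genome_id", "species", "genus", "taxon_class", "group_label",
            "total_length", "source",
        ],
    )
    if manifest["genome_id"].duplicated().any():
        dupes = manifest.loc[manifest["genome_id"].duplicated(), "genome_id"]
        raise ValueError(f"duplicate genome_id in manifest: {dupes.tolist()}")
    if (manifest["total_length"] <= 0).any():
        raise ValueError("manifest contains non-positive genome length")
    return manifest


def categorize_report(
    assignments: pd.DataFrame,
    total_reads: Mapping[str, int] | int,
    minority_threshold: float = DEFAULT_MINORITY_THRESHOLD,
) -> pd.DataFrame:
    """Build per-method composition columns with the reserved categories.

    ``assignments`` is long format with columns (method, label, kind, count)
    where ``kind`` is one of genus/higher/unassigned/nohit. ``total_reads``
    is the per-method read total (or one integer shared by all methods).
    Genera below ``minority_threshold`` percent in every method collapse
    into "Minorities". Returns long format (method, label, percent) whose
    per-method percentages sum to 100.
    """
    need = {"method", "label", "kind", "count"}
    if not need <= set(assignments.columns):
        raise ValueError(f"assignments need columns {sorted(need)}")
    methods = list(dict.fromkeys(assignments["method"]))
    if isinstance(total_reads, int):
        total_reads = {m: total_reads for m in methods}
    if any(total_reads[m] <= 0 for m in methods):
        raise ValueError("total_reads must be positive for every method")

    df = assignments.copy()
    df["percent"] = [
        100.0 * c / total_reads[m] for m, c in zip(df["method"], df["count"])
    ]

    genus_rows = df[df["kind"] == "genus"]
    # fold rule: below threshold in ALL methods -> Minorities
    max_by_genus = genus_rows.groupby("label")["percent"].max()
    minorities = set(max_by_genus[max_by_genus < minority_threshold].index)

    out_rows = []
    kind_to_cat = {"higher": "Higher than genus", "unassigned": "Unassigned",
                   "nohit": "No hits"}
    for m in methods:
        sub = df[df["method"] == m]
        named = sub[(sub["kind"] == "genus") & ~sub["label"].isin(minorities)]
        for _, r in named.iterrows():
            out_rows.append({"method": m, "label": r["label"], "percent": r["percent"]})
        minority_pct = sub[(sub["kind"] == "genus") & sub["label"].isin(minorities)][
            "percent"
        ].sum()
        out_rows.append({"method": m, "label": "Minorities", "percent": minority_pct})
        for kind, cat in kind_to_cat.items():
            out_rows.append({
                "method": m, "label": cat,
                "percent": sub[sub["kind"] == kind]["percent"].sum(),
            })
        # anything not yet assigned (reads recruited above genus etc. already
        # counted); remainder closes the balance to 100%
        assigned = sum(r["percent"] for r in out_rows if r["method"] == m)
        if assigned > 100.0 + 0.01:
            raise ValueError(f"method {m!r}: composition sums to {assigned:.3f} > 100")
    out = pd.DataFrame(out_rows, columns=["method", "label", "percent"])
    return out
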