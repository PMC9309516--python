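"""Bundled example data.

``load_survey_abundance`` returns the species-by-sample relative-abundance
table from a published fruit/flower surface metagenome survey (nine samples:
white guava, closed/open medlar flowers, two passion-fruit and four papaya
ripening stages), as called by fragment-recruitment plotting. Values are the
percentage of each sample's quality-trimmed reads recruited to a species'
genome; a trailing asterisk in the source marks two read clouds and is
parsed into a boolean column.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SURVEY_SAMPLES = ["WGF", "MFC", "MFO", "PFA", "PFR", "PAU", "PAA", "PAR1", "PAR2"]


def load_survey_abundance() -> pd.DataFrame:
    """Long-format survey table: sample_id, group, kingdom, species, percent,
    two_clouds."""
    ref = resources.files("frpipe.data") / "fruit_flower_species_abundance.tsv"
    with resources.as_file(ref) as path:
        wide = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    rows = []
    for _, r in wide.iterrows():
        for sample in SURVEY_SAMPLES:
            cell = r.get(sample)
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            cell = str(cell).strip()
            two = cell.endswith("*")
            rows.append({
                "sample_id": sample,
                "group": r["group"],
                "kingdom": r["kingdom"],
                "species": r["species"],
                "percent": float(cell.rstrip("*")),
                "two_clouds": two,
            })
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "kingdom", "species", "percent", "two_clouds"],
    )
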