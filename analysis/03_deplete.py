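#!/usr/bin/env python
"""Remove host-plant reads (>= 60% identity and >= 60% query coverage).

The demo plants 10% host reads at 2% divergence; depletion should remove
almost exactly that fraction.
"""

import pandas as pd

from common import CONFIG, WORKDIR
from frpipe.pipeline import run_pipeline

run_pipeline(CONFIG, WORKDIR, ["deplete"])

stats = pd.read_csv(WORKDIR / "depleted" / "depletion_stats.tsv", sep="\t")
trim = pd.read_csv(WORKDIR / "trimmed" / "trim_stats.tsv", sep="\t")
print(stats.to_string(index=False))
removed = stats["Number of MSRs aligned to plant genomes"].iloc[0]
total = trim["Total number of MSRs after trimming"].iloc[0]
print(f"-> removed {removed} of {total} trimmed reads "
      f"({100.0 * removed / total:.2f}%)")
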