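#!/usr/bin/env python
"""Recruit reads to the genome database and call species presence.

Per genome: best qualifying hit per read, recruited-read ANI, ten-section
coverage counts, the RSD uniformity statistic, two-cloud detection, and the
presence rule (>= 1000 reads, RSD < 0.8).
"""

import pandas as pd

from common import CONFIG, WORKDIR
from frpipe.pipeline import run_pipeline

run_pipeline(CONFIG, WORKDIR, ["build-db", "recruit", "call"])

calls = pd.read_csv(WORKDIR / "calls" / "demo.presence.tsv", sep="\t")
cols = ["species", "present", "ani", "ani_band", "two_clouds",
        "relative_abundance", "n_reads", "rsd", "fail_reasons"]
print(calls[cols].to_string(index=False))
present = calls.loc[calls["present"], "species"].tolist()
print(f"-> present: {present}")
rejected = calls.loc[~calls["present"], ["species", "fail_reasons"]]
for _, r in rejected.iterrows():
    print(f"-> rejected {r['species']}: {r['fail_reasons'] or 'no reads'}")
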