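#!/usr/bin/env python
"""Render the fragment recruitment plots (one per genome) with TSV twins.

Planted members show a flat read band at their planted identity; the
artifact genome shows a single dense block in one genome tenth; the decoy
stays empty.
"""

from common import CONFIG, WORKDIR
from frpipe.pipeline import run_pipeline

outputs = run_pipeline(CONFIG, WORKDIR, ["report"])
pngs = [p for p in outputs["report"] if p.endswith(".png")]
print(f"wrote {len(pngs)} recruitment plots (with TSV twins) under "
      f"{WORKDIR / 'figures'}")
for p in pngs:
    print(" ", p)
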