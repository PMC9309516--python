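#!/usr/bin/env python
"""Alpha diversity of the demo sample (and, with one sample, nothing more).

Simpson (D) and Pielou (Je) over the recruited relative abundances; the
between-sample statistics (PERMANOVA, SIMPER, PCA) need several samples and
are demonstrated on the bundled multi-sample survey table in
07_survey_stats.py.
"""

import pandas as pd

from common import CONFIG, WORKDIR
from frpipe.pipeline import run_pipeline

run_pipeline(CONFIG, WORKDIR, ["diversity"])

div = pd.read_csv(WORKDIR / "stats" / "diversity.tsv", sep="\t")
print(div.to_string(index=False))
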