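"""Shared locations for the analysis drivers."""

from pathlib import Path

from frpipe.config import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
WORKDIR = RESULTS / "pipeline"

CONFIG = PipelineConfig(seed=11)
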