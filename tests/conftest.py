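import numpy as np
import pytest

from frpipe.io import ReadRecord
from frpipe.synthetic import (
    CommunityDesign, GenomeSpec, Member, generate_genomes, simulate_alignments,
    simulate_reads,
)


def make_read(read_id: str, length: int, quality, rng=None) -> ReadRecord:
    rng = rng or np.random.default_rng(0)
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    q = np.full(length, quality) if np.isscalar(quality) else np.asarray(quality)
    return ReadRecord(read_id, bases, q)


@pytest.fixture(scope="session")
def small_community():
    """A two-member community plus host and no-hit reads, with alignments."""
    specs = [
        GenomeSpec("gA", "Alpha exampli", "Alpha", "Gammaproteobacteria",
                   (30_000, 20_000), seed=1),
        GenomeSpec("gB", "Beta exampli", "Beta", "Firmicutes", (40_000,), seed=2),
    ]
    host_specs = [
        GenomeSpec("hostX", "Hostus x", "Hostus", "Viridiplantae", (60_000,), seed=3),
    ]
    design = CommunityDesign(
        sample_id="s1",
        members=[
            Member("gA", 0.45, divergence=0.03),
            Member("gB", 0.25, divergence=0.0),
        ],
        host_fraction=0.15,
        unclassified_fraction=0.15,
        n_reads=8000,
        seed=42,
    )
    genomes = generate_genomes(specs)
    host = generate_genomes(host_specs)
    reads, truth = simulate_reads(design, genomes, host)
    alignments = simulate_alignments(truth, reads, genomes, host,
                                     design.members, seed=43)
    return {
        "specs": specs, "host_specs": host_specs, "design": design,
        "genomes": genomes, "host": host, "reads": reads, "truth": truth,
        "alignments": alignments,
    }
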