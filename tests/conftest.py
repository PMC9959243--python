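import numpy as np
import pytest

from rilmap.genotypes import GenotypeMatrix, MarkerDef
from rilmap.simulate import (
    ChromosomeSpec,
    GenomeSpec,
    SimConfig,
    simulate_ril_population,
    uniform_marker_loci,
)


def make_matrix(rows: list[str], line_ids=None, markers=None, chrom="1",
                spacing_bp=1_000_000) -> GenotypeMatrix:
    """Build a small matrix from call strings, e.g. ["AABB-", "ABHBA"]."""
    from rilmap.genotypes import SYMBOL_TO_CODE

    n_lines = len(rows[0])
    line_ids = line_ids or [f"L{j+1}" for j in range(n_lines)]
    markers = markers or [
        MarkerDef(f"SNP/{chrom}/{(i + 1) * spacing_bp}", chrom, (i + 1) * spacing_bp)
        for i in range(len(rows))
    ]
    calls = np.array(
        [[SYMBOL_TO_CODE[s] for s in row] for row in rows], dtype=np.int8
    )
    return GenotypeMatrix(line_ids, markers, calls)


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec([ChromosomeSpec(str(i + 1), 100.0, 30_000_000) for i in range(3)])


@pytest.fixture(scope="session")
def f7_population(small_genome):
    """One 96-line F7 population with 30 evenly spaced markers per
    chromosome, shared by tests that only read from it."""
    cfg = SimConfig(n_lines=96, final_generation=7, seed=42)
    truth = simulate_ril_population(small_genome, cfg)
    loci = uniform_marker_loci(small_genome, 30)
    return truth, loci, cfg
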