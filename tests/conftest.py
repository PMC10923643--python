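import numpy as np
import pandas as pd
import pytest

from fruitmethyl import bin_windows, call_dmrs, generate_genome, simulate_methylomes
from fruitmethyl.synthetic_data import SimulationSpec


def make_records(rows):
    """Canonical per-cytosine table from (chrom,pos,strand,context,c,n) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "c_count", "total_count"]
    )
    return df.astype(
        {"chrom": str, "pos": np.int64, "strand": str, "context": str,
         "c_count": np.int64, "total_count": np.int64}
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Parameter-recovery study: flat stage means, +0.15 CHH shift in 10% of
    200-bp windows, 40x coverage — with CHH DMRs called for both later-stage
    comparisons against the first stage."""
    spec = SimulationSpec.recovery(genome_length=600_000, n_genes=80, seed=11)
    sequences, genes, tes = generate_genome(spec)
    tables, truth = simulate_methylomes(spec, sequences, genes=genes)
    sizes = {k: len(v) for k, v in sequences.items() if k != spec.control_name}

    def chh_dmrs(stage_a, stage_b):
        a = tables[stage_a]
        b = tables[stage_b]
        windows = bin_windows(
            a[a["chrom"] != spec.control_name],
            b[b["chrom"] != spec.control_name],
            sizes,
            contexts=("CHH",),
        )
        return call_dmrs(windows)

    return {
        "spec": spec,
        "sequences": sequences,
        "genes": genes,
        "tables": tables,
        "truth": truth,
        "sizes": sizes,
        "dmrs_ef": chh_dmrs("YF", "EF"),
        "dmrs_mf": chh_dmrs("YF", "MF"),
    }
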