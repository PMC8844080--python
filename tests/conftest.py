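import numpy as np
import pandas as pd
import pytest

from methcross.simulate import GenomeSpec, simulate_scenario

TINY_SPEC = GenomeSpec(n_genes=120, n_te_genes=60)


@pytest.fixture(scope="session")
def met1_f1_small():
    """One small met1_f1 scenario shared across tests (read-only)."""
    return simulate_scenario("met1_f1", 11, genome_spec=TINY_SPEC)


@pytest.fixture(scope="session")
def mi_siblings_small():
    return simulate_scenario("mi_siblings", 11, genome_spec=TINY_SPEC)


def random_records(rng, n=200, chroms=("Chr1", "Chr2"), max_pos=10_000):
    """A valid random cytosine-record frame (positions unique per chromosome)."""
    frames = []
    for chrom in chroms:
        pos = rng.choice(np.arange(1, max_pos + 1), size=n // len(chroms), replace=False)
        pos.sort()
        k = len(pos)
        meth = rng.integers(0, 30, k)
        unmeth = rng.integers(0, 30, k)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": rng.choice(["+", "-"], k),
                    "n_meth": meth,
                    "n_unmeth": unmeth,
                    "context": rng.choice(["CG", "CHG", "CHH"], k),
                    "tri": ".",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
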