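import numpy as np
import pytest

from strpopgen.strdata import MISSING, GenotypeTable, Locus


def make_table(pop_calls, locus_names=None, repeat_units=None):
    """Build a GenotypeTable from {population: {locus: [(a, b) in tenths]}}.

    All populations must list the same loci and the same number of
    individuals per locus.
    """
    pops = list(pop_calls)
    locus_names = locus_names or list(next(iter(pop_calls.values())))
    panel = [
        Locus(n, (repeat_units or {}).get(n, 4)) for n in locus_names
    ]
    sample_ids, populations = [], []
    per_locus = {n: [] for n in locus_names}
    for pop in pops:
        n_ind = len(pop_calls[pop][locus_names[0]])
        for i in range(n_ind):
            sample_ids.append(f"{pop}_{i}")
            populations.append(pop)
        for n in locus_names:
            per_locus[n] += list(pop_calls[pop][n])
    calls = {
        n: np.array(v, dtype=np.int64).reshape(-1, 2) for n, v in per_locus.items()
    }
    return GenotypeTable(panel, sample_ids, populations, calls)


@pytest.fixture
def two_pop_table():
    """Two small populations, two loci, including a microvariant and a miss."""
    return make_table(
        {
            "alpha": {
                "TH01": [(60, 70), (93, 93), (60, 60), (70, 93)],
                "FGA": [(200, 210), (210, 220), (200, 200), (MISSING, MISSING)],
            },
            "beta": {
                "TH01": [(60, 60), (60, 70), (70, 70), (93, 70)],
                "FGA": [(220, 230), (220, 220), (230, 230), (200, 230)],
            },
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
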