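import pandas as pd
import pytest

import ncrf
from ncrf.pipeline import classify_reads


def make_assignments(rows):
    """Build an assignment table from (read_id, precursor_id, cls, start,
    end, mismatches) tuples; insert sequences are placeholders."""
    return pd.DataFrame(
        [
            {
                "read_id": r[0],
                "precursor_id": r[1],
                "class": r[2],
                "start": r[3],
                "end": r[4],
                "mismatches": r[5] if len(r) > 5 else 0,
                "insert_length": r[4] - r[3],
                "insert": "A" * (r[4] - r[3]),
            }
            for r in rows
        ]
    )


@pytest.fixture(scope="session")
def tiny_reference():
    """Handcrafted two-class reference with known sequences."""
    seqs = {
        "miRNA-0001": "ACGTACGTAGCTAGCTAGGATCCAGTCAGTCAGGCTAGCTAACGTTGCA",
        "miRNA-0002": "TTGACCGGTTAACCGGATATATCCGGAATTCCGGTTAACCGGTTAACCA",
        "tRNA-0001": "GGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGG",
    }
    annot = pd.DataFrame(
        {
            "precursor_id": list(seqs),
            "class": ["miRNA", "miRNA", "tRNA"],
            "family": ["miRNA-0001", "miRNA-0002", "GlyGCC"],
            "length": [len(s) for s in seqs.values()],
        }
    ).set_index("precursor_id")
    return seqs, annot


@pytest.fixture(scope="session")
def sim_params():
    return ncrf.SimulationParams(seed=1, n_reads=10_000)


@pytest.fixture(scope="session")
def sim_dataset(sim_params):
    """One simulated 10k-read pool with its reference and ground truth."""
    seqs, annot = ncrf.make_reference(sim_params)
    reads, truth = ncrf.simulate_sample(sim_params, seqs, annot)
    return sim_params, seqs, annot, reads, truth


@pytest.fixture(scope="session")
def sim_classified(sim_dataset):
    """The simulated pool run through trimming + assignment."""
    params, seqs, annot, reads, truth = sim_dataset
    index = ncrf.PrecursorIndex(seqs, annot)
    assignments, stats = classify_reads(reads, index, params.adaptor)
    return params, seqs, annot, reads, truth, assignments, stats
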