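import pandas as pd
import pytest

from vdjflow.synthetic import SimConfig, simulate_jhits, simulate_repertoire


def make_contigs(rows):
    """Build a minimal contig table from shorthand dicts."""
    defaults = {
        "cell_id": "cellA", "sample_id": "S1", "locus": "TRB",
        "v_call": "", "d_call": "", "j_call": "", "c_call": "",
        "junction": "", "junction_aa": "", "productive": "T",
        "vj_in_frame": "T", "stop_codon": "F", "duplicate_count": 1,
        "sequence_alignment_aa": "",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, "sequence_id": f"contig{i:03d}", **row}
        if rec["v_call"] == "" and "v_call" not in row:
            rec["v_call"] = f"{rec['locus']}V1*01"
        if rec["j_call"] == "":
            rec["j_call"] = f"{rec['locus']}J1*01"
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11, n_cells=400, n_samples=2)


@pytest.fixture(scope="session")
def sim_repertoire(sim_config):
    return simulate_repertoire(sim_config)


@pytest.fixture(scope="session")
def sim_jhits(sim_config, sim_repertoire):
    contigs, cell_meta, _ = sim_repertoire
    return simulate_jhits(sim_config, contigs, cell_meta)
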