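import numpy as np
import pytest

import selscape as ss


@pytest.fixture(scope="session")
def uniform_spectrum():
    return ss.ContextSpectrum.uniform()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def toy_maf(tmp_path):
    """Three-row MAF: one missense, one silent, one intronic row."""
    lines = [
        "Tumor_Sample_Barcode\tHugo_Symbol\tTranscript_ID\t"
        "Variant_Classification\tCDS_position\tReference_Allele\tTumor_Seq_Allele2",
        "S1\tGENE1\tT1\tMissense_Mutation\t4\tA\tG",
        "S2\tGENE1\tT1\tSilent\t6\tG\tA",
        "S3\tGENE1\tT1\tIntron\t\tC\tT",
    ]
    path = tmp_path / "toy.maf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_sim():
    """Small mixed cohort shared across tests (drivers + neutral genes)."""
    groups = [
        ss.SimulationConfig(
            n_genes=5, n_codons=300, eta=0.03, m0=0.1, m1=8.0, gene_prefix="DRV"
        ),
        ss.SimulationConfig(
            n_genes=20, n_codons=300, eta=0.0, m0=0.1, m1=0.0, gene_prefix="NEU"
        ),
    ]
    return ss.simulate_groups(groups, seed=77)
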