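import numpy as np
import pytest

from smashnipt import simkit


@pytest.fixture(scope="session")
def toy_config():
    """A small 24-chromosome toy genome (~0.6 Mb) for fast unit tests."""
    return simkit.SimulationConfig(
        seed=101,
        chrom_lengths=simkit.default_chrom_lengths(2e-4),
        n_cfdna_fragments=100_000,
        n_snps=60,
        seq_error_rate=0.0,
    )


@pytest.fixture(scope="session")
def toy_reference(toy_config):
    return simkit.make_reference(toy_config)


@pytest.fixture(scope="session")
def sim_bundle(toy_config, toy_reference, tmp_path_factory):
    """A simulated error-free library shared across tests: fragments,
    size-selected pieces, chimeric molecules with truth, and a truth SAM."""
    rng = np.random.default_rng(toy_config.seed)
    frags = simkit.simulate_cfdna(toy_reference, toy_config, rng=rng)
    pieces = simkit.fragmentase_and_select(frags, toy_config, rng=rng)
    molecules, truth = simkit.ligate_chimeras(pieces, toy_config, rng=rng)
    sam_path = tmp_path_factory.mktemp("sim") / "truth.sam"
    simkit.emit_truth_sam(molecules, toy_reference, toy_config, sam_path, rng=rng)
    return {"fragments": frags, "pieces": pieces, "molecules": molecules,
            "truth": truth, "sam": sam_path}


def revcomp_str(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
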