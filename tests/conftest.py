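import pytest

from xlsurf import msio
from xlsurf.grouping import build_spectral_groups
from xlsurf.simulate import SimulationConfig, simulate_dataset


def load_pipeline_inputs(paths, linker):
    """Read a simulated fixture set back through the production readers."""
    spectra = msio.read_mzml(paths["mzml"])
    known = linker.known_mods()
    ms2_hits = msio.read_pepxml(paths["pepxml_ms2"], known)
    ms3_hits = msio.read_pepxml(paths["pepxml_ms3"], known)
    sequences = msio.read_fasta(paths["fasta"])
    msio.locate_peptides(ms2_hits, sequences)
    msio.locate_peptides(ms3_hits, sequences)
    return spectra, ms2_hits, ms3_hits


def groups_from_files(paths, linker):
    return build_spectral_groups(*load_pipeline_inputs(paths, linker))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A mixed fixture set: 5 interlinks, 3 monolinks, 3 singles, 2+2 rest."""
    config = SimulationConfig(
        seed=7, n_interlinks=5, n_monolinks=3, n_singles=3,
        n_incomplete=2, n_unknown=2,
    )
    outdir = tmp_path_factory.mktemp("sim_small")
    paths, truth = simulate_dataset(config, outdir)
    return config, paths, truth
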