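import numpy as np
import pytest

from psmfeat.library import Fragment, PredictedEntry
from psmfeat.peptides import ModifiedPeptide, fragment_mz
from psmfeat.simulate import SimSpec, simulate
from psmfeat.spectra import ExperimentalSpectrum


def entry_for(sequence, charge=2, mods=(), rt=50.0, im=None, intensities=None):
    """Build a PredictedEntry with exact theoretical fragment m/z values."""
    pep = ModifiedPeptide(sequence, tuple(mods), charge)
    n = len(sequence)
    frags = []
    k = 0
    for ion in ("b", "y"):
        for pos in range(1, n):
            inten = intensities[k] if intensities is not None else 1.0 / (k + 1)
            frags.append(Fragment(fragment_mz(pep, ion, pos, 1), inten, ion, pos, 1))
            k += 1
    return PredictedEntry(pep, frags, rt, im)


def spectrum_from_entry(entry, scan_nr=1, rt=10.0, im=None, charge=None):
    mz = entry.mz_array()
    return ExperimentalSpectrum(scan_nr, mz, entry.intensity_array(), rt, im, charge)


@pytest.fixture
def toy_entry():
    return entry_for("PEPTIDEK", charge=2, rt=42.0, im=0.9)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A small end-to-end fixture set shared across integration tests."""
    out = tmp_path_factory.mktemp("sim")
    spec = SimSpec(n_peptides=120, n_scans=200, seed=7)
    paths = simulate(spec, out)
    return spec, paths
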