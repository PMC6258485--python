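import numpy as np
import pytest

from crispra_screen import annotation_tss as ann
from crispra_screen import guide_design as gd
from crispra_screen import screen_simulator as sim


@pytest.fixture(scope="session")
def reference():
    """Synthetic 8-gene reference with planted guides (one duplicate pair)."""
    return sim.make_synthetic_reference(sim.ReferenceConfig(n_genes=8, seed=11))


@pytest.fixture(scope="session")
def designed(reference):
    """Windows, TSS positions and the default-quota designed library."""
    genes = sorted(reference.truth)
    sels = ann.select_tss(genes, reference.cage_peaks)
    windows = [ann.extract_promoter_window(s, reference.genome) for s in sels]
    tss_positions = {s.tss_id: s.tss_position for s in sels}
    lib = gd.design_library(
        windows, tss_positions, declared_families=reference.family_groups
    )
    return windows, tss_positions, lib


@pytest.fixture(scope="session")
def desk_screen():
    """One desk-profile simulated screen with its truth manifest."""
    cfg = sim.default_paper_config(seed=5)
    lib = sim.make_library_for_simulation(cfg)
    return lib, cfg, sim.simulate_screen(lib, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
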