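import numpy as np
import pytest

import glycolac as gl

#: structure and motif strings as printed for the seal milk glycome
#: (novo-LNP-I, 6S-2'-FL, proximal/distal sialyl-H, LacdiNAc, ...)
SEAL_STRUCTURE_STRINGS = [
    "Galβ1-4Glc",
    "Galβ1-4GlcNAc",
    "Galβ1-3GlcNAc",
    "Galβ1-4GlcNAc6S",
    "Galα1-3Gal",
    "Neu5Acα2-3Gal",
    "GalNAcβ1-4GlcNAc",
    "Fucα1-2Galβ1-4GlcNAc",
    "Fucα1-2Gal6Sβ1-4Glc",
    "Fucα1-2(Neu5Acα2-6)Galβ1-4GlcNAc",
    "Fucα1-2Galβ1-4(Neu5Acα2-6)GlcNAc",
    "Galβ1-4GlcNAcβ1-6(Galβ1-3)Galβ1-4Glc",
]


@pytest.fixture(scope="session")
def library():
    return gl.builtin_library()


@pytest.fixture(scope="session")
def low_noise_cohort():
    """Cohort with the study design (5 individuals × 4 timepoints) and
    low individual/sampling noise, so planted structure is recoverable."""
    design = gl.CohortDesign(individual_sigma=0.05, dirichlet_concentration=1000, seed=11)
    return gl.simulate_cohort(design)


@pytest.fixture(scope="session")
def default_cohort():
    return gl.simulate_cohort(gl.CohortDesign(seed=11))


def random_structures(seed, n=30, **kw):
    params = dict(p_extend=0.6, p_branch=0.3, max_size=10, seed=seed)
    params.update(kw)
    return gl.simulate_structures(n, gl.GrammarParams(**params))
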