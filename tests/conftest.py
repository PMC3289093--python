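import numpy as np
import pytest

from curdseq import synthetic


@pytest.fixture(scope="session")
def transcripts():
    """A small fixed transcript population (20 genes, 400-1200 bp)."""
    return synthetic.generate_transcriptome(
        n_genes=20, len_min=400, len_max=1200, gc=0.45, seed=11
    )


@pytest.fixture(scope="session")
def contaminants():
    return synthetic.generate_contaminants(
        n_rrna=2, n_vector=1, n_bacterial=2, length=1500, seed=12
    )


@pytest.fixture(scope="session")
def clean_libraries(transcripts):
    """Error-free, contaminant-free libraries: reads must match origins exactly."""
    design = synthetic.DEDesign(
        fraction_up=0.1, fraction_down=0.1, fold_values=(5.0,), depth=2000
    )
    lib1, lib2, truth = synthetic.simulate_libraries(
        transcripts, design, error_rate=0.0, rrna_fraction=0.0,
        adaptor_rate=0.0, seed=13,
    )
    return lib1, lib2, truth


@pytest.fixture(scope="session")
def contaminated_libraries(transcripts, contaminants):
    """Error-free libraries with 10% rRNA contamination for screening tests."""
    design = synthetic.DEDesign(
        fraction_up=0.0, fraction_down=0.0, fold_values=(3.0,), depth=2500
    )
    lib1, lib2, truth = synthetic.simulate_libraries(
        transcripts, design, error_rate=0.0, rrna_fraction=0.1,
        contaminants=contaminants, adaptor_rate=0.0, seed=14,
    )
    return lib1, lib2, truth
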