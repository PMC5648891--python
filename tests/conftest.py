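import pytest
from hypothesis import settings

settings.register_profile("default-derandomized", derandomize=True, deadline=None)
settings.load_profile("default-derandomized")

from digicount import (
    BarcodeDesign,
    ReadObservation,
    SimulationConfig,
    TemplateReference,
    default_panel_references,
)


@pytest.fixture(scope="session")
def toy_design():
    """4-base all-random barcode followed by a 2-base target."""
    return BarcodeDesign(
        name="toy",
        barcode_length=4,
        random_positions=(1, 2, 3, 4),
        fixed_positions=(),
        target_region=(5, 6),
        length_window=(6, None),
    )


@pytest.fixture(scope="session")
def toy_refs(toy_design):
    return [
        TemplateReference("T1", "AC", toy_design),
        TemplateReference("T2", "GT", toy_design),
    ]


@pytest.fixture
def make_obs(toy_design):
    """Factory for pre-filtered observations with explicit barcodes."""
    counter = {"n": 0}

    def build(barcode, index="A", templates=("T1",), design=toy_design):
        counter["n"] += 1
        return ReadObservation(
            read_id=f"r{counter['n']}",
            sample_index=index,
            sequence=barcode + "AC",
            design=design,
            barcode=barcode,
            templates=tuple(templates),
        )

    return build


def single_template_config(template_id="ST1", copies=500, **overrides) -> SimulationConfig:
    """Simulation config restricted to one panel template at a chosen copy number."""
    refs = [
        TemplateReference(r.template_id, r.target_sequence, r.design, copies)
        for r in default_panel_references()
        if r.template_id == template_id
    ]
    overrides.setdefault("min_reads", 1)
    return SimulationConfig(references=refs, **overrides)


@pytest.fixture(scope="session")
def clean_small_sim():
    """Zero-error simulation of 300 ST1 molecules per index (ground truth known)."""
    from digicount import simulate

    config = single_template_config(
        copies=300,
        seed=11,
        substitution_rate=0.0,
        insertion_rate=0.0,
        deletion_rate=0.0,
        n_rate=0.0,
        index_swap_rate=0.0,
    )
    reads, truth = simulate(config)
    return config, reads, truth
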