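import numpy as np
import pytest

import m7gkit as m


@pytest.fixture(scope="session")
def default_cfg() -> m.SimulationConfig:
    return m.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def reference_truth(default_cfg):
    return m.simulate_trna_reference(default_cfg)


@pytest.fixture(scope="session")
def decoding(reference_truth):
    species, truth = reference_truth
    table = m.build_decoding_table(species)
    class_map = m.classify_codons(table, truth.m7g_ids)
    return table, class_map


@pytest.fixture(scope="session")
def small_cfg() -> m.SimulationConfig:
    """Down-scaled study for unit tests that only need structure, not power."""
    return m.SimulationConfig(
        seed=5,
        n_trna_species=12,
        n_m7g=5,
        tracseq_depth=8_000,
        n_genes=30,
        cds_length_range=(60, 120),
        ribo_depth=40_000,
        rna_depth=100_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    species, truth = m.simulate_trna_reference(small_cfg)
    table = m.build_decoding_table(species)
    class_map = m.classify_codons(table, truth.m7g_ids)
    transcripts, annotation = m.simulate_transcriptome(small_cfg, class_map)
    return {
        "cfg": small_cfg,
        "species": species,
        "truth": truth,
        "table": table,
        "class_map": class_map,
        "transcripts": transcripts,
        "annotation": annotation,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def recodable_class_map() -> m.CodonClassMap:
    """Class map with one m7G codon in each of 15 multi-codon families.

    Every M7G_DECODED codon then has a NON_M7G synonym, so recoding with
    target ALL_M7G is satisfiable for any CDS (single-codon Met/Trp stay
    NON_M7G and are exercised separately as the unsatisfiable case).
    """
    from m7gkit.trna import AA_TO_CODONS, CodonClass, CodonClassMap, SENSE_CODONS

    families = [cods for aa, cods in sorted(AA_TO_CODONS.items()) if len(cods) >= 2]
    m7g = {cods[0] for cods in families[:15]}
    return CodonClassMap(
        class_of={
            c: CodonClass.M7G_DECODED if c in m7g else CodonClass.NON_M7G
            for c in SENSE_CODONS
        }
    )
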