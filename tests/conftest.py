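import numpy as np
import pandas as pd
import pytest

from msci_kit import POPULATIONS, SimConfig, population_profiles, simulate_dataset


def make_profiles(rows: dict[str, tuple]) -> pd.DataFrame:
    """Profiles DataFrame from {gene_id: (I, II, III, IV)}."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(POPULATIONS))
    frame.index.name = "gene_id"
    return frame.astype(float)


def make_annotation(chromosomes: dict[str, str], starts: dict[str, int] | None = None) -> pd.DataFrame:
    """Minimal annotation from {gene_id: chromosome}."""
    gene_ids = list(chromosomes)
    start = [starts.get(g, 1 + 1000 * i) if starts else 1 + 1000 * i for i, g in enumerate(gene_ids)]
    return pd.DataFrame(
        {
            "chromosome": [chromosomes[g] for g in gene_ids],
            "start": start,
            "end": [s + 999 for s in start],
            "length": 1000,
            "strand": "+",
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Hemizygous-X dataset with no compensation, silencing or stage structure."""
    cfg = SimConfig.null_dosage(seed=101)
    annotation, counts, fpkm, truth = simulate_dataset(cfg)
    return {
        "config": cfg,
        "annotation": annotation,
        "counts": counts,
        "fpkm": fpkm,
        "truth": truth,
        "profiles": population_profiles(fpkm),
    }


@pytest.fixture(scope="session")
def msci_dataset():
    """Hemizygous-X dataset with silencing factor 0.1 from stage II onward."""
    cfg = SimConfig.msci(seed=101, silencing_factor=0.1)
    annotation, counts, fpkm, truth = simulate_dataset(cfg)
    return {
        "config": cfg,
        "annotation": annotation,
        "fpkm": fpkm,
        "truth": truth,
        "profiles": population_profiles(fpkm),
    }


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-like scenario: silencing schedule, escapees, archetypes."""
    cfg = SimConfig(seed=202, escapee_fraction=0.03)
    annotation, counts, fpkm, truth = simulate_dataset(cfg)
    return {
        "config": cfg,
        "annotation": annotation,
        "fpkm": fpkm,
        "truth": truth,
        "profiles": population_profiles(fpkm),
    }
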