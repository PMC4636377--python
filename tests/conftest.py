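import numpy as np
import pandas as pd
import pytest

from evotrace.genome import GenomeAnnotation, synthetic_genome


@pytest.fixture(scope="session")
def small_genome() -> GenomeAnnotation:
    """A 4-chromosome, 100-kb-per-chromosome genome for fast tests."""
    return synthetic_genome(n_chromosomes=4, chrom_length=100_000,
                            gene_length=1_000, gene_spacing=1_500)


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Hand-sized annotation: 2 chromosomes, 3 genes of known lengths."""
    genes = pd.DataFrame({
        "gene": ["YFG1", "YFG2", "YFG3"],
        "chromosome": ["chrA", "chrA", "chrB"],
        "start": [20_001, 40_001, 30_001],
        "end": [21_500, 43_000, 30_900],
    })
    return GenomeAnnotation(chrom_lengths={"chrA": 100_000, "chrB": 100_000},
                            genes=genes)


def make_trajectory_table(freqs: dict[str, list[float]],
                          generations: list[int],
                          chromosome: str = "chrA",
                          positions: dict[str, int] | None = None,
                          genes: dict[str, str] | None = None,
                          klass: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for i, (mid, f) in enumerate(freqs.items()):
        row = {"mutation_id": mid, "chromosome": chromosome,
               "position": (positions or {}).get(mid, 20_000 + 10 * i),
               "ref": "A", "alt": "T",
               "class": (klass or {}).get(mid, "SNP"),
               "gene": (genes or {}).get(mid, "")}
        for g, v in zip(generations, f):
            row[f"g{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
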