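import numpy as np
import pytest

from resynth import GenotypeMatrix, MarkerMap, builtin_score_table
from resynth.simulate import default_config, simulate_f2


def make_matrix(rows: dict[str, str], markers=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {individual: 'AHB-...'} strings."""
    ids = list(rows)
    calls = [list(v) for v in rows.values()]
    m = len(calls[0])
    markers = markers or [f"m{i + 1}" for i in range(m)]
    from resynth.scoring import CALL_TO_CODE
    codes = np.array([[CALL_TO_CODE[c] for c in row] for row in calls],
                     dtype=np.uint8)
    return GenotypeMatrix(ids, markers, codes)


def single_chrom_map(n_markers: int, chrom="chr1") -> MarkerMap:
    return MarkerMap([(chrom, f"m{i + 1}") for i in range(n_markers)])


@pytest.fixture(scope="session")
def set1():
    return builtin_score_table("SET1")


@pytest.fixture(scope="session")
def set2():
    return builtin_score_table("SET2")


@pytest.fixture(scope="session")
def set3():
    return builtin_score_table("SET3")


@pytest.fixture(scope="session")
def small_f2():
    """200 individuals x 100 markers (5 chromosomes), phased, seeded."""
    cfg = default_config(n_individuals=200, n_chromosomes=5,
                         markers_per_chromosome=20, seed=42)
    gm, mm, haps = simulate_f2(cfg)
    return gm, mm, haps


@pytest.fixture()
def genotype_file(tmp_path):
    """A valid 3x2 genotype TSV on disk."""
    p = tmp_path / "geno.tsv"
    p.write_text("id\tm1\tm2\nind1\tA\tH\nind2\tB\t-\nind3\tH\tH\n")
    return p


@pytest.fixture()
def marker_file(tmp_path):
    p = tmp_path / "markers.tsv"
    p.write_text("chr1\tm1\nchr1\tm2\n")
    return p
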