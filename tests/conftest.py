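import numpy as np
import pytest

from csslkit.formats_io import HET, HOM_ALT, HOM_REF, MISSING, VariantTable
from csslkit.allele_model import AlleleClass, AlleleClassTrack
from csslkit.simulate import SimConfig, simulate_population


def make_variant_table(pos, gts, samples, chrom="chr1", ref=None, alt=None):
    """Build a VariantTable from 1-based positions and a genotype matrix."""
    pos = np.asarray(pos, dtype=np.int64)
    gts = np.asarray(gts, dtype=np.int8)
    n = len(pos)
    chroms = np.array([chrom] * n, dtype=object) if isinstance(chrom, str) else np.asarray(chrom, dtype=object)
    ref = np.array(ref if ref else ["A"] * n, dtype=object)
    alt = np.array(alt if alt else ["T"] * n, dtype=object)
    return VariantTable(chroms, pos, ref, alt, gts, list(samples))


def make_track(pos, classes, line_id="L1", chrom="chr1"):
    n = len(pos)
    chroms = np.array([chrom] * n, dtype=object) if isinstance(chrom, str) else np.asarray(chrom, dtype=object)
    return AlleleClassTrack(
        line_id, chroms, np.asarray(pos, dtype=np.int64),
        np.asarray(classes, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small clean population shared across tests (two 10-Mb chromosomes)."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        n_lines=4,
        shared_tracts_per_chrom=0,
        mas_target_length_bp=3_000_000,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, SNP-only population for sequence-exact pseudo-genome tests."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 2_000_000},
        n_lines=2,
        marker_density=100 / 1_000_000,
        genotype_error=0.0,
        missing_rate=0.0,
        indel_fraction=0.0,
        shared_tracts_per_chrom=0,
        mas_target_length_bp=500_000,
        seed=5,
    )
    return simulate_population(cfg)
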