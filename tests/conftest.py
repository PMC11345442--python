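import numpy as np
import pandas as pd
import pytest

from eccdna_charter import synthetic_data as sd
from eccdna_charter.formats import AnnotationTrack, EccDNACatalog, GenomeModel


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    return sd.SimConfig(seed=7, n_chrom=2, chrom_length=200_000)


@pytest.fixture(scope="session")
def small_genome(small_config) -> GenomeModel:
    return sd.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_genome, small_config) -> AnnotationTrack:
    return sd.generate_annotation(small_genome, small_config)


@pytest.fixture(scope="session")
def small_catalogs(small_genome, small_annotation, small_config):
    cfg = sd.SimConfig(
        seed=7, n_chrom=2, chrom_length=200_000,
        n_samples=4, n_high=2, abundance_split=(800.0, 100.0),
    )
    return sd.generate_eccdna_catalogs(small_genome, small_annotation, cfg)


def make_catalog(rows, sample_id="S", mapped=10_000_000) -> EccDNACatalog:
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "split_reads", "discordant_reads", "score"]
    )
    return EccDNACatalog(sample_id, df, mapped_read_total=mapped)


def uniform_catalog(genome: GenomeModel, n: int, seed: int, length_sampler=None,
                    sample_id="U", mapped=10_000_000) -> EccDNACatalog:
    """Records with uniform midpoints: the null for placement statistics."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.lengths)
    lens = np.array([genome.lengths[c] for c in chroms])
    probs = lens / lens.sum()
    ci = rng.choice(len(chroms), size=n, p=probs)
    mid = (rng.random(n) * lens[ci]).astype(np.int64)
    if length_sampler is None:
        rec_len = rng.integers(50, 300, size=n)
    else:
        rec_len = length_sampler(rng, n)
    rec_len = np.minimum(rec_len, lens[ci])
    start = np.clip(mid - rec_len // 2, 0, lens[ci] - rec_len)
    df = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": start,
            "end": start + rec_len,
            "split_reads": 1,
            "discordant_reads": 0,
            "score": 10.0,
        }
    )
    return EccDNACatalog(sample_id, df, mapped_read_total=mapped)
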