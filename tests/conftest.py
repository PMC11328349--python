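import numpy as np
import pytest

from edittrace.edit_calling import LocusAssay


def random_genome(seed: int, length: int, n_contigs: int = 1) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {
        f"ctg{i}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_contigs)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240816)


@pytest.fixture
def toy_assay():
    """One 106-nt amplicon with the 23-nt window in the middle."""
    rng = np.random.default_rng(11)
    left = "".join(rng.choice(list("ACGT"), size=40))
    window = "".join(rng.choice(list("ACGT"), size=23))
    right = "".join(rng.choice(list("ACGT"), size=43))
    amp = left + window + right
    return LocusAssay(
        locus_id="chr1_100",
        reference_amplicon=amp,
        window_start=40,
        left_kmer=amp[:12],
        right_kmer=amp[-12:],
    )
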