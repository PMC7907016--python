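import numpy as np
import pytest

from mrkit.core_io import HarmonizedInstrument, load_paper_fixture


@pytest.fixture(scope="session")
def fixture9():
    """The bundled nine-SNP homocysteine -> CAD instrument set."""
    return load_paper_fixture()


def make_instruments(bx, sx, by, sy):
    """Build harmonized instruments from parallel arrays."""
    return [
        HarmonizedInstrument(
            snp_id=f"snp{j}",
            effect_allele="A",
            other_allele="G",
            beta_exp=float(bx[j]),
            se_exp=float(sx[j]),
            beta_out=float(by[j]),
            se_out=float(sy[j]),
        )
        for j in range(len(bx))
    ]


def random_instruments(rng, n, weak=False):
    """Random instrument sets for property tests."""
    bx = rng.normal(0.1 if not weak else 0.02, 0.05, n)
    bx[bx == 0] = 0.01
    sx = rng.uniform(0.005, 0.02, n)
    by = rng.normal(0.0, 0.05, n)
    sy = rng.uniform(0.01, 0.06, n)
    return make_instruments(bx, sx, by, sy)
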