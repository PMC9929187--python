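import numpy as np
import pytest

from mrsumstats import GwasRecord, HarmonizedInstrument
from mrsumstats.synthetic import make_paperlike_fixture


def make_instrument(snp_id="rs1", bx=0.1, sx=0.01, by=0.02, sy=0.01,
                    **kwargs) -> HarmonizedInstrument:
    defaults = dict(effect_allele="A", other_allele="G",
                    eaf_exp=0.3, eaf_out=0.3, n_exp=10000.0, n_out=10000.0)
    defaults.update(kwargs)
    return HarmonizedInstrument(
        snp_id=snp_id, beta_exp=bx, se_exp=sx, pval_exp=1e-10,
        beta_out=by, se_out=sy, pval_out=0.5, **defaults)


def instrument_panel(bx, by, sy, sx=None, **kwargs):
    """Build a list of instruments from parallel effect arrays."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx)
    return [make_instrument(f"rs{i+1}", float(bx[i]), float(sx[i]),
                            float(by[i]), float(sy[i]), **kwargs)
            for i in range(len(bx))]


def make_record(snp_id="rs1", **kwargs) -> GwasRecord:
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.01, pval=1e-10, n=10000.0)
    defaults.update(kwargs)
    return GwasRecord(snp_id=snp_id, **defaults)


@pytest.fixture(scope="session")
def paperlike(tmp_path_factory):
    """The paper-scale synthetic fixture bundle (written once per session)."""
    out = tmp_path_factory.mktemp("paperlike")
    return make_paperlike_fixture(out, seed=7)
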