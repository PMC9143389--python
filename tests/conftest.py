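import numpy as np
import pytest

from twoqsar import DescriptorTable


@pytest.fixture
def small_csv(tmp_path):
    """3 compounds x 2 descriptors, one missing cell, pKa columns."""
    path = tmp_path / "small.csv"
    path.write_text(
        "id,name,log_kp,pka_acid,pka_base,log_P,V_m\n"
        "c1,water,-3.30,,,-1.38,0.32\n"
        "c2,phenol,-2.09,9.99,,1.46,0.87\n"
        "c3,lidocaine,-1.70,,7.9,NA,2.34\n"
    )
    return path


@pytest.fixture
def table_factory():
    def make(values, names=None, ids=None, **kw):
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        names = names or [f"d{j}" for j in range(p)]
        ids = ids or [f"c{i}" for i in range(n)]
        return DescriptorTable(ids, names, values, **kw)
    return make
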