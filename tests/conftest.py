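import numpy as np
import pytest

from margmeta import BivariateDataset, StudyRecord


def make_complete(y1, s1, y2, s2, rho_w=None):
    """Complete bivariate dataset from parallel lists."""
    rho = [rho_w] * len(y1) if rho_w is None or np.isscalar(rho_w) else rho_w
    return BivariateDataset(tuple(
        StudyRecord(str(i + 1), float(a), float(b), float(c), float(d),
                    None if rho[i] is None else float(rho[i]))
        for i, (a, b, c, d) in enumerate(zip(y1, s1, y2, s2))
    ))


@pytest.fixture
def small_complete_ds():
    """Five complete studies with known within-study correlations."""
    return make_complete(
        y1=[0.2, -0.1, 0.4, 0.0, 0.3],
        s1=[0.3, 0.5, 0.4, 0.6, 0.35],
        y2=[1.8, 2.2, 2.1, 1.9, 2.4],
        s2=[0.4, 0.45, 0.3, 0.5, 0.38],
        rho_w=[0.5, 0.3, 0.6, 0.4, 0.5],
    )


@pytest.fixture
def disjoint_ds():
    """Outcome 1 and outcome 2 reported by disjoint sets of studies."""
    recs = [
        StudyRecord("a", y1=0.1, s1=0.3),
        StudyRecord("b", y1=0.4, s1=0.5),
        StudyRecord("c", y2=2.2, s2=0.4),
        StudyRecord("d", y2=1.9, s2=0.6),
    ]
    return BivariateDataset(tuple(recs))
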