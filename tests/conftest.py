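import numpy as np
import pytest

from scmethrna.io_formats import GenomicRegion
from scmethrna.methylome_regions import RegionMethylationMatrix


def make_region_matrix(frac, ncpg=None, reads=None, cell_ids=None, feature_class="window1kb"):
    """Build a RegionMethylationMatrix from a fraction array (NaN = missing).

    Coverage metadata defaults to 1 CpG / 20 reads wherever a fraction is
    present.
    """
    frac = np.asarray(frac, dtype=float)
    n_r, n_c = frac.shape
    present = ~np.isnan(frac)
    if ncpg is None:
        ncpg = present.astype(np.int64)
    else:
        ncpg = np.asarray(ncpg, dtype=np.int64)
    if reads is None:
        reads = present.astype(np.int64) * 20
    else:
        reads = np.asarray(reads, dtype=np.int64)
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n_c)]
    regions = [
        GenomicRegion("chr1", i * 1000, (i + 1) * 1000, feature_class,
                      f"{feature_class}:chr1:{i * 1000}-{(i + 1) * 1000}")
        for i in range(n_r)
    ]
    return RegionMethylationMatrix(regions, list(cell_ids), frac, ncpg, reads)


@pytest.fixture
def two_group_labels():
    def _labels(n_per_group, g1="IVM", g2="invivo"):
        ids = [f"cell_{i}" for i in range(2 * n_per_group)]
        return {c: (g1 if i < n_per_group else g2) for i, c in enumerate(ids)}

    return _labels
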