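import numpy as np
import pandas as pd
import pytest

from snptitrate.caller import CallSet


def build_callset(
    gt,
    quals=None,
    alleles=None,
    chrom="chr1",
    start_pos=100,
    filters=None,
    samples=None,
    info=None,
):
    """Construct a small CallSet by hand for metric and filter tests.

    ``gt`` is (n_individuals, n_sites) with the package genotype codes;
    ``alleles`` a list of (ref, alt) pairs; ``info`` optional extra site
    columns (e.g. hard-filter annotations).
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_ind, n_sites = gt.shape
    if alleles is None:
        alleles = [("A", "G")] * n_sites
    if quals is None:
        quals = [100.0] * n_sites
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(start_pos, start_pos + n_sites, dtype=np.int64),
            "ref": [a[0] for a in alleles],
            "alt": [a[1] for a in alleles],
            "qual": np.asarray(quals, dtype=float),
            "af": 0.1,
            "filter": filters if filters is not None else ["."] * n_sites,
        }
    )
    if info:
        for k, v in info.items():
            sites[k] = v
    if samples is None:
        samples = [f"ind{i + 1}" for i in range(n_ind)]
    return CallSet(sites=sites, gt=gt, gq=np.full(gt.shape, 50.0), samples=list(samples))


@pytest.fixture
def toy_callset():
    # 3 individuals x 4 sites with one het, one hom_alt, one missing entry
    return build_callset(
        [
            [0, 1, 2, -1],
            [0, 1, 0, 0],
            [0, 0, 2, 1],
        ]
    )
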