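import numpy as np
import pandas as pd
import pytest

from aidmeth.io import BetaMatrix, Manifest, PairedDesign, ProbeAnnotation


def make_manifest(positions, design_types=None, genes=None, features=None,
                  pseudo=None, chrom="chr1"):
    """Small hand-built manifest; positions may be a list or dict chrom->list."""
    if isinstance(positions, dict):
        items = [(c, p) for c, ps in positions.items() for p in ps]
    else:
        items = [(chrom, p) for p in positions]
    n = len(items)
    design_types = design_types or ["II"] * n
    genes = genes or [frozenset()] * n
    features = features or ["IGR"] * n
    pseudo = pseudo or [False] * n
    return Manifest(
        ProbeAnnotation(
            probe_id=f"cg{i:06d}", chromosome=c, position=p,
            design_type=design_types[i],
            genes=genes[i] if isinstance(genes[i], frozenset) else frozenset(genes[i]),
            feature=features[i], is_pseudogene=pseudo[i],
        )
        for i, (c, p) in enumerate(items)
    )


@pytest.fixture
def four_pair_design():
    return PairedDesign(tuple(
        (f"P{i}", f"P{i}_ctrl", f"P{i}_aid") for i in range(1, 5)
    ))


@pytest.fixture
def small_betas(four_pair_design):
    rng = np.random.default_rng(0)
    probes = [f"cg{i:06d}" for i in range(20)]
    cols = [s for pair in four_pair_design.pairs for s in pair[1:]]
    vals = rng.uniform(0.05, 0.95, size=(20, 8))
    return BetaMatrix(pd.DataFrame(vals, index=pd.Index(probes, name="probe_id"),
                                   columns=cols))
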