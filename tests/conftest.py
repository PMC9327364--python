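import pandas as pd
import pytest

from lncloc.expression import SampleDesign, compute_rpkm, expression_filter
from lncloc.simulate import SyntheticConfig, simulate_counts


@pytest.fixture(scope="session")
def planted_run():
    """Default-condition synthetic run: 2000 transcripts, 4-fold planted
    asymmetry, 5 replicates per fraction."""
    cfg = SyntheticConfig(n_transcripts=2000, seed=7)
    counts, design, truth = simulate_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def planted_expression(planted_run):
    cfg, counts, design, truth = planted_run
    rpkm = compute_rpkm(counts, truth.lengths)
    return expression_filter(rpkm, design, truth.lengths)


@pytest.fixture()
def toy_design():
    rows = []
    for cond in ("control",):
        for frac in ("nuclear", "cytoplasmic"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{cond}_{frac}_rep{rep}",
                        "condition": cond,
                        "fraction": frac,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))
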