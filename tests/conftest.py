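import pytest

from dualguide.design import GuideRecord
from dualguide.simulate import SimConfig, simulate_counts, simulate_library


def make_guides(gene: str, n: int, spacer_len: int = 20, **kw) -> list[GuideRecord]:
    """n deterministic distinct guides for one gene."""
    bases = "ACGT"
    out = []
    for i in range(n):
        spacer = (bases[i % 4] * 4 + bases[(i // 4) % 4] * 4 + "ACGT" * 5)[:spacer_len]
        spacer = spacer[:-2] + bases[i % 4] + bases[(i * 7) % 4]  # keep distinct
        out.append(GuideRecord(guide_id=f"{gene}_g{i + 1}", gene=gene, spacer=spacer,
                               gpp_pick_order=i + 1, **kw))
    return out


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen shared by read-through tests."""
    cfg = SimConfig(n_essential_genes=4, n_nonessential_genes=4, n_sl_pairs=2,
                    n_null_pairs=6, sequencing_depth=500, seed=11)
    library, truth = simulate_library(cfg)
    counts = simulate_counts(library, truth, cfg)
    return cfg, library, truth, counts
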