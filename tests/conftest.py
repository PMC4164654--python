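import numpy as np
import pytest

import sumoacet as sa


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic dataset shared by cheap encoder/pipeline tests."""
    cfg = sa.GeneratorConfig(n_pos=20, n_neg=30, seed=3)
    records, sites, providers = sa.generate_dataset(cfg)
    windows = sa.extract_all_windows(records)
    X, y = sa.encode_windows(windows, providers)
    return {"config": cfg, "records": records, "sites": sites,
            "providers": providers, "windows": windows, "X": X, "y": y}


@pytest.fixture(scope="session")
def full_scale_windows():
    """Windows at the emulated study scale: 218 positive, 2780 negative."""
    cfg = sa.GeneratorConfig(seed=1)
    records, _, _ = sa.generate_dataset(cfg)
    return sa.extract_all_windows(records)


@pytest.fixture(scope="session")
def recovery_run():
    """The parameter-recovery experiment: balanced 150+150 windows with the
    default planted signal, ranked by mRMR and scanned by IFS (k = 1..101,
    step 5, jackknife random forests).  Session-scoped because the jackknife
    scan is the most expensive computation in the suite."""
    cfg = sa.GeneratorConfig(n_pos=150, n_neg=150, seed=7)
    records, _, providers = sa.generate_dataset(cfg)
    windows = sa.extract_all_windows(records)
    X, y = sa.encode_windows(windows, providers)
    table = sa.rank_features(X, y)
    result = sa.ifs_curve(table, X, y, k_min=1, k_max=101, k_step=5, seed=7)
    planted = {d.key for d in sa.planted_descriptors(cfg)}
    return {"config": cfg, "X": X, "y": y, "mrmr": table,
            "ifs": result, "planted": planted}
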