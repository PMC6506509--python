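import numpy as np
import pytest

from helpers import prep, recovery_dataset, recovery_pair


@pytest.fixture(scope="session")
def small_counts():
    """A tiny deterministic count matrix with two spike-ins."""
    from schet import CountMatrix, flag_spikeins

    rng = np.random.default_rng(42)
    counts = rng.poisson(5, size=(8, 6))
    cm = CountMatrix(
        counts=counts,
        gene_ids=[f"G{i}" for i in range(6)] + ["ERCC-0001", "ERCC-0002"],
        cell_ids=[f"C{j}" for j in range(6)],
        dataset_id="tiny",
    )
    return flag_spikeins(cm)


@pytest.fixture(scope="session")
def recovery_data():
    """One dataset at the standard recovery condition, preprocessed."""
    cm, truth = recovery_dataset(seed=11)
    sf, nm = prep(cm)
    return {"cm": cm, "truth": truth, "sf": sf, "nm": nm}


@pytest.fixture(scope="session")
def recovery_pair_data():
    """A shared-module dataset pair at the recovery condition, preprocessed."""
    pair = recovery_pair(seed=11)
    out = []
    for cm, truth in pair:
        sf, nm = prep(cm)
        out.append({"cm": cm, "truth": truth, "sf": sf, "nm": nm})
    return out
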