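"""Shared fixtures: small synthetic federations and derived plans.

Everything is generated programmatically and seeded; session scope keeps
the suite fast since the fixtures are read-only.
"""

import numpy as np
import pytest

import fedlesion as fl


def make_dataset(n_institutions=3, n_train=10, n_test=5, seed=1, offset_step=25.0,
                 **spec_kwargs):
    specs = {
        f"I{i + 1}": fl.VolumeSpec(manufacturer=f"vendor{chr(65 + i)}",
                                   manufacturer_offset=offset_step * i,
                                   seed=0, **spec_kwargs)
        for i in range(n_institutions)}
    return fl.generate_federated_dataset(specs, n_train=n_train, n_test=n_test,
                                         seed=seed)


@pytest.fixture(scope="session")
def dataset():
    """3 institutions x (10 train + 5 test), manufacturer-shifted."""
    return make_dataset()


@pytest.fixture(scope="session")
def global_fingerprint(dataset):
    locals_ = [fl.compute_local_fingerprint(i, dataset.train_volumes(i), "nosyn")
               for i in dataset.institution_ids()]
    return fl.build_global_fingerprint(locals_, "nosyn")


@pytest.fixture(scope="session")
def plan(global_fingerprint):
    return fl.derive_plan(global_fingerprint)


@pytest.fixture(scope="session")
def train_candidates(dataset, plan):
    """Pooled training candidates of institution I1 (positives and negatives)."""
    cands = [c for v in dataset.train_volumes("I1")
             for c in fl.propose_candidates(v, plan)]
    assert any(c.is_positive for c in cands) and any(not c.is_positive for c in cands)
    return cands


@pytest.fixture(scope="session")
def trained_state(train_candidates):
    state = fl.init_model(seed=0)
    new, _losses = fl.local_train(state, train_candidates,
                                  fl.TrainConfig(epochs=5), seed=0)
    return new


def brute_force_stats(samples):
    """Independent intensity-statistics oracle: sorted-order interpolation."""
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size

    def pct(q):
        # linear interpolation between order statistics
        pos = q / 100.0 * (n - 1)
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return s[lo] + frac * (s[hi] - s[lo])

    return {"mean": s.mean(), "std": s.std(), "min": s[0], "max": s[-1],
            "median": pct(50.0), "p0_5": pct(0.5), "p99_5": pct(99.5)}
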