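"""Shared fixtures: small synthetic datasets and one trained tiny model.

Generator parameters here use reduced frames (320 px) and lesion sizes so
individual tests stay fast; the full-frame conditions are exercised by the
acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

import rcmseg as r

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


SMALL = dict(image_height=320, image_width=320, lesion_axis_px=(30.0, 50.0),
             n_lesions_per_slice=(1, 3), fissure_width_px=4.0)


@pytest.fixture(scope="session")
def small_params():
    return r.GeneratorParams(**SMALL, seed=5)


@pytest.fixture(scope="session")
def small_slice(small_params):
    return r.generate_slice(small_params, r.slice_rng(small_params, 0, 0, 0))


@pytest.fixture(scope="session")
def full_slice():
    """One full-frame (1000 x 1000) slice at default conditions."""
    params = r.GeneratorParams(seed=3)
    return r.generate_slice(params, r.slice_rng(params, 0, 0, 0))


@pytest.fixture(scope="session")
def patch_dataset():
    """Labeled patches from a 4-case synthetic set, split by case."""
    params = r.GeneratorParams(n_cases=4, stacks_per_case=1, slices_per_stack=3,
                               seed=7)
    stacks = r.generate_dataset(params)
    rule = r.PatchRule(stride=106)
    by_case = {}
    for st in stacks:
        ps = [p for sl in st.slices for p in r.tile_slice(sl, rule)]
        by_case.setdefault(st.case_id, []).extend(ps)
    return by_case


@pytest.fixture(scope="session")
def trained_tiny(patch_dataset):
    """A tiny-width classifier trained on three cases, with its loss log
    and a held-out case for evaluation."""
    cases = sorted(patch_dataset)
    train_p = [p for c in cases[:3] for p in patch_dataset[c]]
    test_p = patch_dataset[cases[3]]
    model = r.build_model(r.BackboneSpec.tiny(), seed=1, dtype=np.float32)
    model, log = r.train(
        model, train_p,
        r.TrainConfig(learning_rate=2e-3, epochs=10, batch_size=16, seed=0),
        aug=None)
    return model, log, train_p, test_p
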