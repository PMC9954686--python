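import numpy as np
import pytest

from slicevit.cohort import CohortSpec, generate_cohort
from slicevit.decompose import DecomposeParams, build_manifest, decompose_cohort
from slicevit.models import canonical_config
from slicevit.splits import stratified_split


def tiny_ovitad_config(num_classes=3, **overrides):
    """Reduced-width 56-pixel configuration used for desk-scale training."""
    kw = dict(embed_dim=64, head_dim=8, depth=2, mlp_dim=128,
              dropout=0.0, emb_dropout=0.0)
    kw.update(overrides)
    return canonical_config("ovitad", num_classes=num_classes, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects/class structural cohort with strong class signal."""
    spec = CohortSpec(n_per_class={"AD": 6, "HC": 6, "MCI": 6}, modality="smri",
                      effect_size=2.5, noise_sd=0.03, seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_manifest(small_cohort, tmp_path_factory):
    """Decomposed slice manifest of the small cohort with an 80/10/10 split."""
    spec, volumes = small_cohort
    out = tmp_path_factory.mktemp("slices")
    records = decompose_cohort(volumes, DecomposeParams(), out)
    by_class = {}
    for v in volumes:
        by_class.setdefault(v.label, []).append(v.subject_id)
    split = stratified_split(by_class, seed=1)
    return build_manifest(records, split.assignment)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
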