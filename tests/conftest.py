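import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdzgram import labels, synth
from pdzgram.io import ClassRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def interaction_world():
    """Default synthetic screen: 85 domains x 181 peptides, 500 pairs, 5% noise."""
    cfg = synth.SynthConfig(seed=1)
    domains = synth.generate_domains(cfg)
    peptides = synth.generate_peptides(cfg)
    table = synth.generate_interactions(domains, peptides, cfg, n_pairs=500)
    instances = labels.build_interaction_dataset(
        domains.sequences + peptides.sequences, table.records, 3)
    return {"cfg": cfg, "domains": domains, "peptides": peptides,
            "table": table, "instances": instances}


@pytest.fixture(scope="session")
def class_world():
    """90 synthetic domains with default planted class tags."""
    cfg = synth.SynthConfig(seed=2, n_domains=90)
    domains = synth.generate_domains(cfg)
    records = [ClassRecord(i, c) for i, c in sorted(domains.classes.items())]
    instances = labels.build_class_dataset(domains.sequences, records, 3)
    return {"cfg": cfg, "domains": domains, "records": records, "instances": instances}


@pytest.fixture(scope="session")
def fivegram_world():
    """Class dataset with five informative trigrams spread over the classes."""
    planted = {"I": ("774", "744"), "II": ("775", "755"), "I-II": ("776",)}
    cfg = synth.SynthConfig(seed=4, n_domains=90, planted_grams=planted)
    domains = synth.generate_domains(cfg)
    records = [ClassRecord(i, c) for i, c in sorted(domains.classes.items())]
    instances = labels.build_class_dataset(domains.sequences, records, 3)
    grams = sorted({g for gs in planted.values() for g in gs})
    return {"cfg": cfg, "instances": instances, "planted_grams": grams}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
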