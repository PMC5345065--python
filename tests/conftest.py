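import numpy as np
import pandas as pd
import pytest

from letm.pedigree import RelatednessMatrix
from letm.synthetic import make_crossing_design, simulate_cohort


@pytest.fixture(scope="session")
def design_cohort():
    """One default 4-family, 2-environment synthetic cohort (640 males)."""
    return simulate_cohort(make_crossing_design(seed=42))


@pytest.fixture(scope="session")
def trio_records():
    return [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B")]


def random_pedigree_records(rng, n_founders=6, n_offspring=20):
    """Random valid pedigree: founders then offspring of earlier individuals."""
    records = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in records]
    dams, sires = ids[: n_founders // 2], ids[n_founders // 2 :]
    for k in range(n_offspring):
        dam = str(rng.choice(dams))
        sire = str(rng.choice(sires))
        oid = f"O{k}"
        records.append((oid, dam, sire))
        # offspring may become parents of later offspring (multi-generation)
        if rng.random() < 0.3:
            (dams if rng.random() < 0.5 else sires).append(oid)
    return records


def identity_relatedness(ids) -> RelatednessMatrix:
    return RelatednessMatrix(list(ids), np.eye(len(ids)))


def unrelated_cohort(rng, n, mu_theta=4.0, sigma_eta=1.0):
    """Cohort of unrelated individuals from the no-genetics (probit) limit."""
    X = np.exp(rng.normal(np.log(4.0), 0.3, n))
    eta = X + sigma_eta * rng.standard_normal(n)
    Y = (eta > mu_theta).astype(int)
    ids = [f"i{k}" for k in range(n)]
    frame = pd.DataFrame(
        {
            "individual_id": ids,
            "family_id": "f0",
            "environment_id": "e0",
            "sex": "M",
            "X": X,
            "Y": Y,
        }
    )
    return frame, identity_relatedness(ids)
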