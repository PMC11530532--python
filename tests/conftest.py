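"""Shared fixtures: a default synthetic cohort and direct score-frame builders."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from elitesport import CohortConfig, build_score_table, generate_cohort
from elitesport.schemes import DOMAINS


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-configuration cohort (n = 296, planted structure)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_table(default_synthetic):
    return build_score_table(default_synthetic.cohort)


def make_score_frame(
    rng: np.random.Generator,
    n: int = 296,
    n_elite: int = 22,
    correlation: np.ndarray | None = None,
    elite_shift: dict | None = None,
    continuous_expertise: bool = False,
) -> pd.DataFrame:
    """Score-table-shaped frame with iid (or correlated) standard-normal domains.

    Elite membership is a uniformly random subset, independent of the
    domain scores unless ``elite_shift`` adds per-domain mean shifts to the
    elite rows. Expertise is drawn consistently with the elite flag.
    """
    if correlation is None:
        scores = rng.standard_normal((n, len(DOMAINS)))
    else:
        scores = rng.multivariate_normal(
            np.zeros(len(DOMAINS)), correlation, size=n
        )
    frame = pd.DataFrame(scores, columns=DOMAINS)
    elite = np.zeros(n, dtype=bool)
    elite[rng.choice(n, size=n_elite, replace=False)] = True
    if elite_shift:
        for domain, shift in elite_shift.items():
            frame.loc[elite, domain] += shift
    frame["athlete_id"] = [f"a{i:04d}" for i in range(n)]
    frame["sex"] = rng.choice(["female", "male"], size=n)
    frame["age"] = rng.normal(19.0, 4.0, size=n).clip(12.0)
    frame["sport"] = "volleyball"
    frame["squad_level"] = "junior"
    frame["micronutrient_raw"] = rng.choice(
        [0, 12.5, 25, 37.5, 50, 62.5, 75, 87.5, 100], size=n
    ).astype(float)
    if continuous_expertise:
        # a normal-error outcome, for exact t-test calibration checks
        frame["expertise"] = rng.normal(7.5, 3.5, size=n)
    else:
        frame["expertise"] = np.where(
            elite,
            rng.integers(13, 17, size=n),
            np.clip(np.round(rng.normal(7.0, 2.5, size=n)), 2, 12),
        ).astype(int)
    frame["elite"] = elite
    return frame
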