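"""Individual z-score profiles of elite athletes and ergodicity labels.

A profile compares one elite athlete's eight domain scores against two
baselines: zero (the whole-cohort mean, the superiority baseline) and the
elite-group mean. An athlete is *ergodic* with respect to the group-level
linear-model pattern when superior (z > 0) in basic cognitive function,
lower-body dynamics, AND blood micronutrients simultaneously, and ergodic
with respect to the logistic pattern when superior in basic cognitive
function AND blood micronutrients. The linear criterion's conditions are
a superset of the logistic criterion's, so ergodic_linear implies
ergodic_logistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .schemes import DOMAINS
from .scoring import ScoreTable

#: Domains flagged by the group-level linear model.
LINEAR_CRITERION = (
    "basic_cognitive_function", "lower_body_dynamics", "blood_micronutrients",
)
#: Domains flagged by the group-level logistic model.
LOGISTIC_CRITERION = ("basic_cognitive_function", "blood_micronutrients")

OUTLIER_Z = 1.0


@dataclass
class ProfileReport:
    """One elite athlete's z-profile, outlier flags, and ergodicity labels."""

    athlete_id: str
    z_scores: dict                      # domain -> z
    positive_outliers: list             # domains with z > +1.0
    negative_outliers: list             # domains with z < -1.0
    sum_score: float                    # sum of the eight z-scores
    above_cohort_mean: dict             # domain -> z > 0
    above_elite_mean: dict              # domain -> z > elite-group mean
    ergodic_linear: bool
    ergodic_logistic: bool
    reference_means: dict               # elite-group per-domain means

    def __post_init__(self):
        assert not set(self.positive_outliers) & set(self.negative_outliers)
        assert abs(self.sum_score - sum(self.z_scores.values())) < 1e-12
        # the linear criterion is a superset of the logistic one
        assert (not self.ergodic_linear) or self.ergodic_logistic


def build_profiles(table: ScoreTable | pd.DataFrame) -> list[ProfileReport]:
    """One ProfileReport per elite athlete in the score table."""
    frame = table.frame if isinstance(table, ScoreTable) else table
    elite = frame[frame["elite"]]
    if len(elite) == 0:
        raise ValidationError(
            f"no elite athletes in the table (n={len(frame)} total)"
        )
    reference = {d: float(elite[d].mean()) for d in DOMAINS}
    reports = []
    for _, row in elite.iterrows():
        z = {d: float(row[d]) for d in DOMAINS}
        above_zero = {d: z[d] > 0.0 for d in DOMAINS}
        reports.append(ProfileReport(
            athlete_id=str(row["athlete_id"]),
            z_scores=z,
            positive_outliers=[d for d in DOMAINS if z[d] > OUTLIER_Z],
            negative_outliers=[d for d in DOMAINS if z[d] < -OUTLIER_Z],
            sum_score=float(sum(z.values())),
            above_cohort_mean=above_zero,
            above_elite_mean={d: z[d] > reference[d] for d in DOMAINS},
            ergodic_linear=all(above_zero[d] for d in LINEAR_CRITERION),
            ergodic_logistic=all(above_zero[d] for d in LOGISTIC_CRITERION),
            reference_means=reference,
        ))
    return reports


@dataclass
class ProfileSummary:
    """Cohort-level counts over the elite profiles plus an anonymized table."""

    n: int
    n_positive_outlier: int          # >= 1 domain with z > +1
    n_negative_outlier: int          # >= 1 domain with z < -1
    n_positive_sum: int              # positive sum score
    n_ergodic_linear: int
    n_ergodic_logistic: int
    table: pd.DataFrame = field(repr=False, default=None)


def summarize_profiles(reports: list[ProfileReport]) -> ProfileSummary:
    """Counts over profiles plus a table keyed by descending sum score.

    Athletes are anonymized as 'Athlete 01', 'Athlete 02', ... in order of
    descending sum score.
    """
    if not reports:
        raise ValidationError("no profiles to summarize")
    ordered = sorted(reports, key=lambda r: -r.sum_score)
    rows = []
    for rank, report in enumerate(ordered, start=1):
        rows.append({
            "label": f"Athlete {rank:02d}",
            "athlete_id": report.athlete_id,
            **{d: report.z_scores[d] for d in DOMAINS},
            "sum_score": report.sum_score,
            "n_positive_outliers": len(report.positive_outliers),
            "n_negative_outliers": len(report.negative_outliers),
            "ergodic_linear": report.ergodic_linear,
            "ergodic_logistic": report.ergodic_logistic,
        })
    table = pd.DataFrame(rows)
    return ProfileSummary(
        n=len(reports),
        n_positive_outlier=sum(bool(r.positive_outliers) for r in reports),
        n_negative_outlier=sum(bool(r.negative_outliers) for r in reports),
        n_positive_sum=sum(r.sum_score > 0 for r in reports),
        n_ergodic_linear=sum(r.ergodic_linear for r in reports),
        n_ergodic_logistic=sum(r.ergodic_logistic for r in reports),
        table=table,
    )


def plot_profiles(reports: list[ProfileReport], path) -> None:
    """Profile-line plot (one line per elite athlete, elite mean dashed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.arange(len(DOMAINS))
    fig, ax = plt.subplots(figsize=(10, 5))
    for report in reports:
        ax.plot(xs, [report.z_scores[d] for d in DOMAINS],
                color="firebrick", alpha=0.4, linewidth=1)
    reference = reports[0].reference_means
    ax.plot(xs, [reference[d] for d in DOMAINS], "k--", linewidth=2,
            label="elite mean")
    ax.axhline(0.0, color="gray", linewidth=1)
    ax.set_xticks(xs)
    ax.set_xticklabels([d.replace("_", "\n") for d in DOMAINS], fontsize=8)
    ax.set_ylabel("z score (0 = cohort mean)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
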