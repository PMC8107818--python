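"""Disease-activity-index (DAI) rubric for murine colitis.

Three components — body-weight decline, stool consistency, fecal blood —
each scored 0-4; the composite DAI is their arithmetic mean, so it lives
in [0, 4]. Weight-loss bands are left-open/right-closed, with 15% and
above scoring 4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from qenp.errors import FormatError, ValidationError

#: stool-consistency categories in increasing severity order (score 0..4)
FECAL_STATES = (
    "normal",
    "between_normal_semithin",
    "semithin",
    "between_semithin_sparse",
    "sparse",
)

#: fecal-blood categories in increasing severity order (score 0..4)
BLOOD_STATES = (
    "negative",
    "between_neg_occult",
    "occult",
    "between_occult_gross",
    "gross",
)

_FECAL_SCORE = {state: i for i, state in enumerate(FECAL_STATES)}
_BLOOD_SCORE = {state: i for i, state in enumerate(BLOOD_STATES)}

#: weight-loss band upper edges (inclusive) for scores 0..3; above -> 4
_WEIGHT_BANDS = (0.0, 5.0, 10.0, 15.0)


def score_weight_loss(pct: float) -> int:
    """Score percent body-weight decline on the 0-4 rubric.

    0 -> 0; (0, 5] -> 1; (5, 10] -> 2; (10, 15) -> 3; >= 15 -> 4.
    """
    if pct < 0:
        raise ValidationError(f"weight loss percent must be >= 0, got {pct}")
    if pct >= 15.0:
        return 4
    for score, edge in enumerate(_WEIGHT_BANDS):
        if pct <= edge:
            return score
    return 3


def score_fecal_state(state: str) -> int:
    try:
        return _FECAL_SCORE[state]
    except KeyError:
        raise ValidationError(
            f"unknown fecal state {state!r}; expected one of {FECAL_STATES}"
        ) from None


def score_blood_state(state: str) -> int:
    try:
        return _BLOOD_SCORE[state]
    except KeyError:
        raise ValidationError(
            f"unknown blood state {state!r}; expected one of {BLOOD_STATES}"
        ) from None


@dataclass(frozen=True)
class DaiObservation:
    """One animal-day's rubric inputs with derived scores and composite DAI."""

    weight_loss_pct: float
    fecal_state: str
    blood_state: str
    animal_id: str = ""
    day: int = 0

    @property
    def component_scores(self) -> tuple[int, int, int]:
        return (
            score_weight_loss(self.weight_loss_pct),
            score_fecal_state(self.fecal_state),
            score_blood_state(self.blood_state),
        )

    @property
    def dai(self) -> float:
        return score_dai(self)


def score_dai(obs: DaiObservation) -> float:
    """Composite DAI: mean of the three component scores, in [0, 4]."""
    w, f, b = obs.component_scores
    return (w + f + b) / 3.0


def read_observations(path: str | Path) -> list[DaiObservation]:
    """Read observations TSV: ``animal_id, day, weight_loss_pct, fecal_state, blood_state``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        names = [n.strip() for n in (reader.fieldnames or [])]
        required = ("animal_id", "day", "weight_loss_pct", "fecal_state", "blood_state")
        for col in required:
            if col not in names:
                raise FormatError(f"{path}: missing required column {col!r}")
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    DaiObservation(
                        animal_id=row["animal_id"].strip(),
                        day=int(row["day"]),
                        weight_loss_pct=float(row["weight_loss_pct"]),
                        fecal_state=row["fecal_state"].strip(),
                        blood_state=row["blood_state"].strip(),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc
    return out


def write_scored_observations(
    observations: Sequence[DaiObservation], path: str | Path
) -> None:
    """Write observations plus component scores and DAI (one decimal)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "animal_id", "day", "weight_loss_pct", "fecal_state", "blood_state",
            "weight_score", "fecal_score", "blood_score", "dai",
        ])
        for obs in observations:
            ws, fs, bs = obs.component_scores
            w.writerow([
                obs.animal_id, obs.day, obs.weight_loss_pct,
                obs.fecal_state, obs.blood_state, ws, fs, bs, f"{obs.dai:.1f}",
            ])
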