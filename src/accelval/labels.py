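"""Activity taxonomy, task label sets, and the METs regression dataset.

The 15 daily activities carry a study-specific taxonomy — major body
movement location (upper / lower / total), intensity (sedentary / light /
moderate), and whether the activity is locomotion — from which the five
classification tasks derive their labels. The taxonomy is configuration
data (a delimited text file), not code, so other activity sets can be
substituted.

METs (metabolic equivalents) express activity energy cost as a multiple
of resting oxygen consumption: MET = VO₂ (ml·min⁻¹·kg⁻¹) / 3.5. Each
session's MET value is linked to the element-wise mean of that session's
feature windows to form one regression observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LinkageError
from .features import FEATURE_NAMES

TASKS = ("activity", "intensity", "locomotion", "sedentary", "location")

LOCATIONS = ("upper", "lower", "total")
INTENSITIES = ("sedentary", "light", "moderate")

RESTING_VO2 = 3.5  # ml·min⁻¹·kg⁻¹, the conventional 1-MET reference


@dataclass(frozen=True)
class ActivityMeta:
    """One activity's task taxonomy and session duration."""

    name: str
    body_location: str
    intensity: str
    locomotion: bool
    duration: float  # minutes
    n_participants: int

    def __post_init__(self):
        if self.body_location not in LOCATIONS:
            raise ValueError(f"unknown body location {self.body_location!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if self.intensity == "sedentary" and self.locomotion:
            raise ValueError("sedentary activities cannot be locomotion")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class MetsObservation:
    """Session-level regression record: averaged features plus the MET value."""

    participant_id: str
    activity_name: str
    mean_features: np.ndarray  # length 15, ordered as FEATURE_NAMES
    met: float

    def __post_init__(self):
        self.mean_features = np.asarray(self.mean_features, dtype=float)
        if self.mean_features.shape != (len(FEATURE_NAMES),):
            raise ValueError("mean_features must hold exactly 15 values")
        if self.met <= 0:
            raise ValueError("MET must be > 0")


def default_taxonomy_path() -> Path:
    return Path(str(resources.files("accelval") / "data" / "activity_taxonomy.csv"))


def load_taxonomy(path=None) -> dict[str, ActivityMeta]:
    """Load the activity taxonomy table; defaults to the packaged 15 activities."""
    df = pd.read_csv(path if path is not None else default_taxonomy_path())
    out: dict[str, ActivityMeta] = {}
    for row in df.itertuples(index=False):
        meta = ActivityMeta(
            name=row.activity,
            body_location=row.location,
            intensity=row.intensity,
            locomotion=str(row.locomotion).strip().lower() in ("yes", "true", "1"),
            duration=float(row.duration_min),
            n_participants=int(row.n_participants),
        )
        out[meta.name] = meta
    return out


def save_taxonomy(taxonomy: dict[str, ActivityMeta], path) -> None:
    """Write a taxonomy back out in the same delimited layout it is read from."""
    pd.DataFrame(
        [
            {
                "activity": m.name,
                "location": m.body_location,
                "intensity": m.intensity,
                "locomotion": "yes" if m.locomotion else "no",
                "duration_min": m.duration,
                "n_participants": m.n_participants,
            }
            for m in taxonomy.values()
        ]
    ).to_csv(path, index=False)


def task_labels(meta: ActivityMeta, task: str) -> str:
    """Class label of an activity under one of the five classification tasks."""
    if task == "activity":
        return meta.name
    if task == "intensity":
        return meta.intensity
    if task == "locomotion":
        return "locomotion" if meta.locomotion else "nonlocomotion"
    if task == "sedentary":
        return "sedentary" if meta.intensity == "sedentary" else "nonsedentary"
    if task == "location":
        return meta.body_location
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def labels_for(
    activity_names, taxonomy: dict[str, ActivityMeta], task: str
) -> np.ndarray:
    """Vectorized task labels for a sequence of activity names."""
    missing = set(activity_names) - set(taxonomy)
    if missing:
        raise LookupError(f"unknown activities: {sorted(missing)}")
    return np.array([task_labels(taxonomy[a], task) for a in activity_names])


def mets_from_vo2(vo2: float) -> float:
    """Convert steady-state oxygen uptake (ml·min⁻¹·kg⁻¹) to METs: VO₂ / 3.5."""
    if vo2 < 0:
        raise ValueError("VO₂ cannot be negative")
    return vo2 / RESTING_VO2


def build_mets_dataset(
    feature_windows: pd.DataFrame, met_values: pd.DataFrame
) -> tuple[list[MetsObservation], list[tuple[str, str]]]:
    """Link per-session MET values to session-averaged features.

    Parameters
    ----------
    feature_windows : DataFrame
        Output of :func:`accelval.features.featurize` (possibly concatenated):
        columns ``participant``, ``activity`` and the 15 feature names.
    met_values : DataFrame
        Columns ``participant``, ``activity`` and either ``met`` or ``vo2``.

    Returns
    -------
    (observations, skipped)
        One :class:`MetsObservation` per (participant, activity) pair that
        has both windows and a MET value; ``skipped`` lists sessions with
        windows but no MET value. A MET value whose session has no windows
        is a linkage error (the orphan sessions are named).
    """
    met_values = met_values.copy()
    if "met" not in met_values.columns:
        if "vo2" not in met_values.columns:
            raise ValueError("met_values needs a 'met' or 'vo2' column")
        met_values["met"] = met_values["vo2"].map(mets_from_vo2)
    mets = {
        (str(r.participant), str(r.activity)): float(r.met)
        for r in met_values.itertuples(index=False)
    }
    grouped = feature_windows.groupby(["participant", "activity"], sort=True)
    means = grouped[list(FEATURE_NAMES)].mean()
    window_keys = {(str(p), str(a)) for p, a in means.index}

    orphans = sorted(set(mets) - window_keys)
    if orphans:
        raise LinkageError(f"MET values without feature windows: {orphans}")

    observations, skipped = [], []
    for (participant, activity), row in means.iterrows():
        key = (str(participant), str(activity))
        if key not in mets:
            skipped.append(key)
            continue
        observations.append(
            MetsObservation(
                participant_id=key[0],
                activity_name=key[1],
                mean_features=row.to_numpy(),
                met=mets[key],
            )
        )
    return observations, skipped
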