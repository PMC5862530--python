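"""Event-log data model, readers/writers, crop normalizations and forager
classification.

The canonical on-disk representation of a colony experiment is three plain CSV
files:

``interactions.csv``
    One row per trophallactic event between a forager and a partner:
    ``t_start,t_end,donor_id,recipient_id,volume,donor_crop,recipient_crop,
    forager_is_donor,experiment_id``.  Volumes are signed with the
    repository-wide convention that positive means net flow *from* the forager
    side (the forager is the donor) and negative means flow back into a
    forager's crop.

``feedings.csv``
    One row per visit of a forager to the food source:
    ``forager_id,t_start,t_end,experiment_id``.

``timelines.csv``
    Long-format per-ant crop-load series on a uniform time grid with boolean
    activity flags: ``ant_id,t,crop,in_trophallaxis,at_food,in_nest,
    experiment_id``.

Crop loads come from fluorescence imaging in arbitrary intensity units; two
normalizations are provided (:func:`normalize_crops`): *between experiments*
(divide by the experiment's 90th-percentile crop measurement, used wherever
absolute loads matter) and *per forager* (divide each forager's series by her
own maximum, used for exit-decision analyses where only the forager's relative
satiety matters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "ForagerClassification",
    "ColonyExperiment",
    "INTERACTION_COLUMNS",
    "FEEDING_COLUMNS",
    "TIMELINE_COLUMNS",
    "load_event_logs",
    "write_event_logs",
    "normalize_crops",
    "classify_foragers",
]


class SchemaError(ValueError):
    """A mandatory column is missing or mistyped in an input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a data-model invariant."""


INTERACTION_COLUMNS = [
    "t_start", "t_end", "donor_id", "recipient_id", "volume",
    "donor_crop", "recipient_crop", "forager_is_donor", "experiment_id",
]
FEEDING_COLUMNS = ["forager_id", "t_start", "t_end", "experiment_id"]
TIMELINE_COLUMNS = [
    "ant_id", "t", "crop", "in_trophallaxis", "at_food", "in_nest",
    "experiment_id",
]

_FLAG_COLUMNS = ["in_trophallaxis", "at_food", "in_nest"]


@dataclass
class ForagerClassification:
    """Partition of ants by feeding behaviour.

    Consistent foragers perform many feeding cycles while casual visitors
    touch the food source only a handful of times; counts in between are
    flagged for manual review rather than silently assigned.
    """

    foragers: set = field(default_factory=set)
    non_foragers: set = field(default_factory=set)
    ambiguous: set = field(default_factory=set)

    def role(self, ant_id) -> str:
        if ant_id in self.foragers:
            return "forager"
        if ant_id in self.ambiguous:
            return "ambiguous"
        return "non-forager"


@dataclass
class ColonyExperiment:
    """A fully cross-referenced colony feeding experiment.

    Attributes
    ----------
    interactions : DataFrame with :data:`INTERACTION_COLUMNS`.
    feedings : DataFrame with :data:`FEEDING_COLUMNS`.
    timelines : long DataFrame with :data:`TIMELINE_COLUMNS`.
    roles : mapping ant_id -> ``"forager" | "non-forager" | "queen" |
        "ambiguous"``.
    intake_target : total-volume normalizer (the post-hoc saturation level of
        accumulated food); ``None`` until estimated.
    onset_times : mapping forager -> time of her first return to the nest
        from the food source (end of first feeding). Downstream stages
        restrict each forager's analysis window to ``t >= onset``.
    """

    interactions: pd.DataFrame
    feedings: pd.DataFrame
    timelines: pd.DataFrame
    roles: dict
    intake_target: float | None = None
    onset_times: dict = field(default_factory=dict)

    @property
    def foragers(self) -> list:
        return sorted(a for a, r in self.roles.items() if r == "forager")

    @property
    def non_foragers(self) -> list:
        return sorted(a for a, r in self.roles.items() if r == "non-forager")

    @property
    def n_foragers(self) -> int:
        return len(self.foragers)

    @property
    def dt(self) -> float:
        """Uniform timeline grid spacing (seconds)."""
        t = np.sort(self.timelines["t"].unique())
        if len(t) < 2:
            raise ValidationError("timeline grid has fewer than two points")
        return float(t[1] - t[0])

    @property
    def t_grid(self) -> np.ndarray:
        return np.sort(self.timelines["t"].unique())

    def timeline_of(self, ant_id) -> pd.DataFrame:
        df = self.timelines[self.timelines["ant_id"] == ant_id]
        return df.sort_values("t").reset_index(drop=True)

    def validate(self) -> None:
        """Check cross-reference and grid invariants; raise on violation."""
        ia, fe, tl = self.interactions, self.feedings, self.timelines
        if len(ia) and (ia["t_end"] < ia["t_start"]).any():
            raise ValidationError("interaction with t_end < t_start")
        if len(fe) and (fe["t_end"] < fe["t_start"]).any():
            raise ValidationError("feeding with t_end < t_start")
        if len(ia) and (ia[["donor_crop", "recipient_crop"]] < 0).any().any():
            raise ValidationError("negative crop load in interactions")
        known = set(self.roles)
        referenced = set()
        if len(ia):
            referenced |= set(ia["donor_id"]) | set(ia["recipient_id"])
        if len(fe):
            referenced |= set(fe["forager_id"])
        missing = referenced - known
        if missing:
            raise ValidationError(
                f"records reference unknown ants: {sorted(missing)[:5]}"
            )
        for (eid, aid), g in tl.groupby(["experiment_id", "ant_id"]):
            t = g["t"].to_numpy()
            if len(t) < 2:
                continue
            d = np.diff(np.sort(t))
            if (d <= 0).any():
                raise ValidationError(f"non-monotone timeline grid for ant {aid}")
            if not np.allclose(d, d[0]):
                raise ValidationError(f"non-uniform timeline grid for ant {aid}")
        if self.intake_target is not None and self.intake_target <= 0:
            raise ValidationError("intake_target must be positive")


def _read_csv(path, mandatory, mapping=None, bool_cols=()):
    df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing mandatory column(s) {missing}")
    extra = [c for c in df.columns if c not in mandatory]
    if extra:
        warnings.warn(f"{Path(path).name}: ignoring unknown column(s) {extra}")
        df = df[list(mandatory)]
    for c in bool_cols:
        df[c] = df[c].astype(bool)
    return df


def load_event_logs(
    interactions_path,
    feedings_path,
    timelines_path,
    mapping_path=None,
    classify: bool = True,
) -> ColonyExperiment:
    """Read the three canonical CSVs into a validated :class:`ColonyExperiment`.

    ``mapping_path`` may point to a YAML file whose top-level keys
    (``interactions``/``feedings``/``timelines``) map canonical column names to
    the names used in an external file dialect.

    Foragers are classified from the feeding log (:func:`classify_foragers`)
    unless ``classify`` is false, in which case every ant appearing as
    ``forager_id`` in the feeding log is taken as a forager.
    """
    mapping = {}
    if mapping_path is not None:
        mapping = yaml.safe_load(Path(mapping_path).read_text()) or {}
    ia = _read_csv(interactions_path, INTERACTION_COLUMNS,
                   mapping.get("interactions"), bool_cols=["forager_is_donor"])
    fe = _read_csv(feedings_path, FEEDING_COLUMNS, mapping.get("feedings"))
    tl = _read_csv(timelines_path, TIMELINE_COLUMNS, mapping.get("timelines"),
                   bool_cols=_FLAG_COLUMNS)

    if classify:
        cls = classify_foragers(fe)
        forager_ids = cls.foragers
        ambiguous = cls.ambiguous
    else:
        forager_ids = set(fe["forager_id"].unique())
        ambiguous = set()
    roles = {}
    for aid in tl["ant_id"].unique():
        roles[aid] = "forager" if aid in forager_ids else "non-forager"
    for aid in forager_ids | ambiguous:
        roles[aid] = "forager" if aid in forager_ids else "ambiguous"

    onsets = {}
    for fid, g in fe.groupby("forager_id"):
        if fid in forager_ids:
            onsets[fid] = float(g["t_end"].min())

    exp = ColonyExperiment(
        interactions=ia.reset_index(drop=True),
        feedings=fe.reset_index(drop=True),
        timelines=tl.reset_index(drop=True),
        roles=roles,
        onset_times=onsets,
    )
    exp.validate()
    return exp


def write_event_logs(experiment: ColonyExperiment, out_dir) -> dict:
    """Write the canonical CSV triplet; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.csv",
        "feedings": out / "feedings.csv",
        "timelines": out / "timelines.csv",
    }
    experiment.interactions[INTERACTION_COLUMNS].to_csv(paths["interactions"], index=False)
    experiment.feedings[FEEDING_COLUMNS].to_csv(paths["feedings"], index=False)
    experiment.timelines[TIMELINE_COLUMNS].to_csv(paths["timelines"], index=False)
    return paths


def normalize_crops(
    timelines: pd.DataFrame,
    mode: str,
    ants=None,
) -> tuple[pd.DataFrame, dict]:
    """Normalize raw crop intensities.

    ``mode="between_experiments"`` divides every measurement by the 90th
    percentile of all crop measurements of its experiment, making absolute
    loads comparable across recordings.  ``mode="per_forager"`` divides each
    ant's series by her own maximum, mapping every ant onto her personal
    [0, 1] satiety scale (restricted to ``ants`` if given).

    Returns the normalized copy and the normalizer(s) used (keyed by
    experiment or by ant) so the transform can be inverted.
    """
    tl = timelines.copy()
    normalizers: dict = {}
    if (tl["crop"] < 0).any():
        raise ValidationError("raw crop intensities must be non-negative")
    if mode == "between_experiments":
        for eid, g in tl.groupby("experiment_id"):
            q = float(np.percentile(g["crop"].to_numpy(), 90))
            if q <= 0:
                raise ValidationError(
                    f"experiment {eid}: 90th-percentile normalizer is zero"
                )
            tl.loc[g.index, "crop"] = g["crop"] / q
            normalizers[eid] = q
    elif mode == "per_forager":
        targets = tl["ant_id"].unique() if ants is None else ants
        for aid in targets:
            idx = tl.index[tl["ant_id"] == aid]
            mx = float(tl.loc[idx, "crop"].max()) if len(idx) else 0.0
            if mx <= 0:
                raise ValidationError(f"ant {aid}: all-zero crop series")
            tl.loc[idx, "crop"] = tl.loc[idx, "crop"] / mx
            normalizers[aid] = mx
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return tl, normalizers


def classify_foragers(
    feedings: pd.DataFrame,
    min_cycles: int = 8,
    max_casual_visits: int = 4,
) -> ForagerClassification:
    """Partition ants by feeding-visit counts.

    Ants with at least ``min_cycles`` feedings are consistent foragers; ants
    with at most ``max_casual_visits`` are casual visitors (non-foragers).
    Counts strictly between the two thresholds are flagged ambiguous for
    manual review — the observation colonies showed a clean gap, so no cutoff
    is invented for the grey zone.
    """
    cls = ForagerClassification()
    if len(feedings) == 0:
        return cls
    counts = feedings.groupby("forager_id").size()
    for aid, n in counts.items():
        if n >= min_cycles:
            cls.foragers.add(aid)
        elif n <= max_casual_visits:
            cls.non_foragers.add(aid)
        else:
            cls.ambiguous.add(aid)
    return cls
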