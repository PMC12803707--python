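"""Experimental design: clarity segments, condition codes, events, parcellation.

The design of the listening experiment is a sequence of contiguous 30-33 s
segments, each played at one of five speech-clarity levels (clear speech or
speech masked by twelve-talker babble at +14, +9, +4 or -1 dB SNR).  The five
levels carry fixed integer codes -2..+2 so that "more masking" is a larger
code; the codes double as contrast weights for linear-trend analyses.

Event boundaries (moments where one narrative unit ends and the next begins)
are given per story in seconds; event *centers* -- the midpoints between
consecutive boundaries -- serve as a non-boundary control condition.

Brain regions come from an abstract parcellation table (region id -> network
label), standing in for the Schaefer atlas grouped into seven networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

#: The five speech-clarity conditions, ordered from clear to most masked.
CONDITIONS: tuple[str, ...] = ("clear", "+14 dB", "+9 dB", "+4 dB", "-1 dB")

#: Fixed bijection condition -> contrast code (-2 = clear ... +2 = -1 dB SNR).
CONDITION_CODES: dict[str, int] = {c: i - 2 for i, c in enumerate(CONDITIONS)}

#: High/low speech-clarity grouping for the event-boundary interaction
#: analysis; the middle (+9 dB) condition belongs to neither group.
HIGH_CLARITY: frozenset[str] = frozenset({"clear", "+14 dB"})
LOW_CLARITY: frozenset[str] = frozenset({"+4 dB", "-1 dB"})

#: Seven-network grouping of the parcellation.
NETWORKS: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

SCHEDULE_COLUMNS = ("onset_s", "offset_s", "condition", "code", "story", "version")


@dataclass
class Schedule:
    """Ordered clarity segments for one or more stories.

    Wraps a DataFrame with columns (onset_s, offset_s, condition, code,
    story, version).  Onsets are story-relative seconds.  Within a story the
    segments must be contiguous, non-overlapping, and no two adjacent
    segments may share a condition.  Segment membership uses half-open
    intervals [onset, offset) so any time point belongs to exactly one
    segment.
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SCHEDULE_COLUMNS) - set(self.segments.columns)
        if missing:
            raise InvalidInputError(f"schedule missing columns: {sorted(missing)}")
        self.segments = self.segments.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for cond, code in zip(self.segments["condition"], self.segments["code"]):
            if cond not in CONDITION_CODES:
                raise InvalidInputError(f"unknown condition {cond!r}")
            if int(code) != CONDITION_CODES[cond]:
                raise InvalidInputError(
                    f"condition {cond!r} carries code {code}, "
                    f"expected {CONDITION_CODES[cond]}"
                )
        for story, seg in self.segments.groupby("story", sort=False):
            onsets = seg["onset_s"].to_numpy(float)
            offsets = seg["offset_s"].to_numpy(float)
            if np.any(offsets <= onsets):
                raise InvalidInputError(f"story {story}: empty or inverted segment")
            if not np.all(np.diff(onsets) > 0):
                raise InvalidInputError(f"story {story}: segments out of order")
            if not np.allclose(offsets[:-1], onsets[1:]):
                raise InvalidInputError(
                    f"story {story}: segments overlap or leave gaps"
                )
            conds = seg["condition"].to_numpy()
            if np.any(conds[:-1] == conds[1:]):
                raise InvalidInputError(
                    f"story {story}: adjacent segments share a condition"
                )

    @property
    def stories(self) -> list:
        return list(dict.fromkeys(self.segments["story"]))

    def for_story(self, story) -> pd.DataFrame:
        seg = self.segments[self.segments["story"] == story]
        if seg.empty:
            raise InvalidInputError(f"no segments for story {story!r}")
        return seg

    def duration_s(self, story) -> float:
        return float(self.for_story(story)["offset_s"].max())

    def condition_at(self, time_s: float, story) -> str:
        """Condition of the segment containing ``time_s`` ([onset, offset))."""
        seg = self.for_story(story)
        hit = seg[(seg["onset_s"] <= time_s) & (time_s < seg["offset_s"])]
        if hit.empty:
            raise InvalidInputError(
                f"time {time_s} s lies outside all segments of story {story!r}"
            )
        return str(hit["condition"].iloc[0])


@dataclass
class EventSet:
    """Event-boundary onsets per story, with derived center times.

    Boundaries must be strictly increasing within each story.  Centers are
    the midpoints between consecutive boundaries, so each story contributes
    one fewer center than boundaries.
    """

    boundaries: dict = field(default_factory=dict)  # story -> 1-D float array

    def __post_init__(self) -> None:
        clean = {}
        for story, times in self.boundaries.items():
            arr = np.asarray(times, dtype=float)
            if arr.ndim != 1:
                raise InvalidInputError("boundary times must be one-dimensional")
            if arr.size >= 2 and not np.all(np.diff(arr) > 0):
                raise InvalidInputError(
                    f"story {story}: boundaries not strictly increasing"
                )
            clean[story] = arr
        self.boundaries = clean

    @property
    def centers(self) -> dict:
        return {s: event_centers(b) if b.size >= 2 else np.empty(0)
                for s, b in self.boundaries.items()}


@dataclass
class Parcellation:
    """Region -> network lookup table.

    ``table`` has columns (region_id, network, n_voxels); every region maps
    to exactly one of the seven networks.  ``dmn_temporal_regions`` is an
    optional subdivision of the default-mode network (the temporal portion)
    used only for display-style summaries; it is empty by default.
    """

    table: pd.DataFrame
    dmn_temporal_regions: frozenset = frozenset()

    def __post_init__(self) -> None:
        need = {"region_id", "network", "n_voxels"}
        missing = need - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"parcellation missing columns: {sorted(missing)}")
        if self.table["region_id"].duplicated().any():
            raise InvalidInputError("duplicate region ids in parcellation")
        self.table = self.table.reset_index(drop=True)
        self._network_of = dict(
            zip(self.table["region_id"], self.table["network"])
        )

    @property
    def region_ids(self) -> list:
        return list(self.table["region_id"])

    def network_of(self, region_id) -> str:
        try:
            return self._network_of[region_id]
        except KeyError:
            raise InvalidInputError(f"unknown region id {region_id!r}") from None

    def regions_in(self, network: str) -> list:
        return [r for r, n in self._network_of.items() if n == network]


def event_centers(boundaries) -> np.ndarray:
    """Midpoints between consecutive event boundaries.

    Parameters
    ----------
    boundaries : array-like of float
        Strictly increasing boundary times in seconds; at least two.

    Returns
    -------
    ndarray with ``len(boundaries) - 1`` entries,
    ``centers[i] = (boundaries[i] + boundaries[i+1]) / 2``.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or b.size < 2:
        raise InvalidInputError("need at least two boundary times")
    if not np.all(np.diff(b) > 0):
        raise InvalidInputError("boundary times must be strictly increasing")
    return (b[:-1] + b[1:]) / 2.0


def condition_boxcars(
    schedule: Schedule, n_volumes: int, tr_s: float = 1.0, story=None
) -> pd.DataFrame:
    """Per-condition binary indicator series for one story.

    Volume k covers [k*tr, (k+1)*tr); a volume belongs to the segment that
    contains its onset time (half-open segment intervals), so at every
    in-story volume exactly one of the five indicators is 1.  Volumes after
    the story's end are 0 in all columns.

    Returns a DataFrame of shape (n_volumes, 5) with one column per
    condition in ``CONDITIONS`` order.
    """
    if story is None:
        stories = schedule.stories
        if len(stories) != 1:
            raise InvalidInputError(
                "schedule spans multiple stories; pass `story` explicitly"
            )
        story = stories[0]
    seg = schedule.for_story(story)
    if seg["offset_s"].max() > n_volumes * tr_s + 1e-9:
        raise InvalidInputError(
            f"story {story!r} schedule ({seg['offset_s'].max()} s) exceeds run "
            f"length ({n_volumes * tr_s} s)"
        )
    out = pd.DataFrame(
        np.zeros((n_volumes, len(CONDITIONS))), columns=list(CONDITIONS)
    )
    t = np.arange(n_volumes) * tr_s
    for _, row in seg.iterrows():
        mask = (row["onset_s"] <= t) & (t < row["offset_s"])
        out.loc[mask, row["condition"]] = 1.0
    return out


def clarity_group_of(time_s: float, schedule: Schedule, story=None) -> str:
    """High/low speech-clarity group of the segment containing ``time_s``.

    clear and +14 dB segments -> ``"high"``; +4 and -1 dB -> ``"low"``; the
    middle +9 dB condition -> ``"excluded"`` (it belongs to neither group).
    """
    if story is None:
        stories = schedule.stories
        if len(stories) != 1:
            raise InvalidInputError(
                "schedule spans multiple stories; pass `story` explicitly"
            )
        story = stories[0]
    cond = schedule.condition_at(time_s, story)
    if cond in HIGH_CLARITY:
        return "high"
    if cond in LOW_CLARITY:
        return "low"
    return "excluded"


def network_average(values, parcellation: Parcellation):
    """Unweighted mean over regions within each network.

    ``values`` is either a Series indexed by region id (one scalar per
    region) or a DataFrame with one column per region id (time courses).
    Returns the same kind of object keyed by network.  Networks with no
    regions present in ``values`` are absent from the output.
    """
    if isinstance(values, pd.Series):
        regions = list(values.index)
    elif isinstance(values, pd.DataFrame):
        regions = list(values.columns)
    else:
        raise InvalidInputError(
            "values must be a Series (per-region scalars) or DataFrame "
            "(per-region time courses)"
        )
    groups: dict[str, list] = {}
    for r in regions:
        groups.setdefault(parcellation.network_of(r), []).append(r)
    ordered = [n for n in NETWORKS if n in groups]
    ordered += [n for n in groups if n not in NETWORKS]
    if isinstance(values, pd.Series):
        return pd.Series(
            {n: float(values[groups[n]].mean()) for n in ordered}, name=values.name
        )
    return pd.DataFrame({n: values[groups[n]].mean(axis=1) for n in ordered})


def default_parcellation(
    n_regions: int, voxels_per_region: int = 10
) -> Parcellation:
    """Round-robin assignment of ``n_regions`` regions to the 7 networks."""
    if n_regions < 1:
        raise InvalidParameterError("need at least one region")
    table = pd.DataFrame(
        {
            "region_id": np.arange(n_regions),
            "network": [NETWORKS[i % len(NETWORKS)] for i in range(n_regions)],
            "n_voxels": voxels_per_region,
        }
    )
    return Parcellation(table)
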