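"""Readers, writers, subject exclusion, run configuration and the driver.

All tabular artifacts are plain delimited text: parcel series and event
sets as TSV, schedules as CSV, ground truth and the run manifest as JSON.
Voxel blocks, when materialized on disk, go into a single HDF5 container.
Every pipeline run writes a manifest recording parameters, seed and the
exclusion log, and identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import glm as glm_mod
from . import isc as isc_mod
from . import stats as stats_mod
from .design import EventSet, Parcellation, Schedule, SCHEDULE_COLUMNS
from .errors import DependencyError, InvalidInputError, InvalidParameterError, ParseError
from .synthetic import SynthParams, simulate_dataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# delimited readers/writers


def _read_delimited(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise ParseError(f"{path}: {e}") from e
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: file is empty")
    header = lines[0].split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"{path}: duplicate columns {dupes}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {lineno} has {len(cells)} fields, "
                f"expected {len(header)}"
            )
        rows.append(cells)
    return pd.DataFrame(rows, columns=header)


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index[0] + 2
            raise ParseError(
                f"{path}: non-numeric value in column {c!r} at line {bad}"
            ) from None
    return df


def write_parcel_series(df: pd.DataFrame, path) -> None:
    """Write a (volumes x regions) frame as TSV with a leading volume column."""
    out = df.copy()
    out.insert(0, "volume", np.arange(len(out)))
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_parcel_series(path) -> pd.DataFrame:
    """Read a parcel-series TSV; returns a (volumes x regions) frame."""
    df = _read_delimited(path, "\t")
    if "volume" not in df.columns:
        raise ParseError(f"{path}: missing 'volume' column")
    df = _numeric(df, df.columns, path)
    df = df.sort_values("volume").drop(columns="volume").reset_index(drop=True)
    df.columns = [_maybe_int(c) for c in df.columns]
    return df


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


def write_schedule(schedule: Schedule, path) -> None:
    schedule.segments.to_csv(path, index=False)


def read_schedule(path) -> Schedule:
    df = _read_delimited(str(path), ",")
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: schedule missing columns {sorted(missing)}")
    df = _numeric(df, ["onset_s", "offset_s", "code", "version"], path)
    df["story"] = df["story"].map(_maybe_int)
    return Schedule(df)


def write_events(events: EventSet, path) -> None:
    rows = []
    for story, times in events.boundaries.items():
        rows += [(story, float(t), "boundary") for t in times]
        rows += [(story, float(t), "center") for t in events.centers[story]]
    pd.DataFrame(rows, columns=["story", "onset_s", "type"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(path) -> EventSet:
    df = _read_delimited(path, "\t")
    df = _numeric(df, ["onset_s"], path)
    df["story"] = df["story"].map(_maybe_int)
    boundaries = {
        story: np.sort(sub.loc[sub["type"] == "boundary", "onset_s"].to_numpy())
        for story, sub in df.groupby("story")
    }
    return EventSet(boundaries)


def write_parcellation(parcellation: Parcellation, path) -> None:
    parcellation.table.to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    df = _read_delimited(path, "\t")
    df = _numeric(df, ["n_voxels"], path)
    df["region_id"] = df["region_id"].map(_maybe_int)
    return Parcellation(df)


def write_voxels_h5(voxels: dict, path) -> None:
    """Voxel blocks into one HDF5 container: /sub<id>/story<id>/region<id>."""
    import h5py

    with h5py.File(path, "w") as f:
        for subject, by_story in voxels.items():
            for story, blocks in by_story.items():
                g = f.require_group(f"sub{subject}/story{story}")
                for region, arr in blocks.items():
                    g.create_dataset(f"region{region}", data=arr)


def read_voxels_h5(path) -> dict:
    import h5py

    out: dict = {}
    with h5py.File(path, "r") as f:
        for skey in f:
            subject = _maybe_int(skey.removeprefix("sub"))
            out[subject] = {}
            for tkey in f[skey]:
                story = _maybe_int(tkey.removeprefix("story"))
                out[subject][story] = {
                    _maybe_int(rkey.removeprefix("region")): f[skey][tkey][rkey][()]
                    for rkey in f[skey][tkey]
                }
    return out


# ---------------------------------------------------------------------------
# subject exclusion


def exclude_by_comprehension(scores, chance: float = 0.5) -> list:
    """Retain subjects above chance comprehension on *every* story.

    ``scores`` maps subject -> {story -> proportion correct} (or a
    DataFrame subjects x stories).  A subject at or below ``chance`` on any
    story is excluded (logged with the story and score).  A missing story
    score is an error, not an implicit exclusion.
    """
    if isinstance(scores, pd.DataFrame):
        scores = {s: dict(row) for s, row in scores.iterrows()}
    stories = None
    retained = []
    for subject, per_story in scores.items():
        if stories is None:
            stories = set(per_story)
        missing = stories - set(per_story)
        if missing or set(per_story) - stories:
            raise InvalidInputError(
                f"subject {subject!r}: story scores {sorted(set(per_story))} "
                f"do not match expected {sorted(stories)}"
            )
        vals = {st: float(v) for st, v in per_story.items()}
        if any(not 0.0 <= v <= 1.0 for v in vals.values()):
            raise InvalidInputError(
                f"subject {subject!r}: scores must be proportions in [0, 1]"
            )
        bad = {st: v for st, v in vals.items() if v <= chance}
        if bad:
            logger.info(
                "excluding subject %r: at/below chance (%.2f) on %s",
                subject, chance, bad,
            )
        else:
            retained.append(subject)
    return retained


# ---------------------------------------------------------------------------
# configuration and pipeline driver


@dataclass
class RunConfig:
    """Parameters of one pipeline run (YAML-loadable key/value config)."""

    out_dir: str = "storysync_out"
    seed: int = 0
    stages: tuple = ("simulate", "glm", "isc", "trend", "events")
    alpha: float = 0.05
    q: float = 0.05
    shift_s: float = 5.0
    include_voxels: bool = False
    synth: dict = field(default_factory=dict)  # overrides for SynthParams

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def synth_params(self) -> SynthParams:
        return SynthParams(seed=self.seed, **self.synth)


STAGE_ORDER = ("simulate", "glm", "isc", "trend", "events")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    ``simulate`` writes the synthetic dataset (parcel TSVs, schedule CSV,
    events TSV, parcellation TSV, ground-truth JSON, optional voxel HDF5);
    the analysis stages read those files back, so any stage can be re-run
    from its on-disk inputs.  Returns a manifest dict (also written to
    ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    if not stages:
        raise InvalidParameterError(f"no valid stages in {config.stages}")
    written: list[str] = []

    def _save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        written.append(name)

    if "simulate" in stages:
        params = config.synth_params()
        ds = simulate_dataset(params, include_voxels=config.include_voxels)
        (out / "parcel").mkdir(exist_ok=True)
        for subject, by_story in ds.parcel.items():
            for story, df in by_story.items():
                name = f"parcel/sub{subject}_story{story}.tsv"
                write_parcel_series(df, out / name)
                written.append(name)
        write_schedule(ds.schedule, out / "schedule.csv")
        write_events(ds.events, out / "events.tsv")
        write_parcellation(ds.parcellation, out / "parcellation.tsv")
        (out / "ground_truth.json").write_text(
            json.dumps(_jsonable(asdict(ds.truth)), indent=1)
        )
        written += ["schedule.csv", "events.tsv", "parcellation.tsv",
                    "ground_truth.json"]
        if config.include_voxels and ds.voxels is not None:
            write_voxels_h5(ds.voxels, out / "voxels.h5")
            written.append("voxels.h5")

    def _load_dataset():
        sched_path = out / "schedule.csv"
        if not sched_path.exists():
            raise DependencyError(
                "stage requires 'simulate' outputs (schedule.csv missing); "
                "run the simulate stage first"
            )
        schedule = read_schedule(sched_path)
        parcel: dict = {}
        for p in sorted((out / "parcel").glob("sub*_story*.tsv")):
            stem = p.stem  # sub<i>_story<t>
            subject = _maybe_int(stem.split("_story")[0].removeprefix("sub"))
            story = _maybe_int(stem.split("_story")[1])
            parcel.setdefault(subject, {})[story] = read_parcel_series(p)
        if not parcel:
            raise DependencyError("no parcel series found; run simulate first")
        return schedule, parcel

    if "glm" in stages:
        schedule, parcel = _load_dataset()
        n_volumes = {
            story: len(next(iter(parcel.values()))[story])
            for story in schedule.stories
        }
        design = glm_mod.build_condition_design(schedule, n_volumes)
        weights = glm_mod.clarity_contrast_vector(design)
        concat = {
            s: pd.concat([by_story[t] for t in schedule.stories], ignore_index=True)
            for s, by_story in parcel.items()
        }
        table = glm_mod.fit_contrast_table(concat, design, weights, "clarity_linear")
        _save(table, "glm_contrasts.tsv")
        wide = table.pivot(index="subject", columns="region", values="value")
        _save(stats_mod.group_zmap(wide, "clarity_linear", alpha=config.alpha),
              "glm_zmap.tsv")

    if "isc" in stages:
        schedule, parcel = _load_dataset()
        t_isc = isc_mod.temporal_isc(parcel, schedule, shift_s=config.shift_s)
        tables = [t_isc]
        vox_path = out / "voxels.h5"
        if vox_path.exists():
            voxels = read_voxels_h5(vox_path)
            tables.append(
                isc_mod.spatial_isc(voxels, schedule, shift_s=config.shift_s)
            )
        _save(pd.concat(tables, ignore_index=True), "isc_table.tsv")

    if "trend" in stages:
        isc_path = out / "isc_table.tsv"
        if not isc_path.exists():
            raise DependencyError("trend stage requires isc_table.tsv; run isc first")
        isc_table = _read_delimited(isc_path, "\t")
        # undefined ISC entries round-trip as empty cells -> NaN
        isc_table["isc"] = pd.to_numeric(
            isc_table["isc"].replace("", np.nan), errors="raise"
        )
        _save(stats_mod.trend_zmaps(isc_table, alpha=config.alpha),
              "trend_zmaps.tsv")

    if "events" in stages:
        schedule, parcel = _load_dataset()
        ev_path = out / "events.tsv"
        if not ev_path.exists():
            raise DependencyError("events stage requires events.tsv; run simulate first")
        event_set = read_events(ev_path)
        parc = read_parcellation(out / "parcellation.tsv")
        contrasts = ev.boundary_contrasts(
            parcel, event_set, schedule=schedule, clarity_split=True
        )
        _save(contrasts, "boundary_contrasts.tsv")
        _save(ev.boundary_vs_center_zmap(contrasts, alpha=config.alpha),
              "boundary_zmap.tsv")
        _save(ev.clarity_interaction_zmap(contrasts, alpha=config.alpha),
              "interaction_zmap.tsv")
        tc_b = ev.network_epoch_timecourses(parcel, event_set, parc, "boundary")
        tc_c = ev.network_epoch_timecourses(parcel, event_set, parc, "center")
        _save(ev.network_timecourse_stats(tc_b, tc_c, q=config.q),
              "network_timecourse_stats.tsv")
        cells = contrasts[contrasts["clarity_group"].isin(["high", "low"])]
        _save(
            ev.rm_anova_2x2(
                cells.groupby(["subject", "event_type", "clarity_group"],
                              as_index=False)["value"].mean()
            ),
            "rm_anova.tsv",
        )

    manifest = {
        "config": {**asdict(config), "stages": list(stages)},
        "outputs": written,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "storysync": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
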