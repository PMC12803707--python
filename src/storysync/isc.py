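"""Leave-one-out intersubject correlation, temporal and spatial.

Both analyses first shift every BOLD time course by 5 s so that the sample
recorded at stimulus time ``t + 5`` represents the response to stimulus
time ``t`` (hemodynamic delay), then window the shifted series by the
speech-clarity segments of the schedule.

*Temporal* ISC: per region, each segment's samples are mean-centered within
the segment, same-condition segments are concatenated across segments and
stories, and each subject's concatenated course is Spearman-correlated with
the average of all other subjects' courses.

*Spatial* ISC: per region and condition, each voxel's activity is averaged
over time within a segment and across same-condition segments, the voxel
values are mean-centered across the voxels of the region (per story),
stories are concatenated, and the leave-one-out Spearman correlation is
taken across subjects on these voxel-pattern vectors.

Undefined correlations (zero-variance inputs) are recorded as NaN and
counted, never silently coerced to 0.  Subjects hearing different
randomizations of the conditions form separate subgroups; their ISC tables
are computed independently and pooled afterwards.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CONDITIONS, Schedule
from .errors import InvalidInputError, SubgroupMismatchError

logger = logging.getLogger(__name__)

ISC_COLUMNS = ("subject", "version", "condition", "region", "mode", "isc")


def shift_for_hemodynamics(series, shift_s: float, tr_s: float = 1.0) -> np.ndarray:
    """Align BOLD to stimulus time by dropping the first ``shift_s`` seconds.

    After the shift, index ``t`` of the result holds the BOLD sample
    recorded at ``t + shift_s``, i.e., the response attributed to stimulus
    time ``t``; the usable stimulus span shrinks by ``shift_s``.
    """
    x = np.asarray(series, dtype=float)
    k = shift_s / tr_s
    if abs(k - round(k)) > 1e-9:
        raise InvalidInputError(
            f"shift {shift_s} s is not a whole number of TRs ({tr_s} s)"
        )
    k = int(round(k))
    if k < 0:
        raise InvalidInputError("shift must be non-negative")
    if x.shape[-1] <= k:
        raise InvalidInputError(
            f"series of length {x.shape[-1]} too short for a {k}-sample shift"
        )
    return x[..., k:] if k else x.copy()


def loo_spearman(vectors) -> np.ndarray:
    """Leave-one-out Spearman correlation per subject.

    ``vectors`` is (n_subjects, n_samples).  For each subject the raw
    vectors of the remaining subjects are averaged element-wise *first*;
    ranks (average ranks at ties) are then assigned to the held-out vector
    and to that average, and their Pearson correlation is returned.  A
    held-out vector or mean-of-others with zero variance yields NaN.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise InvalidInputError("need a 2-D array with at least 3 subjects")
    if X.shape[1] < 3:
        raise InvalidInputError("need at least 3 samples per subject")
    n = X.shape[0]
    total = X.sum(axis=0)
    out = np.full(n, np.nan)
    for i in range(n):
        others_mean = (total - X[i]) / (n - 1)
        out[i] = _spearman(X[i], others_mean)
    return out


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    sa = ra.std()
    sb = rb.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((ra - ra.mean()) * (rb - rb.mean())).mean() / (sa * sb))


def _segment_windows(
    schedule: Schedule, story, n_samples: int, tr_s: float
) -> list[tuple[str, np.ndarray]]:
    """(condition, volume-index array) per segment, in schedule order.

    A segment owns the volumes whose stimulus-time midpoints fall in
    [onset, offset); ``n_samples`` is the length of the *shifted* series,
    so windows past its end are truncated.
    """
    t_mid = (np.arange(n_samples) + 0.5) * tr_s
    wins = []
    for _, row in schedule.for_story(story).iterrows():
        idx = np.nonzero((row["onset_s"] <= t_mid) & (t_mid < row["offset_s"]))[0]
        if idx.size:
            wins.append((row["condition"], idx))
    return wins


def _check_subgroup(data: dict, schedule: Schedule) -> int:
    versions = set(schedule.segments["version"])
    if len(versions) != 1:
        raise SubgroupMismatchError(
            f"schedule mixes randomization versions {sorted(versions)}; "
            "compute ISC per subgroup and pool afterwards"
        )
    return int(versions.pop())


def temporal_isc(
    parcel: dict, schedule: Schedule, shift_s: float = 5.0, tr_s: float = 1.0
) -> pd.DataFrame:
    """Temporal leave-one-out ISC per (subject, condition, region).

    ``parcel`` maps subject -> {story -> DataFrame (volumes x regions)};
    all subjects must share the schedule (one randomization subgroup).
    Returns a tidy IscTable (subject, version, condition, region, mode,
    isc) with ``mode == "temporal"``.
    """
    version = _check_subgroup(parcel, schedule)
    subjects = list(parcel)
    if len(subjects) < 3:
        raise InvalidInputError("need at least 3 subjects for leave-one-out ISC")
    stories = schedule.stories
    regions = list(parcel[subjects[0]][stories[0]].columns)
    for s in subjects:
        if set(s_keys := parcel[s].keys()) != set(stories):
            raise SubgroupMismatchError(
                f"subject {s} has stories {sorted(s_keys)}, expected {stories}"
            )

    # per subject: condition -> list of centered segment chunks
    chunks: dict = {s: {c: [] for c in CONDITIONS} for s in subjects}
    for story in stories:
        n_shift = None
        for s in subjects:
            shifted = shift_for_hemodynamics(
                parcel[s][story].to_numpy(dtype=float).T, shift_s, tr_s
            )  # regions x samples
            if n_shift is None:
                n_shift = shifted.shape[1]
                wins = _segment_windows(schedule, story, n_shift, tr_s)
            elif shifted.shape[1] != n_shift:
                raise SubgroupMismatchError(
                    f"subject {s} run length differs within story {story}"
                )
            for cond, idx in wins:
                seg = shifted[:, idx]
                chunks[s][cond].append(seg - seg.mean(axis=1, keepdims=True))

    rows = []
    n_undefined = 0
    for cond in CONDITIONS:
        stacked = np.stack(
            [np.concatenate(chunks[s][cond], axis=1) for s in subjects]
        )  # subjects x regions x samples
        for ri, region in enumerate(regions):
            iscs = loo_spearman(stacked[:, ri, :])
            n_undefined += int(np.isnan(iscs).sum())
            for s, v in zip(subjects, iscs):
                rows.append((s, version, cond, region, "temporal", v))
    if n_undefined:
        logger.warning("temporal ISC: %d undefined (zero-variance) entries",
                       n_undefined)
    return pd.DataFrame(rows, columns=list(ISC_COLUMNS))


def spatial_isc(
    voxels: dict, schedule: Schedule, shift_s: float = 5.0, tr_s: float = 1.0
) -> pd.DataFrame:
    """Spatial leave-one-out ISC per (subject, condition, region).

    ``voxels`` maps subject -> {story -> {region -> ndarray (voxels x
    volumes)}}.  Per subject, condition, region and story, each voxel's
    signal is time-averaged within each segment and across same-condition
    segments, the voxel vector is mean-centered within the region, and the
    per-story vectors are concatenated; the leave-one-out Spearman across
    subjects on those vectors is the spatial ISC.
    """
    version = _check_subgroup(voxels, schedule)
    subjects = list(voxels)
    if len(subjects) < 3:
        raise InvalidInputError("need at least 3 subjects for leave-one-out ISC")
    stories = schedule.stories
    regions = list(voxels[subjects[0]][stories[0]].keys())

    # patterns[s][cond][region] -> list of per-story centered voxel vectors
    patterns: dict = {
        s: {c: {r: [] for r in regions} for c in CONDITIONS} for s in subjects
    }
    for story in stories:
        wins = None
        for s in subjects:
            block = voxels[s][story]
            for region in regions:
                vb = np.asarray(block[region], dtype=float)
                ref = np.asarray(voxels[subjects[0]][story][region])
                if vb.shape[0] != ref.shape[0]:
                    raise InvalidInputError(
                        f"voxel count mismatch in region {region!r}: subject "
                        f"{s} has {vb.shape[0]}, expected {ref.shape[0]}"
                    )
                shifted = shift_for_hemodynamics(vb, shift_s, tr_s)
                if wins is None:
                    wins = _segment_windows(schedule, story, shifted.shape[1], tr_s)
                by_cond: dict = {}
                for cond, idx in wins:
                    by_cond.setdefault(cond, []).append(
                        shifted[:, idx].mean(axis=1)
                    )
                for cond in CONDITIONS:
                    if cond in by_cond:
                        v = np.mean(by_cond[cond], axis=0)
                        patterns[s][cond][region].append(v - v.mean())
        wins = None  # recompute for the next story

    rows = []
    n_undefined = 0
    for cond in CONDITIONS:
        for region in regions:
            stacked = np.stack(
                [np.concatenate(patterns[s][cond][region]) for s in subjects]
            )
            iscs = loo_spearman(stacked)
            n_undefined += int(np.isnan(iscs).sum())
            for s, v in zip(subjects, iscs):
                rows.append((s, version, cond, region, "spatial", v))
    if n_undefined:
        logger.warning("spatial ISC: %d undefined (zero-variance) entries",
                       n_undefined)
    return pd.DataFrame(rows, columns=list(ISC_COLUMNS))


def pool_subgroups(tables) -> pd.DataFrame:
    """Concatenate per-version IscTables; subject sets must be disjoint."""
    tables = list(tables)
    if not tables:
        raise InvalidInputError("no tables to pool")
    seen: dict = {}
    for t in tables:
        for subj, ver in t[["subject", "version"]].drop_duplicates().itertuples(
            index=False
        ):
            if subj in seen and seen[subj] != ver:
                raise InvalidInputError(
                    f"subject {subj!r} appears in versions {seen[subj]} and {ver}"
                )
            seen[subj] = ver
    return pd.concat(tables, ignore_index=True)
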