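"""Boundary-locked epochs, post-minus-pre contrasts, and their statistics.

Narrative event boundaries evoke a transient BOLD response that peaks ~5 s
after the boundary.  The analyses here extract 21-sample epochs (−10..+10 s
at 1 s resolution) around event boundaries and around event centers (the
midpoints between boundaries, a non-boundary control), summarize each
epoch average by the post-minus-pre contrast (mean over +1..+7 s minus mean
over −7..−1 s), and test:

* boundary vs center post-minus-pre, paired t per region;
* the speech-clarity interaction — (boundary_high − boundary_low) −
  (center_high − center_low) — against zero per region;
* per-offset paired tests on network-average epoch time courses with
  Benjamini–Hochberg correction across the 21 offsets;
* the 2×2 within-subject rmANOVA Speech Clarity × Event Type on the
  post-minus-pre contrasts.

Epochs are taken from the *raw* (unshifted) series so that the hemodynamic
delay is visible in the time course; epochs whose window would cross the
run edge are excluded, and events are assigned to high/low clarity by the
segment containing their onset (events in +9 dB segments are excluded from
the clarity split only).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import EventSet, Parcellation, Schedule, clarity_group_of, network_average
from .errors import InvalidInputError
from .stats import fdr_bh, group_zmap, one_sample_t_to_z, paired_t_to_z, t_to_z, ZMAP_COLUMNS

logger = logging.getLogger(__name__)

EPOCH_WINDOW_S = (-10.0, 10.0)
POST_OFFSETS_S = (1.0, 7.0)
PRE_OFFSETS_S = (-7.0, -1.0)

CONTRAST_COLUMNS = (
    "subject", "region", "event_type", "clarity_group", "value", "n_epochs",
)


def extract_epochs(
    series,
    event_times,
    window: tuple[float, float] = EPOCH_WINDOW_S,
    tr_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked epochs from a single time course.

    Event times are mapped to volumes by rounding to the nearest TR.  Each
    event whose full window lies inside the series contributes one row of
    ``(window[1] - window[0]) / tr_s + 1`` samples; sample at offset 0 is
    the event volume.  Returns ``(epochs, kept)`` where ``kept`` marks
    which events contributed; raises if no event has a complete window.
    """
    x = np.asarray(series, dtype=float).ravel()
    times = np.asarray(event_times, dtype=float).ravel()
    lo = int(round(window[0] / tr_s))
    hi = int(round(window[1] / tr_s))
    vols = np.round(times / tr_s).astype(int)
    kept = (vols + lo >= 0) & (vols + hi < x.size)
    n_excl = int((~kept).sum())
    if n_excl:
        logger.info("excluded %d events with incomplete windows", n_excl)
    if not kept.any():
        raise InvalidInputError("no event has a complete epoch window")
    rows = np.stack([x[v + lo : v + hi + 1] for v in vols[kept]])
    return rows, kept


def post_minus_pre(
    epoch_mean,
    tr_s: float = 1.0,
    window: tuple[float, float] = EPOCH_WINDOW_S,
) -> float:
    """Mean over +1..+7 s minus mean over −7..−1 s of one epoch average."""
    e = np.asarray(epoch_mean, dtype=float).ravel()
    n_expected = int(round((window[1] - window[0]) / tr_s)) + 1
    if e.size != n_expected or not np.all(np.isfinite(e)):
        raise InvalidInputError(
            f"need a complete finite epoch of {n_expected} samples, got {e.size}"
        )
    offsets = window[0] + tr_s * np.arange(e.size)
    post = (POST_OFFSETS_S[0] - 1e-9 <= offsets) & (offsets <= POST_OFFSETS_S[1] + 1e-9)
    pre = (PRE_OFFSETS_S[0] - 1e-9 <= offsets) & (offsets <= PRE_OFFSETS_S[1] + 1e-9)
    return float(e[post].mean() - e[pre].mean())


def _event_lists(events: EventSet, event_type: str, story):
    if event_type == "boundary":
        return events.boundaries.get(story, np.empty(0))
    if event_type == "center":
        return events.centers.get(story, np.empty(0))
    raise InvalidInputError(f"unknown event type {event_type!r}")


def epoch_means(
    parcel: dict,
    events: EventSet,
    event_type: str,
    schedule: Schedule | None = None,
    clarity_group: str | None = None,
    tr_s: float = 1.0,
    window: tuple[float, float] = EPOCH_WINDOW_S,
) -> dict:
    """Average event-locked epoch per subject and region, pooled over stories.

    Returns subject -> DataFrame (21 samples x regions).  If
    ``clarity_group`` is ``"high"`` or ``"low"``, only events whose onset
    falls in a segment of that group are used (requires ``schedule``).
    """
    out = {}
    for subject, by_story in parcel.items():
        acc = None
        n = 0
        regions = None
        for story, df in by_story.items():
            times = _event_lists(events, event_type, story)
            if clarity_group is not None:
                if schedule is None:
                    raise InvalidInputError("clarity split requires a schedule")
                times = np.array(
                    [
                        t
                        for t in times
                        if clarity_group_of(t, schedule, story=story) == clarity_group
                    ]
                )
            if times.size == 0:
                continue
            regions = list(df.columns)
            data = df.to_numpy(dtype=float)
            try:
                # one extraction per region over the same events
                per_region = []
                for ri in range(data.shape[1]):
                    rows, kept = extract_epochs(data[:, ri], times, window, tr_s)
                    per_region.append(rows)
            except InvalidInputError:
                continue
            stacked = np.stack(per_region, axis=-1)  # events x 21 x regions
            s = stacked.sum(axis=0)
            acc = s if acc is None else acc + s
            n += stacked.shape[0]
        if acc is None or n == 0:
            raise InvalidInputError(
                f"subject {subject}: no complete epochs for {event_type}"
                + (f"/{clarity_group}" if clarity_group else "")
            )
        out[subject] = pd.DataFrame(acc / n, columns=regions)
    return out


def boundary_contrasts(
    parcel: dict,
    events: EventSet,
    schedule: Schedule | None = None,
    clarity_split: bool = False,
    tr_s: float = 1.0,
) -> pd.DataFrame:
    """Post-minus-pre contrast per subject, region and event type.

    With ``clarity_split=True`` the contrasts are additionally computed per
    high/low clarity group (the +9 dB condition contributes to neither).
    Returns a tidy frame with columns ``CONTRAST_COLUMNS``; the unsplit
    rows carry clarity_group ``"all"``.
    """
    groups = [None] if not clarity_split else [None, "high", "low"]
    rows = []
    for event_type in ("boundary", "center"):
        for grp in groups:
            means = epoch_means(
                parcel, events, event_type, schedule=schedule,
                clarity_group=grp, tr_s=tr_s,
            )
            for subject, df in means.items():
                for region in df.columns:
                    rows.append(
                        (
                            subject,
                            region,
                            event_type,
                            grp or "all",
                            post_minus_pre(df[region].to_numpy(), tr_s),
                            np.nan,
                        )
                    )
    return pd.DataFrame(rows, columns=list(CONTRAST_COLUMNS))


def _pivot(contrasts: pd.DataFrame, event_type: str, clarity_group: str) -> pd.DataFrame:
    sub = contrasts[
        (contrasts["event_type"] == event_type)
        & (contrasts["clarity_group"] == clarity_group)
    ]
    if sub.empty:
        raise InvalidInputError(
            f"no contrasts for event_type={event_type!r}, "
            f"clarity_group={clarity_group!r}"
        )
    return sub.pivot(index="subject", columns="region", values="value")


def boundary_vs_center_zmap(
    contrasts: pd.DataFrame, alpha: float = 0.05, m: int | None = None
) -> pd.DataFrame:
    """Paired t -> z per region: boundary vs center post-minus-pre.

    Positive z means a larger response around boundaries than centers.
    """
    b = _pivot(contrasts, "boundary", "all")
    c = _pivot(contrasts, "center", "all")
    c = c.reindex(index=b.index, columns=b.columns)
    diff = b - c
    dropped = int(diff.isna().any(axis=1).sum())
    if dropped:
        logger.info("boundary-vs-center: %d subjects with missing pairs", dropped)
    return group_zmap(diff, "boundary_vs_center", alpha=alpha, m=m)


def clarity_interaction_zmap(
    contrasts: pd.DataFrame, alpha: float = 0.05, m: int | None = None
) -> pd.DataFrame:
    """z map of the clarity x event-type interaction per region.

    Per subject and region:
    ``(boundary_high - boundary_low) - (center_high - center_low)``, the
    three-way interaction of time window, speech clarity and event type;
    tested against zero across subjects.
    """
    bh = _pivot(contrasts, "boundary", "high")
    bl = _pivot(contrasts, "boundary", "low")
    ch = _pivot(contrasts, "center", "high")
    cl = _pivot(contrasts, "center", "low")
    bl, ch, cl = (x.reindex(index=bh.index, columns=bh.columns) for x in (bl, ch, cl))
    inter = (bh - bl) - (ch - cl)
    return group_zmap(inter, "clarity_x_eventtype", alpha=alpha, m=m)


def network_epoch_timecourses(
    parcel: dict,
    events: EventSet,
    parcellation: Parcellation,
    event_type: str,
    schedule: Schedule | None = None,
    clarity_group: str | None = None,
    tr_s: float = 1.0,
) -> dict:
    """network -> DataFrame (subjects x 21 offsets) of mean epoch courses."""
    means = epoch_means(
        parcel, events, event_type, schedule=schedule,
        clarity_group=clarity_group, tr_s=tr_s,
    )
    subjects = list(means)
    nets: dict = {}
    for subject in subjects:
        per_net = network_average(means[subject], parcellation)
        for net in per_net.columns:
            nets.setdefault(net, []).append(per_net[net].to_numpy())
    offsets = EPOCH_WINDOW_S[0] + tr_s * np.arange(
        int(round((EPOCH_WINDOW_S[1] - EPOCH_WINDOW_S[0]) / tr_s)) + 1
    )
    return {
        net: pd.DataFrame(np.stack(v), index=subjects, columns=offsets)
        for net, v in nets.items()
    }


def network_timecourse_stats(
    courses_a: dict, courses_b: dict, q: float = 0.05
) -> pd.DataFrame:
    """Per-offset paired tests between two epoch conditions, FDR per network.

    ``courses_a``/``courses_b`` map network -> (subjects x 21) frames, e.g.
    boundary vs center.  Within each network the 21 offset-wise paired t
    tests are corrected with Benjamini–Hochberg across offsets.
    """
    rows = []
    for net in courses_a:
        a = courses_a[net]
        b = courses_b[net].reindex(index=a.index)
        ts, ps, zs, dfs = [], [], [], []
        for off in a.columns:
            t, df, z = paired_t_to_z(a[off].to_numpy(), b[off].to_numpy())
            p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
            ts.append(t); ps.append(p); zs.append(z); dfs.append(df)
        mask = fdr_bh(np.asarray(ps), q)
        for off, t, df, z, p, sig in zip(a.columns, ts, dfs, zs, ps, mask):
            rows.append((net, float(off), t, df, z, p, bool(sig)))
    return pd.DataFrame(
        rows, columns=["network", "offset_s", "t", "df", "z", "p", "significant"]
    )


def rm_anova_2x2(cells: pd.DataFrame) -> pd.DataFrame:
    """2x2 within-subject ANOVA on post-minus-pre contrasts.

    ``cells`` is tidy with columns (subject, event_type, clarity_group,
    value) covering both event types (boundary, center) and both clarity
    groups (high, low).  Subjects missing any of the four cells are
    excluded (logged).  Sums of squares follow the standard two-way
    repeated-measures decomposition; each effect is tested against its
    effect-by-subject interaction with df (1, n−1).  In this 2x2 design
    every F equals the squared paired t of the corresponding contrast.

    Returns a frame with rows ``event_type``, ``clarity``, ``interaction``
    and columns (effect, F, df1, df2, p).
    """
    need = {"subject", "event_type", "clarity_group", "value"}
    if not need <= set(cells.columns):
        raise InvalidInputError(f"cells must have columns {sorted(need)}")
    wide = cells.pivot_table(
        index="subject", columns=["event_type", "clarity_group"], values="value"
    )
    expected = [("boundary", "high"), ("boundary", "low"),
                ("center", "high"), ("center", "low")]
    missing_cols = [c for c in expected if c not in wide.columns]
    if missing_cols:
        raise InvalidInputError(f"missing cells: {missing_cols}")
    complete = wide[expected].dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("rmANOVA: excluded %d subjects with incomplete cells", dropped)
    n = len(complete)
    if n < 2:
        raise InvalidInputError("need at least 2 subjects with complete cells")
    y = complete.to_numpy(dtype=float).reshape(n, 2, 2)  # subj x event x clarity

    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a_mean = y.mean(axis=(0, 2))  # event_type marginals
    b_mean = y.mean(axis=(0, 1))  # clarity marginals
    ab_mean = y.mean(axis=0)      # cell means

    rows = []
    for effect, ss_eff, dev in (
        ("event_type", 2 * n * ((a_mean - grand) ** 2).sum(),
         y.mean(axis=2) - subj[:, None] - a_mean[None, :] + grand),
        ("clarity", 2 * n * ((b_mean - grand) ** 2).sum(),
         y.mean(axis=1) - subj[:, None] - b_mean[None, :] + grand),
        ("interaction",
         n * ((ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2).sum(),
         y - y.mean(axis=2)[:, :, None] - y.mean(axis=1)[:, None, :]
         + subj[:, None, None] - ab_mean[None, :, :]
         + a_mean[None, :, None] + b_mean[None, None, :] - grand),
    ):
        mult = 2 if effect != "interaction" else 1
        ss_err = mult * (dev ** 2).sum()
        df1, df2 = 1, n - 1
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = np.inf if ms_err == 0 and ms_eff > 0 else (
            0.0 if ms_eff == 0 else ms_eff / ms_err
        )
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append((effect, float(F), df1, df2, p))
    return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
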