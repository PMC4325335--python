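"""Session orchestration: localizer -> calibration -> main experiment.

Runs the two-part protocol for each site, streams the main run scan-by-scan
in lockstep across sites, exchanges calibrated activation levels and rewards
through the file platform at the configured trigger scans, applies the
task-specific reward rules (single / cooperation / competition) at each
block's feedback scan, and writes a per-block outcome ledger plus a session
summary.  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .analysis import (
    CalibrationProfile,
    calibrate,
    extract_roi,
    incremental_localizer,
    sliding_window_activation,
)
from .classification import ActivationEstimate, Band, estimate_block
from .edl_config import ExperimentConfig, OutputChannelSpec
from .exchange import ExchangeMessage, ExchangePlatform, exchange_due, read_messages, write_message
from .scanner import (
    BlockDesign,
    SubjectProfile,
    localizer_design,
    main_design,
    simulate_run,
    stream,
)

__all__ = [
    "TaskSpec",
    "EffortPolicy",
    "OutcomeRecord",
    "SessionLog",
    "SessionSummary",
    "reach_target",
    "score_single",
    "score_cooperation",
    "score_competition",
    "run_session",
    "group_amplitude_summary",
    "GroupAmplitudeSummary",
    "mean_of_maxima",
    "permutation_site_difference",
    "L_REFERENCE",
    "U_REFERENCE",
]

# Band reference points for the competition accuracy rule: the midpoint of
# the weak band [30, 60] and of the attainable strong band (60, 100].
L_REFERENCE = 45.0
U_REFERENCE = 80.0


@dataclass(frozen=True)
class TaskSpec:
    task: str  # "single" | "cooperation" | "competition"
    target_region: str  # "U" | "L"


@dataclass(frozen=True)
class EffortPolicy:
    """Simulated behaviour: maps the target region to an intended effort with
    Gaussian variability and an occasional attention lapse producing a
    near-zero effort.  A simulation device, not a model of any human cohort.
    """

    mean_by_region: tuple[tuple[str, float], ...] = (("L", 0.45), ("U", 0.80))
    sd: float = 0.10
    lapse_probability: float = 0.05
    lapse_mean: float = 0.05
    lapse_sd: float = 0.02

    def mean_for(self, region: str) -> float:
        for r, m in self.mean_by_region:
            if r == region:
                return m
        raise KeyError(region)

    def sample(self, target_region: str, rng: np.random.Generator) -> float:
        u = rng.uniform()
        e = rng.normal(self.mean_for(target_region), self.sd)
        lapse = rng.normal(self.lapse_mean, self.lapse_sd)
        if u < self.lapse_probability:
            e = lapse
        return float(np.clip(e, 0.0, 1.0))


def reach_target(estimate: ActivationEstimate, target_region: str) -> bool:
    """True iff the band matches the target region (insufficient never
    succeeds)."""
    if target_region == "U":
        return estimate.band is Band.STRONG_U
    if target_region == "L":
        return estimate.band is Band.WEAK_L
    raise ValueError(f"unknown target region {target_region!r}")


def score_single(
    a: ActivationEstimate, target_region: str
) -> tuple[bool, int]:
    """Independent task: reward 1 iff the subject reached the target."""
    ok = reach_target(a, target_region)
    return ok, int(ok)


def score_cooperation(
    a: ActivationEstimate, b: ActivationEstimate, target_region: str
) -> tuple[tuple[bool, int], tuple[bool, int]]:
    """Both rewarded iff both reached the target; otherwise neither."""
    both = reach_target(a, target_region) and reach_target(b, target_region)
    return (both, int(both)), (both, int(both))


def score_competition(
    a: ActivationEstimate,
    b: ActivationEstimate,
    target_region: str,
    tie_tolerance: float = 0.01,
) -> tuple[tuple[bool, int], tuple[bool, int]]:
    """The partner who reached the requested position most accurately wins.

    Accuracy = |relative percent - band reference| (45 for L, 80 for U),
    evaluated only among partners whose band matches the target; if neither
    matches, no reward.  Accuracies within ``tie_tolerance`` percentage
    points of each other count as a tie and reward both — 0.01% of the
    individual maximum is far below both display resolution and any noise
    floor, so only genuinely indistinguishable performances tie.
    """
    ref = U_REFERENCE if target_region == "U" else L_REFERENCE
    ok_a = reach_target(a, target_region)
    ok_b = reach_target(b, target_region)
    if not ok_a and not ok_b:
        return (False, 0), (False, 0)
    if ok_a and not ok_b:
        return (True, 1), (False, 0)
    if ok_b and not ok_a:
        return (False, 0), (True, 1)
    da, db = abs(a.relative_percent - ref), abs(b.relative_percent - ref)
    if da < db - tie_tolerance:
        return (True, 1), (False, 0)
    if db < da - tie_tolerance:
        return (False, 0), (True, 1)
    return (True, 1), (True, 1)


@dataclass
class OutcomeRecord:
    block_index: int
    task: str
    target_region: str
    estimates: dict[str, ActivationEstimate | None]
    success: dict[str, bool]
    reward_delta: dict[str, int]
    cumulative_reward: dict[str, int]
    flags: tuple[str, ...] = ()


@dataclass
class SessionLog:
    records: list[OutcomeRecord]
    site_ids: tuple[str, ...]
    schedule: BlockDesign
    profiles: dict[str, CalibrationProfile]

    TSV_FLOAT = "{:.6f}"

    def to_tsv(self, path: str) -> None:
        cols = ["block", "task", "target"]
        for s in self.site_ids:
            cols += [
                f"raw_{s}", f"relative_{s}", f"band_{s}",
                f"success_{s}", f"reward_{s}", f"cumreward_{s}",
            ]
        cols.append("flags")
        lines = ["\t".join(cols)]
        for rec in self.records:
            row = [str(rec.block_index), rec.task, rec.target_region]
            for s in self.site_ids:
                est = rec.estimates.get(s)
                if est is None:
                    row += ["NA", "NA", "NA"]
                else:
                    row += [
                        self.TSV_FLOAT.format(est.raw_response_percent),
                        self.TSV_FLOAT.format(est.relative_percent),
                        est.band.value,
                    ]
                row += [
                    str(int(rec.success.get(s, False))),
                    str(rec.reward_delta.get(s, 0)),
                    str(rec.cumulative_reward.get(s, 0)),
                ]
            row.append(",".join(rec.flags) if rec.flags else "-")
            lines.append("\t".join(row))
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class SessionSummary:
    """Per-site and per-task success percentages plus a permutation test on
    the between-site success difference."""

    per_site_task_percent: dict[str, dict[str, float]]
    per_site_percent: dict[str, float]
    overall_percent: float
    site_difference_percent: float | None
    permutation_p_value: float | None
    n_blocks: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_site_task_percent": self.per_site_task_percent,
                    "per_site_percent": self.per_site_percent,
                    "overall_percent": self.overall_percent,
                    "site_difference_percent": self.site_difference_percent,
                    "permutation_p_value": self.permutation_p_value,
                    "n_blocks": self.n_blocks,
                },
                fh,
                indent=1,
            )


def permutation_site_difference(
    success_a: Sequence[bool],
    success_b: Sequence[bool],
    n_permutations: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided paired permutation test on the difference in success
    percentage between two sites (block-wise site-label swaps).

    Returns (observed difference in percentage points, p-value).
    """
    a = np.asarray(success_a, dtype=float)
    b = np.asarray(success_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired success vectors required")
    diff = a - b
    obs = diff.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, diff.size))
    perm = (signs * diff).mean(axis=1)
    p = float((np.abs(perm) >= abs(obs) - 1e-12).mean())
    return float(100.0 * obs), p


def summarize(
    records: list[OutcomeRecord],
    site_ids: tuple[str, ...],
    tasks: tuple[str, ...],
    permutation_seed: int = 0,
) -> SessionSummary:
    per_site_task: dict[str, dict[str, float]] = {}
    per_site: dict[str, float] = {}
    for s in site_ids:
        per_site_task[s] = {}
        for t in tasks:
            recs = [r for r in records if r.task == t]
            if recs:
                per_site_task[s][t] = 100.0 * np.mean([r.success[s] for r in recs])
        per_site[s] = 100.0 * np.mean([r.success[s] for r in records])
    overall = 100.0 * np.mean(
        [r.success[s] for r in records for s in site_ids]
    )
    diff = p = None
    if len(site_ids) == 2:
        a, b = site_ids
        diff, p = permutation_site_difference(
            [r.success[a] for r in records],
            [r.success[b] for r in records],
            seed=permutation_seed,
        )
    return SessionSummary(
        per_site_task_percent=per_site_task,
        per_site_percent=per_site,
        overall_percent=float(overall),
        site_difference_percent=diff,
        permutation_p_value=p,
        n_blocks=len(records),
    )


# ---------------------------------------------------------------------------
# group amplitude comparison


@dataclass(frozen=True)
class GroupAmplitudeSummary:
    amplitudes: tuple[tuple[str, float], ...]
    percent_increase: float  # of the second group over the first


def _group_amplitude(value) -> float:
    if np.isscalar(value):
        return float(value)  # already the max of the group-mean curve
    curves = [np.asarray(c, dtype=float) for c in value]
    if not curves:
        raise ValueError("empty group")
    return float(np.mean(curves, axis=0).max())


def group_amplitude_summary(groups: Mapping[str, object]) -> GroupAmplitudeSummary:
    """Group-level amplitude comparison.

    Each group is either a sequence of per-subject localizer response curves
    (averaged across subjects before taking the maximum) or a precomputed
    maximum amplitude of the group-mean curve.  Reports the percent increase
    of the second group over the first (e.g. 7T over 3T).
    """
    names = list(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    amps = tuple((name, _group_amplitude(groups[name])) for name in names)
    a1, a2 = amps[0][1], amps[1][1]
    if a1 <= 0:
        raise ValueError("reference group amplitude must be positive")
    return GroupAmplitudeSummary(
        amplitudes=amps, percent_increase=float(100.0 * (a2 - a1) / a1)
    )


def mean_of_maxima(curves_or_maxima: Sequence) -> float:
    """Mean of per-subject maxima — a *different* summary from the maximum of
    the group-mean curve (per-subject peaks at different latencies do not
    align), kept for documentation and comparison."""
    vals = [
        float(np.max(c)) if not np.isscalar(c) else float(c)
        for c in curves_or_maxima
    ]
    if not vals:
        raise ValueError("empty group")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# full session


def _channel_for(
    channels: Sequence[OutputChannelSpec], site_id: str
) -> OutputChannelSpec | None:
    for ch in channels:
        if ch.site_id == site_id and ch.state:
            return ch
    return None


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_session(
    config: ExperimentConfig,
    subjects: Mapping[str, SubjectProfile],
    policies: Mapping[str, EffortPolicy] | None = None,
    seed: int = 0,
    exchange_root: str = "exchange",
    log_dir: str | None = None,
    calibration_method: str = "window",
    fwhm_mm: float = 3.0,
    r_threshold: float = 0.6,
    min_cluster_voxels: int = 5,
    shared_behavior_seed: bool = False,
    clock_start: str = "2000-01-01T00:00:00",
    profiles: Mapping[str, CalibrationProfile] | None = None,
) -> tuple[SessionLog, SessionSummary]:
    """Execute the full two-part experiment for every configured site.

    Per site: simulate and analyse the functional localizer, extract the
    reference ROI, calibrate the individual maximum; then run the shared
    randomised main schedule, streaming scans in lockstep, exchanging
    activation levels and cumulative rewards at the trigger scans, and
    scoring each block with the task-appropriate reward rule.  Pre-computed
    ``profiles`` skip the localizer stage.  ``shared_behavior_seed`` gives
    every site the same behavioural random stream (for paired comparisons of
    sites that differ only in signal amplitude).
    """
    site_ids = tuple(s.site_id for s in config.sites)
    for sid in site_ids:
        if sid not in subjects:
            raise KeyError(f"no subject profile for site {sid!r}")
    if policies is None:
        policies = {sid: EffortPolicy() for sid in site_ids}

    ss = np.random.SeedSequence(seed)
    sched_ss, perm_ss, shared_beh_ss, *site_ss = ss.spawn(3 + len(site_ids))
    schedule = main_design(config, _derive_seed(sched_ss))
    site_children = {
        sid: dict(zip(("loc", "beh", "main"), site_seed.spawn(3)))
        for sid, site_seed in zip(site_ids, site_ss)
    }
    shared_beh_seed = _derive_seed(shared_beh_ss)

    # --- part 1: localizer + calibration -------------------------------
    cal: dict[str, CalibrationProfile] = {}
    loc_design = localizer_design()
    for sid in site_ids:
        if profiles is not None and sid in profiles:
            cal[sid] = profiles[sid]
            continue
        site = config.site(sid)
        series = simulate_run(
            loc_design,
            subjects[sid],
            site,
            np.ones(loc_design.n_blocks),
            seed=_derive_seed(site_children[sid]["loc"]),
        )
        amap = incremental_localizer(stream(series), loc_design, fwhm_mm=fwhm_mm)
        roi = extract_roi(amap, r_threshold, min_cluster_voxels)
        cal[sid] = calibrate(
            series, roi, loc_design, subject_id=subjects[sid].subject_id,
            method=calibration_method,
        )

    # --- part 2: main experiment ---------------------------------------
    main_seeds = {sid: _derive_seed(site_children[sid]["main"]) for sid in site_ids}
    behavior_rngs = {
        sid: np.random.default_rng(
            shared_beh_seed if shared_behavior_seed
            else _derive_seed(site_children[sid]["beh"])
        )
        for sid in site_ids
    }

    efforts = {
        sid: np.asarray(
            [
                policies[sid].sample(block.target_region, behavior_rngs[sid])
                for block in schedule.blocks
            ]
        )
        for sid in site_ids
    }
    runs = {
        sid: simulate_run(
            schedule, subjects[sid], config.site(sid), efforts[sid],
            seed=main_seeds[sid],
        )
        for sid in site_ids
    }

    platform = ExchangePlatform(root=exchange_root)
    out_ch = {sid: _channel_for(config.output_channels, sid) for sid in site_ids}
    rcv_ch = {sid: _channel_for(config.receive_channels, sid) for sid in site_ids}
    for sid in site_ids:  # fresh files per session
        ch = out_ch[sid]
        if ch is not None:
            path = platform.path_for(ch)
            open(path, "w").close()
    cursors = {sid: 0 for sid in site_ids}

    traces = {sid: [] for sid in site_ids}
    estimates: dict[str, dict[int, ActivationEstimate]] = {sid: {} for sid in site_ids}
    partner_level: dict[str, dict[int, float]] = {sid: {} for sid in site_ids}
    cumulative = {sid: 0 for sid in site_ids}
    records: list[OutcomeRecord] = []

    t0 = _dt.datetime.fromisoformat(clock_start)
    tr = config.sites[0].tr_seconds
    streams = {sid: iter(stream(runs[sid])) for sid in site_ids}
    scale = {sid: config.visualization.scale_for(sid) for sid in site_ids}

    for s in range(1, schedule.n_scans + 1):
        block, local = schedule.block_of_scan(s)
        stamp = (t0 + _dt.timedelta(seconds=(s - 1) * tr)).isoformat()

        for sid in site_ids:
            _, vol = next(streams[sid])
            traces[sid].append(float(vol[cal[sid].roi.mask].mean()))

            if local == schedule.response_window[1]:
                raw = sliding_window_activation(
                    np.asarray(traces[sid]), schedule, block
                )
                est = estimate_block(block, scale[sid] * raw, cal[sid])
                estimates[sid][block] = est

            ch = out_ch[sid]
            if ch is not None and exchange_due(local, ch) and block in estimates[sid]:
                est = estimates[sid][block]
                payload = []
                for key in ch.output_params:
                    if key == "actlevel":
                        payload.append((key, est.relative_percent))
                    elif key == "reward_human":
                        payload.append((key, cumulative[sid]))
                    elif key == "template_label":
                        payload.append((key, est.band.value))
                write_message(
                    platform,
                    ch,
                    ExchangeMessage(
                        site_id=sid,
                        block_index=block,
                        scan_index=local,
                        payload=tuple(payload),
                        timestamp=stamp,
                    ),
                )

        # poll after all sites transmitted this scan (reader never gets
        # a partner's scan-k message before scan k)
        for sid in site_ids:
            ch = rcv_ch[sid]
            if ch is None:
                continue
            result = read_messages(platform, ch, cursors[sid])
            cursors[sid] = result.cursor
            for msg in result.messages:
                for key, value in msg.payload:
                    if key == "actlevel":
                        partner_level[sid][msg.block_index] = float(value)

        if local == schedule.scans_per_block:
            records.append(
                _score_block(
                    schedule, block, site_ids, estimates, partner_level, cumulative
                )
            )

    log = SessionLog(records=records, site_ids=site_ids, schedule=schedule, profiles=cal)
    summary = summarize(
        records, site_ids, config.schedule_params.tasks,
        permutation_seed=_derive_seed(perm_ss),
    )
    if log_dir is not None:
        os.makedirs(log_dir, exist_ok=True)
        log.to_tsv(os.path.join(log_dir, "session_log.tsv"))
        summary.to_json(os.path.join(log_dir, "session_summary.json"))
        for sid, profile in cal.items():
            profile.to_json(os.path.join(log_dir, f"profile_{sid}.json"))
    return log, summary


def _score_block(
    schedule: BlockDesign,
    block: int,
    site_ids: tuple[str, ...],
    estimates: dict[str, dict[int, ActivationEstimate]],
    partner_level: dict[str, dict[int, float]],
    cumulative: dict[str, int],
) -> OutcomeRecord:
    blk = schedule.blocks[block - 1]
    task, target = blk.task, blk.target_region
    ests = {sid: estimates[sid].get(block) for sid in site_ids}
    success = {sid: False for sid in site_ids}
    delta = {sid: 0 for sid in site_ids}
    flags: list[str] = []

    if task == "single":
        for sid in site_ids:
            if ests[sid] is not None:
                success[sid], delta[sid] = score_single(ests[sid], target)
    elif task in ("cooperation", "competition"):
        if len(site_ids) != 2:
            raise ValueError(f"{task} task requires exactly two sites")
        a_id, b_id = site_ids
        a, b = ests[a_id], ests[b_id]
        # scoring uses the exchanged level; absence at feedback time is a
        # timeout and the block fails for both partners
        a_seen = a is not None and block in partner_level[b_id]
        b_seen = b is not None and block in partner_level[a_id]
        if not (a_seen and b_seen):
            flags.append("timeout")
        else:
            scorer = score_cooperation if task == "cooperation" else score_competition
            (sa, ra), (sb, rb) = scorer(a, b, target)
            success[a_id], delta[a_id] = sa, ra
            success[b_id], delta[b_id] = sb, rb
    else:
        raise ValueError(f"unknown task {task!r}")

    for sid in site_ids:
        cumulative[sid] += delta[sid]
    return OutcomeRecord(
        block_index=block,
        task=task,
        target_region=target,
        estimates=ests,
        success=success,
        reward_delta=delta,
        cumulative_reward=dict(cumulative),
        flags=tuple(flags),
    )
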