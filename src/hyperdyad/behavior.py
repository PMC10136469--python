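"""Behavioral stage: response-time cleaning, the dyadic DRT competition
statistic, and the group x block ANCOVA.

Cleaning is two-stage, per participant: response times above 1500 ms
are removed first, then times lying strictly outside mean +/- 3 SD of
that participant's remaining distribution.  DRT for a dyad and block is
the mean over retained trials of the absolute RT difference between the
two members; a trial contributes only when both members' times
survived, so a smaller DRT means the members were more evenly matched
(more intense competition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import BehavioralTrials
from .stats import FTable, mixed_ancova, simple_effects

__all__ = ["CleanRTSet", "DRTTable", "clean_rts", "compute_drt",
           "behavior_test", "cohort_drt"]

RT_CAP_MS = 1500.0


@dataclass
class CleanRTSet:
    dyad_id: str
    block_index: np.ndarray
    trial_index: np.ndarray
    rt_ms_member1: np.ndarray
    rt_ms_member2: np.ndarray
    keep: np.ndarray              # trial retained for DRT (both members clean)
    n_removed_cap: tuple          # (member1, member2)
    n_removed_sd: tuple
    flagged_blocks: tuple         # blocks with < 2 surviving paired trials


def _member_keep(rt: np.ndarray):
    cap_keep = rt <= RT_CAP_MS
    survivors = rt[cap_keep]
    n_cap = int((~cap_keep).sum())
    if survivors.size == 0:
        return cap_keep, n_cap, 0
    mean, sd = survivors.mean(), survivors.std(ddof=0)
    # strict inequality: values exactly at mean +/- 3 SD are retained
    sd_keep = np.abs(rt - mean) <= 3 * sd
    keep = cap_keep & sd_keep
    return keep, n_cap, int((cap_keep & ~sd_keep).sum())


def clean_rts(trials: BehavioralTrials) -> CleanRTSet:
    """Two-stage RT cleaning; a trial is dropped from DRT when either
    member's RT was removed.  Idempotent: cleaning a cleaned set removes
    nothing further only in the sense that re-running on the retained
    trials keeps them all (the SD fence is computed once, not
    iterated)."""
    k1, cap1, sd1 = _member_keep(trials.rt_ms_member1)
    k2, cap2, sd2 = _member_keep(trials.rt_ms_member2)
    keep = k1 & k2
    flagged = tuple(b for b in (1, 2)
                    if (keep & (trials.block_index == b)).sum() < 2
                    and (trials.block_index == b).any())
    return CleanRTSet(trials.dyad_id, trials.block_index, trials.trial_index,
                      trials.rt_ms_member1, trials.rt_ms_member2, keep,
                      (cap1, cap2), (sd1, sd2), flagged)


@dataclass
class DRTTable:
    table: pd.DataFrame   # columns dyad_id, group, block, drt_ms


def compute_drt(clean: CleanRTSet, group: str) -> pd.DataFrame:
    """Per-block DRT = mean |RT1 - RT2| over retained trials; blocks
    with no retained trials get NaN (reported, dropped downstream)."""
    rows = []
    for b in sorted(set(clean.block_index.tolist())):
        sel = clean.keep & (clean.block_index == b)
        if b in clean.flagged_blocks or not sel.any():
            drt = np.nan
        else:
            drt = float(np.mean(np.abs(clean.rt_ms_member1[sel]
                                       - clean.rt_ms_member2[sel])))
        rows.append((clean.dyad_id, group, b, drt))
    return pd.DataFrame(rows, columns=["dyad_id", "group", "block", "drt_ms"])


def cohort_drt(sessions) -> DRTTable:
    frames = [compute_drt(clean_rts(s.behavior), s.group) for s in sessions]
    return DRTTable(pd.concat(frames, ignore_index=True))


def behavior_test(drt: DRTTable, covariates: pd.DataFrame | None = None,
                  covariate_names: tuple[str, ...] = ()):
    """Group x block mixed ANCOVA on DRT plus simple effects.

    ``covariates`` is a per-dyad frame indexed by dyad_id; only
    ``covariate_names`` columns are adjusted for.  Returns
    (FTable, simple-effects DataFrame).
    """
    tbl = drt.table.rename(columns={"dyad_id": "unit"}).dropna(subset=["drt_ms"])
    counts = tbl.groupby("group")["unit"].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need at least 2 dyads per group")
    if covariate_names:
        if covariates is None:
            raise ValueError("covariate_names given without a covariate table")
        tbl = tbl.join(covariates[list(covariate_names)], on="unit")
    ftab = mixed_ancova(tbl, "drt_ms", "group", "block", "unit", covariate_names)
    simple = simple_effects(tbl, "drt_ms", "group", "block", "unit")
    return ftab, simple
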