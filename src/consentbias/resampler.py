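"""Reference ensembles from the participating group.

Two kinds of size-matched reference subsamples are drawn from the
participating group, each resampled over m runs:

* bootstrap groups — uniform random subsets without replacement, the null
  reference for subsample-to-subsample variability;
* PSM groups — greedy 1:1 nearest-neighbour matches (without replacement) to
  the not-participating dyads on the logit of the propensity score, i.e.
  participants whose pre-consent interaction patterns resembled those of the
  dyads that refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .data_model import DyadRecord, ParticipationStatus, records_to_frame
from .util import as_rng, child_rng, child_seed_int

BOOTSTRAP = "bootstrap"
PSM = "psm"


class MatchingExhaustedError(RuntimeError):
    """No admissible match candidate remains for a not-participating dyad."""


@dataclass
class SubsampleRun:
    run_index: int
    seed: int
    kind: str
    member_ids: list[str]
    mean_abs_distance: float | None = None  # logit-propensity scale, PSM only

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("subsample member_ids must be distinct")


def _participating_ids(participating: Sequence[DyadRecord] | pd.DataFrame) -> list[str]:
    if isinstance(participating, pd.DataFrame):
        frame = participating
        if "status" in frame.columns:
            frame = frame[frame["status"] == ParticipationStatus.TESTED.value]
        return frame["dyad_id"].astype(str).tolist()
    for r in participating:
        if r.status is not ParticipationStatus.TESTED:
            raise ValueError(f"dyad {r.dyad_id!r} is not tested; subsamples draw from the participating group")
    return [r.dyad_id for r in participating]


def bootstrap_groups(
    participating: Sequence[DyadRecord] | pd.DataFrame,
    group_size: int,
    m: int,
    master_seed: int,
) -> list[SubsampleRun]:
    """m uniform random subsets (without replacement) of the stated size."""
    ids = np.asarray(_participating_ids(participating), dtype=object)
    if group_size > ids.size:
        raise ValueError(f"group_size {group_size} exceeds participating count {ids.size}")
    if m < 1:
        raise ValueError(f"number of runs must be >= 1, got {m}")
    runs = []
    for k in range(1, m + 1):
        rng = child_rng(master_seed, k)
        members = rng.choice(ids, size=group_size, replace=False)
        runs.append(
            SubsampleRun(
                run_index=k, seed=child_seed_int(master_seed, k),
                kind=BOOTSTRAP, member_ids=[str(x) for x in members],
            )
        )
    return runs


def psm_match(
    participating: Sequence[DyadRecord] | pd.DataFrame,
    not_participating: Sequence[DyadRecord] | pd.DataFrame,
    scores: pd.Series,
    rng: int | np.random.Generator,
    caliper: float | None = None,
    run_index: int = 1,
    seed: int = -1,
) -> SubsampleRun:
    """One greedy 1:1 nearest-neighbour match on logit propensity.

    Not-participating dyads are processed in random order; each takes the
    closest still-unmatched participant (distance ties broken by the rng).
    ``caliper`` is a maximum distance in units of the SD of all logit scores;
    with a caliper an exhausted match is an error, never a smaller group.
    """
    rng = as_rng(rng)
    part_ids = _participating_ids(participating)
    if isinstance(not_participating, pd.DataFrame):
        np_ids = not_participating["dyad_id"].astype(str).tolist()
    else:
        np_ids = [r.dyad_id for r in not_participating]
    if len(np_ids) > len(part_ids):
        raise MatchingExhaustedError(
            f"cannot 1:1 match {len(np_ids)} not-participating dyads from {len(part_ids)} participants"
        )

    def logit_of(ids: list[str]) -> np.ndarray:
        s = scores.reindex(ids).to_numpy(dtype=float)
        if np.any(~np.isfinite(s)) or np.any(s <= 0) or np.any(s >= 1):
            missing = [i for i, v in zip(ids, s) if not np.isfinite(v) or v <= 0 or v >= 1]
            raise ValueError(f"propensity scores missing or degenerate for dyads: {missing}")
        return special.logit(s)

    lp = logit_of(part_ids)
    lnp = logit_of(np_ids)
    if caliper is not None:
        all_logits = np.concatenate([lp, lnp])
        max_dist = caliper * all_logits.std(ddof=1)

    available = np.ones(len(part_ids), dtype=bool)
    matched: dict[int, str] = {}
    distances = []
    order = rng.permutation(len(np_ids))
    for i in order:
        d = np.abs(lp - lnp[i])
        d = np.where(available, d, np.inf)
        best = d.min()
        if not np.isfinite(best) or (caliper is not None and best > max_dist):
            raise MatchingExhaustedError(
                f"no admissible match for dyad {np_ids[i]!r}"
                + (f" within caliper {caliper}" if caliper is not None else "")
            )
        ties = np.flatnonzero(d <= best + 1e-12)
        j = int(rng.choice(ties))
        available[j] = False
        matched[i] = part_ids[j]
        distances.append(best)
    member_ids = [matched[i] for i in range(len(np_ids))]
    return SubsampleRun(
        run_index=run_index, seed=seed, kind=PSM, member_ids=member_ids,
        mean_abs_distance=float(np.mean(distances)),
    )


def psm_ensemble(
    participating: Sequence[DyadRecord] | pd.DataFrame,
    not_participating: Sequence[DyadRecord] | pd.DataFrame,
    scores: pd.Series,
    m: int,
    master_seed: int,
    caliper: float | None = None,
) -> list[SubsampleRun]:
    """m PSM runs differing in processing order and tie-breaks."""
    if m < 1:
        raise ValueError(f"number of runs must be >= 1, got {m}")
    return [
        psm_match(
            participating, not_participating, scores, child_rng(master_seed, k),
            caliper=caliper, run_index=k, seed=child_seed_int(master_seed, k),
        )
        for k in range(1, m + 1)
    ]


def subsample_values(
    runs: Sequence[SubsampleRun],
    empirical: pd.DataFrame,
    measurements: Sequence[str],
) -> np.ndarray:
    """Member-level outcome values per run as an (m, size, n_meas) array."""
    table = empirical.set_index(empirical["dyad_id"].astype(str))[list(measurements)]
    return np.stack([table.loc[r.member_ids].to_numpy(dtype=float) for r in runs])


def runs_to_long(runs: Sequence[SubsampleRun]) -> pd.DataFrame:
    """Long-format (run_index, kind, dyad_id) membership table."""
    rows = [
        {"run_index": r.run_index, "kind": r.kind, "dyad_id": d}
        for r in runs
        for d in r.member_ids
    ]
    return pd.DataFrame(rows, columns=["run_index", "kind", "dyad_id"])


def long_to_runs(long: pd.DataFrame, kind: str) -> list[SubsampleRun]:
    sel = long[long["kind"] == kind]
    return [
        SubsampleRun(run_index=int(k), seed=-1, kind=kind, member_ids=chunk["dyad_id"].astype(str).tolist())
        for k, chunk in sel.groupby("run_index", sort=True)
    ]
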