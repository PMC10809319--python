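"""Refinement/validation of representative binding configurations.

From each representative pose r_k, restraint-free canonical simulations are
run at room and elevated temperature (parallel replicas).  Stability is
scored by the R-value against r_k's own contact set over the final window
of each replica, pooled across replicas; a pose whose contacts survive high
temperature is a strong binding-configuration candidate, while surface
poses degrade.  The refined structure q_k is the final-window room-
temperature frame that best preserves r_k's contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .engine import SamplingSchedule, Snapshot, run_canonical
from .errors import InputError, IntegrationError, McdockError
from .metrics import ContactSet, contact_set, r_value, r_value_trace

logger = logging.getLogger(__name__)


@dataclass
class ValidationEntry:
    """Validation result for one representative pose."""

    label: str
    r_k: Snapshot
    q_k: Snapshot | None
    stats: dict  # T -> (mean R, population SD)
    n_replicas: int
    window_frames: int
    reference_contacts: ContactSet
    failures: list = field(default_factory=list)  # (T, replica, message)


@dataclass
class ValidationReport:
    entries: list

    def to_records(self):
        recs = []
        for e in self.entries:
            rec = {"label": e.label, "n_replicas": e.n_replicas,
                   "window_frames": e.window_frames}
            for T in sorted(e.stats):
                mean, sd = e.stats[T]
                rec[f"R_mean_{int(T)}K"] = mean
                rec[f"R_sd_{int(T)}K"] = sd
            recs.append(rec)
        return recs


def validate_representative(
    system,
    r_k: Snapshot,
    receptor_selection,
    ligand_selection,
    T_list=(300.0, 400.0),
    n_replicas: int = 10,
    length: int = 50_000,
    window: float = 0.4,
    seed: int = 0,
    cutoff: float = 4.5,
    stride: int = 100,
    label: str = "r",
    step_width: float = 0.3,
) -> ValidationEntry:
    """Run the validation protocol for one representative pose.

    ``window`` is the final fraction of each replica used for statistics
    (0.4 mirrors scoring the final stretch of each run).  Replica j at the
    i-th temperature is seeded with seed + 7919·i + j.  Restraints are off.
    Per-replica integration failures are recorded and skipped; the entry
    fails only if every replica of a temperature failed.
    """
    if n_replicas < 1:
        raise InputError("n_replicas must be >= 1")
    if not 0 < window <= 1:
        raise InputError("window must be a fraction in (0, 1]")
    reference = contact_set(r_k, receptor_selection, ligand_selection, cutoff)
    stats = {}
    failures = []
    room_T = min(T_list)
    room_trajs = []
    for i, T in enumerate(T_list):
        trajs = []
        for j in range(n_replicas):
            sched = SamplingSchedule(
                n_trajectories=1,
                prerun_steps=1,
                production_steps=length,
                bias_update_iterations=1,
                snapshot_stride=stride,
                seed=(seed + 7919 * i + j) & 0x7FFFFFFF,
                step_width=step_width,
            )
            try:
                traj = run_canonical(system, T, sched, start=r_k, restraints_on=False)
            except IntegrationError as exc:
                failures.append((T, j, str(exc)))
                logger.warning("replica %d at %g K failed: %s", j, T, exc)
                continue
            trajs.append(traj)
        if not trajs:
            raise McdockError(f"all {n_replicas} replicas failed at {T} K")
        win = max(1, int(round(window * len(trajs[0]))))
        mean, sd, _ = r_value_trace(
            trajs, reference, receptor_selection, ligand_selection, win, cutoff
        )
        stats[float(T)] = (mean, sd)
        if T == room_T:
            room_trajs = trajs
            room_window = win
    q_k = refine_structure(
        room_trajs, reference, receptor_selection, ligand_selection,
        room_window, cutoff,
    )
    return ValidationEntry(
        label=label,
        r_k=r_k,
        q_k=q_k,
        stats=stats,
        n_replicas=n_replicas,
        window_frames=room_window,
        reference_contacts=reference,
        failures=failures,
    )


def refine_structure(
    room_trajectories,
    reference: ContactSet,
    receptor_selection,
    ligand_selection,
    window: int,
    cutoff: float = 4.5,
) -> Snapshot:
    """Refined structure q_k: the final-window room-T frame with maximal
    R-value versus the representative; ties go to the lowest (replica,
    frame) pair."""
    if not room_trajectories:
        raise InputError("refinement needs at least one successful replica")
    best = None
    best_key = None
    for rep_idx, traj in enumerate(room_trajectories):
        if window > len(traj):
            raise InputError("window longer than trajectory")
        offset = len(traj) - window
        for f_idx, snap in enumerate(traj[-window:]):
            obs = contact_set(snap, receptor_selection, ligand_selection, cutoff)
            r = r_value(obs, reference)
            key = (-r, rep_idx, offset + f_idx)
            if best_key is None or key < best_key:
                best_key = key
                best = snap
    return best


def stability_ranking(report: ValidationReport) -> list:
    """Entries ordered by (high-T mean R, then room-T mean R), descending.

    The most stable pose — the one whose contacts survive thermal stress —
    comes first.
    """
    if not report.entries:
        return []
    entries = report.entries
    t_high = max(max(e.stats) for e in entries)
    t_room = min(min(e.stats) for e in entries)
    return sorted(
        entries,
        key=lambda e: (
            -e.stats.get(t_high, (-np.inf,))[0],
            -e.stats.get(t_room, (-np.inf,))[0],
            e.label,
        ),
    )
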