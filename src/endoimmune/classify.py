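"""Attachment-state classification and per-cycle response metrics.

A trajectory is classified by the behaviour of the attached-cell
compartment EA relative to a threshold ``epsilon`` (default 1 cell·ml⁻¹),
after discarding an initial transient of ``tau`` days:

* ``low`` — EA stays at or below the threshold at all post-transient times;
* ``transient`` — EA exceeds the threshold within a cycle but returns to at
  most the threshold at every cycle boundary (low/no disease);
* ``sustained`` — EA exceeds the threshold at every post-transient cycle
  boundary (diseased).

Both exceedance tests use strict inequalities, so EA identically equal to
the threshold is ``low``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model_core import macrophage_fractions
from .simulate import Trajectory

__all__ = [
    "AttachmentReport",
    "CycleMetrics",
    "DEFAULT_EPSILON",
    "end_of_cycle_values",
    "classify_attachment",
    "cycle_metrics",
]

DEFAULT_EPSILON = 1.0   # cells/ml
DEFAULT_TAU = 140.0     # days (5 cycles)


@dataclass
class CycleMetrics:
    """Summary of one menstrual cycle (cycle index ``k`` ends at
    ``t = k * cycle_length``)."""

    k: int
    end_EA: float
    peak_EA: float
    peak_EF: float
    mean_M1_frac: float
    mean_M2_frac: float
    mean_KA: float
    end_M1_frac: float
    end_M2_frac: float
    end_KA: float


@dataclass
class AttachmentReport:
    label: str                      # low | transient | sustained
    epsilon: float
    tau: float
    peak_EA: float                  # max over post-tau cycles
    end_EA: float                   # at the final cycle boundary
    per_cycle: list[CycleMetrics] = field(default_factory=list)
    non_converged: bool = False     # mixed end-of-cycle exceedance post-tau

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def per_cycle_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(c) for c in self.per_cycle])


def _cycle_boundaries(traj: Trajectory, tau: float) -> np.ndarray:
    """Cycle indices k with tau < 28k <= t_end."""
    L = traj.cycle_length
    t_end = traj.times[-1]
    k_min = int(np.floor(tau / L)) + 1
    k_max = int(np.floor(t_end / L + 1e-9))
    if k_max < k_min:
        raise ValueError(
            f"trajectory (t_end={t_end}) has no cycle boundary beyond tau={tau}"
        )
    return np.arange(k_min, k_max + 1)


def end_of_cycle_values(traj: Trajectory, tau: float = 0.0) -> list[tuple[int, float]]:
    """EA evaluated at the exact cycle boundaries ``t = k * cycle_length``
    past the transient, via dense interpolation."""
    ks = _cycle_boundaries(traj, tau)
    L = traj.cycle_length
    vals = traj.at(ks * L)
    vals = np.atleast_2d(vals)
    iEA = 7
    return [(int(k), float(v[iEA])) for k, v in zip(ks, vals)]


def classify_attachment(
    traj: Trajectory,
    epsilon: float = DEFAULT_EPSILON,
    tau: float = DEFAULT_TAU,
) -> AttachmentReport:
    """Classify a trajectory into low / transient / sustained attachment."""
    eoc = end_of_cycle_values(traj, tau)
    if len(eoc) < 2:
        raise ValueError("need at least 2 post-transient cycles to classify")
    ends = np.array([v for _, v in eoc])

    mask = traj.times > tau
    peak_EA = float(traj.column("EA")[mask].max())

    above = ends > epsilon
    non_converged = bool(above.any() and not above.all())
    if above.all():
        label = "sustained"
    elif non_converged:
        # straddling case: judge by the final cycle, flag as non-converged
        label = "sustained" if above[-1] else ("transient" if peak_EA > epsilon else "low")
    elif peak_EA > epsilon:
        label = "transient"
    else:
        label = "low"

    report = AttachmentReport(
        label=label,
        epsilon=epsilon,
        tau=tau,
        peak_EA=peak_EA,
        end_EA=float(ends[-1]),
        per_cycle=cycle_metrics(traj, tau),
        non_converged=non_converged,
    )
    return report


def cycle_metrics(traj: Trajectory, tau: float = DEFAULT_TAU) -> list[CycleMetrics]:
    """Per-cycle response metrics past the transient: end-of-cycle and peak
    EA/EF, and time-averaged / end-of-cycle macrophage activation fractions
    and activated-NK concentration."""
    ks = _cycle_boundaries(traj, tau)
    L = traj.cycle_length
    out: list[CycleMetrics] = []
    t = traj.times
    EA = traj.column("EA")
    EF = traj.column("EF")
    KA = traj.column("KA")
    M = traj.states[:, :3]
    Mtot = M.sum(axis=1)
    if np.any(Mtot <= 0):
        raise ValueError("zero total macrophages in trajectory sample")
    M1f = M[:, 1] / Mtot
    M2f = M[:, 2] / Mtot

    for k in ks:
        t0, t1 = (k - 1) * L, k * L
        sel = (t >= t0) & (t <= t1)
        end = traj.at(t1)
        end_tot = end[0] + end[1] + end[2]
        m1e, m2e = macrophage_fractions(end)
        out.append(
            CycleMetrics(
                k=int(k),
                end_EA=float(end[7]),
                peak_EA=float(EA[sel].max()),
                peak_EF=float(EF[sel].max()),
                mean_M1_frac=float(np.trapezoid(M1f[sel], t[sel]) / (t[sel][-1] - t[sel][0])),
                mean_M2_frac=float(np.trapezoid(M2f[sel], t[sel]) / (t[sel][-1] - t[sel][0])),
                mean_KA=float(np.trapezoid(KA[sel], t[sel]) / (t[sel][-1] - t[sel][0])),
                end_M1_frac=float(m1e),
                end_M2_frac=float(m2e),
                end_KA=float(end[4]),
            )
        )
    return out
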