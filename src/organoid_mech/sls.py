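"""Micropipette-aspiration rheology: creep compliance and SLS fitting.

A creep test records the length ``L(t)`` of the tissue tongue aspirated
into a pipette of inner radius ``Rp`` under a constant suction pressure
``dP``.  For small deformations the half-space result converts the trace
into a creep compliance

    J(t) = 2 pi L(t) / (3 phi Rp dP),

with ``phi`` (default 2.1) a geometric factor for the finite pipette wall.
Organoid creep is well described by the standard linear solid (SLS): a
spring ``k1`` in parallel with a Maxwell arm (spring ``k2`` in series with
a dashpot ``mu``).  Its creep compliance is

    J_SLS(t) = (1/k_st) * (1 - ((k0 - k_st)/k0) * exp(-t/tau)),

where ``k0 = k1 + k2`` is the instantaneous stiffness, ``k_st = k1`` the
steady-state stiffness, and ``tau = mu (k1 + k2) / (k1 k2)`` the
elastic-to-steady-state transition time.  This module extracts
``(k0, k_st, tau)`` by nonlinear least squares and derives the Maxwell
elements, plus per-condition summaries with closed-form test statistics.

All internal computation is in SI units (Pa, s, m); the I/O boundary uses
micrometres for lengths because that is what tracking software exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateModelError,
    FitFailureError,
    InvalidInputError,
    InvalidParameterError,
)
from .stats import TestResult, one_way_anova, pooled_t_test

__all__ = [
    "CreepTrace",
    "CreepCompliance",
    "SLSFit",
    "detect_onset",
    "compute_creep_compliance",
    "sls_creep_model",
    "fit_sls",
    "derive_maxwell_elements",
    "summarize_condition",
    "read_trace_csv",
    "fits_to_frame",
]

DEFAULT_WALL_FACTOR = 2.1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CreepTrace:
    """A timed aspirated-length record with pipette geometry and load.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing.
    aspirated_length
        Tongue length L(t) in micrometres, non-negative after onset.
    pipette_radius
        Pipette inner radius Rp in micrometres (> 0).
    pressure
        Suction magnitude dP in pascals relative to atmosphere (> 0).
    wall_factor
        Dimensionless pipette wall factor phi.
    suction_onset
        Time (s) at which the load begins, or ``None`` for auto-detection.
    label
        Free-text condition / organoid identifier.
    """

    time: np.ndarray
    aspirated_length: np.ndarray
    pipette_radius: float
    pressure: float
    wall_factor: float = DEFAULT_WALL_FACTOR
    suction_onset: float | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        L = np.asarray(self.aspirated_length, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "aspirated_length", L)
        if t.ndim != 1 or L.shape != t.shape:
            raise InvalidInputError("time and aspirated_length must be 1D and equal length")
        if t.size < 2:
            raise InvalidInputError("a trace needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if not (self.pipette_radius > 0):
            raise InvalidInputError(f"pipette_radius must be > 0, got {self.pipette_radius}")
        if not (self.pressure > 0):
            raise InvalidInputError(f"pressure must be > 0, got {self.pressure}")
        if not (self.wall_factor > 0):
            raise InvalidInputError(f"wall_factor must be > 0, got {self.wall_factor}")
        if self.suction_onset is not None and not (t[0] <= self.suction_onset <= t[-1]):
            raise InvalidInputError(
                f"suction_onset {self.suction_onset} outside record [{t[0]}, {t[-1]}]")


@dataclass(frozen=True)
class CreepCompliance:
    """Creep compliance J(t) in 1/Pa, with time re-zeroed at suction onset."""

    time: np.ndarray
    J: np.ndarray
    label: str = ""
    baseline_time: np.ndarray | None = None
    baseline_J: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        J = np.asarray(self.J, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "J", J)
        if t.shape != J.shape:
            raise InvalidInputError("time and J must have the same length")


@dataclass(frozen=True)
class SLSFit:
    """Fitted SLS parameters and the derived Maxwell representation.

    Invariants: ``k0 >= k_st > 0``, ``tau > 0``, ``k1 = k_st``,
    ``k2 = k0 - k_st`` and ``mu = tau k1 k2 / (k1 + k2)``.
    """

    k0: float
    k_st: float
    tau: float
    k1: float
    k2: float
    mu: float
    r_squared: float
    n_points: int
    degenerate_tau: bool = False
    label: str = ""


# ---------------------------------------------------------------------------
# operations


def detect_onset(trace: CreepTrace, baseline_fraction: float = 0.15,
                 n_sigma: float = 3.0) -> float:
    """Estimate the suction-onset time from the pre-load baseline.

    The leading ``baseline_fraction`` of the record (at least 3 samples) is
    treated as the unloaded baseline; onset is the first sample from which
    L stays above the baseline mean + ``n_sigma`` baseline standard
    deviations for 3 consecutive samples (guarding against isolated noise
    spikes).  Falls back to the first sample when the trace rises
    immediately.
    """
    t, L = trace.time, trace.aspirated_length
    nb = max(3, int(round(baseline_fraction * t.size)))
    nb = min(nb, t.size - 1)
    base = L[:nb]
    mu, sd = float(base.mean()), float(base.std())
    # Guard against a perfectly flat synthetic baseline.
    scale = max(abs(L).max(), 1.0)
    sd = max(sd, 1e-12 * scale)
    above = L > mu + n_sigma * sd
    run = min(3, t.size)
    sustained = np.nonzero([above[i:i + run].all() for i in range(t.size - run + 1)])[0]
    if sustained.size == 0:
        return float(t[0])
    return float(t[int(sustained[0])])


def compute_creep_compliance(trace: CreepTrace,
                             keep_baseline: bool = True) -> CreepCompliance:
    """Convert an aspiration trace to a creep-compliance function.

    ``J(t) = 2 pi L(t) / (3 phi Rp dP)`` with ``L/Rp`` dimensionless, so J
    carries units 1/Pa.  Pre-onset samples are discarded (retained as
    baseline metadata when ``keep_baseline``); time is re-zeroed at onset.
    """
    onset = trace.suction_onset
    if onset is None:
        onset = detect_onset(trace)
    t, L = trace.time, trace.aspirated_length
    if not (t[0] <= onset <= t[-1]):
        raise InvalidInputError(f"onset {onset} outside record")
    factor = 2.0 * np.pi / (3.0 * trace.wall_factor * trace.pipette_radius * trace.pressure)
    J_all = factor * L  # L and Rp in the same length unit -> J in 1/Pa
    post = t >= onset
    if post.sum() < 1:
        raise InvalidInputError("no samples at or after suction onset")
    kwargs = {}
    if keep_baseline and (~post).any():
        kwargs = {"baseline_time": t[~post].copy(), "baseline_J": J_all[~post].copy()}
    return CreepCompliance(time=t[post] - onset, J=J_all[post], label=trace.label, **kwargs)


def sls_creep_model(t, k0: float, k_st: float, tau: float):
    """Creep compliance of the standard linear solid, vectorized over t.

    Returns ``(1/k_st) (1 - ((k0 - k_st)/k0) exp(-t/tau))``.
    """
    if not (k_st > 0) or not (k0 >= k_st):
        raise InvalidParameterError(f"need k0 >= k_st > 0, got k0={k0}, k_st={k_st}")
    if not (tau > 0):
        raise InvalidParameterError(f"need tau > 0, got tau={tau}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    return (1.0 / k_st) * (1.0 - ((k0 - k_st) / k0) * np.exp(-t / tau))


def _initial_guess(t: np.ndarray, J: np.ndarray) -> tuple[float, float, float]:
    """Endpoint-based initializer: plateaus give k0 and k_st, the midpoint
    crossing gives tau."""
    J0 = max(float(J[0]), 1e-30)
    tail = J[max(1, int(round(0.9 * J.size))):]
    Jinf = max(float(tail.mean()), J0)
    k0 = 1.0 / J0
    k_st = 1.0 / Jinf
    mid = 0.5 * (J0 + Jinf)
    above = np.nonzero(J >= mid)[0]
    t_mid = float(t[above[0]]) if above.size else float(t[-1]) / 3.0
    tau = max(t_mid, float(t[1] - t[0]), 1e-6)
    return k0, max(k_st, 1e-30), tau


def fit_sls(compliance: CreepCompliance,
            init: tuple[float, float, float] | None = None,
            degenerate_rtol: float = 1e-3) -> SLSFit:
    """Fit the SLS creep-compliance model to a (t, J) record.

    The fit runs in log-parameter space over ``(k_st, k2, tau)`` with
    ``k2 = k0 - k_st``, which enforces positivity and ``k0 >= k_st``
    structurally.  ``r_squared`` is ``1 - SS_res/SS_tot`` about the mean of
    J over the fitted window.  A fit whose transient amplitude ``k2`` is
    negligible relative to ``k_st`` (pure elastic response) is flagged
    ``degenerate_tau``: tau is then unconstrained by the data.
    """
    t = compliance.time
    J = compliance.J
    if t.size < 4:
        raise InvalidInputError(f"need >= 4 post-onset samples, got {t.size}")
    if np.any(J < 0):
        raise InvalidInputError("compliance must be non-negative")
    if not np.all(np.isfinite(J)):
        raise InvalidInputError("compliance contains non-finite values")

    if init is None:
        k0_g, kst_g, tau_g = _initial_guess(t, J)
    else:
        k0_g, kst_g, tau_g = init
        if not (k0_g >= kst_g > 0 and tau_g > 0):
            raise InvalidParameterError("init must satisfy k0 >= k_st > 0, tau > 0")
    k2_g = max(k0_g - kst_g, 1e-9 * kst_g)

    scale = max(float(np.abs(J).max()), 1e-30)

    def residuals(theta):
        k_st, k2, tau = np.exp(theta)
        k0 = k_st + k2
        model = (1.0 / k_st) * (1.0 - (k2 / k0) * np.exp(-t / tau))
        return (model - J) / scale

    theta0 = np.log([kst_g, k2_g, tau_g])
    res = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                        max_nfev=20000)
    if not res.success:
        raise FitFailureError(
            "SLS fit did not converge",
            diagnostics={"status": res.status, "cost": float(res.cost),
                         "residual_norm": float(np.linalg.norm(res.fun))})

    k_st, k2, tau = np.exp(res.x)
    k0 = k_st + k2
    model = (1.0 / k_st) * (1.0 - (k2 / k0) * np.exp(-t / tau))
    ss_res = float(((J - model) ** 2).sum())
    ss_tot = float(((J - J.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)

    degenerate = bool(k2 <= degenerate_rtol * k_st)
    mu = tau * k_st * k2 / (k_st + k2)
    return SLSFit(k0=float(k0), k_st=float(k_st), tau=float(tau),
                  k1=float(k_st), k2=float(k2), mu=float(mu),
                  r_squared=float(r2), n_points=int(t.size),
                  degenerate_tau=degenerate, label=compliance.label)


def derive_maxwell_elements(k0: float, k_st: float, tau: float,
                            rtol: float = 1e-12) -> tuple[float, float, float]:
    """Maxwell-representation elements (k1, k2, mu) from (k0, k_st, tau).

    ``k1 = k_st``, ``k2 = k0 - k_st`` and ``mu = tau k1 k2 / (k1 + k2)``,
    so that ``tau = mu (k1 + k2) / (k1 k2)`` round-trips exactly.
    """
    if not (k_st > 0 and k0 >= k_st):
        raise InvalidParameterError(f"need k0 >= k_st > 0, got k0={k0}, k_st={k_st}")
    if not (tau > 0):
        raise InvalidParameterError(f"need tau > 0, got {tau}")
    k1 = k_st
    k2 = k0 - k_st
    if k2 <= rtol * k0:
        raise DegenerateModelError(
            "k0 = k_st: the Maxwell arm is absent and mu is undefined")
    mu = tau * k1 * k2 / (k1 + k2)
    return float(k1), float(k2), float(mu)


# ---------------------------------------------------------------------------
# condition summaries


def summarize_condition(fits: Sequence[SLSFit],
                        grouping: Sequence[str] | None = None,
                        parameters: tuple[str, ...] = ("k0", "k_st", "tau"),
                        ) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Per-group mean, SD and n of the fitted parameters, plus a comparison.

    Two groups are compared by the two-tailed pooled-variance t test; three
    or more by one-way ANOVA.  Returns the summary table and a mapping from
    parameter name to its :class:`~organoid_mech.stats.TestResult`.
    """
    if grouping is None:
        grouping = [f.label for f in fits]
    if len(grouping) != len(fits):
        raise InvalidInputError("grouping must align with fits")
    groups: dict[str, list[SLSFit]] = {}
    for f, g in zip(fits, grouping):
        groups.setdefault(str(g), []).append(f)
    for g, members in groups.items():
        if len(members) < 2:
            raise InvalidInputError(
                f"group {g!r} has {len(members)} fit(s); need >= 2 replicates")

    rows = []
    for g, members in groups.items():
        row: dict[str, object] = {"group": g, "n": len(members)}
        for p in parameters:
            vals = np.array([getattr(f, p) for f in members], dtype=float)
            row[f"{p}_mean"] = vals.mean()
            row[f"{p}_sd"] = vals.std(ddof=1)
        rows.append(row)
    summary = pd.DataFrame(rows)

    tests: dict[str, TestResult] = {}
    samples = {g: members for g, members in groups.items()}
    if len(samples) >= 2:
        for p in parameters:
            arrays = [np.array([getattr(f, p) for f in m]) for m in samples.values()]
            if len(arrays) == 2:
                tests[p] = pooled_t_test(arrays[0], arrays[1])
            else:
                tests[p] = one_way_anova(*arrays)
    return summary, tests


# ---------------------------------------------------------------------------
# I/O boundary


def read_trace_csv(path: str | Path, pipette_radius: float | None = None,
                   pressure: float | None = None,
                   wall_factor: float = DEFAULT_WALL_FACTOR,
                   suction_onset: float | None = None,
                   label: str | None = None) -> CreepTrace:
    """Read a creep trace from CSV/TSV with columns ``time_s, length_um``.

    Metadata (Rp, dP, phi, label) may live in a JSON sidecar ``<file>.json``
    or be passed explicitly; explicit arguments win.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("time_s", "length_um"):
        if col not in df.columns:
            raise InvalidInputError(f"{path} lacks required column {col!r}")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    rp = pipette_radius if pipette_radius is not None else meta.get("pipette_radius_um")
    dp = pressure if pressure is not None else meta.get("pressure_pa")
    phi = meta.get("wall_factor", wall_factor) if wall_factor == DEFAULT_WALL_FACTOR else wall_factor
    onset = suction_onset if suction_onset is not None else meta.get("suction_onset_s")
    lab = label if label is not None else meta.get("label", path.stem)
    if rp is None or dp is None:
        raise InvalidInputError(
            f"{path}: pipette_radius and pressure must come from arguments or sidecar")
    return CreepTrace(time=df["time_s"].to_numpy(),
                      aspirated_length=df["length_um"].to_numpy(),
                      pipette_radius=float(rp), pressure=float(dp),
                      wall_factor=float(phi), suction_onset=onset, label=str(lab))


def fits_to_frame(fits: Iterable[SLSFit]) -> pd.DataFrame:
    """Tabulate fits as the per-organoid output table."""
    return pd.DataFrame([
        {"label": f.label, "k0_Pa": f.k0, "kst_Pa": f.k_st, "tau_s": f.tau,
         "k1_Pa": f.k1, "k2_Pa": f.k2, "mu_Pas": f.mu,
         "r_squared": f.r_squared, "n_points": f.n_points,
         "degenerate_tau": f.degenerate_tau}
        for f in fits
    ])
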