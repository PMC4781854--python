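"""Drift-diffusion model (DDM) first-passage sampling.

The DDM treats a two-choice decision as a Wiener process with drift ``v``
between absorbing boundaries at 0 and ``a``, starting at ``z_frac * a``.
Response time is the first-passage time plus a fixed non-decision time
``Ter`` covering stimulus encoding and motor execution.  The diffusion
noise scale ``s`` is a free scaling constant fixed at 0.1 by convention.

Sampling uses an Euler-discretized random walk (default step 1 ms).  Walks
that fail to terminate by ``max_time`` are counted and resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DDMParams", "first_passage_p_upper", "sample_ddm_trial", "sample_ddm_trials"]

_BLOCK_STEPS = 256


@dataclass(frozen=True)
class DDMParams:
    """DDM parameter set; units: evidence per second for v, seconds for Ter."""

    v: float
    a: float
    z_frac: float = 0.5
    ter: float = 0.0
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if not 0.0 < self.z_frac < 1.0:
            raise ValueError("z_frac must lie strictly between 0 and 1")
        if self.ter < 0:
            raise ValueError("non-decision time Ter must be nonnegative")
        if self.s <= 0:
            raise ValueError("diffusion noise scale s must be positive")


def first_passage_p_upper(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary.

    P(upper) = (1 - exp(-2 v a z / s^2)) / (1 - exp(-2 v a / s^2)) with
    z = z_frac; equals z_frac in the driftless limit.
    """
    k = 2.0 * params.v * params.a / params.s**2
    if abs(k) < 1e-12:
        return params.z_frac
    return float(np.expm1(-k * params.z_frac) / np.expm1(-k))


def sample_ddm_trials(
    v: np.ndarray,
    a: np.ndarray,
    z_frac: np.ndarray,
    ter: np.ndarray,
    s: float,
    rng: np.random.Generator,
    dt: float = 0.001,
    max_time: float = 5.0,
    max_resample: int = 200,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized first-passage sampling for per-trial parameter arrays.

    Returns ``(upper, rt, n_timeouts)`` where ``upper`` is True for upper
    boundary hits, ``rt`` includes the per-trial non-decision time, and
    ``n_timeouts`` counts walks past ``max_time`` that had to be restarted.
    """
    if dt > 0.001 + 1e-12:
        raise ValueError("Euler step dt must be <= 1 ms")
    v, a, z_frac, ter = np.broadcast_arrays(
        np.asarray(v, float), np.asarray(a, float), np.asarray(z_frac, float), np.asarray(ter, float)
    )
    n = v.size
    shape = v.shape
    v, a, z_frac, ter = (x.ravel() for x in (v, a, z_frac, ter))

    max_steps = int(round(max_time / dt))
    sq = s * np.sqrt(dt)

    upper = np.zeros(n, dtype=bool)
    steps_taken = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    x = z_frac[pending] * a[pending]
    step_count = np.zeros(n, dtype=np.int64)
    n_timeouts = 0
    resamples = 0

    while pending.size:
        block = min(_BLOCK_STEPS, max_steps - int(step_count[pending].min()))
        # Path via cumulative sum; valid up to (and including) first crossing.
        incr = v[pending][None, :] * dt + sq * rng.standard_normal((block, pending.size))
        path = x[None, :] + np.cumsum(incr, axis=0)
        hit_up = path >= a[pending][None, :]
        hit = hit_up | (path <= 0.0)
        crossed = hit.any(axis=0)
        first = hit.argmax(axis=0)

        done_idx = pending[crossed]
        fi = first[crossed]
        upper[done_idx] = hit_up[fi, np.nonzero(crossed)[0]]
        steps_taken[done_idx] = step_count[done_idx] + fi + 1

        keep = ~crossed
        pending = pending[keep]
        x = path[-1, keep]
        step_count[pending] += block

        timed_out = step_count[pending] >= max_steps
        if timed_out.any():
            n_timeouts += int(timed_out.sum())
            resamples += 1
            if resamples > max_resample:
                raise RuntimeError("DDM walk failed to terminate after repeated resampling")
            # restart the timed-out walkers from scratch
            to = pending[timed_out]
            step_count[to] = 0
            x[timed_out] = z_frac[to] * a[to]

    rt = ter + steps_taken * dt
    return upper.reshape(shape), rt.reshape(shape), n_timeouts


def sample_ddm_trial(
    params: DDMParams,
    rng: np.random.Generator,
    dt: float = 0.001,
    max_time: float = 5.0,
) -> tuple[str, float]:
    """Sample one trial; returns ('upper'|'lower', rt in seconds)."""
    up, rt, _ = sample_ddm_trials(
        np.array([params.v]),
        np.array([params.a]),
        np.array([params.z_frac]),
        np.array([params.ter]),
        params.s,
        rng,
        dt=dt,
        max_time=max_time,
    )
    return ("upper" if up[0] else "lower"), float(rt[0])
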