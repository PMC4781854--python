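"""Closed-form EZ diffusion estimation and summed-similarity computation.

The EZ method inverts the drift-diffusion model's closed-form expressions
for accuracy, mean correct RT, and correct-RT variance to recover drift
rate v, boundary separation a, and non-decision time Ter.  It assumes an
unbiased start point (z = a/2) and no across-trial parameter variability.
One Ter per participant (pooled across stimulus classes) is what the
regressor construction downstream needs; a hook accepts an externally
supplied Ter instead.

Summed similarity is the exemplar-model familiarity signal: the sum over
memory-set items of exp(-c * d_i), with d_i the probe-to-item distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EZEstimate", "fit_ez", "edge_correct_pc", "summed_similarity"]


@dataclass(frozen=True)
class EZEstimate:
    """EZ-diffusion estimates together with the summary statistics used."""

    v: float
    a: float
    ter: float
    pc: float
    vrt: float
    mrt: float
    ter_negative: bool = False


def edge_correct_pc(n_correct: int, n_trials: int) -> float:
    """Proportion correct with the 1/(2n) edge correction.

    Pc of exactly 0, 0.5, or 1 makes the EZ equations degenerate; the
    standard correction moves such values half a trial inward.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    pc = n_correct / n_trials
    half = 1.0 / (2.0 * n_trials)
    if pc == 0.0:
        return half
    if pc == 1.0:
        return 1.0 - half
    if pc == 0.5:
        return 0.5 + half
    return pc


def fit_ez(pc: float, vrt: float, mrt: float, s: float = 0.1) -> EZEstimate:
    """Standard EZ closed form.

    With L = logit(Pc):

        v   = sign(Pc - 1/2) * s * (L (L Pc^2 - L Pc + Pc - 1/2) / VRT)^(1/4)
        a   = s^2 L / v
        MDT = (a / 2v) * (1 - exp(-v a / s^2)) / (1 + exp(-v a / s^2))
        Ter = MRT - MDT

    A negative Ter is returned flagged rather than raised, since it is a
    legitimate (if suspicious) outcome of noisy inputs.
    """
    if not 0.0 < pc < 1.0:
        raise ValueError("Pc must lie strictly in (0, 1); apply edge_correct_pc first")
    if pc == 0.5:
        raise ValueError("Pc of exactly 0.5 is degenerate; apply edge_correct_pc first")
    if vrt <= 0:
        raise ValueError("correct-RT variance must be positive")

    ell = float(np.log(pc / (1.0 - pc)))
    x = ell * (ell * pc**2 - ell * pc + pc - 0.5) / vrt
    v = float(np.sign(pc - 0.5) * s * x**0.25)
    a = s**2 * ell / v
    y = -v * a / s**2
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    ter = mrt - float(mdt)
    return EZEstimate(v=v, a=float(a), ter=ter, pc=pc, vrt=vrt, mrt=mrt, ter_negative=ter < 0)


def fit_ez_from_trials(correct: np.ndarray, rt: np.ndarray, s: float = 0.1) -> EZEstimate:
    """EZ fit from raw per-trial correctness and RT vectors."""
    correct = np.asarray(correct, bool)
    rt = np.asarray(rt, float)
    if correct.size < 2 or correct.sum() < 2:
        raise ValueError("need at least two correct trials for an EZ fit")
    pc = edge_correct_pc(int(correct.sum()), correct.size)
    crt = rt[correct]
    return fit_ez(pc, float(crt.var(ddof=1)), float(crt.mean()), s=s)


def summed_similarity(
    probe: np.ndarray,
    memory_set: list[np.ndarray] | np.ndarray,
    c: float = 1.0,
    distance: str = "euclidean",
) -> float:
    """S = sum_i exp(-c * d_i) over the memory set.

    Monotone decreasing in every probe-to-item distance; permutation
    invariant over the memory set.
    """
    if c <= 0:
        raise ValueError("decay c must be positive")
    items = np.atleast_2d(np.asarray(memory_set, float))
    if items.size == 0:
        raise ValueError("memory set must not be empty")
    probe = np.asarray(probe, float)
    if probe.shape[-1] != items.shape[-1]:
        raise ValueError("probe and memory items must share a dimension")
    if distance == "euclidean":
        d = np.linalg.norm(items - probe[None, :], axis=1)
    elif distance == "cityblock":
        d = np.abs(items - probe[None, :]).sum(axis=1)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return float(np.exp(-c * d).sum())
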