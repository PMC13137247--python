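"""Synthetic collective-variable trajectories with known statistics.

Each generator draws i.i.d. frames from a distribution whose target
quantity (conformer fractions, free-energy profile, bound/unbound dF)
is available in closed form and recorded in the trajectory metadata, so
downstream estimators can be validated against exact references.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cg_polymer import GAUCHE_DEGENERACY, wrap_angle
from .constants import kbt
from .errors import PetfesError
from .fes_analysis import CVTrajectory

__all__ = ["FixtureSpec", "generate_fixture", "GENERATORS"]

GENERATORS = ("two_state_torsion", "double_well_cv", "bound_unbound_mixture")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic trajectory; the seed is mandatory."""

    generator: str
    n_frames: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.generator not in GENERATORS:
            raise PetfesError(
                f"unknown generator {self.generator!r}; choose from {GENERATORS}")
        if self.n_frames < 1:
            raise PetfesError("n_frames must be >= 1")
        if self.seed is None:
            raise PetfesError("a seed is mandatory")


def _two_state_torsion(n_frames: int, rng: np.random.Generator, *,
                       delta_e: float = -4.09, T: float = 303.15,
                       n_torsions: int = 4, spread: float = 8.0) -> CVTrajectory:
    """Exact two-state Boltzmann sample of gauche/trans torsion labels.

    Gauche carries degeneracy 2 (+-70 deg wells); angles are jittered
    inside their classification window so the labels are exact.
    """
    w = GAUCHE_DEGENERACY * math.exp(-delta_e / kbt(T))
    p_g = w / (1.0 + w)
    labels = rng.random((n_frames, n_torsions)) < p_g
    sign = np.where(rng.random((n_frames, n_torsions)) < 0.5, 1.0, -1.0)
    jitter = np.clip(rng.normal(0.0, spread, (n_frames, n_torsions)), -35, 35)
    psis = np.where(labels, sign * 70.0 + jitter, 180.0 + jitter)
    cols = {f"psi{i + 1}": wrap_angle(psis[:, i]) for i in range(n_torsions)}
    return CVTrajectory.from_columns(
        metadata={"T": T, "delta_e": delta_e, "p_gauche": p_g,
                  "system": "two_state_torsion"}, **cols)


def _double_well_cv(n_frames: int, rng: np.random.Generator, *,
                    barrier: float = 10.0, half_separation: float = 1.0,
                    T: float = 300.0, cv_name: str = "s0") -> CVTrajectory:
    """I.i.d. Boltzmann samples from V(x) = h ((x/a)^2 - 1)^2.

    Drawn by inverse-CDF on a fine grid; exact to grid resolution.
    """
    span = 2.5 * half_separation
    grid = np.linspace(-span, span, 40_001)
    u = barrier * ((grid / half_separation) ** 2 - 1.0) ** 2
    p = np.exp(-(u - u.min()) / kbt(T))
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    x = np.interp(rng.random(n_frames), cdf, grid)
    return CVTrajectory.from_columns(
        metadata={"T": T, "barrier": barrier,
                  "half_separation": half_separation, "system": "toy"},
        **{cv_name: x})


def _bound_unbound_mixture(n_frames: int, rng: np.random.Generator, *,
                           p_bound: Optional[float] = None,
                           delta_f: Optional[float] = None,
                           T: float = 300.0, threshold: float = 3.0,
                           cv_name: str = "d_COM",
                           switch_frame: Optional[int] = None,
                           p_bound_late: Optional[float] = None
                           ) -> CVTrajectory:
    """Two-basin d_COM distribution with prescribed bound/unbound dF.

    Specify either `p_bound` or `delta_f` (dF = -kBT ln(p_b/p_u)).  With
    `switch_frame`/`p_bound_late` the bound probability changes mid-run,
    giving a two-regime trajectory for convergence tests.
    """
    if (p_bound is None) == (delta_f is None):
        raise PetfesError("specify exactly one of p_bound or delta_f")
    if p_bound is None:
        p_bound = 1.0 / (1.0 + math.exp(delta_f / kbt(T)))
    if not 0 < p_bound < 1:
        raise PetfesError(f"p_bound must lie in (0, 1), got {p_bound}")
    probs = np.full(n_frames, p_bound)
    if switch_frame is not None:
        if p_bound_late is None or not 0 < p_bound_late < 1:
            raise PetfesError("two-regime mixture needs p_bound_late in (0, 1)")
        probs[switch_frame:] = p_bound_late
    bound = rng.random(n_frames) < probs
    # bound basin centred at 2 nm, unbound plateau beyond the threshold;
    # resample any stragglers so the labels are exact by construction
    x = np.where(bound,
                 rng.normal(2.0, 0.25, n_frames),
                 threshold + 0.2 + rng.exponential(0.8, n_frames))
    bad = bound & (x > threshold)
    while bad.any():
        x[bad] = rng.normal(2.0, 0.25, int(bad.sum()))
        bad = bound & (x > threshold)
    x = np.clip(x, 0.1, None)
    df_exact = -kbt(T) * math.log(p_bound / (1.0 - p_bound))
    return CVTrajectory.from_columns(
        metadata={"T": T, "threshold": threshold, "p_bound": p_bound,
                  "delta_f": df_exact, "system": "bound_unbound_mixture"},
        **{cv_name: x})


_DISPATCH = {
    "two_state_torsion": _two_state_torsion,
    "double_well_cv": _double_well_cv,
    "bound_unbound_mixture": _bound_unbound_mixture,
}


def generate_fixture(spec: FixtureSpec) -> CVTrajectory:
    """Draw the trajectory a FixtureSpec describes (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    traj = _DISPATCH[spec.generator](spec.n_frames, rng, **spec.params)
    traj.metadata["seed"] = spec.seed
    traj.metadata["generator"] = spec.generator
    return traj
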