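"""Well-tempered metadynamics and Hamiltonian replica exchange.

The metadynamics engine deposits repulsive Gaussians along chosen
collective variables with heights damped by the well-tempered rule
w = w0 exp(-V/(kB (gamma-1) T)); at long times the deposited bias
converges to -(gamma-1)/gamma times the free energy, so the surface can
be reconstructed either directly from the bias or by reweighting.

Replica exchange follows the solute-tempering idea: each replica evolves
under a Hamiltonian whose solute terms (here the torsion potential and
any pairwise wells flagged scalable) are multiplied by a ladder value
lambda in (0, 1]; wall restraints stay unscaled in every replica.
Configurations are swapped between ladder neighbors by a Metropolis
criterion.  Gaussian heights in scaled replicas are boosted as w/lambda
so the bias compensates the flattened landscape.  Analysis statistics
are taken from the unscaled (lambda = 1) replica.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import KB, kbt
from .errors import PetfesError
from .fes_analysis import BIAS_COLUMN, CVTrajectory

__all__ = [
    "GaussianKernel",
    "MetadBias",
    "MetadSpec",
    "ReplicaLadder",
    "ReplicaState",
    "HrexSchedule",
    "HrexResult",
    "EnergyTerm",
    "wt_height",
    "evaluate_bias",
    "deposit",
    "lambda_ladder",
    "scale_hamiltonian",
    "exchange_probability",
    "replica_scaled_height",
    "fes_from_bias",
    "run_wtmtd",
    "run_hrex_wtmtd",
    "DoubleWell1D",
    "CGChainSystem",
]


# ---------------------------------------------------------------------------
# Bias machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianKernel:
    """One deposited repulsive Gaussian."""

    centers: np.ndarray         # one per biased CV
    widths: np.ndarray          # same shape, > 0
    height: float               # kJ/mol, > 0
    deposit_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_1d(
            np.asarray(self.centers, dtype=float)))
        object.__setattr__(self, "widths", np.atleast_1d(
            np.asarray(self.widths, dtype=float)))
        if np.any(self.widths <= 0):
            raise PetfesError("kernel widths must be positive")
        if self.height <= 0:
            raise PetfesError("kernel height must be positive")


class MetadBias:
    """Ordered Gaussian history with a well-tempered bias factor.

    Kernels are stored in flat arrays (centers (K, d), widths (K, d),
    heights (K,)) and evaluated by direct summation; at desk scale the
    kernel counts stay small enough that no kernel merging is needed.
    """

    def __init__(self, cv_names: Sequence[str], bias_factor: float = 15.0,
                 pace: int = 500, sigma=0.05) -> None:
        if bias_factor <= 1:
            raise PetfesError(f"bias factor must exceed 1, got {bias_factor}")
        self.cv_names = tuple(cv_names)
        self.bias_factor = float(bias_factor)
        self.pace = int(pace)
        self.sigma = np.broadcast_to(np.asarray(sigma, dtype=float),
                                     (len(self.cv_names),)).copy()
        d = len(self.cv_names)
        self._centers = np.empty((0, d))
        self._widths = np.empty((0, d))
        self._heights = np.empty(0)

    @property
    def n_kernels(self) -> int:
        return len(self._heights)

    @property
    def kernels(self) -> list:
        return [GaussianKernel(self._centers[i], self._widths[i],
                               float(self._heights[i]), i)
                for i in range(self.n_kernels)]

    def kernel_arrays(self) -> tuple:
        return self._centers, self._widths, self._heights

    def evaluate(self, point) -> float:
        return float(self.evaluate_many(np.atleast_2d(
            np.asarray(point, dtype=float)))[0])

    def evaluate_many(self, points: np.ndarray) -> np.ndarray:
        """Total bias at an (N, d) array of CV points, kJ/mol."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != len(self.cv_names):
            raise PetfesError(
                f"bias is over {len(self.cv_names)} CVs, got points of "
                f"dimension {points.shape[1]}")
        if self.n_kernels == 0:
            return np.zeros(points.shape[0])
        # (N, K, d) reduced over kernels
        z = (points[:, None, :] - self._centers[None, :, :]) / self._widths
        return np.exp(-0.5 * np.sum(z * z, axis=2)) @ self._heights

    def append_kernel(self, centers, height: float) -> None:
        centers = np.atleast_1d(np.asarray(centers, dtype=float))
        self._centers = np.vstack([self._centers, centers[None, :]])
        self._widths = np.vstack([self._widths, self.sigma[None, :]])
        self._heights = np.append(self._heights, float(height))

    def copy(self) -> "MetadBias":
        out = MetadBias(self.cv_names, self.bias_factor, self.pace, self.sigma)
        out._centers = self._centers.copy()
        out._widths = self._widths.copy()
        out._heights = self._heights.copy()
        return out


def wt_height(current_bias_at_s: float, w0: float, gamma: float,
              T: float) -> float:
    """Well-tempered Gaussian height w0 exp(-V/(kB (gamma-1) T))."""
    if gamma <= 1:
        raise PetfesError(f"bias factor must exceed 1, got {gamma}")
    if w0 <= 0:
        raise PetfesError(f"initial height must be positive, got {w0}")
    if math.isinf(gamma):
        return w0
    return w0 * math.exp(-current_bias_at_s / (KB * (gamma - 1.0) * T))


def evaluate_bias(bias: MetadBias, point) -> float:
    """Total deposited bias at a CV point, kJ/mol (>= 0)."""
    return bias.evaluate(point)


def deposit(bias: MetadBias, point, w0: float, gamma: float,
            T: float) -> MetadBias:
    """Append one well-tempered kernel at `point`; returns the bias."""
    h = wt_height(bias.evaluate(point), w0, gamma, T)
    bias.append_kernel(point, h)
    return bias


def replica_scaled_height(w: float, lam: float) -> float:
    """Gaussian height w/lambda used in the lambda-scaled replica."""
    if not 0 < lam <= 1:
        raise PetfesError(f"lambda must lie in (0, 1], got {lam}")
    if w <= 0:
        raise PetfesError(f"height must be positive, got {w}")
    return w / lam


def fes_from_bias(bias: MetadBias, grid: np.ndarray) -> np.ndarray:
    """Free energy implied by a converged well-tempered bias.

    F(s) = -gamma/(gamma-1) V(s) + const, returned shifted to min 0 on
    the grid (grid is (N,) for one CV or (N, d)).
    """
    grid = np.asarray(grid, dtype=float)
    pts = grid[:, None] if grid.ndim == 1 else grid
    v = bias.evaluate_many(pts)
    g = bias.bias_factor
    f = -(g / (g - 1.0)) * v
    return f - f.min()


# ---------------------------------------------------------------------------
# Replica ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicaLadder:
    """Descending lambda values; the first is exactly 1.

    Ladders built by `lambda_ladder` are strictly decreasing; directly
    constructed ladders may repeat values (a uniform ladder is the
    degenerate case in which every exchange is accepted).
    """

    lambdas: tuple

    def __post_init__(self) -> None:
        lam = tuple(float(x) for x in self.lambdas)
        object.__setattr__(self, "lambdas", lam)
        if not lam or lam[0] != 1.0:
            raise PetfesError("ladder must start at lambda = 1")
        if any(not 0 < x <= 1 for x in lam):
            raise PetfesError("lambda values must lie in (0, 1]")
        if any(b > a for a, b in zip(lam, lam[1:])):
            raise PetfesError("lambda values must be non-increasing")

    def __len__(self) -> int:
        return len(self.lambdas)

    def __iter__(self):
        return iter(self.lambdas)


def lambda_ladder(n: int, lambda_min: float = 0.426934) -> ReplicaLadder:
    """Geometric lambda ladder: lambda_i = lambda_min**((i-1)/(n-1))."""
    if n < 2:
        raise PetfesError(f"a ladder needs at least 2 replicas, got {n}")
    if not 0 < lambda_min < 1:
        raise PetfesError(f"lambda_min must lie in (0, 1), got {lambda_min}")
    lam = [lambda_min ** (i / (n - 1)) for i in range(n)]
    lam[0], lam[-1] = 1.0, lambda_min   # exact endpoints
    return ReplicaLadder(tuple(lam))


# ---------------------------------------------------------------------------
# Hamiltonian scaling and exchange
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyTerm:
    """One named Hamiltonian component; `scalable` marks solute terms."""

    name: str
    value: float
    scalable: bool = False


def scale_hamiltonian(energy_terms: Sequence[EnergyTerm],
                      lam: float) -> list:
    """Multiply solute-scalable terms by lambda; leave the rest untouched."""
    if not 0 < lam <= 1:
        raise PetfesError(f"lambda must lie in (0, 1], got {lam}")
    return [replace(t, value=t.value * lam) if t.scalable else t
            for t in energy_terms]


def exchange_probability(E_i_xi: float, E_i_xj: float, E_j_xi: float,
                         E_j_xj: float, T: float) -> float:
    """Metropolis probability of swapping configurations between replicas.

    E_a_xb is replica a's Hamiltonian evaluated at replica b's
    configuration; the swap is accepted with
    min(1, exp(-[E_i(x_j) + E_j(x_i) - E_i(x_i) - E_j(x_j)] / kBT)).
    """
    for e in (E_i_xi, E_i_xj, E_j_xi, E_j_xj):
        if not math.isfinite(e):
            raise PetfesError("exchange energies must be finite")
    delta = (E_i_xj + E_j_xi - E_i_xi - E_j_xj) / kbt(T)
    return 1.0 if delta <= 0 else math.exp(-delta)


# ---------------------------------------------------------------------------
# Systems the drivers can sample
# ---------------------------------------------------------------------------

class DoubleWell1D:
    """Analytic 1D double well V(x) = h ((x/a)^2 - 1)^2, minima at +-a.

    Serves as the closed-form oracle system for the metadynamics and
    replica-exchange engines: its Boltzmann density and free-energy
    profile are known exactly.
    """

    def __init__(self, barrier: float = 10.0, half_separation: float = 1.0,
                 cv_name: str = "s0", step: float = 0.15,
                 scalable: bool = True) -> None:
        self.barrier = float(barrier)
        self.half_separation = float(half_separation)
        self.cv_names = (cv_name,)
        self.step = float(step)
        self.scalable = scalable

    def potential(self, x) -> np.ndarray:
        u = (np.asarray(x, dtype=float) / self.half_separation) ** 2 - 1.0
        return self.barrier * u * u

    def initial_state(self, rng: np.random.Generator) -> float:
        return float(rng.choice([-1.0, 1.0]) * self.half_separation)

    def cv_values(self, state: float) -> np.ndarray:
        return np.array([state])

    def energy_terms(self, state: float) -> list:
        return [EnergyTerm("double_well", float(self.potential(state)),
                           scalable=self.scalable)]

    def propose(self, state: float, rng: np.random.Generator) -> float:
        return state + self.step * float(rng.standard_normal())


class CGChainSystem:
    """Adapter exposing the coarse-grained PET chain to the drivers.

    CVs: the terminal distance d1 and the Psi torsions.  The torsion
    potential is the solute-scalable term; wall restraints are passed
    separately to the driver and never scaled.
    """

    def __init__(self, geometry, potential, step_deg: float = 30.0,
                 jump_prob: float = 0.25) -> None:
        from .cg_polymer import ChainState, min_terminal_distance
        self._ChainState = ChainState
        self._min_d1 = min_terminal_distance
        self.geometry = geometry
        self.potential = potential
        self.step_deg = float(step_deg)
        self.jump_prob = float(jump_prob)
        self.cv_names = ("d1",) + tuple(
            f"psi{i + 1}" for i in range(geometry.n_torsions))

    def initial_state(self, rng: np.random.Generator) -> np.ndarray:
        return np.full(self.geometry.n_torsions, 180.0)

    def cv_values(self, psis: np.ndarray) -> np.ndarray:
        state = self._ChainState.from_torsions(self.geometry, psis)
        return np.concatenate([[self._min_d1(state)], state.psis])

    def energy_terms(self, psis: np.ndarray) -> list:
        e = float(np.sum(self.potential.energy(psis)))
        return [EnergyTerm("torsion", e, scalable=True)]

    def propose(self, psis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        from .cg_polymer import wrap_angle
        new = psis.copy()
        j = int(rng.integers(len(new)))
        if rng.random() < self.jump_prob:
            new[j] = rng.uniform(-180.0, 180.0)
        else:
            new[j] = wrap_angle(new[j] + self.step_deg * rng.standard_normal())
        return new


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetadSpec:
    """What to bias and how to deposit."""

    cv_names: tuple = ("d1",)
    w0: float = 0.5             # initial Gaussian height, kJ/mol
    sigma: float = 0.05         # Gaussian width, nm
    gamma: float = 15.0         # bias factor
    pace: int = 500             # sampler steps between deposits

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.gamma <= 1 or self.pace < 1:
            raise PetfesError("invalid metadynamics spec")


@dataclass(frozen=True)
class HrexSchedule:
    """Step counts for a (replica-exchange) metadynamics run."""

    n_steps: int
    exchange_interval: int = 500
    record_stride: int = 10

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.exchange_interval < 1 or self.record_stride < 1:
            raise PetfesError("schedule counts must be positive")


@dataclass
class ReplicaState:
    """Bookkeeping for one replica of the ladder."""

    lam: float
    state: object
    bias: MetadBias
    exchange_attempts: int = 0
    exchange_accepts: int = 0

    def __post_init__(self) -> None:
        if self.exchange_accepts > self.exchange_attempts:
            raise PetfesError("acceptances cannot exceed attempts")


@dataclass
class HrexResult:
    """Per-replica trajectories and biases; index 0 is lambda = 1."""

    trajectories: list
    biases: list
    ladder: ReplicaLadder
    exchange_attempts: np.ndarray   # per neighbor pair
    exchange_accepts: np.ndarray

    @property
    def cold(self) -> CVTrajectory:
        """The analysis trajectory: the unscaled (lambda = 1) replica."""
        return self.trajectories[0]

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.exchange_accepts / np.maximum(self.exchange_attempts, 1)


def _total_energy(system, state, lam: float, wall_specs, cvs: np.ndarray,
                  bias: Optional[MetadBias], bias_idx) -> float:
    """lambda-scaled solute energy + unscaled walls + this replica's bias."""
    from .cg_polymer import _wall_energy
    terms = scale_hamiltonian(system.energy_terms(state), lam)
    e = sum(t.value for t in terms)
    for wall in wall_specs:
        i = system.cv_names.index(wall.cv_name)
        e += _wall_energy(float(cvs[i]), wall.limit, wall.k, wall.side_sign,
                          wall.exponent)
    if bias is not None:
        e += bias.evaluate(cvs[bias_idx])
    return e


def run_hrex_wtmtd(system, ladder: ReplicaLadder,
                   bias_spec: Optional[MetadSpec],
                   wall_specs: Sequence = (), schedule: HrexSchedule = None,
                   seed: int = 0, T: float = 300.0) -> HrexResult:
    """Concurrent well-tempered metadynamics over a solute-tempering ladder.

    Every replica evolves by Metropolis MC under its lambda-scaled
    Hamiltonian plus its own wt-MTD bias and the (unscaled) walls.
    Configuration swaps between ladder neighbors are attempted every
    `schedule.exchange_interval` steps, alternating even/odd pairs.
    Gaussian heights in replica i are scaled as w0/lambda_i.  With
    `bias_spec=None` the run is plain Hamiltonian replica exchange.
    """
    if schedule is None:
        raise PetfesError("a schedule is required")
    rng = np.random.default_rng(seed)
    bias_idx = (np.array([system.cv_names.index(c)
                          for c in bias_spec.cv_names])
                if bias_spec is not None else np.zeros(0, dtype=int))
    beta = 1.0 / kbt(T)

    replicas = []
    for lam in ladder:
        bias = None
        if bias_spec is not None:
            bias = MetadBias(bias_spec.cv_names, bias_factor=bias_spec.gamma,
                             pace=bias_spec.pace, sigma=bias_spec.sigma)
        replicas.append(ReplicaState(lam=lam, state=system.initial_state(rng),
                                     bias=bias))
    cvs = [system.cv_values(r.state) for r in replicas]
    energies = [
        _total_energy(system, r.state, r.lam, wall_specs, cv, r.bias, bias_idx)
        for r, cv in zip(replicas, cvs)]

    n_pairs = max(len(ladder) - 1, 1)
    attempts = np.zeros(n_pairs, dtype=int)
    accepts = np.zeros(n_pairs, dtype=int)
    records: list = [[] for _ in replicas]
    swap_parity = 0

    for step in range(1, schedule.n_steps + 1):
        for k, rep in enumerate(replicas):
            cand = system.propose(rep.state, rng)
            cand_cv = system.cv_values(cand)
            e_new = _total_energy(system, cand, rep.lam, wall_specs, cand_cv,
                                  rep.bias, bias_idx)
            if (e_new <= energies[k]
                    or rng.random() < math.exp(-beta * (e_new - energies[k]))):
                rep.state, cvs[k], energies[k] = cand, cand_cv, e_new
        if bias_spec is not None and step % bias_spec.pace == 0:
            for k, rep in enumerate(replicas):
                w0_k = replica_scaled_height(bias_spec.w0, rep.lam)
                s = cvs[k][bias_idx]
                h = wt_height(rep.bias.evaluate(s), w0_k, bias_spec.gamma, T)
                rep.bias.append_kernel(s, h)
                energies[k] += h   # kernel centred at the current point
        if len(ladder) > 1 and step % schedule.exchange_interval == 0:
            for i in range(swap_parity, len(ladder) - 1, 2):
                j = i + 1
                ri, rj = replicas[i], replicas[j]
                e_i_xj = _total_energy(system, rj.state, ri.lam, wall_specs,
                                       cvs[j], ri.bias, bias_idx)
                e_j_xi = _total_energy(system, ri.state, rj.lam, wall_specs,
                                       cvs[i], rj.bias, bias_idx)
                p = exchange_probability(energies[i], e_i_xj, e_j_xi,
                                         energies[j], T)
                attempts[i] += 1
                ri.exchange_attempts += 1
                rj.exchange_attempts += 1
                if rng.random() < p:
                    accepts[i] += 1
                    ri.exchange_accepts += 1
                    rj.exchange_accepts += 1
                    ri.state, rj.state = rj.state, ri.state
                    cvs[i], cvs[j] = cvs[j], cvs[i]
                    energies[i], energies[j] = e_i_xj, e_j_xi
            swap_parity = 1 - swap_parity
        if step % schedule.record_stride == 0:
            for k, rep in enumerate(replicas):
                v = (rep.bias.evaluate(cvs[k][bias_idx])
                     if rep.bias is not None else 0.0)
                records[k].append((step, *cvs[k], v))

    trajectories = []
    for k, rep in enumerate(replicas):
        cols = ["time", *system.cv_names, BIAS_COLUMN]
        df = pd.DataFrame(records[k], columns=cols)
        trajectories.append(CVTrajectory(df, metadata={
            "T": T, "lambda": rep.lam, "seed": seed,
            "system": getattr(system, "label", type(system).__name__),
            "analysis_replica": rep.lam == 1.0,
            "reweighting": "final-bias"}))
    return HrexResult(trajectories=trajectories,
                      biases=[r.bias for r in replicas], ladder=ladder,
                      exchange_attempts=attempts, exchange_accepts=accepts)


def run_wtmtd(system, bias_spec: MetadSpec, wall_specs: Sequence = (),
              schedule: HrexSchedule = None, seed: int = 0,
              T: float = 300.0) -> tuple:
    """Plain well-tempered metadynamics: the single-replica ladder.

    Returns (CVTrajectory, MetadBias) of the only (lambda = 1) replica.
    """
    result = run_hrex_wtmtd(system, ReplicaLadder((1.0,)), bias_spec,
                            wall_specs, schedule, seed=seed, T=T)
    return result.cold, result.biases[0]
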