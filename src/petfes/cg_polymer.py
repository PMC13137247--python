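"""Coarse-grained PET oligomer in torsion space.

The chain is a bead model of a PET tetramer: five rigid aryl-diester
blocks (two carbonyl beads joined by a long through-ring bond) linked by
four ethylene-glycol bonds.  The only degrees of freedom are the four
glycol torsions Psi (the OC-CO dihedral of each ethylene-glycol moiety);
all other torsions are held trans and bond lengths/angles are fixed.
Placing every glycol link between the two terminal marker carbonyls is a
deliberate idealization: it makes the terminal distance d1 a function of
all four Psi, so a lower-wall restraint on d1 steers the full
gauche/trans equilibrium, mirroring how distance restraints were used to
emulate crystalline (all-trans, extended) and amorphous (gauche-rich)
chain statistics.

Sampling is Metropolis Monte Carlo over torsion space with pivot moves
(rotating everything downstream of a glycol bond), which satisfies
detailed balance for the implicit-solvent model used here.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .constants import KB, T_SAMPLING, kbt
from .errors import (
    InvalidAngleError,
    InvalidGeometryError,
    InvalidRestraintError,
    NoDataError,
    SamplerError,
    UnreachableRatioError,
)

__all__ = [
    "ChainGeometry",
    "TorsionPotential",
    "WallRestraint",
    "ChainState",
    "TorsionTrajectory",
    "classify_torsion",
    "classify_torsions",
    "gt_ratio",
    "wall_energy",
    "min_terminal_distance",
    "sample_chain",
    "scan_d1",
    "calibrate_gt_gap",
    "two_state_gap",
    "two_state_populations",
    "wrap_angle",
]

#: Half-width of the gauche classification window, degrees.
GAUCHE_CUTOFF = 120.0
#: Number of equivalent gauche wells (+70 and -70 degrees).
GAUCHE_DEGENERACY = 2


def wrap_angle(psi):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = -np.mod(-np.asarray(psi, dtype=float) + 180.0, 360.0) + 180.0
    return wrapped if np.ndim(psi) else float(wrapped)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainGeometry:
    """Bead geometry of the coarse-grained PET oligomer.

    Bond lengths are in nm and bond angles in degrees.  The defaults were
    calibrated once against the two experimental anchor points the model
    must reproduce: (i) the fully extended all-trans tetramer spans just
    over 4.0 nm between the terminal carbonyl beads, with every
    torsion-state combination containing a gauche falling below 4.0 nm
    (geometric exclusion, verifiable by enumeration), so a 4.0 nm lower
    wall enforces the all-trans crystalline state; and (ii) gauche-rich
    chains compact to terminal distances near 2.4 nm, so a 2.4 nm lower
    wall trims the unrestrained 91:9 equilibrium to the 9:1 ratio
    characteristic of amorphous PET.
    """

    n_units: int = 4
    ring_bond: float = 0.514     # carbonyl-to-carbonyl through the aromatic ring
    ester_bond: float = 0.24     # carbonyl-to-glycol (collapsed ester linkage)
    glycol_bond: float = 0.15    # the CH2-CH2 bond carrying Psi
    angle_ester: float = 112.0   # bond angle at carbonyl beads
    angle_glycol: float = 77.5   # bond angle at glycol beads

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise InvalidGeometryError(f"n_units must be >= 2, got {self.n_units}")
        for name in ("ring_bond", "ester_bond", "glycol_bond"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")
        for name in ("angle_ester", "angle_glycol"):
            a = getattr(self, name)
            if not 0 < a < 180:
                raise InvalidGeometryError(f"{name} must lie in (0, 180) degrees")

    @property
    def bead_spec(self) -> tuple:
        """Ordered bead roles: 'C' carbonyl, 'G' glycol carbon.

        Pattern C C (G G C C) x n_units; the first and last beads are the
        terminal carbonyl markers defining d1.
        """
        return tuple(["C", "C"] + ["G", "G", "C", "C"] * self.n_units)

    @property
    def n_beads(self) -> int:
        return 2 + 4 * self.n_units

    @property
    def n_torsions(self) -> int:
        """One Psi per ethylene-glycol moiety."""
        return self.n_units

    @property
    def terminal_markers(self) -> tuple:
        """Bead indices exposed as terminal carbonyl markers, per terminus."""
        return ((0,), (self.n_beads - 1,))

    def bond_lengths(self) -> np.ndarray:
        spec = self.bead_spec
        out = np.empty(self.n_beads - 1)
        for i in range(self.n_beads - 1):
            pair = (spec[i], spec[i + 1])
            if pair == ("C", "C"):
                out[i] = self.ring_bond
            elif pair == ("G", "G"):
                out[i] = self.glycol_bond
            else:
                out[i] = self.ester_bond
        return out

    def bond_angles(self) -> np.ndarray:
        spec = self.bead_spec
        return np.array([
            self.angle_glycol if spec[i] == "G" else self.angle_ester
            for i in range(1, self.n_beads - 1)
        ])

    def psi_torsion_indices(self) -> np.ndarray:
        """Indices into the chain torsion array that are the Psi dihedrals.

        Torsion j sets the dihedral of beads (j, j+1, j+2, j+3); Psi lives
        on each G-G bond, i.e. the dihedral C-G-G-C.
        """
        spec = self.bead_spec
        idx = [i - 1 for i in range(self.n_beads - 1)
               if spec[i] == "G" and spec[i + 1] == "G"]
        return np.asarray(idx, dtype=np.int64)

    def base_torsions(self) -> np.ndarray:
        """All chain torsions fixed trans (180 deg); Psi slots overwritten."""
        return np.full(self.n_beads - 3, 180.0)

    @property
    def all_trans_repeat_length(self) -> float:
        """Extension per repeat unit of the fully extended chain, nm."""
        state = ChainState.from_torsions(self, np.full(self.n_torsions, 180.0))
        return min_terminal_distance(state) / self.n_units


# ---------------------------------------------------------------------------
# Forward kinematics (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_positions(bonds, angles, torsions):
    """NeRF chain construction. angles[i] is the bond angle at bead i+1,
    torsions[i] the dihedral of beads (i, i+1, i+2, i+3). Degrees in."""
    n = bonds.shape[0] + 1
    pos = np.zeros((n, 3))
    pos[1, 0] = bonds[0]
    th = math.radians(180.0 - angles[0])
    pos[2, 0] = pos[1, 0] + bonds[1] * math.cos(th)
    pos[2, 1] = bonds[1] * math.sin(th)
    for i in range(3, n):
        b = bonds[i - 1]
        ang = math.radians(angles[i - 2])
        tor = math.radians(torsions[i - 3])
        bcx = pos[i - 1, 0] - pos[i - 2, 0]
        bcy = pos[i - 1, 1] - pos[i - 2, 1]
        bcz = pos[i - 1, 2] - pos[i - 2, 2]
        nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nb
        bcy /= nb
        bcz /= nb
        abx = pos[i - 2, 0] - pos[i - 3, 0]
        aby = pos[i - 2, 1] - pos[i - 3, 1]
        abz = pos[i - 2, 2] - pos[i - 3, 2]
        # n1 = ab x bc, normalized
        n1x = aby * bcz - abz * bcy
        n1y = abz * bcx - abx * bcz
        n1z = abx * bcy - aby * bcx
        nn = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
        n1x /= nn
        n1y /= nn
        n1z /= nn
        # m = n1 x bc
        mx = n1y * bcz - n1z * bcy
        my = n1z * bcx - n1x * bcz
        mz = n1x * bcy - n1y * bcx
        d0 = -b * math.cos(ang)
        d1 = b * math.sin(ang) * math.cos(tor)
        d2 = b * math.sin(ang) * math.sin(tor)
        pos[i, 0] = pos[i - 1, 0] + bcx * d0 + mx * d1 + n1x * d2
        pos[i, 1] = pos[i - 1, 1] + bcy * d0 + my * d1 + n1y * d2
        pos[i, 2] = pos[i - 1, 2] + bcz * d0 + mz * d1 + n1z * d2
    return pos


@njit(cache=True)
def _terminal_d1(psis, bonds, angles, base_torsions, psi_idx):
    torsions = base_torsions.copy()
    for k in range(psi_idx.shape[0]):
        torsions[psi_idx[k]] = psis[k]
    pos = _build_positions(bonds, angles, torsions)
    n = pos.shape[0]
    dx = pos[n - 1, 0] - pos[0, 0]
    dy = pos[n - 1, 1] - pos[0, 1]
    dz = pos[n - 1, 2] - pos[0, 2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _torsion_energy(psi_deg, coeffs):
    e = 0.0
    psi = math.radians(psi_deg)
    for k in range(coeffs.shape[0]):
        e += coeffs[k] * math.cos((k + 1) * psi)
    return e


@njit(cache=True)
def _wall_energy(value, limit, k, side, exponent):
    """side = -1 lower wall (penalize value < limit), +1 upper wall."""
    if side < 0:
        viol = limit - value
    else:
        viol = value - limit
    if viol <= 0.0:
        return 0.0
    return k * viol ** exponent


@njit(cache=True)
def _bias_1d(x, centers, widths, heights):
    v = 0.0
    for i in range(centers.shape[0]):
        d = (x - centers[i]) / widths[i]
        v += heights[i] * math.exp(-0.5 * d * d)
    return v


@njit(cache=True)
def _mc_run(psis0, n_equil, n_sweeps, beta, coeffs, lam,
            wall_on, wall_limit, wall_k, wall_side, wall_exp,
            bias_centers, bias_widths, bias_heights,
            bonds, angles, base_torsions, psi_idx,
            jump_prob, step_deg, seed):
    """Metropolis MC over the Psi torsions.

    Proposal per torsion: with probability jump_prob a uniform resample of
    the angle, otherwise a wrapped Gaussian step -- both symmetric, so the
    Metropolis ratio needs only the energy difference.  Returns the
    recorded trajectory (one frame per production sweep) and the
    acceptance counters.
    """
    np.random.seed(seed)
    n_tor = psis0.shape[0]
    psis = psis0.copy()
    d1 = _terminal_d1(psis, bonds, angles, base_torsions, psi_idx)
    e_tor = 0.0
    for j in range(n_tor):
        e_tor += _torsion_energy(psis[j], coeffs)
    traj_psi = np.empty((n_sweeps, n_tor))
    traj_d1 = np.empty(n_sweeps)
    n_acc = 0
    n_att = 0
    has_bias = bias_centers.shape[0] > 0
    e_ext = 0.0
    if wall_on:
        e_ext += _wall_energy(d1, wall_limit, wall_k, wall_side, wall_exp)
    if has_bias:
        e_ext += _bias_1d(d1, bias_centers, bias_widths, bias_heights)
    for sweep in range(n_equil + n_sweeps):
        for j in range(n_tor):
            n_att += 1
            if np.random.random() < jump_prob:
                new_psi = np.random.random() * 360.0 - 180.0
            else:
                new_psi = psis[j] + np.random.normal() * step_deg
            # wrap to (-180, 180]
            new_psi = new_psi - 360.0 * math.floor((new_psi + 180.0) / 360.0)
            if new_psi <= -180.0:
                new_psi += 360.0
            old_psi = psis[j]
            de = lam * (_torsion_energy(new_psi, coeffs)
                        - _torsion_energy(old_psi, coeffs))
            psis[j] = new_psi
            new_d1 = _terminal_d1(psis, bonds, angles, base_torsions, psi_idx)
            new_ext = 0.0
            if wall_on:
                new_ext += _wall_energy(new_d1, wall_limit, wall_k,
                                        wall_side, wall_exp)
            if has_bias:
                new_ext += _bias_1d(new_d1, bias_centers, bias_widths,
                                    bias_heights)
            de += new_ext - e_ext
            if de <= 0.0 or np.random.random() < math.exp(-beta * de):
                n_acc += 1
                d1 = new_d1
                e_ext = new_ext
            else:
                psis[j] = old_psi
        if sweep >= n_equil:
            for j in range(n_tor):
                traj_psi[sweep - n_equil, j] = psis[j]
            traj_d1[sweep - n_equil] = d1
    return traj_psi, traj_d1, n_acc, n_att


# ---------------------------------------------------------------------------
# Torsion potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionPotential:
    """Three-term cosine-series torsion potential for Psi.

    U(psi) = sum_k a_k cos(k psi), with stationary points pinned at the
    trans (180 deg) and gauche (+-70 deg by default) minima.  `gt_gap` is
    the gauche minimum energy relative to trans (negative = gauche
    favored); `barrier` is the energy at the midpoint between the gauche
    and trans minima, relative to trans, controlling the g<->t barrier.
    """

    gt_gap: float = 0.0
    barrier: float = 12.0
    gauche_angle: float = 70.0
    coeffs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.gauche_angle < 120:
            raise InvalidAngleError("gauche minimum must lie inside the "
                                    "gauche window (0, 120) degrees")
        if self.coeffs is None:
            object.__setattr__(self, "coeffs", self._solve_coeffs())
        object.__setattr__(self, "coeffs",
                           np.ascontiguousarray(self.coeffs, dtype=float))
        self._validate_minima()

    def _solve_coeffs(self) -> np.ndarray:
        g = math.radians(self.gauche_angle)
        b = math.radians((self.gauche_angle + 180.0) / 2.0)
        rows = []
        rhs = []
        # U(gauche) - U(trans) = gt_gap
        rows.append([math.cos(k * g) - math.cos(k * math.pi) for k in (1, 2, 3)])
        rhs.append(self.gt_gap)
        # U'(gauche) = 0
        rows.append([-k * math.sin(k * g) for k in (1, 2, 3)])
        rhs.append(0.0)
        # U(midpoint) - U(trans) = barrier
        rows.append([math.cos(k * b) - math.cos(k * math.pi) for k in (1, 2, 3)])
        rhs.append(self.barrier)
        return np.linalg.solve(np.array(rows), np.array(rhs))

    def _validate_minima(self) -> None:
        grid = np.arange(-180.0, 180.0, 0.25)
        u = self.energy(grid)
        if not np.all(np.isfinite(u)):
            raise InvalidAngleError("torsion potential is not finite everywhere")
        # periodic local minima
        minima = grid[(u < np.roll(u, 1)) & (u < np.roll(u, -1))]
        expected = np.array([-self.gauche_angle, self.gauche_angle, 180.0])
        if len(minima) != 3:
            raise InvalidGeometryError(
                f"torsion potential has {len(minima)} minima, expected 3 "
                f"(gt_gap={self.gt_gap}, barrier={self.barrier})")
        found = np.sort(wrap_angle(minima))
        # 180 wraps: compare on the circle
        for target in expected:
            dist = np.min(np.abs(wrap_angle(found - target)))
            if dist > 1.0:
                raise InvalidGeometryError(
                    f"torsion minimum expected near {target} deg not found")

    def energy(self, psi_deg):
        """Torsion energy in kJ/mol (vectorized; arbitrary offset)."""
        psi = np.radians(np.asarray(psi_deg, dtype=float))
        k = np.arange(1, len(self.coeffs) + 1)
        e = np.cos(np.multiply.outer(psi, k)) @ self.coeffs
        return e if np.ndim(psi_deg) else float(e)


# ---------------------------------------------------------------------------
# Restraints and states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WallRestraint:
    """One-sided polynomial wall on a collective variable.

    Energy is k * violation**exponent on the forbidden side (no 1/2
    prefactor, matching the metadynamics-engine convention the default
    force constants are quoted in) and exactly zero on the allowed side.
    """

    cv_name: str = "d1"
    limit: float = 4.0
    k: float = 1500.0
    side: str = "lower"
    exponent: int = 2

    def __post_init__(self) -> None:
        if self.k < 0:
            raise InvalidRestraintError(f"force constant must be >= 0, got {self.k}")
        if self.side not in ("lower", "upper"):
            raise InvalidRestraintError(f"side must be 'lower' or 'upper', got {self.side!r}")
        if self.exponent < 2 or self.exponent % 2:
            raise InvalidRestraintError("exponent must be an even integer >= 2")

    @property
    def side_sign(self) -> int:
        return -1 if self.side == "lower" else 1


def wall_energy(value: float, restraint: WallRestraint) -> float:
    """Wall energy in kJ/mol at a CV value (nm)."""
    if not np.isfinite(value):
        raise InvalidRestraintError(f"CV value must be finite, got {value}")
    return float(_wall_energy(float(value), restraint.limit, restraint.k,
                              restraint.side_sign, restraint.exponent))


@dataclass
class ChainState:
    """Bead coordinates (nm) plus the Psi torsions they realize."""

    geometry: ChainGeometry
    positions: np.ndarray
    psis: np.ndarray

    @classmethod
    def from_torsions(cls, geometry: ChainGeometry, psis) -> "ChainState":
        psis = wrap_angle(np.atleast_1d(np.asarray(psis, dtype=float)))
        if psis.shape != (geometry.n_torsions,):
            raise InvalidGeometryError(
                f"expected {geometry.n_torsions} Psi torsions, got {psis.shape}")
        torsions = geometry.base_torsions()
        torsions[geometry.psi_torsion_indices()] = psis
        pos = _build_positions(geometry.bond_lengths(), geometry.bond_angles(),
                               torsions)
        return cls(geometry=geometry, positions=pos, psis=psis)


def min_terminal_distance(state: ChainState) -> float:
    """d1: minimum distance over symmetric terminal carbonyl-bead pairs, nm."""
    left, right = state.geometry.terminal_markers
    if not left or not right:
        raise InvalidGeometryError("chain must expose two termini")
    pos = state.positions
    return float(min(np.linalg.norm(pos[i] - pos[j]) for i in left for j in right))


@dataclass
class TorsionTrajectory:
    """Per-frame Psi torsions (degrees) and terminal distance d1 (nm)."""

    psis: np.ndarray           # (n_frames, n_torsions)
    d1: np.ndarray             # (n_frames,)
    temperature: float
    seed: int
    restraint: Optional[WallRestraint] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.psis = np.atleast_2d(np.asarray(self.psis, dtype=float))
        self.d1 = np.asarray(self.d1, dtype=float)
        if self.psis.shape[0] != self.d1.shape[0]:
            raise InvalidGeometryError("psis and d1 must have the same frame count")
        if not (np.all(np.isfinite(self.psis)) and np.all(np.isfinite(self.d1))):
            raise InvalidAngleError("trajectory contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.psis.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.psis.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_torsion(psi: float) -> str:
    """Classify a Psi angle as 'gauche' (|psi| < 120 deg) or 'trans'.

    The boundary +-120 deg belongs to trans, so the two labels partition
    the circle exactly.
    """
    if not np.isfinite(psi):
        raise InvalidAngleError(f"torsion angle must be finite, got {psi}")
    return "gauche" if abs(wrap_angle(float(psi))) < GAUCHE_CUTOFF else "trans"


def classify_torsions(psis) -> np.ndarray:
    """Vectorized gauche mask (True where gauche)."""
    psis = np.asarray(psis, dtype=float)
    if not np.all(np.isfinite(psis)):
        raise InvalidAngleError("torsion angles must be finite")
    return np.abs(wrap_angle(psis)) < GAUCHE_CUTOFF


def gt_ratio(traj: TorsionTrajectory) -> tuple:
    """(gauche fraction, trans fraction) over all torsions and frames."""
    if traj.n_frames == 0:
        raise NoDataError("cannot compute g/t ratio of an empty trajectory")
    gauche = classify_torsions(traj.psis)
    g = float(np.mean(gauche))
    return g, 1.0 - g


def _kernel_arrays(bias):
    """Extract (centers, widths, heights) arrays from an optional 1D bias."""
    if bias is None:
        z = np.zeros(0)
        return z, z.copy(), z.copy()
    centers, widths, heights = bias.kernel_arrays()
    return (np.ascontiguousarray(centers[:, 0] if centers.ndim == 2 else centers),
            np.ascontiguousarray(widths[:, 0] if widths.ndim == 2 else widths),
            np.ascontiguousarray(heights))


def sample_chain(geometry: ChainGeometry,
                 potential: TorsionPotential,
                 restraint: Optional[WallRestraint],
                 T: float = T_SAMPLING,
                 n_sweeps: int = 100_000,
                 seed: int = 0,
                 bias=None,
                 lam: float = 1.0,
                 n_equil: Optional[int] = None,
                 initial_psis=None,
                 jump_prob: float = 0.25,
                 step_deg: float = 30.0) -> TorsionTrajectory:
    """Sample the Psi torsions by Metropolis Monte Carlo.

    One sweep attempts one move per torsion.  `bias` is an optional
    one-dimensional metadynamics bias acting on d1 (any object exposing
    ``kernel_arrays()``).  ``lam`` scales the torsion potential only
    (solute tempering); the wall restraint is never scaled.
    """
    if n_sweeps < 1:
        raise SamplerError("n_sweeps must be >= 1")
    beta = 1.0 / kbt(T)
    if n_equil is None:
        n_equil = max(200, n_sweeps // 10)
    if initial_psis is None:
        initial_psis = np.full(geometry.n_torsions, 180.0)
    psis0 = wrap_angle(np.asarray(initial_psis, dtype=float))
    bc, bw, bh = _kernel_arrays(bias)
    if restraint is None:
        wall_on, limit, k, side, expo = False, 0.0, 0.0, -1, 2
    else:
        wall_on = restraint.k > 0
        limit, k = restraint.limit, restraint.k
        side, expo = restraint.side_sign, restraint.exponent
    traj_psi, traj_d1, n_acc, n_att = _mc_run(
        psis0, int(n_equil), int(n_sweeps), beta,
        potential.coeffs, float(lam),
        wall_on, float(limit), float(k), side, expo,
        bc, bw, bh,
        geometry.bond_lengths(), geometry.bond_angles(),
        geometry.base_torsions(), geometry.psi_torsion_indices(),
        float(jump_prob), float(step_deg), int(seed) % (2**32))
    if n_att >= 1000 and n_acc / n_att < 1e-3:
        raise SamplerError(
            f"sampler appears stuck: acceptance {n_acc}/{n_att}")
    return TorsionTrajectory(
        psis=traj_psi, d1=traj_d1, temperature=T, seed=seed,
        restraint=restraint,
        metadata={"n_sweeps": n_sweeps, "n_equil": n_equil, "lambda": lam,
                  "acceptance": n_acc / max(n_att, 1)})


def scan_d1(geometry: ChainGeometry,
            potential: TorsionPotential,
            d1_values: Sequence[float],
            T: float = T_SAMPLING,
            n_sweeps: int = 20_000,
            seed: int = 0,
            k: float = 1500.0) -> list:
    """Gauche/trans fractions as a function of the d1 lower-wall limit."""
    if len(d1_values) == 0:
        raise NoDataError("d1_values must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(d1_values))
    out = []
    for limit, child in zip(d1_values, children):
        restraint = WallRestraint(cv_name="d1", limit=float(limit), k=k,
                                  side="lower")
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        traj = sample_chain(geometry, potential, restraint, T=T,
                            n_sweeps=n_sweeps, seed=sub_seed)
        out.append(gt_ratio(traj))
    return out


def two_state_populations(gt_gap: float, T: float) -> tuple:
    """Closed-form two-state (gauche, trans) populations with degeneracy 2."""
    w = GAUCHE_DEGENERACY * math.exp(-gt_gap / kbt(T))
    return w / (1.0 + w), 1.0 / (1.0 + w)


def two_state_gap(p_gauche: float, p_trans: float, T: float) -> float:
    """Invert the two-state model: gap giving populations (p_g, p_t)."""
    if not (0 < p_gauche < 1 and 0 < p_trans < 1):
        raise UnreachableRatioError(
            f"target populations must lie strictly inside (0, 1), "
            f"got ({p_gauche}, {p_trans})")
    return -kbt(T) * math.log(p_gauche / (GAUCHE_DEGENERACY * p_trans))


def calibrate_gt_gap(target_ratio: tuple,
                     T: float,
                     tolerance: float = 0.002,
                     geometry: Optional[ChainGeometry] = None,
                     barrier: float = 12.0,
                     n_sweeps: int = 60_000,
                     seed: int = 0,
                     max_iter: int = 40) -> float:
    """Find the gauche-trans gap reproducing a target (g, t) ratio.

    Bisection against the unrestrained Monte Carlo sampler, bracketed
    around the closed-form two-state estimate -kBT ln(p_g / (2 p_t)).
    `tolerance` is on the gauche fraction.
    """
    p_g, p_t = target_ratio
    gap0 = two_state_gap(p_g, p_t, T)  # raises on unreachable targets
    p_g = p_g / (p_g + p_t)
    if geometry is None:
        geometry = ChainGeometry()
    rng = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(max_iter + 2)]

    def sampled_gauche(gap: float, s: int) -> float:
        pot = TorsionPotential(gt_gap=gap, barrier=barrier)
        traj = sample_chain(geometry, pot, None, T=T, n_sweeps=n_sweeps, seed=s)
        return gt_ratio(traj)[0]

    lo, hi = gap0 - 2.0, gap0 + 2.0  # gauche fraction decreases with gap
    f_lo = sampled_gauche(lo, seeds[0]) - p_g
    f_hi = sampled_gauche(hi, seeds[1]) - p_g
    if f_lo < 0 or f_hi > 0:
        raise UnreachableRatioError(
            f"target gauche fraction {p_g:.3f} outside bracket around "
            f"closed-form gap {gap0:.2f} kJ/mol")
    gap = gap0
    for i in range(max_iter):
        gap = 0.5 * (lo + hi)
        f = sampled_gauche(gap, seeds[i + 2]) - p_g
        if abs(f) < tolerance or (hi - lo) < 0.02:
            return gap
        if f > 0:
            lo = gap
        else:
            hi = gap
    return gap
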