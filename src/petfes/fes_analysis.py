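"""Reweighted free-energy surfaces and bound/unbound thermodynamics.

Biased trajectories are turned into unbiased statistics with the
final-bias (umbrella-like) estimator: each frame i receives a weight
w_i proportional to exp(+V_final(s_i)/kBT), where V_final is the fully
deposited metadynamics bias evaluated at the frame's biased collective
variables.  Free-energy surfaces are weighted histograms on a grid,
F = -kBT ln(p), shifted so the occupied minimum is zero; statistical
errors come from contiguous-block analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import kbt
from .errors import NoDataError, PetfesError

__all__ = [
    "CVTrajectory",
    "FESGrid",
    "StatePartition",
    "FreeEnergyResult",
    "frame_weights",
    "discard_transient",
    "make_fes",
    "block_error",
    "state_delta_f",
    "convergence_series",
    "delta_delta_f",
]

#: Column name holding the instantaneous metadynamics bias.
BIAS_COLUMN = "metad.bias"


@dataclass
class CVTrajectory:
    """Named per-frame collective variables plus optional bias energy.

    `data` holds a 'time' column, one column per CV (distances in nm,
    angles in degrees) and optionally a 'metad.bias' column in kJ/mol.
    `metadata` records temperature, lambda, and a system label
    (e.g. 'aPET', 'cPET', 'toy').
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time" not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, "time", np.arange(len(self.data), dtype=float))
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise PetfesError("CV trajectory contains non-finite values")

    @classmethod
    def from_columns(cls, metadata: Optional[dict] = None, **columns) -> "CVTrajectory":
        return cls(pd.DataFrame(columns), metadata=dict(metadata or {}))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def cv_names(self) -> tuple:
        return tuple(c for c in self.data.columns
                     if c not in ("time", BIAS_COLUMN))

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise NoDataError(f"trajectory has no column {name!r}; "
                              f"available: {list(self.data.columns)}")
        return self.data[name].to_numpy(dtype=float)

    def cv_matrix(self, names: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.column(n) for n in names])

    def slice(self, start: int = 0, stop: Optional[int] = None) -> "CVTrajectory":
        return CVTrajectory(self.data.iloc[start:stop].reset_index(drop=True),
                            metadata=dict(self.metadata))


@dataclass
class FESGrid:
    """Binned free-energy surface with block errors.

    `values` is F per bin in kJ/mol with the occupied minimum shifted to
    zero; unoccupied bins are NaN and flagged False in `occupied`.
    """

    edges: list                 # one edge array per CV dimension
    values: np.ndarray
    errors: Optional[np.ndarray] = None
    cv_names: tuple = ()
    normalization: str = "minimum shifted to 0"

    def __post_init__(self) -> None:
        occ = np.isfinite(self.values)
        if occ.any():
            vmin = np.nanmin(self.values)
            if abs(vmin) > 1e-9:
                raise PetfesError(f"FES minimum must be 0, got {vmin}")
        if self.errors is not None and np.any(self.errors[occ] < 0):
            raise PetfesError("FES errors must be non-negative")

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.values)

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class StatePartition:
    """Bound/unbound predicate on a single CV.

    Frames with the CV on `bound_side` of `threshold` are bound; frames
    exactly at the threshold count as bound.
    """

    cv_name: str = "d_COM"
    threshold: float = 3.0
    bound_side: str = "below"

    def __post_init__(self) -> None:
        if self.bound_side not in ("below", "above"):
            raise PetfesError("bound_side must be 'below' or 'above'")

    def bound_mask(self, values: np.ndarray) -> np.ndarray:
        if self.bound_side == "below":
            return values <= self.threshold
        return values >= self.threshold

    def descriptor(self) -> str:
        return f"{self.cv_name}:{self.bound_side}:{self.threshold:g}"


@dataclass(frozen=True)
class FreeEnergyResult:
    """A bound-minus-unbound free-energy difference with its error."""

    delta_f: float              # kJ/mol
    error: float                # kJ/mol, >= 0
    window: str = "full"
    system: str = ""
    temperature: float = float("nan")
    partition: str = ""

    def __post_init__(self) -> None:
        if self.error < 0:
            raise PetfesError("error must be non-negative")


# ---------------------------------------------------------------------------
# Reweighting
# ---------------------------------------------------------------------------

def frame_weights(traj: CVTrajectory, bias, T: float,
                  cv_names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Per-frame unbiasing weights from the final deposited bias.

    w_i proportional to exp(+V_final(s_i)/kBT), normalized to sum to 1.
    `bias` is any object exposing ``evaluate_many(points)`` (a
    MetadBias); pass None for an unbiased trajectory (uniform weights).
    """
    if traj.n_frames == 0:
        raise NoDataError("cannot weight an empty trajectory")
    if bias is None:
        return np.full(traj.n_frames, 1.0 / traj.n_frames)
    names = tuple(cv_names) if cv_names is not None else tuple(bias.cv_names)
    points = traj.cv_matrix(names)
    v = np.asarray(bias.evaluate_many(points), dtype=float)
    logw = v / kbt(T)
    logw -= logw.max()          # shift invariance of normalized weights
    w = np.exp(logw)
    return w / w.sum()


def discard_transient(traj: CVTrajectory, weights: np.ndarray,
                      fraction: float = 0.2) -> tuple:
    """Drop the first `fraction` of frames and renormalize the weights."""
    if not 0 <= fraction < 1:
        raise PetfesError("transient fraction must lie in [0, 1)")
    start = int(round(fraction * traj.n_frames))
    sub = traj.slice(start)
    w = np.asarray(weights, dtype=float)[start:]
    if w.sum() <= 0:
        raise NoDataError("no weight left after transient discard")
    return sub, w / w.sum()


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

def _weighted_hist(points: np.ndarray, weights: np.ndarray, bins) -> tuple:
    ndim = points.shape[1]
    if np.isscalar(bins) or (isinstance(bins, np.ndarray) and bins.ndim == 1):
        bins = [bins] * ndim
    hist, edges = np.histogramdd(points, bins=list(bins), weights=weights)
    return hist, [np.asarray(e) for e in edges]


def make_fes(traj: CVTrajectory, weights: np.ndarray,
             cv_names: Sequence[str], bins, T: float,
             errors: Optional[np.ndarray] = None) -> FESGrid:
    """Weighted free-energy surface over one or two CVs.

    F(bin) = -kBT ln(sum of weights in bin), shifted so the occupied
    minimum is zero; empty bins are NaN.
    """
    cv_names = tuple(cv_names)
    if not 1 <= len(cv_names) <= 2:
        raise PetfesError("make_fes supports 1 or 2 CVs")
    w = np.asarray(weights, dtype=float)
    if w.shape != (traj.n_frames,):
        raise PetfesError("weights must have one entry per frame")
    if w.sum() <= 0:
        raise NoDataError("total weight is zero")
    points = traj.cv_matrix(cv_names)
    hist, edges = _weighted_hist(points, w, bins)
    with np.errstate(divide="ignore"):
        f = -kbt(T) * np.log(hist)
    f[hist <= 0] = np.nan
    f -= np.nanmin(f)
    return FESGrid(edges=edges, values=f, errors=errors, cv_names=cv_names)


def block_error(traj: CVTrajectory, weights: np.ndarray, cv_name: str,
                bins, T: float, n_blocks: int = 5) -> np.ndarray:
    """Per-bin standard error of the 1D FES from contiguous blocks.

    The trajectory is split into `n_blocks` contiguous equal blocks
    (remainder frames join the last block); the per-bin spread of the
    block-wise free energies gives the standard error.  Bins empty in
    some block get NaN.
    """
    if n_blocks < 2:
        raise PetfesError(f"n_blocks must be >= 2, got {n_blocks}")
    if traj.n_frames < n_blocks:
        raise NoDataError("fewer frames than blocks")
    x = traj.column(cv_name)
    w = np.asarray(weights, dtype=float)
    edges = np.histogram_bin_edges(x, bins=bins)
    size = traj.n_frames // n_blocks
    block_f = []
    for b in range(n_blocks):
        lo = b * size
        hi = (b + 1) * size if b < n_blocks - 1 else traj.n_frames
        hist, _ = np.histogram(x[lo:hi], bins=edges, weights=w[lo:hi])
        tot = hist.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            f = -kbt(T) * np.log(hist / tot)
        f[hist <= 0] = np.nan
        block_f.append(f)
    block_f = np.array(block_f)
    # align blocks on their weighted mean over commonly occupied bins
    common = np.all(np.isfinite(block_f), axis=0)
    if common.any():
        block_f -= block_f[:, common].mean(axis=1, keepdims=True)
    err = np.std(block_f, axis=0, ddof=1) / math.sqrt(n_blocks)
    err[~common] = np.nan
    return err


# ---------------------------------------------------------------------------
# State integration
# ---------------------------------------------------------------------------

def _delta_f_from_masks(w: np.ndarray, bound: np.ndarray, T: float) -> float:
    wb = w[bound].sum()
    wu = w[~bound].sum()
    if wb <= 0 or wu <= 0:
        raise NoDataError("both bound and unbound regions need weight; "
                          f"got bound={wb:g}, unbound={wu:g}")
    return -kbt(T) * math.log(wb / wu)


def state_delta_f(traj: CVTrajectory, weights: np.ndarray,
                  partition: StatePartition, T: float,
                  n_blocks: int = 5) -> FreeEnergyResult:
    """Bound-minus-unbound free energy from Boltzmann-weighted populations.

    dF = -kBT ln(W_bound / W_unbound); the error is the contiguous-block
    standard error of dF (blocks missing one of the regions are skipped).
    """
    x = traj.column(partition.cv_name)
    w = np.asarray(weights, dtype=float)
    bound = partition.bound_mask(x)
    df = _delta_f_from_masks(w, bound, T)
    errs = []
    size = max(traj.n_frames // n_blocks, 1)
    for b in range(n_blocks):
        lo = b * size
        hi = (b + 1) * size if b < n_blocks - 1 else traj.n_frames
        if lo >= traj.n_frames:
            break
        try:
            errs.append(_delta_f_from_masks(w[lo:hi], bound[lo:hi], T))
        except NoDataError:
            continue
    error = (float(np.std(errs, ddof=1) / math.sqrt(len(errs)))
             if len(errs) >= 2 else 0.0)
    return FreeEnergyResult(delta_f=df, error=error,
                            system=str(traj.metadata.get("system", "")),
                            temperature=T, partition=partition.descriptor())


def convergence_series(traj: CVTrajectory, weights: np.ndarray,
                       partition: StatePartition, window: int, stride: int,
                       T: float) -> list:
    """dF on growing trajectory prefixes.

    Prefixes of length window, window+stride, ... up to the full
    trajectory (always included), mirroring a free-energy-vs-accumulated-
    time convergence plot.
    """
    if stride <= 0:
        raise PetfesError(f"stride must be positive, got {stride}")
    if not 1 <= window <= traj.n_frames:
        raise PetfesError("window must lie in [1, n_frames]")
    x = traj.column(partition.cv_name)
    w = np.asarray(weights, dtype=float)
    bound = partition.bound_mask(x)
    ends = list(range(window, traj.n_frames + 1, stride))
    if ends[-1] != traj.n_frames:
        ends.append(traj.n_frames)
    out = []
    for end in ends:
        df = _delta_f_from_masks(w[:end], bound[:end], T)
        out.append(FreeEnergyResult(
            delta_f=df, error=0.0, window=f"frames[0:{end}]",
            system=str(traj.metadata.get("system", "")),
            temperature=T, partition=partition.descriptor()))
    # the final entry carries the full-trajectory block error
    out[-1] = state_delta_f(traj, weights, partition, T)
    return out


def delta_delta_f(result_a: FreeEnergyResult,
                  result_b: FreeEnergyResult) -> FreeEnergyResult:
    """Relative free-energy difference dF_a - dF_b with quadrature error."""
    if not math.isclose(result_a.temperature, result_b.temperature,
                        rel_tol=1e-9):
        raise PetfesError("cannot subtract results at different temperatures")
    if result_a.partition != result_b.partition:
        raise PetfesError("cannot subtract results with different partitions")
    return FreeEnergyResult(
        delta_f=result_a.delta_f - result_b.delta_f,
        error=math.hypot(result_a.error, result_b.error),
        window=f"({result_a.window})-({result_b.window})",
        system=f"{result_a.system}-{result_b.system}",
        temperature=result_a.temperature,
        partition=result_a.partition)
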